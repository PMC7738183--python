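"""Fluorescence correlation spectroscopy sizing and diameter-mixture analysis.

The FCS autocorrelation of freely diffusing fluorescent particles in a 3-D
Gaussian confocal volume decays on the diffusion time scale
``tau_d = omega_r**2 / (4 D)``.  Fitting ``G(tau)`` therefore yields the
diffusion coefficient ``D``, which the Stokes-Einstein relation

    R_h = k_B T / (6 pi eta(T) D)

converts to a hydrodynamic radius once the water viscosity ``eta(T)`` at the
recorded sample temperature is known.  Viscosity follows the empirical Vogel
equation ``eta(T) = exp(A + B / (C + T))`` with temperature in Kelvin.

Fast multiplicative components from fluorophore dark states (blinking and
triplet kinetics) are modelled as exponential relaxations multiplying the
diffusive part of the correlation.

Diameter distributions (e.g. from cryo-EM particle measurements) are analysed
as one- or two-component Gaussian mixtures fitted by expectation-maximization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "K_BOLTZMANN",
    "VOGEL_A",
    "VOGEL_B",
    "VOGEL_C",
    "FcsCurve",
    "FcsFit",
    "Calibration",
    "RhResult",
    "MixtureFit",
    "fcs_model",
    "fit_curve",
    "select_fcs_model",
    "calibrate",
    "viscosity",
    "stokes_einstein",
    "diffusion_coefficient",
    "aggregate_rh",
    "summarize_diameters",
    "fit_diameter_mixture",
]

K_BOLTZMANN = 1.380649e-23  # J/K (exact, SI)

# Vogel viscosity parameters for water, eta in mPa*s, T in K.
VOGEL_A = -3.72
VOGEL_B = 578.919  # K
VOGEL_C = -137.546  # K

#: Supported temperature range for the Vogel parametrisation, K.
VOGEL_T_RANGE = (278.0, 320.0)


@dataclass
class FcsCurve:
    """A measured or simulated autocorrelation curve.

    Attributes
    ----------
    tau : ndarray
        Lag times, s; strictly increasing and positive.
    g : ndarray
        Autocorrelation values ``G(tau)`` (baseline 1 at long lags).
    temperature : float
        Sample temperature during the run, K.
    duration : float
        Acquisition duration, s.
    """

    tau: np.ndarray
    g: np.ndarray
    temperature: float = 298.15
    duration: float = 30.0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.tau.ndim != 1 or self.tau.size < 2:
            raise ValueError("tau must be a 1-D array with at least 2 points")
        if np.any(self.tau <= 0) or np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be positive and strictly increasing")
        if self.g.shape != self.tau.shape or not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite and match tau in shape")


@dataclass
class Calibration:
    """Confocal-volume calibration: lateral and axial 1/e^2 focus radii, m."""

    omega_r: float
    omega_z: float

    @property
    def structure(self) -> float:
        return self.omega_z / self.omega_r


@dataclass
class FcsFit:
    """Fitted parameters of the blinking (optionally + triplet) diffusion model."""

    f: np.ndarray          # mean occupancies per diffusing component
    n: np.ndarray          # molecular brightnesses per component
    tau_d: np.ndarray      # diffusion times, s
    omega_r: float         # lateral focus radius, m
    omega_z: float         # axial focus radius, m
    t_b: float             # blinking fraction
    tau_b: float           # blinking relaxation time, s
    t_t: float = 0.0       # triplet fraction
    tau_t: float = 0.0     # triplet relaxation time, s
    model: str = "blink"
    temperature: float = 298.15
    rss: float = np.nan
    n_obs: int = 0

    @property
    def d(self) -> float:
        """Diffusion coefficient of the first component, m^2/s."""
        return self.omega_r**2 / (4.0 * float(self.tau_d[0]))

    @property
    def n_params(self) -> int:
        base = 2 * len(self.tau_d) + 2  # (f, tau_d) per component + blink pair
        return base + (2 if self.model == "blink_triplet" else 0)

    def aicc(self) -> float:
        """Gaussian AICc from the residual sum of squares."""
        n, k = self.n_obs, self.n_params
        aic = n * math.log(self.rss / n) + 2 * k
        if n - k - 1 > 0:
            aic += 2.0 * k * (k + 1) / (n - k - 1)
        return aic


@dataclass
class RhResult:
    """Run-averaged hydrodynamic radius."""

    rh_runs: np.ndarray  # per-run radii, m
    mean: float
    sd: float
    k_boltzmann: float = K_BOLTZMANN

    @property
    def diameter_nm(self) -> float:
        return 2.0 * self.mean * 1e9


def viscosity(temperature: float | np.ndarray) -> float | np.ndarray:
    """Water viscosity eta(T) in mPa*s via the Vogel equation.

    ``eta = exp(A + B/(C + T))`` with T in Kelvin.  Raises outside the
    supported range where the parametrisation was established.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t + VOGEL_C <= 0):
        raise ValueError("temperature must satisfy C + T > 0 (T in Kelvin)")
    if np.any((t < VOGEL_T_RANGE[0]) | (t > VOGEL_T_RANGE[1])):
        raise ValueError(
            f"temperature {temperature} K outside supported range {VOGEL_T_RANGE}"
        )
    eta = np.exp(VOGEL_A + VOGEL_B / (VOGEL_C + t))
    return float(eta) if np.isscalar(temperature) else eta


def stokes_einstein(d: float, temperature: float) -> float:
    """Hydrodynamic radius R_h (m) from diffusion coefficient (m^2/s) at T (K)."""
    if d <= 0:
        raise ValueError("diffusion coefficient must be positive")
    eta_pa_s = viscosity(temperature) * 1e-3
    return K_BOLTZMANN * temperature / (6.0 * math.pi * eta_pa_s * d)


def diffusion_coefficient(rh: float, temperature: float) -> float:
    """Inverse of :func:`stokes_einstein`: D (m^2/s) from R_h (m)."""
    if rh <= 0:
        raise ValueError("hydrodynamic radius must be positive")
    eta_pa_s = viscosity(temperature) * 1e-3
    return K_BOLTZMANN * temperature / (6.0 * math.pi * eta_pa_s * rh)


def fcs_model(
    tau: np.ndarray,
    *,
    f: np.ndarray | float,
    n: np.ndarray | float = 1.0,
    tau_d: np.ndarray | float,
    omega_ratio: float,
    t_b: float = 0.0,
    tau_b: float = 1e-3,
    t_t: float = 0.0,
    tau_t: float = 1e-5,
) -> np.ndarray:
    """Autocorrelation of 3-D diffusion with blinking (and optional triplet).

    ``G(tau) = 1 + [sum_i f_i n_i^2 X_i(tau)] / (sum_i f_i n_i)^2 * B(tau) * T(tau)``

    with the 3-D Gaussian-volume diffusion factor
    ``X_i = (1 + tau/tau_d_i)^-1 (1 + (tau/tau_d_i)(omega_r/omega_z)^2)^-1/2``
    and dark-state factors ``B = 1 + T_b e^(-tau/tau_b)/(1 - T_b)`` (likewise
    for the triplet with T_t, tau_t).  The occupancies ``f_i`` are mean
    molecule numbers, so for a single species the zero-lag amplitude is
    ``G(0) - 1 = 1/f``.

    Parameters
    ----------
    omega_ratio : float
        ``omega_r / omega_z`` (< 1 for an elongated confocal volume).
    """
    tau = np.asarray(tau, dtype=float)
    f = np.atleast_1d(np.asarray(f, dtype=float))
    n = np.broadcast_to(np.atleast_1d(np.asarray(n, dtype=float)), f.shape)
    tau_d = np.atleast_1d(np.asarray(tau_d, dtype=float))
    if not (0.0 <= t_b < 1.0 and 0.0 <= t_t < 1.0):
        raise ValueError("dark-state fractions must lie in [0, 1)")
    if np.any(tau_d <= 0):
        raise ValueError("diffusion times must be positive")

    x = tau[:, None] / tau_d[None, :]
    diff = 1.0 / (1.0 + x) / np.sqrt(1.0 + x * omega_ratio**2)
    num = np.sum(f * n**2 * diff, axis=1)
    den = np.sum(f * n) ** 2
    g = num / den
    if t_b > 0:
        g = g * (1.0 + t_b * np.exp(-tau / tau_b) / (1.0 - t_b))
    if t_t > 0:
        g = g * (1.0 + t_t * np.exp(-tau / tau_t) / (1.0 - t_t))
    return 1.0 + g


def _fit_correlation(
    curve: FcsCurve,
    omega_ratio: float,
    with_blink: bool,
    with_triplet: bool,
    fit_structure: bool = False,
    n_starts: int = 6,
    seed: int = 0,
) -> dict:
    """Multi-start least squares on G(tau)-1.  Returns best parameter dict."""
    tau, y = curve.tau, curve.g - 1.0
    amp0 = max(float(np.max(y)), 1e-6)
    # lag where the decay first falls to half its initial amplitude
    below = np.nonzero(y <= 0.5 * amp0)[0]
    tau_half = tau[below[0]] if below.size else tau[len(tau) // 2]

    rng = np.random.default_rng(seed)
    starts = []
    for mult in (1.0, 0.3, 3.0, 10.0, 0.1, 1.0)[: max(n_starts, 1)]:
        jit = 1.0 if mult == 1.0 else float(rng.uniform(0.8, 1.2))
        starts.append(
            {
                "f": 1.0 / amp0,
                "tau_d": tau_half * mult * jit,
                "t_b": 0.2 if with_blink else 0.0,
                "tau_b": max(tau_half / 30.0, tau[0] * 3),
                "t_t": 0.1 if with_triplet else 0.0,
                "tau_t": max(tau_half / 300.0, tau[0]),
                "s": 1.0 / omega_ratio,
            }
        )

    names = ["f", "tau_d"]
    lo = [1e-6, tau[0] / 10.0]
    hi = [1e9, tau[-1] * 10.0]
    if with_blink:
        names += ["t_b", "tau_b"]
        lo += [0.0, tau[0] / 10.0]
        hi += [0.95, tau[-1]]
    if with_triplet:
        names += ["t_t", "tau_t"]
        lo += [0.0, tau[0] / 10.0]
        hi += [0.95, tau[-1]]
    if fit_structure:
        names += ["s"]
        lo += [1.5]
        hi += [50.0]

    def unpack(theta):
        p = dict(zip(names, theta))
        return p

    def resid(theta, start):
        p = {**start, **unpack(theta)}
        g = fcs_model(
            tau,
            f=p["f"],
            tau_d=p["tau_d"],
            omega_ratio=1.0 / p["s"] if fit_structure else omega_ratio,
            t_b=p["t_b"],
            tau_b=p["tau_b"],
            t_t=p["t_t"],
            tau_t=p["tau_t"],
        )
        return g - 1.0 - y

    best = None
    for start in starts:
        theta0 = np.clip([start[k] for k in names], lo, hi)
        try:
            sol = least_squares(
                resid,
                theta0,
                args=(start,),
                bounds=(lo, hi),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=5000,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best["rss"] - 1e-30:
            best = {**start, **unpack(sol.x), "rss": rss, "success": sol.success}
    if best is None:
        raise RuntimeError("FCS fit failed to converge from all starts")
    return best


def fit_curve(
    curve: FcsCurve,
    model: str = "blink",
    calibration: Calibration | None = None,
    n_starts: int = 6,
    seed: int = 0,
) -> FcsFit:
    """Fit a single-species diffusion model with blinking (+ optional triplet).

    The structure parameter ``omega_z/omega_r`` is fixed from the calibration;
    free parameters are the mean occupancy, the diffusion time and the
    dark-state fractions/relaxation times.  Brightness cancels for a single
    species and is fixed at 1.
    """
    if model not in ("blink", "blink_triplet"):
        raise ValueError(f"unknown model {model!r}")
    if calibration is None:
        raise ValueError("a confocal-volume calibration is required")
    if len(curve.tau) < (7 if model == "blink_triplet" else 5):
        raise ValueError("curve has fewer points than free parameters")
    p = _fit_correlation(
        curve,
        omega_ratio=1.0 / calibration.structure,
        with_blink=True,
        with_triplet=(model == "blink_triplet"),
        n_starts=n_starts,
        seed=seed,
    )
    return FcsFit(
        f=np.array([p["f"]]),
        n=np.array([1.0]),
        tau_d=np.array([p["tau_d"]]),
        omega_r=calibration.omega_r,
        omega_z=calibration.omega_z,
        t_b=p["t_b"],
        tau_b=p["tau_b"],
        t_t=p["t_t"],
        tau_t=p["tau_t"],
        model=model,
        temperature=curve.temperature,
        rss=p["rss"],
        n_obs=len(curve.tau),
    )


def select_fcs_model(fit_blink: FcsFit, fit_triplet: FcsFit) -> FcsFit:
    """Choose the triplet-augmented model only if AICc improves by >= 2."""
    if fit_triplet.aicc() <= fit_blink.aicc() - 2.0:
        return fit_triplet
    return fit_blink


def calibrate(
    curve: FcsCurve, d_ref: float, temperature: float | None = None
) -> Calibration:
    """Calibrate the confocal volume from a reference-dye correlation curve.

    Fits a diffusion-only single-species model with a free structure
    parameter; with the dye's known diffusion coefficient ``d_ref`` (m^2/s)
    the lateral focus radius follows as ``omega_r = sqrt(4 d_ref tau_d)``.
    """
    if d_ref <= 0:
        raise ValueError("reference diffusion coefficient must be positive")
    p = _fit_correlation(
        curve,
        omega_ratio=0.2,
        with_blink=False,
        with_triplet=False,
        fit_structure=True,
    )
    omega_r = math.sqrt(4.0 * d_ref * p["tau_d"])
    return Calibration(omega_r=omega_r, omega_z=p["s"] * omega_r)


def aggregate_rh(fits: list[FcsFit]) -> RhResult:
    """Average hydrodynamic radii across runs, each at its own temperature.

    Converting each run with its own recorded temperature (through the Vogel
    viscosity) before averaging removes run-to-run thermal variation from the
    reported radius.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 runs to aggregate")
    rh = np.array([stokes_einstein(f.d, f.temperature) for f in fits])
    return RhResult(rh_runs=rh, mean=float(np.mean(rh)), sd=float(np.std(rh, ddof=1)))


def summarize_diameters(diameters: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and sample SD of a diameter list."""
    d = np.asarray(diameters, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 diameters")
    return float(np.mean(d)), float(np.std(d, ddof=1))


@dataclass
class MixtureFit:
    """k-component 1-D Gaussian mixture fit (components ascending by mean)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray  # (n_points, k) responsibilities
    log_likelihood: float
    ll_trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    converged: bool = True
    bic_gain: float = 0.0  # BIC(single Gaussian) - BIC(this mixture)

    @property
    def separable(self) -> bool:
        """Whether the components are genuinely distinct.

        Requires adjacent means farther apart than half a pooled SD *and*
        positive BIC support over a single Gaussian (a one-component sample
        otherwise gets split into two spuriously separated halves).
        """
        if len(self.means) < 2:
            return False
        pooled = np.sqrt(np.sum(self.weights * self.sds**2))
        return bool(np.all(np.diff(self.means) > 0.5 * pooled)) and self.bic_gain > 0


def _em_1d(x, mu, sd, w, max_iter=500, tol=1e-10):
    """Plain EM for a 1-D Gaussian mixture; returns params and the LL trace."""
    n = x.size
    ll_trace = []
    ll_old = -np.inf
    for _ in range(max_iter):
        logpdf = (
            -0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
            - np.log(sd[None, :])
            - 0.5 * math.log(2 * math.pi)
            + np.log(w[None, :])
        )
        m = logpdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.sum(np.exp(logpdf - m), axis=1))
        ll = float(np.sum(lse))
        ll_trace.append(ll)
        r = np.exp(logpdf - lse[:, None])
        nk = r.sum(axis=0)
        if np.any(nk < 1e-10):
            raise FloatingPointError("component collapsed to zero weight")
        w = nk / n
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < 1e-12):
            raise FloatingPointError("component variance collapsed")
        sd = np.sqrt(var)
        if ll - ll_old < tol * max(1.0, abs(ll)):
            return mu, sd, w, r, ll, np.array(ll_trace), True
        ll_old = ll
    return mu, sd, w, r, ll, np.array(ll_trace), False


def fit_diameter_mixture(
    diameters: np.ndarray, k: int = 2, n_restarts: int = 10, seed: int = 0
) -> MixtureFit:
    """Fit a k-component Gaussian mixture to a diameter sample by EM.

    Runs ``n_restarts`` seeded initialisations (quantile-spread means with
    jitter) and keeps the highest-likelihood solution; components are
    reported in ascending order of mean.  Degenerate restarts (weight or
    variance collapse) are discarded; an error is raised only if every
    restart degenerates.
    """
    x = np.asarray(diameters, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        mu, sd = float(np.mean(x)), float(np.std(x))
        ll = float(np.sum(-0.5 * ((x - mu) / sd) ** 2 - math.log(sd)
                          - 0.5 * math.log(2 * math.pi)))
        return MixtureFit(
            means=np.array([mu]), sds=np.array([sd]), weights=np.array([1.0]),
            posteriors=np.ones((x.size, 1)), log_likelihood=ll,
            ll_trace=np.array([ll]),
        )
    if x.size < 15 * k:
        raise ValueError(f"need at least {15 * k} points for a {k}-component fit")

    rng = np.random.default_rng(seed)
    qs = np.quantile(x, np.linspace(0.15, 0.85, k))
    sd0 = np.std(x) / k
    best = None
    for _ in range(n_restarts):
        mu0 = qs + rng.normal(0, sd0 / 2, size=k)
        try:
            mu, sd, w, r, ll, trace, conv = _em_1d(
                x, mu0.copy(), np.full(k, sd0 * k / 1.5), np.full(k, 1.0 / k)
            )
        except FloatingPointError:
            continue
        if best is None or ll > best[4]:
            best = (mu, sd, w, r, ll, trace, conv)
    if best is None:
        raise RuntimeError("all EM restarts degenerated")
    mu, sd, w, r, ll, trace, conv = best
    order = np.argsort(mu)
    # BIC support over a single Gaussian (3k-1 free parameters per mixture)
    mu1, sd1 = float(np.mean(x)), float(np.std(x))
    ll1 = float(np.sum(-0.5 * ((x - mu1) / sd1) ** 2 - math.log(sd1)
                       - 0.5 * math.log(2 * math.pi)))
    bic1 = -2 * ll1 + 2 * math.log(x.size)
    bic_k = -2 * ll + (3 * k - 1) * math.log(x.size)
    return MixtureFit(
        means=mu[order], sds=sd[order], weights=w[order],
        posteriors=r[:, order], log_likelihood=ll, ll_trace=trace, converged=conv,
        bic_gain=bic1 - bic_k,
    )
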