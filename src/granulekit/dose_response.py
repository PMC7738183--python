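"""Calcium dose-response assembly and mono/biphasic Hill decomposition.

Fraction-fused vs calcium curves are fitted with a mixture of Hill terms

    F(C) = F_max * sum_j w_j * C^h_j / (C^h_j + K_j^h_j),   sum_j w_j = 1

where ``K_j`` is the half-activation calcium (``K_1/2``) of component j.
A biphasic (two-component) response indicates two granule subpopulations
with distinct calcium sensors; treatments that delete one subpopulation
collapse the curve to a single component.

Estimation is weighted least squares with binomial variance weights;
model selection compares one- vs two-component fits by AICc computed on the
binomial log-likelihood of the fused/docked counts (sample size = total
granules), with conservative extra rules on the minor-component weight and
the separation of the two half-activation constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "assemble",
    "fit_dose_response",
    "select_model",
    "compare_scenarios",
]


@dataclass
class DoseResponseCurve:
    """Fraction of docked granules fused per calcium level, with Wilson CIs."""

    calcium_um: np.ndarray
    n_docked: np.ndarray
    n_fused: np.ndarray
    fraction: np.ndarray = field(init=False)
    ci_low: np.ndarray = field(init=False)
    ci_high: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.calcium_um = np.asarray(self.calcium_um, dtype=float)
        self.n_docked = np.asarray(self.n_docked, dtype=int)
        self.n_fused = np.asarray(self.n_fused, dtype=int)
        if np.any(self.n_docked <= 0):
            raise ValueError("each calcium level needs at least one docked granule")
        if np.any(self.n_fused > self.n_docked) or np.any(self.n_fused < 0):
            raise ValueError("fused counts must lie in [0, docked]")
        self.fraction = self.n_fused / self.n_docked
        self.ci_low, self.ci_high = proportion_confint(
            self.n_fused, self.n_docked, alpha=0.05, method="wilson"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "calcium_um": self.calcium_um,
                "n_docked": self.n_docked,
                "n_fused": self.n_fused,
                "fraction": self.fraction,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class HillFit:
    """One- or two-component Hill fit of a dose-response curve.

    ``k_half`` is ascending for two-component fits.  ``stderr`` holds
    asymptotic standard errors in the same order as ``param_names``.
    ``aicc`` is computed on the binomial log-likelihood of the counts with
    the total granule number as sample size.
    """

    n_components: int
    f_max: float
    weights: np.ndarray
    k_half: np.ndarray
    hill: np.ndarray
    rss: float
    aicc: float
    log_likelihood: float
    stderr: dict[str, float]
    converged: bool = True

    def predict(self, calcium) -> np.ndarray:
        c = np.asarray(calcium, dtype=float)
        out = np.zeros_like(c)
        for w, k, h in zip(self.weights, self.k_half, self.hill):
            out += w * c**h / (c**h + k**h)
        return self.f_max * out


def assemble(outcomes: pd.DataFrame, window_s: float | None = None) -> DoseResponseCurve:
    """Build a dose-response curve from a per-granule outcome table.

    ``outcomes`` needs columns ``calcium_um`` and ``fused`` (and ``onset_s``
    if ``window_s`` is given: only events with onset inside the post-trigger
    window count as fused).
    """
    df = outcomes.copy()
    fused = df["fused"].astype(bool)
    if window_s is not None:
        fused = fused & (df["onset_s"] <= window_s)
    df["_fused"] = fused
    grp = df.groupby("calcium_um", sort=True)["_fused"].agg(["count", "sum"])
    return DoseResponseCurve(
        calcium_um=grp.index.to_numpy(),
        n_docked=grp["count"].to_numpy(),
        n_fused=grp["sum"].to_numpy(),
    )


def _binomial_loglik(curve: DoseResponseCurve, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(
        np.sum(curve.n_fused * np.log(p) + (curve.n_docked - curve.n_fused) * np.log1p(-p))
    )


def fit_dose_response(
    curve: DoseResponseCurve,
    n_components: int = 1,
    weighted: bool = True,
    shared_hill: bool = True,
    n_starts: int = 8,
    seed: int = 0,
) -> HillFit:
    """Weighted least-squares Hill(-mixture) fit with multi-start initialisation.

    Residuals are weighted by the inverse binomial standard deviation of each
    level (``weighted=False`` disables this for sensitivity analysis).  The
    Hill coefficient is shared across components by default, keeping the
    two-component model at five parameters.  Bounds: h in [0.5, 6],
    K in [0.5, 500] uM.  Raises if no start converges.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    c = curve.calcium_um
    if len(c) < 5:
        raise ValueError("need at least 5 calcium levels")
    y = curve.fraction
    if weighted:
        var = np.clip(y * (1 - y), 0.25 / np.max(curve.n_docked), None) / curve.n_docked
        wts = 1.0 / np.sqrt(var)
    else:
        wts = np.ones_like(y)

    k_lo, k_hi, h_lo, h_hi = 0.5, 500.0, 0.5, 6.0
    two = n_components == 2
    sep_h = two and not shared_hill
    # theta layout: [f_max, k1, h1, (w1, k2, (h2))]
    names = ["f_max", "k_half_1", "hill_1"]
    lo = [0.01, k_lo, h_lo]
    hi = [1.0, k_hi, h_hi]
    if two:
        names += ["w_1", "k_half_2"]
        lo += [0.0, k_lo]
        hi += [1.0, k_hi]
        if sep_h:
            names += ["hill_2"]
            lo += [h_lo]
            hi += [h_hi]

    def model(theta):
        if not two:
            f_max, k1, h1 = theta
            return f_max * c**h1 / (c**h1 + k1**h1)
        if sep_h:
            f_max, k1, h1, w1, k2, h2 = theta
        else:
            f_max, k1, h1, w1, k2 = theta
            h2 = h1
        return f_max * (
            w1 * c**h1 / (c**h1 + k1**h1) + (1 - w1) * c**h2 / (c**h2 + k2**h2)
        )

    def resid(theta):
        return (model(theta) - y) * wts

    rng = np.random.default_rng(seed)
    f0 = float(np.clip(np.max(y) * 1.05, 0.05, 1.0))
    starts = []
    if two:
        for k1 in (3.0, 10.0):
            for k2 in (30.0, 100.0, 300.0):
                starts.append([f0, k1, 3.0, 0.5, k2])
        while len(starts) < n_starts:
            k1, k2 = np.sort(np.exp(rng.uniform(np.log(1), np.log(300), 2)))
            starts.append([f0, k1, 3.0, float(rng.uniform(0.3, 0.7)), k2])
        if sep_h:
            starts = [s + [3.0] for s in starts]
    else:
        starts = [[f0, k, 2.0] for k in np.geomspace(2, 200, 4)]
        while len(starts) < n_starts:
            starts.append([f0, float(np.exp(rng.uniform(np.log(1), np.log(300)))),
                           float(rng.uniform(1.0, 4.0))])

    best = None
    for s in starts[:n_starts]:
        try:
            sol = least_squares(resid, np.clip(s, lo, hi), bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, max_nfev=3000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None:
        raise RuntimeError("dose-response fit failed from all starts")
    sol, rss = best

    # asymptotic standard errors from the weighted Jacobian
    stderr = {}
    try:
        jac = sol.jac
        dof = max(len(c) - len(sol.x), 1)
        cov = np.linalg.pinv(jac.T @ jac) * rss / dof
        for nm, se in zip(names, np.sqrt(np.clip(np.diag(cov), 0, None))):
            stderr[nm] = float(se)
    except np.linalg.LinAlgError:
        stderr = {nm: np.nan for nm in names}

    theta = sol.x
    if two:
        if sep_h:
            f_max, k1, h1, w1, k2, h2 = theta
        else:
            f_max, k1, h1, w1, k2 = theta
            h2 = h1
        weights = np.array([w1, 1 - w1])
        ks = np.array([k1, k2])
        hs = np.array([h1, h2])
        order = np.argsort(ks)
        weights, ks, hs = weights[order], ks[order], hs[order]
    else:
        f_max, k1, h1 = theta
        weights, ks, hs = np.array([1.0]), np.array([k1]), np.array([h1])

    fit = HillFit(
        n_components=n_components, f_max=float(f_max), weights=weights,
        k_half=ks, hill=hs, rss=rss, aicc=np.nan, log_likelihood=np.nan,
        stderr=stderr,
    )
    ll = _binomial_loglik(curve, fit.predict(c))
    n_obs = int(np.sum(curve.n_docked))
    k_par = len(theta)
    aicc = -2 * ll + 2 * k_par
    if n_obs - k_par - 1 > 0:
        aicc += 2 * k_par * (k_par + 1) / (n_obs - k_par - 1)
    fit.log_likelihood = ll
    fit.aicc = aicc
    return fit


def select_model(
    fit1: HillFit,
    fit2: HillFit,
    delta_aicc: float = 2.0,
    min_weight: float = 0.15,
    min_k_ratio: float = 2.0,
) -> tuple[HillFit, dict]:
    """Choose between mono- and biphasic fits of the same curve.

    The two-component fit wins only if its AICc improves by at least
    ``delta_aicc``, its minor component carries at least ``min_weight`` of
    the amplitude, and its half-activation constants differ by at least a
    factor ``min_k_ratio``; otherwise the monophasic fit is returned.
    """
    k_ratio = float(fit2.k_half[1] / fit2.k_half[0])
    evidence = {
        "delta_aicc": fit1.aicc - fit2.aicc,
        "min_weight": float(fit2.weights.min()),
        "k_ratio": k_ratio,
    }
    biphasic = (
        fit2.aicc <= fit1.aicc - delta_aicc
        and fit2.weights.min() >= min_weight
        and k_ratio >= min_k_ratio
    )
    evidence["chosen"] = 2 if biphasic else 1
    return (fit2 if biphasic else fit1), evidence


def compare_scenarios(
    fits: dict[str, HillFit], reference: str = "untreated"
) -> pd.DataFrame:
    """Tabulate per-scenario components and flag losses vs a reference.

    A reference component counts as retained in a scenario if that scenario
    has a component whose ``K_1/2`` lies within a factor 2; flags report the
    loss of the reference's high-affinity (low K) and low-affinity (high K)
    components.
    """
    if reference not in fits:
        raise ValueError(f"reference scenario {reference!r} missing")
    ref = fits[reference]
    rows = []
    for name, fit in fits.items():
        retained = []
        for k_ref in ref.k_half:
            ok = any(0.5 <= k / k_ref <= 2.0 for k in fit.k_half)
            retained.append(ok)
        flags = []
        if len(ref.k_half) > 1:
            if not retained[0]:
                flags.append("high-affinity component lost")
            if not retained[-1]:
                flags.append("low-affinity component lost")
        rows.append(
            {
                "scenario": name,
                "n_components": fit.n_components,
                "k_half_um": tuple(np.round(fit.k_half, 2)),
                "weights": tuple(np.round(fit.weights, 3)),
                "flags": "; ".join(flags) if flags else
                         ("reference" if name == reference else "no shift"),
            }
        )
    return pd.DataFrame(rows)
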