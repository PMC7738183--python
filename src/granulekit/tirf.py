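"""Single-granule TIRF fusion photometry.

Detects docked granules in an image stack, extracts 5x5-pixel photometric
traces, segments fusion events, fits the two-step content-release model, and
classifies fast vs slow release modes from the fitted collapse step
``delta_ic``.

The two-step model describes the stereotyped shape of a content-marker
release event: fluorescence decreases when the fusion pore opens (content
escapes), rises abruptly when the granule membrane collapses into the planar
bilayer (remaining content is pulled into the evanescent field; the step
height ``delta_ic`` reports how much content was still aboard), then decays
as the marker diffuses away.

Coordinates are pixel-centered, 0-based, (x, y) = (column, row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

__all__ = [
    "IntensityTrace",
    "FusionEvent",
    "DetectionResult",
    "preprocess",
    "detect",
    "extract_traces",
    "segment_event",
    "fit_release",
    "classify_modes",
    "release_durations_by_cell",
    "centroid_drift",
    "normalize_docking",
    "manders",
]

#: delta_ic scale (counts) separating slow from fast modes when the mixture
#: classifier degenerates to a single component; midway between the default
#: generator modes.
DEFAULT_DELTA_IC_REFERENCE = 200.0


@dataclass
class IntensityTrace:
    """Background-subtracted photometry of one granule ROI."""

    values: np.ndarray
    frame_interval: float
    roi_center: tuple[float, float]  # (x, y), px
    roi_half_width: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval


@dataclass
class FusionEvent:
    """Fitted two-step release parameters of one fusion event."""

    onset_frame: int
    collapse_frame: int
    delta_ic: float
    pore_rate: float
    post_rate: float
    i_dock: float
    duration: float
    mode: str = "unclassified"
    fit_rss: float = np.nan

    def __post_init__(self) -> None:
        if self.collapse_frame < self.onset_frame:
            raise ValueError("collapse cannot precede onset")
        if self.delta_ic < 0 or self.duration < 0:
            raise ValueError("delta_ic and duration must be non-negative")


@dataclass
class DetectionResult:
    """Detected sub-pixel spot centers and the threshold that produced them."""

    centers: np.ndarray  # (n, 2) array of (x, y)
    threshold: float
    filter_window: int = 1


def preprocess(stack: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel temporal moving average with a shrinking window at the edges.

    The window is centred on each frame and clipped to the stack bounds, so
    output length equals input length and ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = stack.shape[0]
    if window > n:
        raise ValueError("window longer than the stack")
    if window == 1:
        return np.asarray(stack, dtype=float).copy()
    h = window // 2
    c = np.concatenate(
        [np.zeros((1, *stack.shape[1:])), np.cumsum(stack, axis=0, dtype=float)]
    )
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    out = (c[hi + 1] - c[lo]) / (hi - lo + 1)[:, None, None]
    return out


def detect(
    stack: np.ndarray,
    k_mad: float = 6.0,
    min_separation: float = 4.0,
) -> DetectionResult:
    """Locate granules on the per-pixel maximum projection of the stack.

    Local maxima above ``median + k_mad * MAD`` of the projection are kept,
    maxima closer than ``min_separation`` px are merged to the brighter one,
    and centers are refined to sub-pixel precision by an intensity-weighted
    centroid over a 5x5 window (background-subtracted at the median).
    """
    if stack.size == 0:
        raise ValueError("empty stack")
    proj = np.max(np.asarray(stack, dtype=float), axis=0)
    med = float(np.median(proj))
    # 1.4826 makes the MAD a consistent estimator of a Gaussian sigma
    mad = 1.4826 * float(np.median(np.abs(proj - med)))
    thr = med + k_mad * mad
    peaks = peak_local_max(
        proj, min_distance=max(int(round(min_separation)), 1), threshold_abs=thr
    )
    centers = []
    h, w = proj.shape
    for r, c in peaks:
        r0, r1 = max(r - 2, 0), min(r + 3, h)
        c0, c1 = max(c - 2, 0), min(c + 3, w)
        win = np.clip(proj[r0:r1, c0:c1] - med, 0, None)
        if win.sum() <= 0:
            centers.append((float(c), float(r)))
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        centers.append(
            (float((cc * win).sum() / win.sum()), float((rr * win).sum() / win.sum()))
        )
    return DetectionResult(
        centers=np.array(centers, dtype=float).reshape(-1, 2), threshold=thr
    )


def extract_traces(
    stack: np.ndarray,
    centers: np.ndarray,
    frame_interval: float = 0.05,
    half_width: int = 2,
    annulus: tuple[int, int] = (5, 7),
) -> list[IntensityTrace]:
    """Photometry: per-frame sum over a (2h+1)x(2h+1) ROI around each center,
    background-subtracted using the median of an annulus (clipped to the
    image) scaled to the ROI pixel count."""
    stack = np.asarray(stack, dtype=float)
    _, h, w = stack.shape
    r_in, r_out = annulus
    n_roi = (2 * half_width + 1) ** 2
    traces = []
    for cx, cy in np.atleast_2d(centers):
        ix, iy = int(round(cx)), int(round(cy))
        if ix - half_width < 0 or iy - half_width < 0 or ix + half_width >= w or iy + half_width >= h:
            raise ValueError(f"ROI at ({cx:.1f}, {cy:.1f}) exceeds image bounds")
        roi = stack[:, iy - half_width : iy + half_width + 1,
                    ix - half_width : ix + half_width + 1].sum(axis=(1, 2))
        y0, y1 = max(iy - r_out, 0), min(iy + r_out + 1, h)
        x0, x1 = max(ix - r_out, 0), min(ix + r_out + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        rad2 = (yy - iy) ** 2 + (xx - ix) ** 2
        ring = (rad2 >= r_in**2) & (rad2 <= r_out**2)
        bg = np.median(stack[:, y0:y1, x0:x1][:, ring], axis=1)
        traces.append(
            IntensityTrace(
                values=roi - n_roi * bg,
                frame_interval=frame_interval,
                roi_center=(float(cx), float(cy)),
                roi_half_width=half_width,
            )
        )
    return traces


def _noise_sd(values: np.ndarray) -> float:
    """Robust noise SD (scaled MAD about the median).

    Estimated from amplitudes, not successive differences, so it stays
    unbiased when temporal filtering has correlated neighbouring frames.
    """
    sd = 1.4826 * float(np.median(np.abs(values - np.median(values))))
    return sd if sd > 0 else 1e-9


def segment_event(
    trace: IntensityTrace,
    baseline_frames: int = 20,
    k_onset: float = 5.0,
    m_onset: int = 5,
    k_end: float = 2.0,
    m_end: int = 5,
) -> tuple[int, int] | None:
    """Find the onset and completion frames of a release event, if any.

    Onset is the first frame where the trace leaves the docked-baseline band
    (baseline mean +/- ``k_onset`` x noise SD) and stays out for at least
    ``m_onset`` frames.  The end is the first later frame where the trace
    re-enters the post-release band (final plateau +/- ``k_end`` x noise SD)
    and stays in for at least ``m_end`` frames.  Returns ``None`` for traces
    that never leave baseline.
    """
    v = trace.values
    if v.size < baseline_frames + m_onset:
        raise ValueError("trace shorter than the baseline window")
    base = float(np.mean(v[:baseline_frames]))
    sd = max(_noise_sd(v[:baseline_frames]), 1e-9)
    out = np.abs(v - base) > k_onset * sd
    out[:baseline_frames] = False
    onset = _first_run(out, m_onset)
    if onset is None:
        return None
    # the k_onset crossing lags the true departure for slowly-decaying
    # events; walk back to the last frame still inside a tight band and
    # report that frame (the trace still sits at dock level at the onset
    # instant, so the last quiescent frame is the onset)
    while onset > 1 and np.abs(v[onset - 1] - base) > 1.5 * sd:
        onset -= 1
    onset = max(onset - 1, 0)
    plateau = float(np.median(v[-m_end:]))
    inside = np.abs(v - plateau) <= max(k_end * sd, 1e-9)
    inside[: onset + 1] = False
    end = _first_run(inside, m_end)
    if end is None:
        end = v.size - 1
    return onset, end


def _first_run(mask: np.ndarray, m: int) -> int | None:
    count = 0
    for i, flag in enumerate(mask):
        count = count + 1 if flag else 0
        if count >= m:
            return i - m + 1
    return None


def _two_step(t, t_collapse, i_dock, onset, pore_rate, peak, post_rate):
    """Two-step profile with the collapse pinned at ``t_collapse``.

    The collapse step height and a continuous collapse time are not jointly
    identifiable from sampled data (shifting the collapse within one frame
    interval while rescaling the step reproduces the samples exactly), so
    the collapse is parameterised by the first post-collapse frame time and
    the post segment by its value ``peak`` at that frame.
    """
    out = np.full_like(t, i_dock)
    pore = (t >= onset) & (t < t_collapse)
    out[pore] = i_dock * np.exp(-pore_rate * (t[pore] - onset))
    post = t >= t_collapse
    out[post] = peak * np.exp(-post_rate * (t[post] - t_collapse))
    return out


def fit_release(
    trace: IntensityTrace,
    bounds: tuple[int, int],
    collapse_search: int = 1,
) -> FusionEvent:
    """Least-squares fit of the two-step release model to one event.

    The collapse frame is profiled discretely over candidate frames
    (``+/- collapse_search`` around each of the five largest upward jumps
    in the segment); for each candidate the docked intensity, onset time,
    pore-loss rate, peak and post-collapse decay rate are fitted by
    continuous least squares (initialised from trace landmarks).  ``delta_ic`` is the fitted peak
    minus the extrapolated pre-collapse intensity.  A trace no candidate
    fits is flagged ``unclassified``, never silently dropped.  ``duration``
    is the segment length in seconds.
    """
    onset_fr, end_fr = bounds
    t = trace.times
    v = trace.values
    dt = trace.frame_interval
    i_dock0 = float(np.mean(v[:onset_fr])) if onset_fr > 0 else float(v[0])
    # collapse landmarks: the largest upward frame-to-frame jumps inside the
    # event (the post-collapse peak can sit below early pore-phase values,
    # so the segment maximum is not a usable landmark for slow events)
    seg = slice(onset_fr + 1, max(end_fr, onset_fr + 2))
    jumps = np.diff(v[seg])
    if jumps.size:
        top = np.argsort(jumps)[::-1][:5]
        collapse_fr0 = onset_fr + 2 + int(top[0])
        candidates = sorted(
            {onset_fr + 2 + int(j) + d for j in top for d in range(-collapse_search, collapse_search + 1)}
        )
    else:
        collapse_fr0 = onset_fr + 1
        candidates = [collapse_fr0]
    peak0 = max(float(v[collapse_fr0]), 1e-3)
    dip0 = float(np.min(v[onset_fr : collapse_fr0 + 1]))
    dt_collapse0 = max((collapse_fr0 - onset_fr) * dt, dt)
    pore_rate0 = max(-np.log(max(dip0, 1e-3) / max(i_dock0, 1e-3)) / dt_collapse0, 0.01)
    span = max((end_fr - collapse_fr0) * dt, dt)
    post_rate0 = max(np.log(peak0 / max(abs(v[end_fr]), 1e-3)) / span, 0.01)

    lo = [0.0, 0.0, 1e-3, 0.0, 1e-3]
    hi = [np.inf, t[-1], 1e3, np.inf, 1e3]
    best = None
    for c_fr in candidates:
        if not onset_fr < c_fr <= end_fr:
            continue
        t_c = c_fr * dt
        theta0 = np.clip(
            [i_dock0, onset_fr * dt, pore_rate0, max(float(v[c_fr]), 1e-3), post_rate0],
            lo, hi,
        )

        def resid(theta):
            return _two_step(t, t_c, *theta) - v

        try:
            sol = least_squares(resid, theta0, bounds=(lo, hi),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol, rss, c_fr)
    if best is None:
        return FusionEvent(
            onset_frame=onset_fr, collapse_frame=onset_fr, delta_ic=0.0,
            pore_rate=np.nan, post_rate=np.nan, i_dock=i_dock0,
            duration=(end_fr - onset_fr) * dt, mode="unclassified",
        )
    sol, rss, c_fr = best
    i_dock, onset_t, pore_rate, peak, post_rate = sol.x
    i_pre = i_dock * float(np.exp(-pore_rate * (c_fr * dt - onset_t)))
    return FusionEvent(
        onset_frame=int(round(onset_t / dt)),
        collapse_frame=c_fr,
        delta_ic=max(float(peak - i_pre), 0.0),
        pore_rate=float(pore_rate),
        post_rate=float(post_rate),
        i_dock=float(i_dock),
        duration=(end_fr - onset_fr) * dt,
        fit_rss=rss,
    )


def classify_modes(
    events: list[FusionEvent],
    min_events: int = 20,
    reference_scale: float = DEFAULT_DELTA_IC_REFERENCE,
    seed: int = 0,
) -> tuple[list[FusionEvent], dict]:
    """Label events slow/fast from a 2-component Gaussian mixture on delta_ic.

    The lower-mean component is the slow mode.  If the mixture degenerates
    (a component weight below 0.05, means within half a pooled SD, or no
    BIC support for two components over one — a single Gaussian otherwise
    gets split into two overlapping halves) all events receive the single
    label implied by the surviving component's position relative to
    ``reference_scale``.  Posterior ties break to slow.  Returns the
    relabelled events and a threshold report.
    """
    if len(events) < min_events:
        raise ValueError(f"need at least {min_events} events, got {len(events)}")
    x = np.array([e.delta_ic for e in events]).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=10, random_state=seed).fit(x)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    pooled = float(np.sqrt(np.sum(weights * sds**2)))
    degenerate = (
        weights.min() < 0.05
        or (means[1] - means[0]) < 0.5 * pooled
        or gm1.bic(x) <= gm.bic(x)
    )
    report = {
        "means": means.tolist(),
        "sds": sds.tolist(),
        "weights": weights.tolist(),
        "degenerate": bool(degenerate),
    }
    if degenerate:
        main = means[int(np.argmax(weights))]
        label = "slow" if main <= reference_scale else "fast"
        report["single_label"] = label
        for e in events:
            e.mode = label
        return events, report
    post = gm.predict_proba(x)[:, order]
    for e, p in zip(events, post):
        e.mode = "slow" if p[0] >= p[1] else "fast"
    crossing = float((means[0] * sds[1] + means[1] * sds[0]) / (sds[0] + sds[1]))
    report["boundary"] = crossing
    return events, report


def release_durations_by_cell(durations_by_cell: dict) -> pd.DataFrame:
    """Per-cell mean/SD of release durations plus a pooled group summary row.

    ``durations_by_cell`` maps a cell id to its event durations (s) or to a
    list of :class:`FusionEvent`.  Mirrors per-cell averaging: each cell
    contributes one mean regardless of its event count.
    """
    if not durations_by_cell:
        raise ValueError("empty group")
    rows = []
    for cell, items in durations_by_cell.items():
        durs = np.array(
            [it.duration if isinstance(it, FusionEvent) else float(it) for it in items]
        )
        if durs.size == 0:
            raise ValueError(f"cell {cell!r} has no events")
        rows.append(
            {"cell": cell, "n_events": durs.size, "mean_s": float(np.mean(durs)),
             "sd_s": float(np.std(durs, ddof=1)) if durs.size > 1 else 0.0}
        )
    df = pd.DataFrame(rows)
    cell_means = df["mean_s"].to_numpy()
    df.attrs["group_mean_s"] = float(np.mean(cell_means))
    df.attrs["group_sd_s"] = float(np.std(cell_means, ddof=1)) if len(cell_means) > 1 else 0.0
    return df


def centroid_drift(
    stack: np.ndarray,
    center: tuple[float, float],
    frames_a: slice,
    frames_b: slice,
    half_width: int = 2,
) -> float:
    """Displacement (px) of a spot's intensity-weighted centroid between two
    frame ranges.

    Granules that wander between docking and fusion onset are excluded from
    release-mode analysis (``drift > 2`` px is the conventional cut) because
    the fixed ROI no longer captures their full photometry.
    """
    stack = np.asarray(stack, dtype=float)
    ix, iy = int(round(center[0])), int(round(center[1]))
    win = stack[:, iy - half_width : iy + half_width + 1,
                ix - half_width : ix + half_width + 1]
    if win.shape[1:] != (2 * half_width + 1, 2 * half_width + 1):
        raise ValueError("window exceeds image bounds")
    yy, xx = np.mgrid[-half_width : half_width + 1, -half_width : half_width + 1]

    def centroid(img):
        img = np.clip(img - np.median(img), 0, None)
        total = img.sum()
        if total <= 0:
            return 0.0, 0.0
        return float((xx * img).sum() / total), float((yy * img).sum() / total)

    ax, ay = centroid(win[frames_a].mean(axis=0))
    bx, by = centroid(win[frames_b].mean(axis=0))
    return float(np.hypot(bx - ax, by - ay))


def normalize_docking(count: float, reference_count: float) -> float:
    """Docked-granule count relative to a reference condition."""
    if reference_count <= 0:
        raise ValueError("reference count must be positive")
    return count / reference_count


def manders(
    img_a: np.ndarray,
    img_b: np.ndarray,
    thr_a: float | None = None,
    thr_b: float | None = None,
) -> tuple[float, float]:
    """Manders colocalization coefficients (M1, M2) of two channels.

    ``M1`` is the fraction of channel-A intensity on pixels where channel B
    exceeds its threshold; ``M2`` is the symmetric quantity.  Thresholds
    default to per-channel Otsu.  Both coefficients lie in [0, 1].
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if not a.any() or not b.any():
        raise ValueError("Manders coefficients undefined for an all-zero channel")
    if thr_a is None:
        thr_a = float(threshold_otsu(a))
    if thr_b is None:
        thr_b = float(threshold_otsu(b))
    if thr_a < 0 or thr_b < 0:
        raise ValueError("thresholds must be non-negative")
    m1 = float(a[b > thr_b].sum() / a.sum())
    m2 = float(b[a > thr_a].sum() / b.sum())
    return m1, m2
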