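"""Tabular statistics for granule biochemistry.

Covers the lipidomics pipeline (internal-standard/protein normalization,
syt9/syt7 volcano statistics with Welch's t-test, per-class enrichment),
immunodepletion protein fractions from western band intensities, and
secretion normalizations (fractional secretion, protein-normalized relative
secretion, and baseline/positive-control normalization of calcium-indicator
traces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import LipidTable, SecretionMeasurement

__all__ = [
    "DepletionRecord",
    "normalize_lipids",
    "volcano",
    "class_enrichment",
    "depletion_fractions",
    "fractional_secretion",
    "relative_secretion",
    "dff_normalize",
]


def normalize_lipids(table: LipidTable) -> LipidTable:
    """Divide each sample's areas by its internal-standard area and protein mass."""
    if (table.internal_standard <= 0).any() or (table.protein <= 0).any():
        raise ValueError("internal standard and protein must be positive")
    norm = table.areas.div(table.internal_standard, axis=1).div(table.protein, axis=1)
    return LipidTable(
        areas=norm,
        species_class=table.species_class,
        groups=table.groups,
        internal_standard=pd.Series(1.0, index=table.internal_standard.index),
        protein=pd.Series(1.0, index=table.protein.index),
    )


def volcano(
    table: LipidTable,
    log_base: int = 2,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-species syt9/syt7 ratio and Welch significance.

    Replicates are averaged per group, the syt9/syt7 ratio of means is
    log-transformed (base 2 by default, base 10 selectable), and the
    p-value comes from a two-tailed Welch (unequal-variance) t-test on the
    per-replicate normalized values.  ``significant`` marks p < ``alpha``
    per species (or the Benjamini-Hochberg-adjusted p when ``bh_correct``).
    """
    if log_base not in (2, 10):
        raise ValueError("log_base must be 2 or 10")
    g7 = table.groups[table.groups == "syt7"].index
    g9 = table.groups[table.groups == "syt9"].index
    if len(g7) < 2 or len(g9) < 2:
        raise ValueError("need at least 2 replicates per group")
    a7 = table.areas[g7].to_numpy()
    a9 = table.areas[g9].to_numpy()
    mean7 = a7.mean(axis=1)
    mean9 = a9.mean(axis=1)
    if np.any(mean7 <= 0) or np.any(mean9 <= 0):
        raise ValueError("zero group mean; cannot form a ratio")
    log = np.log2 if log_base == 2 else np.log10
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(a9, a7, axis=1, equal_var=False)
    if np.any(~np.isfinite(p)):
        raise ValueError("zero variance in both groups for some species")
    p_eff = multipletests(p, method="fdr_bh")[1] if bh_correct else p
    df = pd.DataFrame(
        {
            "species": table.areas.index,
            "class": table.species_class.reindex(table.areas.index).to_numpy(),
            "ratio": mean9 / mean7,
            f"log{log_base}_ratio": log(mean9 / mean7),
            "p": p,
            f"neg_log{log_base}_p": -log(p),
            "significant": p_eff < alpha,
        }
    ).reset_index(drop=True)
    return df


def class_enrichment(table: LipidTable) -> pd.DataFrame:
    """Per-sample lipid-class totals normalized to the syt7 group mean, log2.

    Class areas are totalled per sample, each class total is divided by the
    syt7-group mean for that class, and the result is log2-transformed.
    Returns per-class group means and SDs (syt7 rows average to 0 by
    construction).
    """
    classes = table.species_class.reindex(table.areas.index)
    totals = table.areas.groupby(classes).sum()  # class x sample
    g7 = table.groups[table.groups == "syt7"].index
    ref = totals[g7].mean(axis=1)
    if (ref <= 0).any() or (totals <= 0).any().any():
        raise ValueError("a lipid class is absent from a group")
    log_fold = np.log2(totals.div(ref, axis=0))
    rows = []
    for grp in table.groups.unique():
        cols = table.groups[table.groups == grp].index
        rows.append(
            pd.DataFrame(
                {
                    "class": log_fold.index,
                    "group": grp,
                    "log2_fold": log_fold[cols].mean(axis=1).to_numpy(),
                    "sd": log_fold[cols].std(axis=1, ddof=1).to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class DepletionRecord:
    """Fractions of a protein on syt7 vs syt9 granules from depletion blots."""

    protein: str
    control: float
    dep7: float
    dep9: float
    fraction_syt7: float
    fraction_syt9: float
    raw_fraction_syt7: float
    raw_fraction_syt9: float


def depletion_fractions(
    control: float, dep7: float, dep9: float, protein: str = ""
) -> DepletionRecord:
    """Protein partitioning between subpopulations from band intensities.

    The syt7-depleted supernatant lost whatever rode on syt7 granules, so
    ``fraction_syt7 = (control - dep7)/control`` (likewise for syt9).  Raw
    fractions are retained for QC; reported fractions are clipped to [0, 1]
    and renormalized to sum to 1.
    """
    if control <= 0:
        raise ValueError("control intensity must be positive")
    raw7 = (control - dep7) / control
    raw9 = (control - dep9) / control
    f7 = min(max(raw7, 0.0), 1.0)
    f9 = min(max(raw9, 0.0), 1.0)
    total = f7 + f9
    if total > 0:
        f7, f9 = f7 / total, f9 / total
    return DepletionRecord(
        protein=protein, control=control, dep7=dep7, dep9=dep9,
        fraction_syt7=f7, fraction_syt9=f9,
        raw_fraction_syt7=raw7, raw_fraction_syt9=raw9,
    )


def fractional_secretion(secreted: float, lysate: float) -> float:
    """Percent of total content secreted: ``100 * secreted/(secreted + lysate)``."""
    if secreted < 0 or lysate < 0:
        raise ValueError("signals must be non-negative")
    if secreted + lysate == 0:
        raise ValueError("secreted and lysate cannot both be zero")
    return 100.0 * secreted / (secreted + lysate)


def relative_secretion(
    measurements: list[SecretionMeasurement] | pd.DataFrame,
    reference_scenario: str = "untreated",
    reference_stimulus: float = 90.0,
) -> pd.DataFrame:
    """Protein-normalized secretion relative to the reference condition mean.

    Each sample's secreted signal is divided by its protein mass, then by the
    mean protein-normalized signal of the reference condition (untreated at
    90 mM KCl by default).
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = pd.DataFrame([vars(m) for m in measurements])
    df = measurements.copy()
    df["per_protein"] = df["secreted"] / df["protein"]
    ref = df[
        (df["scenario"] == reference_scenario)
        & (df["stimulus_mm_kcl"] == reference_stimulus)
    ]
    if ref.empty:
        raise ValueError(
            f"reference condition ({reference_scenario}, {reference_stimulus} mM) missing"
        )
    df["relative"] = df["per_protein"] / ref["per_protein"].mean()
    return df


def dff_normalize(
    trace: np.ndarray, baseline_window: slice | int, control: float
) -> np.ndarray:
    """Calcium-indicator normalization ``(F - F0)/(F_control - F0)``.

    ``F0`` is the mean over the pre-stimulus baseline window; ``control`` is
    the positive-control fluorescence (e.g. after permeabilisation in
    saturating calcium) and must exceed the baseline.
    """
    f = np.asarray(trace, dtype=float)
    if isinstance(baseline_window, int):
        baseline_window = slice(0, baseline_window)
    f0 = float(np.mean(f[baseline_window]))
    if control <= f0:
        raise ValueError("positive control must exceed the baseline")
    return (f - f0) / (control - f0)
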