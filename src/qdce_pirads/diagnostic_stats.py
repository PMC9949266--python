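"""Zone-stratified diagnostic statistics and the cohort comparison tests.

Detection rate DR = TP/(TP+FN) and positive predictive value
PPV = TP/(TP+FP) are computed from sector-weighted lesion counts: within a
zone each lesion contributes the share of its unit weight that falls on
that zone's sectors, while whole-gland counts are plain lesion counts
(weights sum to 1 per lesion). Cancer prevalence is a zone's share of the
weighted pathology-positive (TP+FN) mass. Undefined ratios (zero
denominators) are reported as missing (None), never as 0.

Group comparisons use a weighted Pearson chi-square on 2x2 weighted-count
tables (DR/PPV) and the Mann-Whitney U test for continuous variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .radpath_labeling import LabeledLesion
from .synthetic_cohort import SectorMap, ZONES

__all__ = [
    "DiagnosticSummary",
    "summarize",
    "cancer_prevalence",
    "weighted_chisq",
    "mann_whitney",
    "lesions_per_patient",
]

SCOPES = ("whole_gland",) + ZONES


@dataclass(frozen=True)
class DiagnosticSummary:
    """Weighted TP/FP/FN counts and the derived DR/PPV/CP for one scope."""

    scope: str
    tp_w: float
    fp_w: float
    fn_w: float
    dr: float | None
    ppv: float | None
    cp: float | None


def _scope_weight(labeled: LabeledLesion, scope: str, sector_map: SectorMap | None) -> float:
    if scope == "whole_gland":
        return 1.0 if labeled.label != "EXCLUDED" else 0.0
    if sector_map is None:
        raise ValueError("zone scopes require a sector map")
    total = 0.0
    for sector, w in labeled.sector_weights.items():
        if sector not in sector_map.zone_of:
            raise ValueError(f"unknown sector id {sector!r}")
        if sector_map.zone_of[sector] == scope:
            total += w
    return total


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def summarize(
    labeled: Sequence[LabeledLesion],
    sector_map: SectorMap | None = None,
    scope: str = "whole_gland",
) -> DiagnosticSummary:
    """Weighted diagnostic summary over one scope (whole gland, TZ or PZ)."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    counts = {"TP": 0.0, "FP": 0.0, "FN": 0.0}
    path_pos_total = 0.0
    path_pos_scope = 0.0
    for item in labeled:
        w = _scope_weight(item, scope, sector_map)
        if item.label in counts:
            counts[item.label] += w
        if item.label in ("TP", "FN"):
            path_pos_scope += w
            path_pos_total += 1.0
    tp, fp, fn = counts["TP"], counts["FP"], counts["FN"]
    return DiagnosticSummary(
        scope=scope,
        tp_w=tp,
        fp_w=fp,
        fn_w=fn,
        dr=_ratio(tp, tp + fn),
        ppv=_ratio(tp, tp + fp),
        cp=_ratio(path_pos_scope, path_pos_total),
    )


def cancer_prevalence(
    labeled: Sequence[LabeledLesion], sector_map: SectorMap
) -> dict[str, float | None]:
    """Zonal cancer prevalence: each zone's share of weighted TP+FN mass.

    The shares sum to 1 when every counted sector belongs to TZ or PZ.
    With no pathology-positive lesions both values are missing (None).
    """
    return {z: summarize(labeled, sector_map, z).cp for z in ZONES}


def weighted_chisq(
    group_a: tuple[float, float],
    group_b: tuple[float, float],
    continuity: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table of (possibly non-integer) weighted counts.

    ``group_a`` / ``group_b`` are (weighted successes, weighted failures).
    df = 1; upper-tail p from the chi-square distribution; no continuity
    correction unless requested. A zero expected cell yields (nan, nan)
    with a warning. On integer tables this is exactly the classical
    Pearson statistic; scaling all weights by k scales the statistic by k.
    """
    table = np.array([group_a, group_b], dtype=float)
    if np.any(table < 0):
        raise ValueError("weighted counts must be non-negative")
    if np.any(table.sum(axis=1) <= 0):
        raise ValueError("both groups need a positive weighted total")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected == 0):
        warnings.warn("zero expected cell; chi-square p-value undefined", stacklevel=2)
        return float("nan"), float("nan")
    dev = np.abs(table - expected)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    return stat, float(stats.chi2.sf(stat, df=1))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for combined n <= 20 without ties; otherwise
    the tie-corrected normal approximation. The returned U counts pairs
    won by ``x`` (so a fully smaller ``x`` gives U = 0). A degenerate
    pooled sample with all values equal returns p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def lesions_per_patient(n_lesions: int, n_patients: int) -> float:
    """Average lesion multiplicity of a cohort (lesions per patient)."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    return n_lesions / n_patients
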