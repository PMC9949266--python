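"""Ktrans-augmented PI-RADS scoring and race-specific threshold tuning.

The update rule uses two Ktrans cutoffs (t_low <= t_high, min^-1):

* an MRI-negative score (PI-RADS 0-2) is upgraded to 3 when the lesion's
  Ktrans is strictly **higher** than ``t_high`` (high perfusion despite an
  unremarkable or occult MRI finding);
* a suspicious score (PI-RADS 3-5) is downgraded to 2 when Ktrans is
  strictly **lower** than ``t_low``.

The rule is idempotent and monotone in Ktrans for a fixed initial score.
``brute_force_thresholds`` exhaustively scans a (t_low, t_high) grid —
augmented with the no-op sentinel (0, +inf) — and returns the pair that
maximizes the detection rate subject to the positive predictive value not
falling below its baseline, along with the full DR/PPV surfaces. The
sentinel reproduces the baseline, so a feasible solution always exists and
the achieved DR and PPV are never below baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .radpath_labeling import Criterion, LabeledLesion, label_lesions, sector_weights
from .synthetic_cohort import Lesion, SectorMap
from .diagnostic_stats import SCOPES, summarize

__all__ = [
    "ThresholdPair",
    "SearchGrid",
    "ThresholdSearchResult",
    "SENTINEL",
    "update_pirads",
    "relabel_with_qdce",
    "brute_force_thresholds",
]


@dataclass(frozen=True)
class ThresholdPair:
    """A (t_low, t_high) Ktrans cutoff pair in min^-1, 0 <= t_low <= t_high."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_low <= self.t_high):
            raise ValueError("require 0 <= t_low <= t_high")


#: the no-op pair: never downgrades (ktrans < 0 impossible), never upgrades
SENTINEL = ThresholdPair(0.0, math.inf)


@dataclass(frozen=True)
class SearchGrid:
    """Uniform threshold grid; defaults cover 0-0.35 min^-1 at 0.001 steps,
    matching the x1e-3 resolution at which tuned thresholds are reported."""

    lo: float = 0.0
    hi: float = 0.35
    step: float = 0.001

    def __post_init__(self) -> None:
        if self.lo < 0 or self.hi < self.lo or self.step <= 0:
            raise ValueError("need 0 <= lo <= hi and step > 0")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step)) + 1
        return np.linspace(self.lo, self.hi, n)


def update_pirads(pirads: int, ktrans: float, thresholds: ThresholdPair) -> int:
    """Apply the two-threshold Ktrans update to a single PI-RADS score."""
    if not 0 <= pirads <= 5:
        raise ValueError("pirads must be in 0..5")
    if not ktrans >= 0:
        raise ValueError("ktrans must be non-negative (and not NaN)")
    if pirads <= 2 and ktrans > thresholds.t_high:
        return 3
    if pirads >= 3 and ktrans < thresholds.t_low:
        return 2
    return pirads


def _lesions_of(labeled: Sequence[LabeledLesion | Lesion]) -> list[Lesion]:
    return [item.lesion if isinstance(item, LabeledLesion) else item for item in labeled]


def _require_ktrans(lesion: Lesion) -> float:
    if not math.isfinite(lesion.ktrans):
        raise ValueError(f"lesion {lesion.lesion_id} has no measured ktrans")
    return lesion.ktrans


def relabel_with_qdce(
    labeled: Sequence[LabeledLesion],
    thresholds: ThresholdPair,
    criterion: Criterion,
) -> list[LabeledLesion]:
    """Re-score every lesion with the Ktrans rule, then re-label.

    An MRI-occult pathology lesion (FN) whose Ktrans clears ``t_high``
    becomes MRI-positive (-> TP); a low-Ktrans false positive is downgraded
    below the criterion and drops out of the PPV denominator.
    """
    updated = []
    for lesion in _lesions_of(labeled):
        new_score = update_pirads(lesion.pirads, _require_ktrans(lesion), thresholds)
        updated.append(replace(lesion, pirads=new_score) if new_score != lesion.pirads else lesion)
    return label_lesions(updated, criterion)


@dataclass(frozen=True)
class ThresholdSearchResult:
    """Outcome of the exhaustive threshold scan."""

    thresholds: ThresholdPair
    dr: float
    ppv: float | None
    baseline_dr: float
    baseline_ppv: float | None
    n_rescored: int
    t_low_grid: np.ndarray
    t_high_grid: np.ndarray
    dr_surface: np.ndarray   # shape (len(t_low_grid), len(t_high_grid)); NaN where t_low > t_high
    ppv_surface: np.ndarray


def brute_force_thresholds(
    labeled: Sequence[LabeledLesion],
    grid: SearchGrid | None = None,
    criterion: Criterion = Criterion(3, 2),
    scope: str = "whole_gland",
    sector_map: SectorMap | None = None,
) -> ThresholdSearchResult:
    """Exhaustively search (t_low, t_high) pairs for the best DR at no PPV cost.

    Every pair on the grid with ``t_low <= t_high`` — plus the no-op
    sentinel — is evaluated; the winner maximizes DR subject to
    PPV >= baseline PPV, with deterministic tie-breaking: highest PPV,
    then fewest re-scored lesions, then smallest t_high, then smallest
    t_low. Because the update rule separates into a downgrade move that
    depends only on t_low (PI-RADS >= 3 lesions) and an upgrade move that
    depends only on t_high (PI-RADS <= 2 lesions), all counts are sums of
    two one-dimensional profiles and the full surfaces come out of a
    single vectorized pass.
    """
    if not labeled:
        raise ValueError("labeled lesion set is empty")
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    grid = grid or SearchGrid()
    lesions = _lesions_of(labeled)

    kt = np.array([_require_ktrans(l) for l in lesions])
    pirads = np.array([l.pirads for l in lesions])
    path = np.array([l.isup >= criterion.min_isup for l in lesions])
    if scope == "whole_gland":
        w = np.ones(len(lesions))
    else:
        if sector_map is None:
            raise ValueError("zone scopes require a sector map")
        w = np.array(
            [
                sum(
                    wt
                    for s, wt in sector_weights(l).items()
                    if sector_map.zone_of[s] == scope
                )
                for l in lesions
            ]
        )

    t_low = grid.values
    if t_low[0] > 0.0:
        t_low = np.concatenate(([0.0], t_low))
    t_high = np.concatenate((grid.values, [math.inf]))

    down = pirads >= 3  # downgrade candidates; MRI-positive iff also >= min_pirads
    up = ~down          # upgrade candidates (scores 0-2); upgraded score is exactly 3
    upgrade_counts = criterion.min_pirads <= 3

    def profile_low(mask: np.ndarray) -> np.ndarray:
        # weight that SURVIVES t_low (stays MRI-positive): kt >= t_low
        sel = down & (pirads >= criterion.min_pirads) & mask
        return (w[sel, None] * (kt[sel, None] >= t_low[None, :])).sum(axis=0)

    def profile_high(mask: np.ndarray) -> np.ndarray:
        # weight UPGRADED into MRI-positive: kt > t_high
        if not upgrade_counts:
            return np.zeros(t_high.size)
        sel = up & mask
        return (w[sel, None] * (kt[sel, None] > t_high[None, :])).sum(axis=0)

    tp = profile_low(path)[:, None] + profile_high(path)[None, :]
    fp = profile_low(~path)[:, None] + profile_high(~path)[None, :]
    path_total = float(w[path].sum())
    if path_total <= 0:
        raise ValueError("no pathology-positive weight in scope; DR undefined")

    n_changed = ((down[:, None] & (kt[:, None] < t_low[None, :])).sum(axis=0))[:, None] + (
        (up[:, None] & (kt[:, None] > t_high[None, :])).sum(axis=0)
    )[None, :]

    dr = tp / path_total
    denom = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(denom > 0, tp / np.where(denom > 0, denom, 1.0), np.nan)

    valid = t_low[:, None] <= t_high[None, :]
    i0 = int(np.searchsorted(t_low, 0.0))  # baseline: sentinel (0, +inf)
    j0 = t_high.size - 1
    baseline_dr = float(dr[i0, j0])
    baseline_ppv = float(ppv[i0, j0]) if np.isfinite(ppv[i0, j0]) else None

    feasible = valid & ((denom == 0) | np.isnan(ppv) | (ppv >= (baseline_ppv or 0.0) - 1e-12))
    idx = np.flatnonzero(feasible)
    ii, jj = np.unravel_index(idx, dr.shape)
    ppv_key = np.where(np.isnan(ppv.ravel()[idx]), -1.0, ppv.ravel()[idx])
    order = np.lexsort(
        (t_low[ii], t_high[jj], n_changed.ravel()[idx], -ppv_key, -dr.ravel()[idx])
    )
    bi, bj = int(ii[order[0]]), int(jj[order[0]])

    dr_surface = np.where(valid, dr, np.nan)
    ppv_surface = np.where(valid, ppv, np.nan)
    best_ppv = ppv[bi, bj]
    return ThresholdSearchResult(
        thresholds=ThresholdPair(float(t_low[bi]), float(t_high[bj])),
        dr=float(dr[bi, bj]),
        ppv=float(best_ppv) if np.isfinite(best_ppv) else None,
        baseline_dr=baseline_dr,
        baseline_ppv=baseline_ppv,
        n_rescored=int(n_changed[bi, bj]),
        t_low_grid=t_low,
        t_high_grid=t_high,
        dr_surface=dr_surface,
        ppv_surface=ppv_surface,
    )
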