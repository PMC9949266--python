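"""Radiology-pathology lesion labeling and sector weighting.

A lesion is MRI-positive when its PI-RADS score reaches the criterion's
minimum, and pathology-positive when its ISUP grade does. The truth table
is then

* TP — MRI-positive and pathology-positive,
* FP — MRI-positive, pathology-negative,
* FN — MRI-negative, pathology-positive,
* EXCLUDED — negative on both modalities under this criterion (a lesion
  record always carries at least one positive finding in absolute terms,
  but a strict criterion can render it doubly negative; such lesions carry
  zero weight and never enter any count).

Each non-excluded lesion distributes a total weight of exactly 1 uniformly
over the sectors it occupies, so zone-level counts are weighted sums while
whole-gland counts stay integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .synthetic_cohort import Lesion

__all__ = ["Criterion", "LabeledLesion", "label_lesions", "sector_weights", "LABELS"]

LABELS = ("TP", "FP", "FN", "EXCLUDED")


@dataclass(frozen=True)
class Criterion:
    """A (MRI-positive, pathology-positive) threshold pair.

    ``min_pirads`` in 3..5, ``min_isup`` in 1..5. The two analyses of
    record are (3, 1) — any cancer vs any suspicious MRI finding — and
    (3, 2) / (4, 2) for clinically significant cancer.
    """

    min_pirads: int = 3
    min_isup: int = 1

    def __post_init__(self) -> None:
        if not 3 <= self.min_pirads <= 5:
            raise ValueError("min_pirads must be in 3..5")
        if not 1 <= self.min_isup <= 5:
            raise ValueError("min_isup must be in 1..5")

    def mri_positive(self, lesion: Lesion) -> bool:
        return lesion.pirads >= self.min_pirads

    def path_positive(self, lesion: Lesion) -> bool:
        return lesion.isup >= self.min_isup


@dataclass(frozen=True)
class LabeledLesion:
    """A lesion together with its TP/FP/FN/EXCLUDED label and sector weights."""

    lesion: Lesion
    label: str
    sector_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        total = sum(self.sector_weights.values())
        if self.label == "EXCLUDED":
            if total != 0:
                raise ValueError("EXCLUDED lesions must carry zero weight")
        elif abs(total - 1.0) > 1e-9:
            raise ValueError("sector weights of a counted lesion must sum to 1")


def sector_weights(lesion: Lesion) -> dict[str, float]:
    """Uniform per-sector weights: each occupied sector gets 1/|sectors|."""
    if not lesion.sectors:
        raise ValueError("lesion has no sectors")
    w = 1.0 / len(lesion.sectors)
    return {s: w for s in sorted(lesion.sectors)}


def classify(lesion: Lesion, criterion: Criterion) -> str:
    mri = criterion.mri_positive(lesion)
    path = criterion.path_positive(lesion)
    if mri and path:
        return "TP"
    if mri:
        return "FP"
    if path:
        return "FN"
    return "EXCLUDED"


def label_lesions(lesions: Sequence[Lesion], criterion: Criterion) -> list[LabeledLesion]:
    """Label every lesion under the criterion and attach its sector weights.

    Total function on valid lesions; deterministic.
    """
    out = []
    for lesion in lesions:
        label = classify(lesion, criterion)
        weights = {} if label == "EXCLUDED" else sector_weights(lesion)
        out.append(LabeledLesion(lesion, label, weights))
    return out
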