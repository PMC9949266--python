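import numpy as np
import pytest

from qdce_pirads.synthetic_cohort import (
    CohortConfig,
    Lesion,
    LognormalSpec,
    SectorMap,
    default_cohort_config,
)


@pytest.fixture
def sector_map() -> SectorMap:
    return SectorMap.default()


@pytest.fixture
def fig2_lesions() -> list[Lesion]:
    """The three-lesion worked example: one concordant lesion (PI-RADS 4,
    ISUP 3), one MRI-only finding (PI-RADS 3, no pathology) and one
    MRI-occult pathology lesion (ISUP 1)."""
    return [
        Lesion("L1", "P1", isup=3, pirads=4, zone="PZ", sectors={"PZ1"}, ktrans=0.25),
        Lesion("L2", "P1", isup=0, pirads=3, zone="PZ", sectors={"PZ2"}, ktrans=0.15),
        Lesion("L3", "P1", isup=1, pirads=0, zone="TZ", sectors={"TZ1"}, ktrans=0.30),
    ]


@pytest.fixture
def cohort_config() -> CohortConfig:
    return default_cohort_config(seed=42)


def make_confounded_config(seed: int) -> CohortConfig:
    """Pre-matching cohort: covariates per the unmatched characteristics
    table — AA men present with larger prostate volumes (median 41 vs 37 cc),
    so PV confounds the group comparison."""
    import dataclasses

    base = default_cohort_config(seed=seed)
    aa = dataclasses.replace(
        base.groups["AA"],
        age=LognormalSpec(61.0, 10.0),
        psa=LognormalSpec(6.7, 2.6),
        pv=LognormalSpec(41.0, 22.0),
    )
    w = dataclasses.replace(
        base.groups["W"],
        age=LognormalSpec(63.0, 10.0),
        psa=LognormalSpec(6.2, 4.7),
        pv=LognormalSpec(37.0, 18.0),
    )
    return dataclasses.replace(base, groups={"AA": aa, "W": w})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
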