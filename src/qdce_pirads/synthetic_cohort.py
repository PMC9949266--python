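"""Seeded synthetic prostate-mpMRI cohorts.

Generates patients (two self-identified race strata, AA and W, with
matched-cohort clinical covariates), lesions (pathology ISUP grade, MRI
PI-RADS score, zone and sector placement, quantitative Ktrans/kep/ADC),
and Tofts-model DCE concentration curves, so that the whole downstream
pipeline — matching, radiology-pathology labeling, diagnostic statistics
and threshold tuning — is exercisable without any patient data.

Design of the generative model:

* clinical covariates (age, PSA, prostate volume) are log-normal, matched
  to printed median/IQR — strictly positive, right-skewed variables;
* pathology lesion multiplicity is ``1 + Poisson(lambda)`` per patient
  (every prostatectomy patient carries at least one pathology lesion);
* each pathology lesion is MRI-detected with a per-group probability;
  detected lesions draw a PI-RADS score from the per-group category
  frequencies, undetected ones are MRI-occult (``pirads = 0``);
* MRI-only findings (``isup = 0``, i.e. pathology-negative) arrive as an
  independent per-patient Poisson stream;
* quantitative MRI values are normals truncated at zero, keyed by
  (race group, lesion category) — published summaries are mean +/- SD and
  the quantities are physically non-negative.

Everything is driven by :class:`CohortConfig`; the module-level default
configuration encodes the matched-cohort summary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .pk_models import ConcentrationCurve, ParkerAIF, ToftsParams, parker_aif, tofts_forward

__all__ = [
    "RACE_GROUPS",
    "ZONES",
    "Patient",
    "Lesion",
    "SectorMap",
    "LognormalSpec",
    "TruncNormSpec",
    "GroupConfig",
    "CohortConfig",
    "DceAcquisition",
    "default_cohort_config",
    "generate_patients",
    "generate_lesions",
    "generate_dce_curve",
    "sample_quantitative",
    "validate_lesion_sectors",
]

RACE_GROUPS = ("AA", "W")
ZONES = ("TZ", "PZ")

#: lesion categories keying the quantitative-MRI distributions
CATEGORIES = ("isup1", "cspca", "mri_only")

_Z75 = 0.6744897501960817  # standard normal 75th percentile


def _is_missing(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass(frozen=True)
class Patient:
    """A matched-cohort patient: clinical covariates plus race-group label."""

    patient_id: str
    race_group: str
    age: float
    psa: float
    pv: float

    def __post_init__(self) -> None:
        if self.race_group not in RACE_GROUPS:
            raise ValueError(f"race_group must be one of {RACE_GROUPS}")
        if not (self.age > 0 and self.psa > 0 and self.pv > 0):
            raise ValueError("age, psa and pv must all be positive")

    @property
    def psad(self) -> float:
        """PSA density, ng/mL/cc (PSA / prostate volume)."""
        return self.psa / self.pv


@dataclass(frozen=True)
class SectorMap:
    """Zone-labelled partition of the prostate into sectors.

    The default is a simplified 12-sector sheet (6 transition-zone, 6
    peripheral-zone sectors); any richer map — up to a full PI-RADS v2.1
    sector sheet — can be supplied as long as every sector carries exactly
    one zone and each zone is non-empty.
    """

    sector_ids: tuple[str, ...]
    zone_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.sector_ids) != set(self.zone_of):
            raise ValueError("sector_ids and zone_of must cover the same sectors")
        bad = {z for z in self.zone_of.values() if z not in ZONES}
        if bad:
            raise ValueError(f"unknown zones in sector map: {sorted(bad)}")
        for zone in ZONES:
            if not any(z == zone for z in self.zone_of.values()):
                raise ValueError(f"sector map has no sector in zone {zone}")

    def sectors_in(self, zone: str) -> tuple[str, ...]:
        return tuple(s for s in self.sector_ids if self.zone_of[s] == zone)

    @classmethod
    def default(cls, n_tz: int = 6, n_pz: int = 6) -> "SectorMap":
        ids = tuple(f"TZ{i+1}" for i in range(n_tz)) + tuple(f"PZ{i+1}" for i in range(n_pz))
        return cls(ids, {s: s[:2] for s in ids})


@dataclass(frozen=True)
class Lesion:
    """A unified lesion record: pathology truth, MRI finding, quantitative MRI.

    ``isup == 0`` marks an MRI-only finding with no pathology correlate;
    ``pirads == 0`` marks an MRI-occult lesion found only on whole-mount
    histopathology. A record negative on both modalities is invalid.
    Quantitative values may be NaN (not measured); measured values must be
    non-negative (ADC strictly positive).
    """

    lesion_id: str
    patient_id: str
    isup: int
    pirads: int
    zone: str
    sectors: frozenset[str]
    ktrans: float = float("nan")
    kep: float = float("nan")
    adc: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.isup <= 5 and 0 <= self.pirads <= 5):
            raise ValueError("isup and pirads must be in 0..5")
        if self.isup == 0 and self.pirads == 0:
            raise ValueError("lesion must be MRI-positive and/or pathology-positive")
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}")
        if not self.sectors:
            raise ValueError("lesion must occupy at least one sector")
        object.__setattr__(self, "sectors", frozenset(self.sectors))
        for name, val in (("ktrans", self.ktrans), ("kep", self.kep)):
            if not _is_missing(val) and not val >= 0:
                raise ValueError(f"{name} must be >= 0 when measured")
        if not _is_missing(self.adc) and not self.adc > 0:
            raise ValueError("adc must be > 0 when measured")


def validate_lesion_sectors(lesion: Lesion, sector_map: SectorMap) -> None:
    """Raise if any of the lesion's sectors lies outside its declared zone."""
    for s in lesion.sectors:
        if s not in sector_map.zone_of:
            raise ValueError(f"lesion {lesion.lesion_id}: unknown sector {s!r}")
        if sector_map.zone_of[s] != lesion.zone:
            raise ValueError(
                f"lesion {lesion.lesion_id}: sector {s!r} is in zone "
                f"{sector_map.zone_of[s]}, not {lesion.zone}"
            )


@dataclass(frozen=True)
class LognormalSpec:
    """Log-normal distribution pinned to a printed median and IQR."""

    median: float
    iqr: float

    def __post_init__(self) -> None:
        if not (self.median > 0 and self.iqr > 0):
            raise ValueError("median and iqr must be positive")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        # q75 - q25 = median * (e^{z sigma} - e^{-z sigma}) with z = 0.6745
        return math.asinh(self.iqr / (2.0 * self.median)) / _Z75

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(self.mu, self.sigma, size=n))

    def quantile(self, q: float) -> float:
        return math.exp(self.mu + self.sigma * stats.norm.ppf(q))


@dataclass(frozen=True)
class TruncNormSpec:
    """Normal(mean, sd) truncated at zero — for non-negative quantitative MRI."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("scale must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a = -self.mean / self.sd  # truncation boundary in standard units
        return stats.truncnorm.rvs(a, np.inf, loc=self.mean, scale=self.sd, size=n, random_state=rng)

    @property
    def truncated_mean(self) -> float:
        """Exact mean of the zero-truncated distribution."""
        a = -self.mean / self.sd
        return self.mean + self.sd * stats.norm.pdf(a) / stats.norm.sf(a)


def _check_freqs(name: str, freqs: Mapping[int, float]) -> None:
    if not freqs:
        raise ValueError(f"{name}: empty frequency table")
    if any(v < 0 for v in freqs.values()):
        raise ValueError(f"{name}: negative frequency")
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name}: frequencies must sum to 1 (got {sum(freqs.values())})")


@dataclass(frozen=True)
class GroupConfig:
    """Per-race-group generative parameters."""

    age: LognormalSpec
    psa: LognormalSpec
    pv: LognormalSpec
    lesions_per_patient_mean: float
    isup_freqs: Mapping[int, float]      # over grades 1..5, pathology lesions
    pirads_freqs: Mapping[int, float]    # over scores 3..5, MRI-visible lesions
    detection_prob: Mapping[str, float]  # P(MRI-visible) per category isup1/cspca
    mri_only_rate: float                 # Poisson rate of isup=0 findings / patient
    quant: Mapping[str, Mapping[str, TruncNormSpec]]  # category -> param -> spec

    def __post_init__(self) -> None:
        if self.lesions_per_patient_mean < 1:
            raise ValueError("lesions/patient mean must be >= 1 (every patient has a lesion)")
        for cat in ("isup1", "cspca"):
            if not 0 <= self.detection_prob.get(cat, -1) <= 1:
                raise ValueError(f"detection_prob[{cat!r}] must be a probability")
        if self.mri_only_rate < 0:
            raise ValueError("mri_only_rate must be >= 0")
        _check_freqs("isup_freqs", self.isup_freqs)
        _check_freqs("pirads_freqs", self.pirads_freqs)
        for cat in CATEGORIES:
            if cat not in self.quant:
                raise ValueError(f"missing quantitative spec for category {cat!r}")
            for param in ("ktrans", "kep", "adc"):
                if param not in self.quant[cat]:
                    raise ValueError(f"missing {param!r} spec for category {cat!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Full synthetic-cohort configuration (two groups + shared structure)."""

    groups: Mapping[str, GroupConfig]
    p_tz: float = 0.30
    sector_span_freqs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.30, 3: 0.15, 4: 0.10}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.groups) != set(RACE_GROUPS):
            raise ValueError(f"groups must be exactly {RACE_GROUPS}")
        if not 0 <= self.p_tz <= 1:
            raise ValueError("p_tz must be a probability")
        _check_freqs("sector_span_freqs", self.sector_span_freqs)
        if any(k < 1 for k in self.sector_span_freqs):
            raise ValueError("sector spans must be >= 1")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def _quant_table(
    ktrans: tuple[float, float], kep: tuple[float, float], adc: tuple[float, float]
) -> Mapping[str, TruncNormSpec]:
    return {
        "ktrans": TruncNormSpec(*ktrans),
        "kep": TruncNormSpec(*kep),
        "adc": TruncNormSpec(*adc),
    }


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Matched-cohort defaults.

    Clinical covariates use the post-matching medians/IQRs; ISUP and
    PI-RADS category frequencies come from the printed per-group lesion
    counts (the ISUP >= 4 and PI-RADS >= 4 rows are split 70/30 into their
    constituent grades, which the source tables do not break down);
    per-category detection probabilities and the MRI-only rates are
    calibrated jointly from the all-lesion and csPCa TP/FN/FP counts
    (e.g. AA: 32 of 41 csPCa lesions MRI-detected, 36 of 63 overall, 8
    pathology-negative MRI findings over 37 patients). Quantitative distributions (Ktrans and kep
    in min^-1, ADC in 1e-6 mm^2/s) are the per-group mean +/- SD summaries:
    ISUP grade 1, ISUP grade >= 2 (csPCa), and — for pathology-negative
    MRI-only findings — the PI-RADS >= 3 MRI-based row.
    """
    aa = GroupConfig(
        age=LognormalSpec(61.0, 9.75),
        psa=LognormalSpec(6.7, 2.5),
        pv=LognormalSpec(41.0, 23.0),
        lesions_per_patient_mean=1.7,
        isup_freqs=_normalize({1: 22, 2: 27, 3: 9, 4: 3.5, 5: 1.5}),
        pirads_freqs=_normalize({3: 11, 4: 23.1, 5: 9.9}),
        detection_prob={"isup1": 4 / 22, "cspca": 32 / 41},
        mri_only_rate=8 / 37,
        quant={
            "isup1": _quant_table((0.2070, 0.1206), (0.6137, 0.1961), (953.0, 96.9)),
            "cspca": _quant_table((0.2322, 0.1024), (0.6804, 0.1881), (909.0, 211.0)),
            "mri_only": _quant_table((0.2338, 0.1075), (0.6788, 0.1887), (945.1, 222.1)),
        },
    )
    w = GroupConfig(
        age=LognormalSpec(62.0, 10.0),
        psa=LognormalSpec(5.95, 4.6),
        pv=LognormalSpec(40.0, 22.5),
        lesions_per_patient_mean=1.5,
        isup_freqs=_normalize({1: 28, 2: 55, 3: 19, 4: 6.3, 5: 2.7}),
        pirads_freqs=_normalize({3: 18, 4: 44.8, 5: 19.2}),
        detection_prob={"isup1": 10 / 28, "cspca": 64 / 83},
        mri_only_rate=9 / 74,
        quant={
            "isup1": _quant_table((0.1898, 0.1499), (0.5836, 0.2682), (954.0, 191.0)),
            "cspca": _quant_table((0.1877, 0.0797), (0.6606, 0.2378), (899.0, 171.0)),
            "mri_only": _quant_table((0.1865, 0.0961), (0.6548, 0.2443), (901.5, 170.3)),
        },
    )
    return CohortConfig(groups={"AA": aa, "W": w}, seed=seed)


def _normalize(counts: Mapping[int, float]) -> Mapping[int, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


# rng stream ids, spawned off the config seed so stages are independent
_STREAM_PATIENTS, _STREAM_LESIONS, _STREAM_CURVES = 0, 1, 2


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def generate_patients(config: CohortConfig, n_aa: int, n_w: int) -> list[Patient]:
    """Draw a two-group patient cohort from the configured covariate model.

    Deterministic for a fixed ``config.seed``; returns exactly ``n_aa`` AA
    followed by ``n_w`` W patients.
    """
    if n_aa <= 0 or n_w <= 0:
        raise ValueError("both group sizes must be positive")
    rng = _rng(config, _STREAM_PATIENTS)
    patients: list[Patient] = []
    for group, n in (("AA", n_aa), ("W", n_w)):
        g = config.groups[group]
        age = g.age.sample(rng, n)
        psa = g.psa.sample(rng, n)
        pv = g.pv.sample(rng, n)
        for i in range(n):
            patients.append(
                Patient(f"{group}-{i+1:04d}", group, float(age[i]), float(psa[i]), float(pv[i]))
            )
    return patients


def lesion_category(isup: int) -> str:
    """Quantitative-distribution category for a lesion's pathology grade."""
    if isup >= 2:
        return "cspca"
    if isup == 1:
        return "isup1"
    return "mri_only"


def sample_quantitative(
    config: CohortConfig,
    group: str,
    category: str,
    param: str,
    n: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` values of a quantitative-MRI parameter for one stratum.

    Uses the same zero-truncated normal sampler that ``generate_lesions``
    uses internally, so stratum-level summaries computed from these draws
    reflect the generator exactly.
    """
    if rng is None:
        rng = _rng(config, _STREAM_LESIONS)
    return config.groups[group].quant[category][param].sample(rng, n)


def _draw_cat(rng: np.random.Generator, freqs: Mapping[int, float]) -> int:
    keys = sorted(freqs)
    return int(rng.choice(keys, p=[freqs[k] for k in keys]))


def generate_lesions(
    patients: Sequence[Patient],
    config: CohortConfig,
    sector_map: SectorMap | None = None,
) -> list[Lesion]:
    """Generate pathology and MRI-only lesions for every patient.

    Each patient receives ``1 + Poisson(mean - 1)`` pathology lesions and an
    independent ``Poisson(mri_only_rate)`` count of pathology-negative MRI
    findings. Zone, sector span and quantitative values follow the config;
    all returned lesions satisfy the type invariants and are sector-
    consistent with ``sector_map``.
    """
    if not patients:
        raise ValueError("patients must be non-empty")
    sector_map = sector_map or SectorMap.default()
    for zone in ZONES:
        if not sector_map.sectors_in(zone):
            raise ValueError(f"sector map has no sectors in zone {zone}")
    rng = _rng(config, _STREAM_LESIONS)
    lesions: list[Lesion] = []
    for p in patients:
        g = config.groups[p.race_group]
        n_path = 1 + int(rng.poisson(g.lesions_per_patient_mean - 1.0))
        n_mri_only = int(rng.poisson(g.mri_only_rate))
        for j in range(n_path + n_mri_only):
            if j < n_path:
                isup = _draw_cat(rng, g.isup_freqs)
                detected = rng.random() < g.detection_prob[lesion_category(isup)]
                pirads = _draw_cat(rng, g.pirads_freqs) if detected else 0
            else:
                isup = 0
                pirads = _draw_cat(rng, g.pirads_freqs)
            zone = "TZ" if rng.random() < config.p_tz else "PZ"
            pool = sector_map.sectors_in(zone)
            span = min(_draw_cat(rng, config.sector_span_freqs), len(pool))
            picked = rng.choice(len(pool), size=span, replace=False)
            sectors = frozenset(pool[int(i)] for i in picked)
            cat = lesion_category(isup)
            q = g.quant[cat]
            lesion = Lesion(
                lesion_id=f"{p.patient_id}-L{j+1}",
                patient_id=p.patient_id,
                isup=isup,
                pirads=pirads,
                zone=zone,
                sectors=sectors,
                ktrans=float(q["ktrans"].sample(rng, 1)[0]),
                kep=float(q["kep"].sample(rng, 1)[0]),
                adc=float(q["adc"].sample(rng, 1)[0]),
            )
            validate_lesion_sectors(lesion, sector_map)
            lesions.append(lesion)
    return lesions


@dataclass(frozen=True)
class DceAcquisition:
    """DCE-MRI acquisition timing: frame spacing and pre/post frame counts.

    Defaults mirror the scanned protocol — 5 baseline frames, ~70
    post-injection frames at 5 s temporal resolution.
    """

    dt: float = 5.0       # seconds
    n_pre: int = 5
    n_post: int = 70

    def __post_init__(self) -> None:
        if not 4.0 <= self.dt <= 8.0:
            raise ValueError("temporal resolution dt must be in [4, 8] seconds")
        if self.n_pre < 1:
            raise ValueError("need at least one pre-contrast frame")
        if self.n_post < 2:
            raise ValueError("need at least two post-contrast frames")

    @property
    def times_minutes(self) -> np.ndarray:
        return np.arange(self.n_pre + self.n_post) * self.dt / 60.0


def generate_dce_curve(
    lesion: Lesion,
    acquisition: DceAcquisition | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    aif_params: ParkerAIF | None = None,
) -> ConcentrationCurve:
    """Simulate a lesion's tissue concentration curve.

    The first ``n_pre`` frames are zero-mean baseline; from injection
    onward the curve is the Tofts forward model with the lesion's
    (ktrans, kep) driven by the Parker population AIF, plus additive
    zero-mean Gaussian noise of standard deviation ``noise_sd`` (mmol/L).
    """
    acquisition = acquisition or DceAcquisition()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if _is_missing(lesion.ktrans) or _is_missing(lesion.kep):
        raise ValueError(f"lesion {lesion.lesion_id} has no (ktrans, kep) to simulate from")
    t_post = np.arange(acquisition.n_post) * acquisition.dt / 60.0
    model = aif_params or ParkerAIF()
    aif = parker_aif(t_post, model)
    ct = tofts_forward(ToftsParams(lesion.ktrans, lesion.kep), aif, aif_model=model)
    c = np.concatenate([np.zeros(acquisition.n_pre), ct.c])
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        c = c + rng.normal(0.0, noise_sd, size=c.size)
    return ConcentrationCurve(acquisition.times_minutes, c)
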