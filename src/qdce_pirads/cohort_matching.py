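"""Propensity-score caliper matching of AA to W patients.

Group membership (AA = 1) is modelled by maximum-likelihood logistic
regression on age, PSA and prostate volume; AA cases are then greedily
matched 1:ratio to W controls without replacement on the logit-propensity
scale, subject to a caliper (default 0.2 x SD of the logit propensity,
the conventional width). Cases are processed in descending propensity
order with ties broken by patient id, so matching is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diagnostic_stats import mann_whitney
from .synthetic_cohort import Patient

__all__ = [
    "MatchResult",
    "estimate_propensity",
    "caliper_match",
    "match_cohort",
    "standardized_mean_difference",
    "balance_table",
]

DEFAULT_COVARIATES = ("age", "psa", "pv")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a 1:ratio caliper match."""

    matched_sets: tuple[tuple[str, tuple[str, ...]], ...]
    propensity: Mapping[str, float]
    caliper_used: float
    dropped_cases: tuple[str, ...]

    @property
    def matched_ids(self) -> tuple[str, ...]:
        """All matched patient ids, cases first within each set."""
        out: list[str] = []
        for case, controls in self.matched_sets:
            out.append(case)
            out.extend(controls)
        return tuple(out)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def estimate_propensity(
    patients: Sequence[Patient],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> dict[str, float]:
    """Fit a logistic propensity model P(group == AA | covariates).

    Returns a patient_id -> probability mapping with every value strictly
    inside (0, 1). Deterministic (no randomness in the MLE). Raises
    ``ValueError`` with guidance when the groups are perfectly separated
    and the MLE diverges.
    """
    groups = {p.race_group for p in patients}
    if groups != {"AA", "W"}:
        raise ValueError("both AA and W patients are required to fit a propensity model")
    x = np.array([[getattr(p, c) for c in covariates] for p in patients], dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite")
    y = np.array([1.0 if p.race_group == "AA" else 0.0 for p in patients])
    model = sm.Logit(y, sm.add_constant(x))
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError here
        raise ValueError(
            "propensity model failed to fit — groups are likely perfectly "
            "separated on the chosen covariates; drop or coarsen a covariate"
        ) from exc
    probs = np.asarray(res.predict())
    if not res.mle_retvals.get("converged", True) or np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError(
            "propensity MLE did not converge to interior probabilities — "
            "check for perfect separation on the covariates"
        )
    return {p.patient_id: float(pr) for p, pr in zip(patients, probs)}


def caliper_match(
    propensity: Mapping[str, float],
    cases: Sequence[str],
    controls: Sequence[str],
    ratio: int = 2,
    caliper: float | None = None,
) -> MatchResult:
    """Greedy nearest-neighbour 1:ratio matching without replacement.

    Distances are on the logit-propensity scale. A case needing fewer than
    ``ratio`` in-caliper controls is dropped (its candidate controls are
    not consumed). ``caliper`` defaults to 0.2 x SD of the logit
    propensities of all listed patients.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if not cases or not controls:
        raise ValueError("both case and control pools must be non-empty")
    logits = {pid: _logit(propensity[pid]) for pid in list(cases) + list(controls)}
    if caliper is None:
        caliper = 0.2 * float(np.std(list(logits.values()), ddof=1))
    if not caliper > 0:
        raise ValueError("caliper must be positive")

    # descending propensity, ties broken by id, for a deterministic order
    order = sorted(cases, key=lambda pid: (-logits[pid], pid))
    available = sorted(controls)
    matched: list[tuple[str, tuple[str, ...]]] = []
    dropped: list[str] = []
    for case in order:
        ranked = sorted(available, key=lambda cid: (abs(logits[cid] - logits[case]), cid))
        picks = [cid for cid in ranked if abs(logits[cid] - logits[case]) <= caliper][:ratio]
        if len(picks) < ratio:
            dropped.append(case)
            continue
        for cid in picks:
            available.remove(cid)
        matched.append((case, tuple(picks)))
    return MatchResult(tuple(matched), dict(propensity), float(caliper), tuple(dropped))


def match_cohort(
    patients: Sequence[Patient],
    ratio: int = 2,
    caliper: float | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> MatchResult:
    """Estimate propensities and run the 1:ratio caliper match in one call."""
    prop = estimate_propensity(patients, covariates)
    cases = [p.patient_id for p in patients if p.race_group == "AA"]
    controls = [p.patient_id for p in patients if p.race_group == "W"]
    return caliper_match(prop, cases, controls, ratio=ratio, caliper=caliper)


def standardized_mean_difference(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen-style SMD: (mean_x - mean_y) / pooled SD."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = math.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def balance_table(
    patients: Sequence[Patient],
    result: MatchResult,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Pre-/post-matching covariate balance: medians, IQRs, SMD, Mann-Whitney p.

    One row per covariate and stage (pre/post), shaped like the cohort
    characteristics tables of a matched-cohort report.
    """
    by_id = {p.patient_id: p for p in patients}
    matched = [by_id[i] for i in result.matched_ids]
    rows = []
    for stage, pool in (("pre", list(patients)), ("post", matched)):
        aa = [p for p in pool if p.race_group == "AA"]
        w = [p for p in pool if p.race_group == "W"]
        for cov in covariates:
            xa = np.array([getattr(p, cov) for p in aa])
            xw = np.array([getattr(p, cov) for p in w])
            _, pval = mann_whitney(xa, xw)
            rows.append(
                {
                    "stage": stage,
                    "covariate": cov,
                    "n_aa": len(xa),
                    "n_w": len(xw),
                    "median_aa": np.median(xa),
                    "iqr_aa": np.subtract(*np.percentile(xa, [75, 25])),
                    "median_w": np.median(xw),
                    "iqr_w": np.subtract(*np.percentile(xw, [75, 25])),
                    "smd": standardized_mean_difference(xa, xw),
                    "mw_p": pval,
                }
            )
    return pd.DataFrame(rows)
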