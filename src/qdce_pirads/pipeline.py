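"""End-to-end orchestration: simulate -> match -> fit -> label -> evaluate ->
tune -> report.

Every stage reads and writes plain CSV/JSON files inside an output
directory, so stages are independently re-runnable from the command line
and the whole pipeline is a pure function of (config, seed): re-running
with the same configuration reproduces byte-identical outputs.

The default configuration emulates the study design: a patient pool with
an AA:W imbalance is generated, AA cases are propensity-matched 1:2 to W
controls on age/PSA/PV, lesions and noisy DCE curves are simulated for
the matched cohort, Ktrans/kep are re-estimated from the curves by the
Tofts fit, lesions are labeled TP/FP/FN under the configured criteria,
zone-stratified CP/DR/PPV are compared between groups, and race-specific
Ktrans thresholds are tuned by exhaustive search.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as qio
from .cohort_matching import balance_table, match_cohort
from .diagnostic_stats import lesions_per_patient, mann_whitney, summarize, weighted_chisq
from .pirads_qdce import SearchGrid, brute_force_thresholds, relabel_with_qdce
from .pk_models import fit_dce_curve
from .radpath_labeling import Criterion, label_lesions
from .synthetic_cohort import (
    CohortConfig,
    DceAcquisition,
    SectorMap,
    default_cohort_config,
    generate_dce_curve,
    generate_lesions,
    generate_patients,
)

__all__ = ["PipelineConfig", "run_pipeline",
           "stage_simulate", "stage_match", "stage_fit", "stage_label",
           "stage_evaluate", "stage_tune", "stage_report"]

log = logging.getLogger("qdce_pirads")

SCOPES = ("whole_gland", "TZ", "PZ")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs; ``seed`` governs every source of randomness."""

    seed: int = 7
    n_aa: int = 37
    n_w_pool: int = 185
    ratio: int = 2
    caliper: float | None = None
    noise_sd: float = 0.02            # mmol/L additive curve noise
    acquisition: DceAcquisition = field(default_factory=DceAcquisition)
    criteria: tuple[Criterion, ...] = (Criterion(3, 1), Criterion(3, 2))
    tune_criterion: Criterion = Criterion(3, 2)
    grid: SearchGrid = field(default_factory=SearchGrid)
    alpha: float = 0.05
    cohort: CohortConfig | None = None
    write_surfaces: bool = False

    def __post_init__(self) -> None:
        cohort = self.cohort or default_cohort_config()
        object.__setattr__(self, "cohort", cohort.with_seed(self.seed))

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        """Build a config from a YAML file of overrides (all keys optional)."""
        data = qio.load_yaml(path)
        kwargs: dict = {}
        for key in ("seed", "n_aa", "n_w_pool", "ratio", "caliper", "noise_sd",
                    "alpha", "write_surfaces"):
            if key in data:
                kwargs[key] = data[key]
        if "acquisition" in data:
            kwargs["acquisition"] = DceAcquisition(**data["acquisition"])
        if "criteria" in data:
            kwargs["criteria"] = tuple(Criterion(int(mp), int(mi)) for mp, mi in data["criteria"])
        if "tune_criterion" in data:
            mp, mi = data["tune_criterion"]
            kwargs["tune_criterion"] = Criterion(int(mp), int(mi))
        if "grid" in data:
            kwargs["grid"] = SearchGrid(**data["grid"])
        if "cohort" in data:
            kwargs["cohort"] = qio.cohort_config_from_dict(data["cohort"])
        if seed is not None:
            kwargs["seed"] = seed
        return cls(**kwargs)


def _crit_tag(criterion: Criterion) -> str:
    return f"pirads{criterion.min_pirads}_isup{criterion.min_isup}"


def _matched_ids(outdir: Path) -> set[str] | None:
    path = outdir / "matched_patients.csv"
    if not path.exists():
        return None
    return set(pd.read_csv(path)["patient_id"].astype(str))


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    """Generate the patient pool and its lesions; write patients/lesions CSV."""
    outdir.mkdir(parents=True, exist_ok=True)
    patients = generate_patients(config.cohort, config.n_aa, config.n_w_pool)
    lesions = generate_lesions(patients, config.cohort, SectorMap.default())
    qio.patients_to_frame(patients).to_csv(outdir / "patients.csv", index=False)
    qio.lesions_to_frame(lesions).to_csv(outdir / "lesions.csv", index=False)
    log.info("simulate: %d patients -> %d lesions", len(patients), len(lesions))


def stage_match(config: PipelineConfig, outdir: Path) -> None:
    """Propensity-match AA to W 1:ratio; write matched cohort + balance report."""
    patients = qio.frame_to_patients(pd.read_csv(outdir / "patients.csv"))
    result = match_cohort(patients, ratio=config.ratio, caliper=config.caliper)
    by_id = {p.patient_id: p for p in patients}
    rows = []
    for set_idx, (case, controls) in enumerate(result.matched_sets):
        for role, pid in [("case", case)] + [("control", c) for c in controls]:
            p = by_id[pid]
            rows.append({"patient_id": pid, "race_group": p.race_group, "age": p.age,
                         "psa": p.psa, "pv": p.pv, "psad": p.psad,
                         "matched_set": set_idx, "role": role,
                         "propensity": result.propensity[pid]})
    pd.DataFrame(rows).to_csv(outdir / "matched_patients.csv", index=False)
    balance_table(patients, result).to_csv(outdir / "balance.csv", index=False)
    log.info("match: %d sets (1:%d), %d cases dropped, caliper %.4f",
             len(result.matched_sets), config.ratio, len(result.dropped_cases),
             result.caliper_used)


def stage_fit(config: PipelineConfig, outdir: Path) -> None:
    """Simulate each matched lesion's DCE curve and re-estimate (ktrans, kep).

    Writes the curves (long CSV), per-lesion fit diagnostics and
    ``lesions_fitted.csv`` in which ktrans/kep are the fitted estimates —
    downstream stages consume measured, not generative, values.
    """
    lesions = qio.frame_to_lesions(pd.read_csv(outdir / "lesions.csv"))
    matched = _matched_ids(outdir)
    if matched is not None:
        lesions = [l for l in lesions if l.patient_id in matched]
    curves, fits, fitted = {}, [], []
    for i, lesion in enumerate(lesions):
        rng = np.random.default_rng([config.seed, 2, i])
        curve = generate_dce_curve(lesion, config.acquisition, config.noise_sd, rng)
        fit = fit_dce_curve(curve, config.acquisition.n_pre)
        curves[lesion.lesion_id] = curve
        fits.append({"lesion_id": lesion.lesion_id,
                     "ktrans_true": lesion.ktrans, "kep_true": lesion.kep,
                     "ktrans_fit": fit.params.ktrans, "kep_fit": fit.params.kep,
                     "residual_norm": fit.residual_norm, "converged": fit.converged})
        fitted.append(replace(lesion, ktrans=fit.params.ktrans, kep=fit.params.kep))
    qio.write_curves_csv(curves, outdir / "dce_curves.csv")
    pd.DataFrame(fits).to_csv(outdir / "dce_fits.csv", index=False)
    qio.lesions_to_frame(fitted).to_csv(outdir / "lesions_fitted.csv", index=False)
    log.info("fit: %d lesions fitted (noise SD %.3f mmol/L)", len(fitted), config.noise_sd)


def _analysis_lesions(outdir: Path) -> pd.DataFrame:
    path = outdir / "lesions_fitted.csv"
    if not path.exists():
        path = outdir / "lesions.csv"
    df = pd.read_csv(path)
    matched = _matched_ids(outdir)
    if matched is not None:
        df = df[df["patient_id"].astype(str).isin(matched)].reset_index(drop=True)
    return df


def stage_label(config: PipelineConfig, outdir: Path) -> None:
    """Label lesions TP/FP/FN/EXCLUDED under each configured criterion."""
    lesions = qio.frame_to_lesions(_analysis_lesions(outdir))
    for criterion in config.criteria:
        labeled = label_lesions(lesions, criterion)
        qio.labeled_to_frame(labeled).to_csv(
            outdir / f"labeled_{_crit_tag(criterion)}.csv", index=False
        )
        counts = pd.Series([x.label for x in labeled]).value_counts().to_dict()
        log.info("label %s: %s", _crit_tag(criterion), counts)


def _group_of(outdir: Path) -> Mapping[str, str]:
    df = pd.read_csv(outdir / "patients.csv")
    return dict(zip(df["patient_id"].astype(str), df["race_group"].astype(str)))


def stage_evaluate(config: PipelineConfig, outdir: Path) -> None:
    """Zone-stratified CP/DR/PPV per group and the between-group tests."""
    group_of = _group_of(outdir)
    sector_map = SectorMap.default()
    diag_rows, cmp_rows = [], []
    for criterion in config.criteria:
        tag = _crit_tag(criterion)
        labeled = qio.frame_to_labeled(pd.read_csv(outdir / f"labeled_{tag}.csv"))
        per_group = {
            g: [x for x in labeled if group_of[x.lesion.patient_id] == g] for g in ("AA", "W")
        }
        for scope in SCOPES:
            summaries = {g: summarize(per_group[g], sector_map, scope) for g in ("AA", "W")}
            for g, s in summaries.items():
                diag_rows.append({"criterion": tag, "group": g, "scope": scope,
                                  "tp_w": s.tp_w, "fp_w": s.fp_w, "fn_w": s.fn_w,
                                  "cp": s.cp, "dr": s.dr, "ppv": s.ppv})
            for metric, cells in (("dr", ("tp_w", "fn_w")), ("ppv", ("tp_w", "fp_w"))):
                a, b = summaries["AA"], summaries["W"]
                ta = (getattr(a, cells[0]), getattr(a, cells[1]))
                tb = (getattr(b, cells[0]), getattr(b, cells[1]))
                if min(sum(ta), sum(tb)) > 0:
                    stat, p = weighted_chisq(ta, tb)
                else:
                    stat, p = float("nan"), float("nan")
                cmp_rows.append({"criterion": tag, "scope": scope, "metric": metric,
                                 "chi2": stat, "p": p})
    pd.DataFrame(diag_rows).to_csv(outdir / "diagnostics.csv", index=False)
    pd.DataFrame(cmp_rows).to_csv(outdir / "comparisons.csv", index=False)

    # quantitative-MRI summary (mean +/- SD per stratum, Mann-Whitney p)
    lesions_df = _analysis_lesions(outdir)
    lesions_df["group"] = lesions_df["patient_id"].astype(str).map(group_of)
    strata = {
        "ISUP=1": lesions_df["isup"] == 1,
        "ISUP>=2": lesions_df["isup"] >= 2,
        "PIRADS>=3": lesions_df["pirads"] >= 3,
    }
    quant_rows = []
    for name, mask in strata.items():
        sub = lesions_df[mask]
        for param in ("ktrans", "kep", "adc"):
            xa = sub.loc[sub["group"] == "AA", param].dropna().to_numpy()
            xw = sub.loc[sub["group"] == "W", param].dropna().to_numpy()
            p = mann_whitney(xa, xw)[1] if len(xa) and len(xw) else float("nan")
            quant_rows.append({"stratum": name, "param": param,
                               "n_aa": len(xa), "mean_aa": xa.mean() if len(xa) else float("nan"),
                               "sd_aa": xa.std(ddof=1) if len(xa) > 1 else float("nan"),
                               "n_w": len(xw), "mean_w": xw.mean() if len(xw) else float("nan"),
                               "sd_w": xw.std(ddof=1) if len(xw) > 1 else float("nan"),
                               "mw_p": p})
    pd.DataFrame(quant_rows).to_csv(outdir / "quant_summary.csv", index=False)
    log.info("evaluate: %d diagnostic rows, %d quant rows", len(diag_rows), len(quant_rows))


def stage_tune(config: PipelineConfig, outdir: Path) -> None:
    """Race-specific Ktrans threshold search + before/after diagnostics."""
    group_of = _group_of(outdir)
    sector_map = SectorMap.default()
    criterion = config.tune_criterion
    tag = _crit_tag(criterion)
    labeled = qio.frame_to_labeled(pd.read_csv(outdir / f"labeled_{tag}.csv"))
    thresholds: dict[str, dict] = {}
    before_after = []
    for g in ("AA", "W"):
        sub = [x for x in labeled if group_of[x.lesion.patient_id] == g]
        result = brute_force_thresholds(sub, config.grid, criterion)
        thresholds[g] = {
            "t_low": result.thresholds.t_low,
            "t_high": result.thresholds.t_high,
            "dr_before": result.baseline_dr, "dr_after": result.dr,
            "ppv_before": result.baseline_ppv, "ppv_after": result.ppv,
            "n_rescored": result.n_rescored,
        }
        updated = relabel_with_qdce(sub, result.thresholds, criterion)
        for scope in SCOPES:
            pre = summarize(sub, sector_map, scope)
            post = summarize(updated, sector_map, scope)
            before_after.append({"group": g, "scope": scope,
                                 "dr_before": pre.dr, "dr_after": post.dr,
                                 "ppv_before": pre.ppv, "ppv_after": post.ppv})
        if config.write_surfaces:
            np.savez(outdir / f"surfaces_{g}.npz",
                     t_low=result.t_low_grid, t_high=result.t_high_grid,
                     dr=result.dr_surface, ppv=result.ppv_surface)
    (outdir / "thresholds.json").write_text(json.dumps(thresholds, indent=2))
    pd.DataFrame(before_after).to_csv(outdir / "updated_diagnostics.csv", index=False)
    log.info("tune: thresholds %s", {g: (v["t_low"], v["t_high"]) for g, v in thresholds.items()})


def _pct(x) -> str:
    return "-" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{100 * x:.1f}"


def _md_table(df: pd.DataFrame, float_fmt: str = "{:.3g}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return "-" if np.isnan(v) else float_fmt.format(v)
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep] + body)


def stage_report(config: PipelineConfig, outdir: Path) -> dict:
    """Render the Markdown report and the machine-readable metrics JSON.

    Percentages are rounded only here; every CSV and the JSON keep full
    precision.
    """
    patients = pd.read_csv(outdir / "matched_patients.csv")
    lesions = _analysis_lesions(outdir)
    diagnostics = pd.read_csv(outdir / "diagnostics.csv")
    comparisons = pd.read_csv(outdir / "comparisons.csv")
    quant = pd.read_csv(outdir / "quant_summary.csv")
    balance = pd.read_csv(outdir / "balance.csv")
    thresholds = json.loads((outdir / "thresholds.json").read_text())
    updated = pd.read_csv(outdir / "updated_diagnostics.csv")

    lesions["group"] = lesions["patient_id"].astype(str).map(_group_of(outdir))
    path_lesions = lesions[lesions["isup"] >= 1]
    cohort_rows = []
    for g, sub in (("ALL", patients), ("AA", patients[patients.race_group == "AA"]),
                   ("W", patients[patients.race_group == "W"])):
        les = path_lesions if g == "ALL" else path_lesions[path_lesions["group"] == g]
        n_pat = len(sub)
        cohort_rows.append({
            "group": g, "n_patients": n_pat,
            "age_median": sub["age"].median(), "psa_median": sub["psa"].median(),
            "pv_median": sub["pv"].median(),
            "n_path_lesions": len(les),
            "lesions_per_patient": round(lesions_per_patient(len(les), n_pat), 2),
        })
    cohort_df = pd.DataFrame(cohort_rows)

    diag_pct = diagnostics.copy()
    for col in ("cp", "dr", "ppv"):
        diag_pct[col] = diag_pct[col].map(lambda v: float(_pct(v)) if _pct(v) != "-" else np.nan)

    report = [
        "# Synthetic-cohort mpMRI diagnostic report",
        "",
        f"Seed {config.seed}; {len(patients)} matched patients "
        f"({(patients.race_group == 'AA').sum()} AA : {(patients.race_group == 'W').sum()} W), "
        f"{len(lesions)} analysed lesions.",
        "",
        "## Matched cohort characteristics",
        "",
        _md_table(cohort_df),
        "",
        "## Covariate balance (pre/post matching)",
        "",
        _md_table(balance.round(3)),
        "",
        "## Diagnostic performance (CP/DR/PPV in %, by criterion, group, zone)",
        "",
        _md_table(diag_pct.round(1)),
        "",
        "## Between-group comparisons (weighted Pearson chi-square)",
        "",
        _md_table(comparisons),
        "",
        "## Quantitative MRI by stratum (Ktrans/kep min^-1, ADC 1e-6 mm^2/s)",
        "",
        _md_table(quant.round(4)),
        "",
        "## Ktrans thresholds (brute-force, DR maximized at no PPV cost)",
        "",
        _md_table(pd.DataFrame(
            [{"group": g, **v} for g, v in thresholds.items()]).round(4)),
        "",
        "## Diagnostics before/after the PI-RADS Ktrans update",
        "",
        _md_table(updated.round(4)),
        "",
    ]
    (outdir / "report.md").write_text("\n".join(report))

    metrics = {
        "seed": config.seed,
        "n_patients": int(len(patients)),
        "n_lesions": int(len(lesions)),
        "cohort": cohort_rows,
        "diagnostics": diagnostics.to_dict(orient="records"),
        "comparisons": comparisons.to_dict(orient="records"),
        "quant_summary": quant.to_dict(orient="records"),
        "thresholds": thresholds,
        "updated_diagnostics": updated.to_dict(orient="records"),
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, allow_nan=True))
    log.info("report: wrote report.md and metrics.json")
    return metrics


_STAGES = (stage_simulate, stage_match, stage_fit, stage_label, stage_evaluate, stage_tune)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order and return the metrics bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qio.save_yaml(qio.cohort_config_to_dict(config.cohort), outdir / "cohort_config.yaml")
    for stage in _STAGES:
        try:
            stage(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage.__name__} failed: {exc}") from exc
    return stage_report(config, outdir)
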