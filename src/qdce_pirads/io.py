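"""CSV / YAML interfaces for cohorts, lesions, labels, curves and config.

All tabular I/O is plain CSV with documented headers:

* ``patients.csv`` — patient_id, race_group, age, psa, pv, psad
* ``lesions.csv`` — lesion_id, patient_id, isup, pirads, zone,
  sectors (``;``-joined ids), ktrans, kep, adc (blank = not measured)
* ``labeled_lesions.csv`` — lesion columns + label + sector_weights
  (``sector:weight`` pairs, ``;``-joined)
* curve CSV — long format, columns lesion_id, t_seconds (or t_minutes,
  auto-detected from the header) and concentration_mM
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .pk_models import ConcentrationCurve
from .radpath_labeling import LabeledLesion
from .synthetic_cohort import (
    CohortConfig,
    GroupConfig,
    Lesion,
    LognormalSpec,
    Patient,
    TruncNormSpec,
)

__all__ = [
    "patients_to_frame",
    "frame_to_patients",
    "lesions_to_frame",
    "frame_to_lesions",
    "labeled_to_frame",
    "frame_to_labeled",
    "write_curves_csv",
    "read_curves_csv",
    "cohort_config_to_dict",
    "cohort_config_from_dict",
    "save_yaml",
    "load_yaml",
]


def patients_to_frame(patients: Sequence[Patient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "race_group": [p.race_group for p in patients],
            "age": [p.age for p in patients],
            "psa": [p.psa for p in patients],
            "pv": [p.pv for p in patients],
            "psad": [p.psad for p in patients],
        }
    )


def frame_to_patients(df: pd.DataFrame) -> list[Patient]:
    return [
        Patient(str(r.patient_id), str(r.race_group), float(r.age), float(r.psa), float(r.pv))
        for r in df.itertuples(index=False)
    ]


def lesions_to_frame(lesions: Sequence[Lesion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lesion_id": [l.lesion_id for l in lesions],
            "patient_id": [l.patient_id for l in lesions],
            "isup": [l.isup for l in lesions],
            "pirads": [l.pirads for l in lesions],
            "zone": [l.zone for l in lesions],
            "sectors": [";".join(sorted(l.sectors)) for l in lesions],
            "ktrans": [l.ktrans for l in lesions],
            "kep": [l.kep for l in lesions],
            "adc": [l.adc for l in lesions],
        }
    )


def _opt(value) -> float:
    return float("nan") if pd.isna(value) else float(value)


def frame_to_lesions(df: pd.DataFrame) -> list[Lesion]:
    return [
        Lesion(
            lesion_id=str(r.lesion_id),
            patient_id=str(r.patient_id),
            isup=int(r.isup),
            pirads=int(r.pirads),
            zone=str(r.zone),
            sectors=frozenset(str(r.sectors).split(";")),
            ktrans=_opt(r.ktrans),
            kep=_opt(r.kep),
            adc=_opt(r.adc),
        )
        for r in df.itertuples(index=False)
    ]


def labeled_to_frame(labeled: Sequence[LabeledLesion]) -> pd.DataFrame:
    df = lesions_to_frame([item.lesion for item in labeled])
    df["label"] = [item.label for item in labeled]
    df["sector_weights"] = [
        ";".join(f"{s}:{w:.10g}" for s, w in sorted(item.sector_weights.items()))
        for item in labeled
    ]
    return df


def frame_to_labeled(df: pd.DataFrame) -> list[LabeledLesion]:
    lesions = frame_to_lesions(df.drop(columns=["label", "sector_weights"]))
    out = []
    for lesion, (_, row) in zip(lesions, df.iterrows()):
        raw = str(row["sector_weights"])
        weights = {}
        if raw and raw != "nan":
            for pair in raw.split(";"):
                sector, w = pair.rsplit(":", 1)
                weights[sector] = float(w)
        out.append(LabeledLesion(lesion, str(row["label"]), weights))
    return out


def write_curves_csv(curves: Mapping[str, ConcentrationCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "lesion_id": lesion_id,
                "t_seconds": curve.t * 60.0,
                "concentration_mM": curve.c,
            }
        )
        for lesion_id, curve in curves.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> dict[str, ConcentrationCurve]:
    """Read long-format curves; time column auto-detected by header name."""
    df = pd.read_csv(path)
    if "t_minutes" in df.columns:
        t_min = df["t_minutes"].to_numpy(float)
    elif "t_seconds" in df.columns:
        t_min = df["t_seconds"].to_numpy(float) / 60.0
    else:
        raise ValueError("curve CSV needs a t_minutes or t_seconds column")
    out: dict[str, ConcentrationCurve] = {}
    for lesion_id, sub in df.assign(_t=t_min).groupby("lesion_id", sort=False):
        out[str(lesion_id)] = ConcentrationCurve(
            sub["_t"].to_numpy(), sub["concentration_mM"].to_numpy(float)
        )
    return out


# --- cohort configuration (YAML/JSON-friendly nested dicts) ---------------


def cohort_config_to_dict(config: CohortConfig) -> dict:
    def spec(s: LognormalSpec) -> dict:
        return {"median": s.median, "iqr": s.iqr}

    def quant(q: Mapping[str, Mapping[str, TruncNormSpec]]) -> dict:
        return {
            cat: {p: {"mean": t.mean, "sd": t.sd} for p, t in params.items()}
            for cat, params in q.items()
        }

    return {
        "seed": config.seed,
        "p_tz": config.p_tz,
        "sector_span_freqs": {int(k): float(v) for k, v in config.sector_span_freqs.items()},
        "groups": {
            name: {
                "age": spec(g.age),
                "psa": spec(g.psa),
                "pv": spec(g.pv),
                "lesions_per_patient_mean": g.lesions_per_patient_mean,
                "isup_freqs": {int(k): float(v) for k, v in g.isup_freqs.items()},
                "pirads_freqs": {int(k): float(v) for k, v in g.pirads_freqs.items()},
                "detection_prob": dict(g.detection_prob),
                "mri_only_rate": g.mri_only_rate,
                "quant": quant(g.quant),
            }
            for name, g in config.groups.items()
        },
    }


def cohort_config_from_dict(data: Mapping) -> CohortConfig:
    def spec(d: Mapping) -> LognormalSpec:
        return LognormalSpec(float(d["median"]), float(d["iqr"]))

    groups = {}
    for name, g in data["groups"].items():
        groups[name] = GroupConfig(
            age=spec(g["age"]),
            psa=spec(g["psa"]),
            pv=spec(g["pv"]),
            lesions_per_patient_mean=float(g["lesions_per_patient_mean"]),
            isup_freqs={int(k): float(v) for k, v in g["isup_freqs"].items()},
            pirads_freqs={int(k): float(v) for k, v in g["pirads_freqs"].items()},
            detection_prob={str(k): float(v) for k, v in g["detection_prob"].items()},
            mri_only_rate=float(g["mri_only_rate"]),
            quant={
                cat: {p: TruncNormSpec(float(t["mean"]), float(t["sd"])) for p, t in params.items()}
                for cat, params in g["quant"].items()
            },
        )
    return CohortConfig(
        groups=groups,
        p_tz=float(data.get("p_tz", 0.30)),
        sector_span_freqs={int(k): float(v) for k, v in data["sector_span_freqs"].items()},
        seed=int(data.get("seed", 0)),
    )


def save_yaml(data: Mapping, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(data), sort_keys=True))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
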