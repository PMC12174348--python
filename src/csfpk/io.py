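"""Readers/writers for the package's delimited-text formats.

All tabular formats are comma-separated UTF-8 with a mandatory header
row and period decimal marker; times are hours from first dose.

* parameter files: YAML with keys V, Cl, V2, Cl2, Vcsf, Qcsf (mL, mL/h)
  plus optional metadata (species, body_weight_kg);
* datasets: NONMEM-style event records with columns subject_id, time_h,
  dv_ug_per_mL, matrix, amt_ug, rate_ug_per_h, route, lloq_flag —
  dose rows carry nonzero amt and empty dv;
* profiles: time_h, serum_ug_per_mL, csf_ug_per_mL;
* plates: sample_id, role, concentration, response.

Every run-level output can be accompanied by a provenance record
(config hash, seed, package version) so results are attributable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DatasetFormatError, ValidationError
from .estimation import FitResult, PKDataset
from .pk_model import ConcentrationProfile, DoseEvent, PKParameters

__all__ = [
    "read_params",
    "write_params",
    "read_dataset",
    "write_dataset",
    "read_profile",
    "write_profile",
    "write_fit_report",
    "provenance_record",
]

_DATASET_COLUMNS = [
    "subject_id",
    "time_h",
    "dv_ug_per_mL",
    "matrix",
    "amt_ug",
    "rate_ug_per_h",
    "route",
    "lloq_flag",
]


def read_params(path) -> tuple[PKParameters, dict]:
    """Load a parameter file; returns (parameters, metadata)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DatasetFormatError(f"{path}: expected a key-value parameter file")
    meta = {k: v for k, v in data.items() if k not in PKParameters.names}
    return PKParameters.from_dict(data), meta


def write_params(path, params: PKParameters, metadata: dict | None = None) -> None:
    doc = dict(params.as_dict())
    if metadata:
        doc.update(metadata)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_profile(path, profile: ConcentrationProfile) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_profile(path) -> ConcentrationProfile:
    df = pd.read_csv(path)
    required = ["time_h", "serum_ug_per_mL", "csf_ug_per_mL"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing}")
    return ConcentrationProfile(
        times=df["time_h"].to_numpy(),
        serum=df["serum_ug_per_mL"].to_numpy(),
        csf=df["csf_ug_per_mL"].to_numpy(),
    )


def write_dataset(path, dataset: PKDataset) -> None:
    """Serialize observations and dose events into one event-record table."""
    rows = []
    for sid in dataset.subjects:
        for e in dataset.doses[sid]:
            rows.append(
                {
                    "subject_id": sid,
                    "time_h": e.start,
                    "dv_ug_per_mL": np.nan,
                    "matrix": "serum" if e.route != "icv_infusion" else "csf",
                    "amt_ug": e.amount,
                    "rate_ug_per_h": e.rate,
                    "route": e.route,
                    "lloq_flag": 0,
                }
            )
        sub = dataset.observations[dataset.observations["subject_id"] == sid]
        for _, r in sub.iterrows():
            rows.append(
                {
                    "subject_id": sid,
                    "time_h": r["time_h"],
                    "dv_ug_per_mL": r["conc"],
                    "matrix": r["matrix"],
                    "amt_ug": 0.0,
                    "rate_ug_per_h": 0.0,
                    "route": "",
                    "lloq_flag": int(bool(r["below_lloq"])),
                }
            )
    df = pd.DataFrame(rows, columns=_DATASET_COLUMNS)
    # body weights and LLOQs ride along as a comment-style header
    with open(path, "w", encoding="utf-8") as fh:
        meta = {
            "body_weights": dataset.body_weights,
            "lloq": dict(dataset.lloq),
        }
        fh.write("# csfpk-dataset " + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


def read_dataset(path) -> PKDataset:
    """Parse an event-record dataset; malformed rows are reported with
    their line numbers."""
    path = Path(path)
    meta = {"body_weights": {}, "lloq": {}}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# csfpk-dataset"):
            meta = json.loads(first.split("# csfpk-dataset", 1)[1])
            header_line = 2
            df = pd.read_csv(fh, dtype={"subject_id": str})
        else:
            header_line = 1
            fh.seek(0)
            df = pd.read_csv(fh, dtype={"subject_id": str})
    missing = [c for c in _DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required columns {missing}")

    bad_lines = []
    for col in ("time_h", "dv_ug_per_mL", "amt_ug", "rate_ug_per_h"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        bad_lines.extend((int(i) + header_line + 1, col) for i in bad)
        df[col] = coerced
    if bad_lines:
        detail = ", ".join(f"line {ln} ({col})" for ln, col in bad_lines)
        raise DatasetFormatError(f"{path}: non-numeric values at {detail}")
    if (df["time_h"] < 0).any():
        ln = int(df.index[df["time_h"] < 0][0]) + header_line + 1
        raise ValidationError(f"{path}: negative time at line {ln}")

    dose_rows = df[df["amt_ug"].fillna(0) > 0]
    obs_rows = df[~(df["amt_ug"].fillna(0) > 0)]
    doses: dict[str, tuple[DoseEvent, ...]] = {}
    for sid, grp in dose_rows.groupby("subject_id", sort=False):
        events = []
        for _, r in grp.iterrows():
            rate = float(r["rate_ug_per_h"]) if r["rate_ug_per_h"] else 0.0
            duration = float(r["amt_ug"]) / rate if rate > 0 else 0.0
            route = r["route"] if isinstance(r["route"], str) and r["route"] else "iv_bolus"
            events.append(DoseEvent(route, float(r["amt_ug"]), float(r["time_h"]), duration))
        doses[str(sid)] = tuple(sorted(events, key=lambda e: e.start))

    observations = pd.DataFrame(
        {
            "subject_id": obs_rows["subject_id"].astype(str),
            "time_h": obs_rows["time_h"].astype(float),
            "conc": obs_rows["dv_ug_per_mL"].astype(float),
            "matrix": obs_rows["matrix"],
            "below_lloq": obs_rows["lloq_flag"].astype(bool),
        }
    ).reset_index(drop=True)
    body_weights = {str(k): float(v) for k, v in meta.get("body_weights", {}).items()}
    for sid in observations["subject_id"].unique():
        body_weights.setdefault(sid, float("nan"))
    return PKDataset(
        observations=observations,
        doses=doses,
        body_weights=body_weights,
        lloq={str(k): float(v) for k, v in meta.get("lloq", {}).items()},
    )


def write_fit_report(path, result: FitResult) -> None:
    """Structured key-value fit report."""
    lines = ["[estimates]"]
    for name in PKParameters.names:
        lines.append(f"{name} = {getattr(result.estimates, name)!r}")
    lines.append("[standard_errors]")
    for name, se in result.standard_errors.items():
        lines.append(f"{name} = {se!r}")
    lines.append("[diagnostics]")
    lines.append(f"objective = {result.objective!r}")
    lines.append(f"converged = {result.converged}")
    lines.append(f"n_obs = {result.n_obs}")
    if result.non_identifiable:
        lines.append(f"non_identifiable = {','.join(result.non_identifiable)}")
    if result.summary:
        lines.append("[population_summary]")
        for name, stats_ in result.summary.items():
            lines.append(
                f"{name} = geometric_mean {stats_['geometric_mean']!r}, bsv_cv {stats_['bsv_cv']!r}"
            )
    if result.settings:
        lines.append("[settings]")
        for key, value in result.settings.items():
            lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def provenance_record(config: dict, seed: int | None) -> dict:
    """Run provenance: config hash, seed, package version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "csfpk_version": __version__,
    }
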