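"""Plain-text readers and writers for waveforms, annotations, and cohorts.

All on-disk formats are diffable delimited or key-value text:

* waveform: CSV, header ``time_s,ppg_au``, one row per sample;
* annotation: YAML with window boundaries and the mouth-pressure target;
* cohort: a directory with ``subjects.csv``, a ``cohort.yaml`` provenance
  stamp, and one waveform/annotation pair per trial under ``waveforms/``.

Readers validate the type invariants (uniform sampling, finite values,
label consistency, trial linkage) and fail loudly naming the offending
row or file.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, LinkageError
from .synthetic_cohort import (
    ManeuverAnnotation,
    SimConfig,
    SubjectRecord,
    WaveformRecording,
)

__all__ = [
    "CohortBundle",
    "read_waveform",
    "write_waveform",
    "read_annotation",
    "write_annotation",
    "read_cohort",
    "write_cohort",
    "make_bundle",
    "config_digest",
    "read_feature_table",
    "write_feature_table",
]

_SPACING_TOL = 1e-6  # s, allowed deviation from uniform sampling
_METADATA_COLUMNS = [
    "subject_id",
    "age",
    "bnp",
    "filling_pressure",
    "overload_15",
    "overload_10",
]


@dataclass
class CohortBundle:
    subjects: list[SubjectRecord]
    provenance: dict

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise FormatError("subject_ids must be unique")


def config_digest(config: SimConfig) -> str:
    """Stable hash of a simulation config (provenance stamping)."""
    payload = yaml.safe_dump(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_bundle(subjects: list[SubjectRecord], config: Optional[SimConfig] = None) -> CohortBundle:
    provenance = {}
    if config is not None:
        provenance = {"config": asdict(config), "config_digest": config_digest(config),
                      "seed": config.seed}
    return CohortBundle(subjects=subjects, provenance=provenance)


# ---------------------------------------------------------------------------
# waveform files


def write_waveform(rec: WaveformRecording, path) -> Path:
    path = Path(path)
    times = rec.times()
    data = np.column_stack([times, rec.samples])
    np.savetxt(
        path, data, delimiter=",", header="time_s,ppg_au", comments="",
        fmt=["%.7f", "%.6g"],
    )
    return path


def read_waveform(path) -> WaveformRecording:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"waveform file not found: {path}")
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "ppg_au"]:
        raise FormatError(
            f"{path}: expected header 'time_s,ppg_au', got {list(df.columns)}"
        )
    if len(df) < 2:
        raise FormatError(f"{path}: need at least two samples")
    t = df["time_s"].to_numpy(dtype=float)
    x = df["ppg_au"].to_numpy(dtype=float)
    bad = ~np.isfinite(x)
    if bad.any():
        row = int(np.argmax(bad))
        raise FormatError(f"{path}: non-finite sample at row {row}")
    if not np.all(np.isfinite(t)):
        row = int(np.argmax(~np.isfinite(t)))
        raise FormatError(f"{path}: non-finite time at row {row}")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise FormatError(f"{path}: time column must be strictly increasing")
    dev = np.abs(dt - dt_med)
    if dev.max() > _SPACING_TOL:
        row = int(np.argmax(dev)) + 1
        raise FormatError(
            f"{path}: non-uniform sample spacing at row {row} "
            f"(deviation {dev.max():.2e} s)"
        )
    return WaveformRecording(samples=x, sampling_rate=round(1.0 / dt_med, 6), t0=float(t[0]))


# ---------------------------------------------------------------------------
# annotation files


def write_annotation(ann: ManeuverAnnotation, path) -> Path:
    path = Path(path)
    payload = {
        "rest_start": float(ann.rest_window[0]),
        "rest_end": float(ann.rest_window[1]),
        "strain_start": float(ann.strain_window[0]),
        "strain_end": float(ann.strain_window[1]),
        "recovery_start": float(ann.recovery_window[0]),
        "recovery_end": float(ann.recovery_window[1]),
        "target_mouth_pressure": float(ann.target_mouth_pressure),
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_annotation(path) -> ManeuverAnnotation:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    payload = yaml.safe_load(path.read_text())
    try:
        return ManeuverAnnotation(
            rest_window=(payload["rest_start"], payload["rest_end"]),
            strain_window=(payload["strain_start"], payload["strain_end"]),
            recovery_window=(payload["recovery_start"], payload["recovery_end"]),
            target_mouth_pressure=payload.get("target_mouth_pressure", 25.0),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed annotation ({exc})") from exc


# ---------------------------------------------------------------------------
# cohort directories


def _trial_stem(subject_id: str, k: int) -> str:
    return f"{subject_id}_t{k + 1}"


def write_cohort(bundle: CohortBundle, out_dir) -> dict:
    """Write a cohort directory; returns the paths written."""
    out_dir = Path(out_dir)
    wave_dir = out_dir / "waveforms"
    wave_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    paths = {"subjects": out_dir / "subjects.csv", "trials": []}
    for subj in bundle.subjects:
        rows.append(
            {
                "subject_id": subj.subject_id,
                "age": subj.age,
                "bnp": subj.bnp,
                "filling_pressure": subj.filling_pressure,
                "overload_15": subj.overload_15,
                "overload_10": subj.overload_10,
                "n_trials": len(subj.trials),
            }
        )
        for k, (rec, ann) in enumerate(subj.trials):
            stem = _trial_stem(subj.subject_id, k)
            wav = write_waveform(rec, wave_dir / f"{stem}.csv")
            annp = write_annotation(ann, wave_dir / f"{stem}.yaml")
            paths["trials"].append((wav, annp))
    pd.DataFrame(rows).to_csv(paths["subjects"], index=False, float_format="%.10g")
    meta = out_dir / "cohort.yaml"
    meta.write_text(yaml.safe_dump(bundle.provenance, sort_keys=True))
    paths["provenance"] = meta
    return paths


def read_cohort(cohort_dir) -> CohortBundle:
    """Load a cohort directory, re-validating labels and trial linkage."""
    cohort_dir = Path(cohort_dir)
    meta_path = cohort_dir / "subjects.csv"
    if not meta_path.exists():
        raise FormatError(f"missing cohort metadata: {meta_path}")
    df = pd.read_csv(meta_path)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{meta_path}: missing columns {missing}")
    wave_dir = cohort_dir / "waveforms"
    subjects = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        pressure = float(row["filling_pressure"])
        for cut, col in ((15.0, "overload_15"), (10.0, "overload_10")):
            if bool(row[col]) != (pressure > cut):
                raise FormatError(
                    f"{sid}: stored {col}={bool(row[col])} inconsistent with "
                    f"filling_pressure={pressure:g} mmHg"
                )
        trials = []
        n_trials = int(row.get("n_trials", 0))
        for k in range(n_trials):
            stem = _trial_stem(sid, k)
            wav_path = wave_dir / f"{stem}.csv"
            ann_path = wave_dir / f"{stem}.yaml"
            if not wav_path.exists() or not ann_path.exists():
                raise LinkageError(
                    f"subject {sid}, trial {k + 1}: missing file {wav_path.name}"
                    if not wav_path.exists()
                    else f"subject {sid}, trial {k + 1}: missing file {ann_path.name}"
                )
            trials.append((read_waveform(wav_path), read_annotation(ann_path)))
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age=float(row["age"]),
                filling_pressure=pressure,
                bnp=float(row["bnp"]),
                overload_15=bool(row["overload_15"]),
                overload_10=bool(row["overload_10"]),
                trials=trials,
            )
        )
    prov_path = cohort_dir / "cohort.yaml"
    provenance = yaml.safe_load(prov_path.read_text()) if prov_path.exists() else {}
    return CohortBundle(subjects=subjects, provenance=provenance or {})


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: feature table requires a subject_id column")
    return df
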