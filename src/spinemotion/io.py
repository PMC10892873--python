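"""Delimited-text I/O for trial data, study directories and reports.

All time-series files are UTF-8 CSV with a header row and '.' decimals:
``t,th1,th2,th3,th4`` for encoder streams (degrees) and
``t,qw,qx,qy,qz,valid`` for orientation streams (scalar-first unit
quaternions, ``valid`` as 0/1).  Floats are written with ``%.10g`` so a
canonical file survives a read/write round trip byte for byte.

A study directory holds one encoder and one mocap CSV per trial, a
``study.json`` manifest with the trial grid, and (for synthetic studies)
a ``ledger.json`` with the injected ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .series import JointAngleSeries, OrientationSeries, SchemaError, TrialRecord

__all__ = [
    "read_encoder_csv",
    "write_encoder_csv",
    "read_orientation_csv",
    "write_orientation_csv",
    "write_study",
    "read_study",
    "write_report",
    "read_report",
]

_FLOAT_FMT = "%.10g"
ENCODER_HEADER = "t,th1,th2,th3,th4"
ORIENTATION_HEADER = "t,qw,qx,qy,qz,valid"


def _check_header(path, expected: str) -> None:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if header != expected:
        raise SchemaError(f"{path}, line 1: expected header {expected!r}, got {header!r}")


def read_encoder_csv(path, segment: str = "cervical", quantization_step: float = 0.0219) -> JointAngleSeries:
    _check_header(path, ENCODER_HEADER)
    df = pd.read_csv(path)
    try:
        return JointAngleSeries(
            df["t"].to_numpy(),
            df[["th1", "th2", "th3", "th4"]].to_numpy(),
            segment,
            quantization_step,
        )
    except KeyError as exc:  # pragma: no cover - guarded by header check
        raise SchemaError(f"{path}: missing column {exc}") from exc


def write_encoder_csv(series: JointAngleSeries, path) -> None:
    df = pd.DataFrame(
        {
            "t": series.timestamps,
            "th1": series.theta[:, 0],
            "th2": series.theta[:, 1],
            "th3": series.theta[:, 2],
            "th4": series.theta[:, 3],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_orientation_csv(path, source: str = "reference", frame: str = "mocap") -> OrientationSeries:
    _check_header(path, ORIENTATION_HEADER)
    df = pd.read_csv(path)
    return OrientationSeries(
        df["t"].to_numpy(),
        df[["qw", "qx", "qy", "qz"]].to_numpy(),
        df["valid"].to_numpy().astype(bool),
        source,
        frame,
    )


def write_orientation_csv(series: OrientationSeries, path) -> None:
    df = pd.DataFrame(
        {
            "t": series.timestamps,
            "qw": series.quaternions[:, 0],
            "qx": series.quaternions[:, 1],
            "qy": series.quaternions[:, 2],
            "qz": series.quaternions[:, 3],
            "valid": series.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def write_study(trials: list[TrialRecord], out_dir, ledger: dict | None = None) -> None:
    """Write a study directory: per-trial CSVs plus manifest (and ledger)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"trials": []}
    for tr in trials:
        enc = f"{tr.trial_id}_encoders.csv"
        moc = f"{tr.trial_id}_mocap.csv"
        write_encoder_csv(tr.encoders, out / enc)
        write_orientation_csv(tr.mocap, out / moc)
        manifest["trials"].append(
            {
                "trial_id": tr.trial_id,
                "segment": tr.segment,
                "condition": tr.condition,
                "speed": tr.speed,
                "is_calibration": tr.is_calibration,
                "encoder_file": enc,
                "mocap_file": moc,
                "quantization_step": tr.encoders.quantization_step,
            }
        )
    with open(out / "study.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if ledger is not None:
        with open(out / "ledger.json", "w", encoding="utf-8") as fh:
            json.dump(ledger, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_study(study_dir) -> tuple[list[TrialRecord], dict | None]:
    """Load a study directory written by :func:`write_study`."""
    root = Path(study_dir)
    manifest_path = root / "study.json"
    if not manifest_path.exists():
        raise SchemaError(f"no study.json manifest in {study_dir}")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    trials = []
    for item in manifest["trials"]:
        enc = read_encoder_csv(
            root / item["encoder_file"], item["segment"], item.get("quantization_step", 0.0219)
        )
        moc = read_orientation_csv(root / item["mocap_file"])
        trials.append(
            TrialRecord(
                trial_id=item["trial_id"],
                segment=item["segment"],
                condition=item["condition"],
                speed=item["speed"],
                encoders=enc,
                mocap=moc,
                is_calibration=bool(item.get("is_calibration", False)),
            )
        )
    ledger = None
    ledger_path = root / "ledger.json"
    if ledger_path.exists():
        with open(ledger_path, "r", encoding="utf-8") as fh:
            ledger = json.load(fh)
    return trials, ledger


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
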