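"""Readers, writers and run configuration.

Datasets travel as long-format CSV — one row per (session, electrode
pair, frequency) — since no standard interchange format exists for
multi-channel bioimpedance spectra.  Required columns:

``subject_id, day_index, repeat_index, electrode_a, electrode_b,
frequency_hz, impedance_ohm``

plus optional ``hand_temp_c`` and ``placement_label``.  Impedances are
written with 9 significant digits, so a write/read round trip is
lossless at that precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import PAIRS, StudyData
from .synth import GeneratorConfig

__all__ = [
    "REQUIRED_COLUMNS",
    "read_dataset",
    "write_dataset",
    "write_report",
    "read_report",
    "read_run_config",
]

logger = logging.getLogger("limbid")

REQUIRED_COLUMNS = (
    "subject_id",
    "day_index",
    "repeat_index",
    "electrode_a",
    "electrode_b",
    "frequency_hz",
    "impedance_ohm",
)

REPORT_SCHEMA_VERSION = 1


def write_dataset(data: StudyData, path: str | Path) -> None:
    """Write a study as long-format CSV (9 significant digits)."""
    frame = data.to_long_frame()
    frame.to_csv(path, index=False, float_format="%.9g")
    logger.info("wrote %d rows (%d sessions) to %s", len(frame), data.n_sessions, path)


def read_dataset(path: str | Path) -> StudyData:
    """Read a long-format CSV into a validated :class:`StudyData`.

    Validates that every session carries exactly the 10 electrode
    pairs on the complete frequency grid with positive impedances;
    errors name the offending session and pairs.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty dataset file") from None
    if frame.empty:
        raise ValueError(f"{path}: empty dataset file")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    if (frame["impedance_ohm"] <= 0).any():
        bad = frame.loc[frame["impedance_ohm"] <= 0].iloc[0]
        raise ValueError(
            f"{path}: non-positive impedance for subject {bad['subject_id']} "
            f"day {bad['day_index']} pair ({bad['electrode_a']},{bad['electrode_b']})"
        )

    grid = np.sort(frame["frequency_hz"].unique()).astype(float)
    pair_pos = {p: i for i, p in enumerate(PAIRS)}
    freq_pos = {f: i for i, f in enumerate(grid)}

    keys = ["subject_id", "day_index", "repeat_index"]
    has_temp = "hand_temp_c" in frame.columns
    has_label = "placement_label" in frame.columns
    channels, meta_rows = [], []
    for (subject, day, repeat), g in frame.groupby(keys, sort=True):
        mat = np.full((len(PAIRS), grid.size), np.nan)
        a = g["electrode_a"].to_numpy(dtype=int)
        b = g["electrode_b"].to_numpy(dtype=int)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        for k in range(len(g)):
            pair = (int(lo[k]), int(hi[k]))
            if pair not in pair_pos:
                raise ValueError(f"{path}: invalid electrode pair {pair}")
            mat[pair_pos[pair], freq_pos[float(g["frequency_hz"].iloc[k])]] = (
                g["impedance_ohm"].iloc[k]
            )
        if np.isnan(mat).any():
            missing = [
                PAIRS[i] for i in range(len(PAIRS)) if np.isnan(mat[i]).any()
            ]
            raise ValueError(
                f"{path}: incomplete session (subject {subject}, day {day}, "
                f"repeat {repeat}): missing pairs {missing}"
            )
        channels.append(mat)
        meta_rows.append(
            {
                "subject_id": str(subject),
                "day_index": int(day),
                "repeat_index": int(repeat),
                "hand_temp_c": float(g["hand_temp_c"].iloc[0]) if has_temp else np.nan,
                "placement_label": (
                    "" if not has_label or pd.isna(g["placement_label"].iloc[0])
                    else str(g["placement_label"].iloc[0])
                ),
            }
        )
    data = StudyData(
        channels=np.stack(channels), meta=pd.DataFrame(meta_rows), frequencies=grid
    )
    logger.info(
        "read %d sessions (%d subjects, %d days) from %s",
        data.n_sessions, len(data.subjects), len(data.days), path,
    )
    return data


def write_report(report, out_dir: str | Path) -> Path:
    """Write an :class:`~limbid.identify.EvalReport` as JSON + CSVs.

    AUC is reported with 4 decimals and EER with 2 (the conventional
    printing precision for biometric benchmarks); the ROC sweep and
    confusion matrix go to sibling CSV files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "selection": report.selection,
        "model": report.kind,
        "n_days": report.n_days,
        "accuracy_pct": round(report.accuracy, 2),
        "eer_pct": round(report.eer, 2),
        "auc": round(report.auc, 4),
        "n_test": report.n_test,
    }
    if report.day_curve is not None:
        payload["day_curve"] = report.day_curve.to_dict(orient="records")
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    report.roc.to_csv(out_dir / "roc.csv", index=False)
    report.confusion.to_csv(out_dir / "confusion.csv")
    logger.info("wrote report to %s", json_path)
    return json_path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_run_config(path: str | Path) -> dict:
    """Load a structured run config (YAML); ``seed`` is required.

    Recognized top-level keys: ``seed`` (required), ``n_subjects``,
    ``n_days``, ``repeats_per_day``, ``scenario``, and ``generator``
    (a mapping of :class:`~limbid.synth.GeneratorConfig` fields).
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "seed" not in cfg:
        raise ValueError(f"{path}: config must declare a 'seed'")
    gen = cfg.get("generator", {})
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(gen) - known
    if unknown:
        raise ValueError(f"{path}: unknown generator fields {sorted(unknown)}")
    # YAML lists -> tuples for range-valued fields
    for key, val in list(gen.items()):
        if isinstance(val, list):
            gen[key] = tuple(val)
    cfg["generator"] = gen
    return cfg
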