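"""File formats for sessions, scores, cohorts and agreement tables.

Conventions: CSV files are comma-separated UTF-8 with a header row and '.'
decimals; floats are written at 6 decimal places so a write-read-write
round trip is byte-identical.  Angles are stored in degrees and sags/scores
in arc minutes; column names carry their unit suffix.  JSON documents carry
a ``schema_version`` field and are validated on read, with errors naming
the offending field.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _tool_version
from .analysis import Agreement2x2, DetectionResult, NormativeModel
from .geometry import TestLocation
from .observer import ObserverModel
from .session import ProtocolConfig, RunResult, ScoreMap
from .staircase import Response, StaircaseConfig, Trial

__all__ = [
    "SchemaError",
    "write_scoremap_csv",
    "read_scoremap_csv",
    "write_session_bundle",
    "read_session_bundle",
    "write_agreement_json",
    "read_agreement_json",
    "write_agreement_csv",
    "read_agreement_csv",
    "write_observer_json",
    "read_observer_json",
    "write_normative_json",
    "read_normative_json",
    "write_trace_csv",
    "write_detection_report",
    "write_radial_csv",
    "protocol_to_dict",
    "protocol_from_dict",
]

FLOAT_FORMAT = "%.6f"

SCOREMAP_COLUMNS = [
    "subject_id",
    "meridian_deg",
    "eccentricity_deg",
    "run_index",
    "threshold_arcmin",
    "score_arcmin",
]


class SchemaError(ValueError):
    """A file failed validation against its documented schema."""


def _require(d: dict, key: str, context: str) -> object:
    if key not in d:
        raise SchemaError(f"{context}: missing required field '{key}'")
    return d[key]


def _load_json(path: str | Path, context: str) -> dict:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{context}: malformed JSON in {path}: {exc}") from exc


def _dump_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------- ScoreMap
def write_scoremap_csv(
    scoremaps: ScoreMap | Sequence[ScoreMap], path: str | Path
) -> None:
    """Tidy per-run CSV; one or several subjects per file.

    The score column is computed from thresholds rounded to the file's
    6-decimal precision, so write -> read -> write is byte-identical.
    """
    if isinstance(scoremaps, ScoreMap):
        scoremaps = [scoremaps]
    rows = []
    for sm in scoremaps:
        rounded: dict = {}
        for loc in sm.locations():
            vals = [round(v, 6) for v in sm.thresholds(loc)]
            rounded[loc] = float(np.mean(vals)) if vals else float("nan")
        for r in sm.runs:
            rows.append(
                {
                    "subject_id": sm.subject_id,
                    "meridian_deg": r.location.meridian_deg,
                    "eccentricity_deg": r.location.eccentricity_deg,
                    "run_index": r.run_index,
                    "threshold_arcmin": round(r.threshold_arcmin, 6)
                    if not math.isnan(r.threshold_arcmin)
                    else float("nan"),
                    "score_arcmin": rounded[r.location],
                }
            )
    df = pd.DataFrame(rows)[SCOREMAP_COLUMNS]
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_scoremap_csv(path: str | Path) -> list[ScoreMap]:
    """Read score maps (one per subject) from a tidy per-run CSV."""
    df = pd.read_csv(path)
    missing_cols = [c for c in SCOREMAP_COLUMNS[:-1] if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"score-map CSV {path}: missing required column(s) {missing_cols}"
        )
    maps: list[ScoreMap] = []
    for subject_id, group in df.groupby("subject_id", sort=False):
        runs = []
        for _, row in group.iterrows():
            thr = float(row["threshold_arcmin"])
            runs.append(
                RunResult(
                    location=TestLocation(
                        float(row["meridian_deg"]), float(row["eccentricity_deg"])
                    ),
                    run_index=int(row["run_index"]),
                    seed=0,
                    threshold_arcmin=thr,
                    converged=not math.isnan(thr),
                    n_trials=0,
                )
            )
        maps.append(ScoreMap(subject_id=str(subject_id), runs=runs))
    return maps


# ------------------------------------------------------------------ traces
def write_trace_csv(trials: Sequence[Trial], path: str | Path) -> None:
    """Per-trial staircase trace."""
    df = pd.DataFrame(
        {
            "trial_index": [t.index for t in trials],
            "sag_arcmin": [t.sag_arcmin for t in trials],
            "step_arcmin": [t.step_arcmin for t in trials],
            "response": [t.response.value for t in trials],
            "is_reversal": [t.is_reversal for t in trials],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _trial_to_dict(t: Trial) -> dict:
    return {
        "trial_index": t.index,
        "sag_arcmin": t.sag_arcmin,
        "step_arcmin": t.step_arcmin,
        "response": t.response.value,
        "is_reversal": t.is_reversal,
    }


def _trial_from_dict(d: dict) -> Trial:
    return Trial(
        index=int(d["trial_index"]),
        sag_arcmin=float(d["sag_arcmin"]),
        step_arcmin=float(d["step_arcmin"]),
        response=Response(d["response"]),
        is_reversal=bool(d["is_reversal"]),
    )


# ---------------------------------------------------------------- protocol
def protocol_to_dict(protocol: ProtocolConfig) -> dict:
    return {
        "grid": [loc.key for loc in protocol.grid],
        "runs_per_location": protocol.runs_per_location,
        "staircase": dataclasses.asdict(protocol.staircase),
        "interleave_meridians": protocol.interleave_meridians,
        "master_seed": protocol.master_seed,
    }


def protocol_from_dict(d: dict) -> ProtocolConfig:
    grid = tuple(TestLocation.from_key(k) for k in _require(d, "grid", "protocol"))
    return ProtocolConfig(
        grid=grid,
        runs_per_location=int(d.get("runs_per_location", 2)),
        staircase=StaircaseConfig(**d.get("staircase", {})),
        interleave_meridians=bool(d.get("interleave_meridians", True)),
        master_seed=int(d.get("master_seed", 0)),
    )


# ------------------------------------------------------------------ bundle
def write_session_bundle(
    scoremap: ScoreMap,
    path: str | Path,
    observer: ObserverModel | None = None,
) -> None:
    """Self-describing session record: config, seeds, scores and traces.

    Re-running the bundled protocol config (same master seed) against the
    bundled observer reproduces the ScoreMap exactly.
    """
    runs = []
    for r in scoremap.runs:
        entry = {
            "location": r.location.key,
            "run_index": r.run_index,
            "seed": r.seed,
            "threshold_arcmin": None
            if math.isnan(r.threshold_arcmin)
            else r.threshold_arcmin,
            "converged": r.converged,
            "n_trials": r.n_trials,
        }
        if r.state is not None:
            entry["trials"] = [_trial_to_dict(t) for t in r.state.trials]
            entry["reversal_sags_arcmin"] = list(r.state.reversal_sags)
        runs.append(entry)
    bundle = {
        "schema_version": 1,
        "tool_version": _tool_version,
        "subject_id": scoremap.subject_id,
        "protocol": protocol_to_dict(scoremap.protocol)
        if scoremap.protocol
        else None,
        "observer": observer.to_dict() if observer is not None else "human",
        "provenance": scoremap.provenance,
        "runs": runs,
    }
    _dump_json(bundle, path)


def read_session_bundle(path: str | Path) -> tuple[ScoreMap, ObserverModel | None]:
    d = _load_json(path, "session bundle")
    for key in ("schema_version", "subject_id", "runs"):
        _require(d, key, "session bundle")
    runs = []
    for entry in d["runs"]:
        thr = entry.get("threshold_arcmin")
        runs.append(
            RunResult(
                location=TestLocation.from_key(_require(entry, "location", "run")),
                run_index=int(_require(entry, "run_index", "run")),
                seed=int(entry.get("seed", 0)),
                threshold_arcmin=float("nan") if thr is None else float(thr),
                converged=bool(entry.get("converged", thr is not None)),
                n_trials=int(entry.get("n_trials", 0)),
            )
        )
    protocol = protocol_from_dict(d["protocol"]) if d.get("protocol") else None
    scoremap = ScoreMap(
        subject_id=str(d["subject_id"]),
        runs=runs,
        protocol=protocol,
        provenance=d.get("provenance", {}),
    )
    obs = d.get("observer")
    observer = (
        ObserverModel.from_dict(obs) if isinstance(obs, dict) else None
    )
    return scoremap, observer


# --------------------------------------------------------------- agreement
def write_agreement_json(table: Agreement2x2, path: str | Path) -> None:
    _dump_json(
        {"schema_version": 1, "a": table.a, "b": table.b, "c": table.c, "d": table.d},
        path,
    )


def read_agreement_json(path: str | Path) -> Agreement2x2:
    d = _load_json(path, "agreement table")
    counts = {}
    for key in "abcd":
        v = _require(d, key, "agreement table")
        if not isinstance(v, int) or v < 0:
            raise SchemaError(
                f"agreement table: field '{key}' must be a non-negative integer"
            )
        counts[key] = v
    return Agreement2x2(**counts)


def write_agreement_csv(table: Agreement2x2, path: str | Path) -> None:
    pd.DataFrame(
        {"a": [table.a], "b": [table.b], "c": [table.c], "d": [table.d]}
    ).to_csv(path, index=False)


def read_agreement_csv(path: str | Path) -> Agreement2x2:
    df = pd.read_csv(path)
    for key in "abcd":
        if key not in df.columns:
            raise SchemaError(f"agreement CSV: missing required column '{key}'")
    row = df.iloc[0]
    return Agreement2x2(a=int(row.a), b=int(row.b), c=int(row.c), d=int(row.d))


# ---------------------------------------------------------------- observer
def write_observer_json(observer: ObserverModel, path: str | Path) -> None:
    _dump_json(observer.to_dict(), path)


def read_observer_json(path: str | Path) -> ObserverModel:
    d = _load_json(path, "observer")
    _require(d, "distortion_arcmin", "observer")
    return ObserverModel.from_dict(d)


# --------------------------------------------------------------- normative
def write_normative_json(model: NormativeModel, path: str | Path) -> None:
    _dump_json(model.to_dict(), path)


def read_normative_json(path: str | Path) -> NormativeModel:
    d = _load_json(path, "normative model")
    for key in ("mean_arcmin", "sd_arcmin", "n_subjects"):
        _require(d, key, "normative model")
    return NormativeModel.from_dict(d)


# ---------------------------------------------------------------- reports
def write_detection_report(
    result: DetectionResult,
    scoremap: ScoreMap,
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-location detection report: z-scores and 2-SD / detection flags."""
    rows = []
    for loc, z in sorted(result.z_scores.items()):
        rows.append(
            {
                "meridian_deg": loc.meridian_deg,
                "eccentricity_deg": loc.eccentricity_deg,
                "score_arcmin": scoremap.score(loc),
                "z": z,
                "flag_display": loc in result.display_flagged_locations,
                "flag_detect": loc in result.flagged_locations,
            }
        )
    df = pd.DataFrame(rows)
    if csv_path is not None:
        df.to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
    if json_path is not None:
        _dump_json(
            {
                "schema_version": 1,
                "subject_id": result.subject_id,
                "positive": result.positive,
                "n_flagged": len(result.flagged_locations),
                "flagged_locations": [l.key for l in result.flagged_locations],
                "display_flagged_locations": [
                    l.key for l in result.display_flagged_locations
                ],
                "missing_locations": [l.key for l in result.missing_locations],
                "z_scores": {l.key: z for l, z in sorted(result.z_scores.items())},
            },
            json_path,
        )
    return df


def write_radial_csv(
    scoremap: ScoreMap, result: DetectionResult | None, path: str | Path
) -> None:
    """Radial-plot export: per-location score plus display-band flag."""
    flagged = set(result.display_flagged_locations) if result else set()
    rows = [
        {
            "meridian_deg": loc.meridian_deg,
            "eccentricity_deg": loc.eccentricity_deg,
            "score_arcmin": scoremap.score(loc),
            "flagged": loc in flagged,
        }
        for loc in scoremap.locations()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)
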