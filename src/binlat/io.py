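"""Delimited-text and JSON persistence for every pipeline artifact.

All files are UTF-8, comma-delimited with "." decimals and one header row.
Undefined values are serialized as the literal token ``NA`` (never an empty
string) and read back as NaN.  ``read_sessions`` reports malformed rows by
1-based row number.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path

from .metrics import METRIC_NAMES, MetricVector
from .normative import DivergenceProfile, NormativeTable, NormRange
from .schema import (
    AudiogramRecord,
    LateralizationSession,
    StimulusDescriptor,
    Trial,
    is_na,
)
from .thresholds import TrackRecord, TrackTrial, extract_threshold

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

SESSION_COLUMNS = (
    "participant_id",
    "group",
    "phase",
    "cue_type",
    "cue_value",
    "presentation_index",
    "response_key",
)
TRACK_COLUMNS = (
    "participant_id",
    "phase",
    "condition",
    "run_index",
    "trial_index",
    "level_db",
    "correct",
    "reversal",
    "valid",
)
AUDIOMETRY_COLUMNS = ("participant_id", "phase", "ear", "frequency", "threshold")


class FormatError(ValueError):
    """File-level structural problem (missing columns, bad header)."""


class ValidationError(ValueError):
    """Row-level content problem; the message names the offending row."""


def _fmt(x: float) -> str:
    return NA_TOKEN if is_na(x) else repr(float(x))


def _parse(tok: str) -> float:
    return float("nan") if tok == NA_TOKEN or tok == "" else float(tok)


def _check_columns(fieldnames, required, path) -> None:
    missing = set(required) - set(fieldnames or ())
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")


# --- lateralization sessions ----------------------------------------------

def write_sessions(sessions: list[LateralizationSession], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SESSION_COLUMNS)
        for s in sessions:
            for t in s.trials:
                cue = (
                    ""
                    if t.stimulus.cue_value is None
                    else repr(float(t.stimulus.cue_value))
                )
                w.writerow(
                    [
                        s.participant_id,
                        s.group,
                        s.phase,
                        t.stimulus.cue_type,
                        cue,
                        t.presentation_index,
                        t.response_key,
                    ]
                )


def read_sessions(path: str | Path) -> list[LateralizationSession]:
    """Load sessions grouped per participant x phase.

    Incomplete sessions are loaded with a warning (check
    ``session.is_complete()``); malformed rows raise :class:`ValidationError`
    naming the 1-based data row.
    """
    grouped: dict[tuple[str, str, str], list[Trial]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, SESSION_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            try:
                cue_raw = (row["cue_value"] or "").strip()
                cue = None if cue_raw in ("", NA_TOKEN) else float(cue_raw)
                stim = StimulusDescriptor(row["cue_type"].strip(), cue)
                trial = Trial(
                    stim,
                    int(row["presentation_index"]),
                    int(row["response_key"]),
                )
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
            key = (row["participant_id"], row["group"], row["phase"])
            grouped.setdefault(key, []).append(trial)
    sessions = []
    for (pid, group, phase), trials in grouped.items():
        s = LateralizationSession(pid, group, phase, trials)
        if not s.is_complete():
            logger.warning(
                "session %s/%s is incomplete (%d trials)", pid, phase, len(trials)
            )
        sessions.append(s)
    return sessions


# --- metric tables ---------------------------------------------------------

def write_metrics(
    rows: list[tuple[str, str, MetricVector]], path: str | Path
) -> None:
    """Wide table: participant_id, phase, then the 31 metrics in fixed order."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(("participant_id", "phase") + METRIC_NAMES)
        for pid, phase, mv in rows:
            w.writerow([pid, phase] + [_fmt(v) for v in mv.values])


def read_metrics(path: str | Path) -> list[tuple[str, str, MetricVector]]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, ("participant_id", "phase") + METRIC_NAMES, path)
        for i, row in enumerate(reader, start=1):
            try:
                mv = MetricVector(tuple(_parse(row[name]) for name in METRIC_NAMES))
            except ValueError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
            out.append((row["participant_id"], row["phase"], mv))
    return out


# --- normative tables ------------------------------------------------------

def write_normative(table: NormativeTable, path: str | Path) -> None:
    payload = {
        name: {
            "lo": rng.lo,
            "hi": rng.hi,
            "mean": rng.mean,
            "sd": rng.sd,
            "iqr": rng.iqr,
            "n_controls": rng.n_controls,
        }
        for name, rng in table.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_normative(path: str | Path) -> NormativeTable:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    table = NormativeTable()
    for name, d in payload.items():
        table[name] = NormRange(
            lo=d["lo"],
            hi=d["hi"],
            mean=d["mean"],
            sd=d["sd"],
            iqr=d["iqr"],
            n_controls=d["n_controls"],
        )
    return table


# --- divergence profiles ---------------------------------------------------

def write_divergence(profiles: list[DivergenceProfile], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ("participant_id", "phase")
            + METRIC_NAMES
            + ("count", "is_normal_lateralization")
        )
        for p in profiles:
            w.writerow(
                [p.participant_id, p.phase]
                + [p.flags[name] for name in METRIC_NAMES]
                + [p.count, p.is_normal_lateralization]
            )


# --- adaptive tracks -------------------------------------------------------

def write_tracks(
    tracks: dict[tuple[str, str], list[TrackRecord]], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TRACK_COLUMNS)
        for (pid, phase), runs in tracks.items():
            for run in runs:
                for j, t in enumerate(run.trials, start=1):
                    w.writerow(
                        [
                            pid,
                            phase,
                            run.condition,
                            run.run_index,
                            j,
                            repr(float(t.level)),
                            int(t.correct),
                            int(t.is_reversal),
                            int(run.valid),
                        ]
                    )


def read_tracks(path: str | Path) -> dict[tuple[str, str], list[TrackRecord]]:
    grouped: dict[tuple[str, str, str, int], list[tuple[TrackTrial, bool]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, TRACK_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            try:
                trial = TrackTrial(
                    float(row["level_db"]),
                    bool(int(row["correct"])),
                    bool(int(row["reversal"])),
                )
                key = (
                    row["participant_id"],
                    row["phase"],
                    row["condition"],
                    int(row["run_index"]),
                )
                grouped.setdefault(key, []).append((trial, bool(int(row["valid"]))))
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
    out: dict[tuple[str, str], list[TrackRecord]] = {}
    for (pid, phase, condition, run_index), pairs in grouped.items():
        valid = all(v for _, v in pairs)
        track = TrackRecord(condition, run_index, [t for t, _ in pairs], valid)
        track.threshold = extract_threshold(track)
        out.setdefault((pid, phase), []).append(track)
    return out


# --- audiometry ------------------------------------------------------------

def write_audiometry(records: list[AudiogramRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(AUDIOMETRY_COLUMNS)
        for r in records:
            w.writerow(
                [r.participant_id, r.phase, r.ear, repr(float(r.frequency)), repr(float(r.threshold))]
            )


def read_audiometry(path: str | Path) -> list[AudiogramRecord]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, AUDIOMETRY_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            try:
                out.append(
                    AudiogramRecord(
                        row["participant_id"],
                        row["phase"],
                        row["ear"],
                        float(row["frequency"]),
                        float(row["threshold"]),
                    )
                )
            except ValueError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return out


# --- longitudinal outputs --------------------------------------------------

def write_changes(records, path: str | Path) -> None:
    """Long-format change table: participant, phase_pair, metric, cluster, change."""
    from .longitudinal import CLUSTER_OF_METRIC

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(("participant_id", "phase_pair", "metric", "cluster", "change"))
        for r in records:
            pair = "->".join(r.phase_pair)
            for name in METRIC_NAMES:
                if name in r.metric_changes:
                    w.writerow(
                        [
                            r.participant_id,
                            pair,
                            name,
                            CLUSTER_OF_METRIC[name],
                            _fmt(r.metric_changes[name]),
                        ]
                    )


def write_summary(summary: dict, path: str | Path) -> None:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, float) and math.isnan(obj):
            return None
        return obj

    Path(path).write_text(json.dumps(clean(summary), indent=1), encoding="utf-8")
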