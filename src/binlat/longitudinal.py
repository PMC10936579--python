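"""Phase-to-phase change quantification in control-dispersion units.

The change of a metric between two phases is expressed in units of the
control group's dispersion for that metric, signed so that positive means
the later value sits closer to the control mean (improvement) and negative
means it moved away.  Divergence-count deltas classify each patient's
trajectory per phase pair as improved / stable / deteriorated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, MetricVector
from .normative import DivergenceProfile, NormativeTable
from .schema import DEFAULT_PHASE_ORDER, is_na

logger = logging.getLogger(__name__)

NA = float("nan")

#: Metric clusters of the change heat map: A shift of the auditory space,
#: B variability, C slopes, D perceived ranges, E monaural perception,
#: F extreme (non-physiological) ITDs.
CLUSTERS: dict[str, tuple[str, ...]] = {
    "A": (
        "itd_mean",
        "ild_mean",
        "itd_l_fit",
        "itd_r_fit",
        "ild_l_fit",
        "ild_r_fit",
        "itd_center",
        "ild_center",
        "diotic_percept",
    ),
    "B": (
        "diotic_std",
        "ild_std",
        "itd_std",
        "itd_l_std",
        "itd_r_std",
        "ild_l_std",
        "ild_r_std",
        "itd_std_ratio",
        "ild_std_ratio",
    ),
    "C": (
        "ild_l_slope",
        "ild_r_slope",
        "itd_l_slope",
        "itd_r_slope",
        "ild_slope_ratio",
        "itd_slope_ratio",
    ),
    "D": ("itd_range", "ild_range", "range_ratio"),
    "E": ("mon_left", "mon_right"),
    "F": ("neg_1500", "pos_1500"),
}

CLUSTER_OF_METRIC: dict[str, str] = {
    m: c for c, ms in CLUSTERS.items() for m in ms
}
assert set(CLUSTER_OF_METRIC) == set(METRIC_NAMES)

TRAJECTORY_IMPROVED = "improved"
TRAJECTORY_STABLE = "stable"
TRAJECTORY_DETERIORATED = "deteriorated"


@dataclass(frozen=True)
class ChangeRecord:
    participant_id: str
    phase_pair: tuple[str, str]  # (earlier, later)
    metric_changes: dict[str, float]
    divergence_delta: int
    trajectory: str


def change_score(
    x_earlier: float, x_later: float, control_mean: float, control_sd: float
) -> float:
    """Signed change in control-dispersion units; positive = toward control.

    ``(|x_earlier - mean| - |x_later - mean|) / sd``.  NaN when either phase
    value is undefined.
    """
    if control_sd <= 0 or is_na(control_sd):
        raise ValueError(f"control dispersion must be > 0, got {control_sd}")
    if is_na(x_earlier) or is_na(x_later):
        return NA
    return (abs(x_earlier - control_mean) - abs(x_later - control_mean)) / control_sd


def phase_pairs(phase_order: tuple[str, ...] = DEFAULT_PHASE_ORDER) -> list[tuple[str, str]]:
    """Adjacent pairs plus first-vs-last, in phase order."""
    pairs = [
        (phase_order[i], phase_order[i + 1]) for i in range(len(phase_order) - 1)
    ]
    if len(phase_order) > 2:
        pairs.insert(1, (phase_order[0], phase_order[-1]))
    return pairs


def _classify_trajectory(delta: int) -> str:
    if delta < 0:
        return TRAJECTORY_IMPROVED
    if delta > 0:
        return TRAJECTORY_DETERIORATED
    return TRAJECTORY_STABLE


def phase_comparison(
    profiles: dict[tuple[str, str], DivergenceProfile],
    vectors: dict[tuple[str, str], MetricVector] | None = None,
    table: NormativeTable | None = None,
    phase_order: tuple[str, ...] = DEFAULT_PHASE_ORDER,
    dispersion: str = "sd",
) -> tuple[list[ChangeRecord], dict]:
    """Trajectories and per-metric change scores for every phase pair.

    ``profiles``/``vectors`` are keyed by ``(participant_id, phase)``.
    Metric change scores are computed when both ``vectors`` and ``table``
    are given; ``dispersion`` selects the control unit (``"sd"`` default,
    ``"iqr"`` variant).  Participants with fewer than two phases are
    skipped with a logged notice.
    """
    if dispersion not in ("sd", "iqr"):
        raise ValueError(f"unknown dispersion {dispersion!r}")
    participants = sorted({pid for pid, _ in profiles})
    records: list[ChangeRecord] = []
    for pid in participants:
        phases = [ph for ph in phase_order if (pid, ph) in profiles]
        if len(phases) < 2:
            logger.info("participant %s has < 2 phases; skipped", pid)
            continue
        for earlier, later in phase_pairs(phase_order):
            if earlier not in phases or later not in phases:
                continue
            p_e, p_l = profiles[(pid, earlier)], profiles[(pid, later)]
            delta = p_l.count - p_e.count
            changes: dict[str, float] = {}
            if vectors is not None and table is not None:
                v_e, v_l = vectors[(pid, earlier)], vectors[(pid, later)]
                for name in METRIC_NAMES:
                    rng = table[name]
                    unit = rng.sd if dispersion == "sd" else rng.iqr
                    if unit <= 0 or is_na(unit):
                        logger.info(
                            "metric %s has nonpositive control %s; change NA",
                            name,
                            dispersion,
                        )
                        changes[name] = NA
                        continue
                    changes[name] = change_score(v_e[name], v_l[name], rng.mean, unit)
                    if is_na(changes[name]):
                        logger.info(
                            "metric %s undefined for %s in %s or %s; change NA",
                            name,
                            pid,
                            earlier,
                            later,
                        )
            records.append(
                ChangeRecord(pid, (earlier, later), changes, delta, _classify_trajectory(delta))
            )
    summary = summarize_changes(records, phase_order)
    return records, summary


def summarize_changes(
    records: list[ChangeRecord],
    phase_order: tuple[str, ...] = DEFAULT_PHASE_ORDER,
) -> dict:
    """Per-pair trajectory counts plus mean/SD of divergence-count deltas."""
    summary: dict = {"phase_pairs": {}}
    for pair in phase_pairs(phase_order):
        recs = [r for r in records if r.phase_pair == pair]
        if not recs:
            continue
        deltas = np.array([r.divergence_delta for r in recs], dtype=float)
        summary["phase_pairs"]["->".join(pair)] = {
            "n": len(recs),
            "improved": sum(r.trajectory == TRAJECTORY_IMPROVED for r in recs),
            "stable": sum(r.trajectory == TRAJECTORY_STABLE for r in recs),
            "deteriorated": sum(r.trajectory == TRAJECTORY_DETERIORATED for r in recs),
            "mean_delta": float(deltas.mean()),
            "sd_delta": float(deltas.std(ddof=1)) if len(deltas) > 1 else NA,
        }
    total = [r.trajectory for r in records]
    summary["total"] = {
        "stable_or_improved": sum(t != TRAJECTORY_DETERIORATED for t in total),
        "deteriorated": sum(t == TRAJECTORY_DETERIORATED for t in total),
    }
    return summary


def metric_change_matrix(records: list[ChangeRecord]) -> pd.DataFrame:
    """Signed-change table, one row per participant x phase pair.

    Columns are the 31 metrics ordered by cluster A..F; a two-level column
    index carries the cluster letter.  Positive entries move toward the
    control mean, negative away.
    """
    cluster_order = [m for c in sorted(CLUSTERS) for m in CLUSTERS[c]]
    rows = []
    index = []
    for r in records:
        index.append((r.participant_id, "->".join(r.phase_pair)))
        rows.append([r.metric_changes.get(m, NA) for m in cluster_order])
    columns = pd.MultiIndex.from_tuples(
        [(CLUSTER_OF_METRIC[m], m) for m in cluster_order],
        names=["cluster", "metric"],
    )
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["participant_id", "phase_pair"]),
        columns=columns,
    )
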