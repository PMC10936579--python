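"""The 31-variable quantitative description of a lateralization session.

Metric families
---------------
* slopes (6): per-side ordinary-least-squares slopes of response key on cue
  value for the three left-favoring and three right-favoring physiological
  stimuli of each cue family, plus their log left/right ratios;
* location (9): family means, side-fit means, centers of perceived-center
  stimuli, and the diotic percept;
* variability (9): per-stimulus response standard deviations aggregated per
  family and side, plus log side ratios;
* ranges (3): spans of per-stimulus mean responses plus their log ratio;
* monaural (2) and extreme-ITD (2) mean responses.

All key-scale metrics live on the 1..9 response scale (one key step equals
1/8 of the interaural distance).  Undefined values are represented as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .schema import (
    ILD_SET,
    ITD_EXTREME,
    ITD_PHYSIOLOGICAL,
    KEY_CENTER,
    LateralizationSession,
    Trial,
)

NA = float("nan")

#: Fixed order of the 31 metrics; stable across runs and serialized tables.
METRIC_NAMES: tuple[str, ...] = (
    # slopes (6)
    "ild_l_slope",
    "ild_r_slope",
    "itd_l_slope",
    "itd_r_slope",
    "ild_slope_ratio",
    "itd_slope_ratio",
    # location (9)
    "itd_mean",
    "ild_mean",
    "itd_l_fit",
    "itd_r_fit",
    "ild_l_fit",
    "ild_r_fit",
    "itd_center",
    "ild_center",
    "diotic_percept",
    # variability (9)
    "diotic_std",
    "ild_std",
    "itd_std",
    "itd_l_std",
    "itd_r_std",
    "ild_l_std",
    "ild_r_std",
    "itd_std_ratio",
    "ild_std_ratio",
    # ranges (3)
    "itd_range",
    "ild_range",
    "range_ratio",
    # monaural (2)
    "mon_left",
    "mon_right",
    # extreme ITDs (2)
    "neg_1500",
    "pos_1500",
)

N_METRICS = len(METRIC_NAMES)
assert N_METRICS == 31

#: Floors applied before the log ratios so that degenerate (deterministic or
#: fully side-oriented) response patterns stay finite and comparable.
STD_FLOOR_KEYS = 0.1
RANGE_FLOOR_KEYS = 0.5

_SIDE_STIMULI = {
    ("itd", "left"): (-600.0, -400.0, -200.0),
    ("itd", "right"): (200.0, 400.0, 600.0),
    ("ild", "left"): (-12.0, -8.0, -4.0),
    ("ild", "right"): (4.0, 8.0, 12.0),
}


@dataclass(frozen=True)
class SideFit:
    """OLS line through the retained trials of one side of one cue family."""

    side: str  # "left" | "right"
    cue_family: str  # "itd" | "ild"
    slope: float  # keys per cue unit (keys/µs or keys/dB)
    intercept: float  # keys at zero cue
    fitted_mean: float  # mean prediction at the three side stimuli


@dataclass(frozen=True)
class MetricVector:
    """The 31 named lateralization metrics of one session."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != N_METRICS:
            raise ValueError(f"expected {N_METRICS} metrics, got {len(self.values)}")

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "MetricVector":
        missing = set(METRIC_NAMES) - set(d)
        extra = set(d) - set(METRIC_NAMES)
        if missing or extra:
            raise ValueError(f"metric schema mismatch: missing={missing} extra={extra}")
        return cls(tuple(float(d[name]) for name in METRIC_NAMES))

    def __getitem__(self, name: str) -> float:
        return self.values[METRIC_NAMES.index(name)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(METRIC_NAMES, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def retain_trials(session: LateralizationSession) -> LateralizationSession:
    """Drop the first presentation of every stimulus; keep the rest in order.

    The response to the first trial of each stimulus is discarded from all
    analyses; a complete session retains 5 trials per non-diotic stimulus
    and 7 diotic trials.
    """
    drop: set[tuple[tuple[str, float | None], int]] = set()
    for key, trials in session.stimulus_groups().items():
        if len(trials) < 2:
            raise ValueError(
                f"stimulus {key} has a single presentation; cannot discard the "
                "first trial and retain any"
            )
        first = min(t.presentation_index for t in trials)
        drop.add((key, first))
    kept = [
        t
        for t in session.trials
        if (t.stimulus.key, t.presentation_index) not in drop
    ]
    return replace(session, trials=kept)


def _family_trials(
    session: LateralizationSession, family: str, cues: tuple[float, ...]
) -> dict[float, list[int]]:
    """Responses per cue value; the diotic stimulus contributes at cue 0."""
    out: dict[float, list[int]] = {c: [] for c in cues}
    for t in session.trials:
        if t.stimulus.cue_type == family and t.stimulus.cue_value in out:
            out[t.stimulus.cue_value].append(t.response_key)
        elif t.stimulus.cue_type == "diotic" and 0.0 in out:
            out[0.0].append(t.response_key)
    return out


def fit_side_line(trials: list[Trial], side: str, family: str) -> SideFit:
    """OLS of response key on cue value over the retained trials of one side.

    The fit uses the individual trials, not per-stimulus means; with
    balanced repetition counts the slope is identical either way.
    ``fitted_mean`` is the mean prediction at the three side cue values
    (equal to the prediction at the middle stimulus).
    """
    cues = _SIDE_STIMULI[(family, side)]
    by_cue: dict[float, list[int]] = {c: [] for c in cues}
    for t in trials:
        if t.stimulus.cue_type != family or t.stimulus.cue_value not in by_cue:
            raise ValueError(
                f"trial with stimulus {t.stimulus.key} does not belong to the "
                f"{side} {family} side set {cues}"
            )
        by_cue[t.stimulus.cue_value].append(t.response_key)
    for c in cues:
        if not by_cue[c]:
            raise ValueError(f"missing retained trials for {family} {c:+g} ({side})")

    x = [int(c) for c in cues for _ in by_cue[c]]
    y = [int(r) for c in cues for r in by_cue[c]]
    # closed-form OLS in exact integer arithmetic (cues and keys are
    # integers): a flat or balanced pattern yields slope exactly 0, which
    # the NA contract of the log slope ratio depends on — float summation
    # leaves ~1e-17 residues of order-dependent sign there
    n = len(x)
    num = n * sum(a * b for a, b in zip(x, y)) - sum(x) * sum(y)
    den = n * sum(a * a for a in x) - sum(x) ** 2
    slope = num / den
    intercept = (sum(y) - slope * sum(x)) / n
    fitted_mean = float(intercept + slope * np.mean(cues))
    return SideFit(side, family, slope, intercept, fitted_mean)


def slope_ratio(slope_left: float, slope_right: float) -> float:
    """Natural log of the left/right slope quotient; NaN when it is <= 0."""
    if slope_right == 0:
        return NA
    q = slope_left / slope_right
    if q <= 0 or math.isnan(q):
        return NA
    return math.log(q)


def location_metrics(session: LateralizationSession) -> dict[str, float]:
    """Side-bias metrics of a retained session.

    Family means average the responses over the physiological stimulus set
    of the family including the diotic trials (extreme ITDs and monaural
    stimuli excluded).  Center metrics are the mean cue value, in native cue
    units, over trials answered with key 5 (NaN when key 5 never occurs).
    """
    out: dict[str, float] = {}
    for family, cues, span_set in (
        ("itd", ITD_PHYSIOLOGICAL, "itd"),
        ("ild", ILD_SET, "ild"),
    ):
        by_cue = _family_trials(session, family, cues + (0.0,))
        all_resp = [r for rs in by_cue.values() for r in rs]
        out[f"{family}_mean"] = float(np.mean(all_resp)) if all_resp else NA
        center_cues = [
            c for c, rs in by_cue.items() for r in rs if r == KEY_CENTER
        ]
        out[f"{family}_center"] = float(np.mean(center_cues)) if center_cues else NA
    diotic = [
        t.response_key for t in session.trials if t.stimulus.cue_type == "diotic"
    ]
    out["diotic_percept"] = float(np.mean(diotic)) if diotic else NA
    return out


def _per_stimulus_stats(
    session: LateralizationSession, family: str, cues: tuple[float, ...]
) -> tuple[dict[float, float], dict[float, float]]:
    """(mean, sample std) of responses per cue, diotic included at cue 0."""
    by_cue = _family_trials(session, family, cues + (0.0,))
    means: dict[float, float] = {}
    stds: dict[float, float] = {}
    for c, rs in by_cue.items():
        if len(rs) < 2:
            raise ValueError(
                f"{family} stimulus {c:+g} has {len(rs)} retained trial(s); "
                "need >= 2 for a sample standard deviation"
            )
        means[c] = float(np.mean(rs))
        stds[c] = float(np.std(rs, ddof=1))
    return means, stds


def _floored_log_ratio(num: float, den: float, floor: float) -> float:
    return math.log(max(num, floor) / max(den, floor))


def variability_metrics(session: LateralizationSession) -> dict[str, float]:
    """Per-stimulus sample standard deviations aggregated per family/side."""
    out: dict[str, float] = {}
    diotic = [
        t.response_key for t in session.trials if t.stimulus.cue_type == "diotic"
    ]
    if len(diotic) < 2:
        raise ValueError("need >= 2 retained diotic trials for diotic_std")
    out["diotic_std"] = float(np.std(diotic, ddof=1))
    for family, cues in (("itd", ITD_PHYSIOLOGICAL), ("ild", ILD_SET)):
        _, stds = _per_stimulus_stats(session, family, cues)
        left = _SIDE_STIMULI[(family, "left")]
        right = _SIDE_STIMULI[(family, "right")]
        out[f"{family}_std"] = float(np.mean(list(stds.values())))
        out[f"{family}_l_std"] = float(np.mean([stds[c] for c in left]))
        out[f"{family}_r_std"] = float(np.mean([stds[c] for c in right]))
        out[f"{family}_std_ratio"] = _floored_log_ratio(
            out[f"{family}_l_std"], out[f"{family}_r_std"], STD_FLOOR_KEYS
        )
    return out


def range_metrics(session: LateralizationSession) -> dict[str, float]:
    """Spans of per-stimulus mean responses and their ILD/ITD log ratio."""
    out: dict[str, float] = {}
    for family, cues in (("itd", ITD_PHYSIOLOGICAL), ("ild", ILD_SET)):
        by_cue = _family_trials(session, family, cues + (0.0,))
        means = [float(np.mean(rs)) for rs in by_cue.values() if rs]
        out[f"{family}_range"] = max(means) - min(means) if means else NA
    out["range_ratio"] = _floored_log_ratio(
        out["ild_range"], out["itd_range"], RANGE_FLOOR_KEYS
    )
    return out


def extreme_and_monaural(session: LateralizationSession) -> dict[str, float]:
    """Mean responses to the monaural and the +-1500 µs stimuli."""

    def mean_of(pred) -> float:
        rs = [t.response_key for t in session.trials if pred(t.stimulus)]
        return float(np.mean(rs)) if rs else NA

    return {
        "mon_left": mean_of(lambda s: s.cue_type == "mono_left"),
        "mon_right": mean_of(lambda s: s.cue_type == "mono_right"),
        "neg_1500": mean_of(lambda s: s.cue_type == "itd" and s.cue_value == -1500),
        "pos_1500": mean_of(lambda s: s.cue_type == "itd" and s.cue_value == 1500),
    }


def compute_metric_vector(session: LateralizationSession) -> MetricVector:
    """Assemble all 31 metrics of one session (first trials discarded here)."""
    retained = retain_trials(session)
    values: dict[str, float] = {}

    for family in ("ild", "itd"):
        fits: dict[str, SideFit] = {}
        for side in ("left", "right"):
            cues = _SIDE_STIMULI[(family, side)]
            side_trials = [
                t
                for t in retained.trials
                if t.stimulus.cue_type == family and t.stimulus.cue_value in cues
            ]
            fits[side] = fit_side_line(side_trials, side, family)
        values[f"{family}_l_slope"] = fits["left"].slope
        values[f"{family}_r_slope"] = fits["right"].slope
        values[f"{family}_l_fit"] = fits["left"].fitted_mean
        values[f"{family}_r_fit"] = fits["right"].fitted_mean
        values[f"{family}_slope_ratio"] = slope_ratio(
            fits["left"].slope, fits["right"].slope
        )

    values.update(location_metrics(retained))
    values.update(variability_metrics(retained))
    values.update(range_metrics(retained))
    values.update(extreme_and_monaural(retained))
    return MetricVector.from_dict(values)


# --- documented mirror contract -------------------------------------------
# Mirroring a session (negated cues, responses reflected about key 5,
# monaural sides swapped) maps the metric vector as follows.

#: metrics that swap left/right labels without value change
MIRROR_SWAP = (
    ("ild_l_slope", "ild_r_slope"),
    ("itd_l_slope", "itd_r_slope"),
    ("itd_l_std", "itd_r_std"),
    ("ild_l_std", "ild_r_std"),
)
#: metrics that swap left/right labels and reflect about key 5
MIRROR_SWAP_REFLECT = (
    ("itd_l_fit", "itd_r_fit"),
    ("ild_l_fit", "ild_r_fit"),
    ("mon_left", "mon_right"),
    ("neg_1500", "pos_1500"),
)
#: key-scale metrics that reflect about key 5
MIRROR_REFLECT = ("itd_mean", "ild_mean", "diotic_percept")
#: signed metrics that negate
MIRROR_NEGATE = (
    "ild_slope_ratio",
    "itd_slope_ratio",
    "itd_center",
    "ild_center",
    "itd_std_ratio",
    "ild_std_ratio",
)
#: metrics invariant under mirroring
MIRROR_INVARIANT = (
    "diotic_std",
    "ild_std",
    "itd_std",
    "itd_range",
    "ild_range",
    "range_ratio",
)


def mirror_metric_vector(mv: MetricVector) -> MetricVector:
    """The metric vector of the mirrored session, from the mirror contract."""
    d = mv.as_dict()
    out = dict(d)
    for a, b in MIRROR_SWAP:
        out[a], out[b] = d[b], d[a]
    for a, b in MIRROR_SWAP_REFLECT:
        out[a], out[b] = 10.0 - d[b], 10.0 - d[a]
    for name in MIRROR_REFLECT:
        out[name] = 10.0 - d[name]
    for name in MIRROR_NEGATE:
        out[name] = -d[name]
    return MetricVector.from_dict(out)
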