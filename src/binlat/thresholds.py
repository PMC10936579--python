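"""Adaptive tone-in-noise staircase, BMLD, and audiometric summaries.

The detection task is a three-interval forced choice: the observer picks
the interval containing the tone, so chance performance is 1/3.  The tone
level follows a transformed one-up/three-down staircase (down after three
consecutive correct responses, up after any error) with a 4 dB step until
the second reversal and 2 dB thereafter, stopping at the tenth reversal.
The threshold is the mean of the last eight reversal levels; the staircase
converges to the (1/2)^(1/3) ~ 79.4 %-correct point of the psychometric
function.  The binaural masking level difference (BMLD) is the N0S0
threshold minus the better of the two N0Spi thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import ndtr, ndtri

from .normative import normal_range
from .schema import AudiogramRecord, is_na

NA = float("nan")

CONDITIONS = ("N0S0", "N0Spi")
#: Initial tone level per condition (dB SPL).
START_LEVELS = {"N0S0": 65.0, "N0Spi": 50.0}
MAX_TONE_LEVEL = 80.0
STEP_INITIAL = 4.0
STEP_FINAL = 2.0
STEP_SWITCH_REVERSAL = 2  # steps shrink once this many reversals occurred
TOTAL_REVERSALS = 10
REVERSALS_AVERAGED = 8
N_DOWN = 3
#: Cap requests beyond MAX_TONE_LEVEL tolerated before a track is invalid.
CAP_STRIKES = 3

PTA3_FREQUENCIES = (500.0, 1000.0, 3000.0)


def convergence_target(n_down: int) -> float:
    """Asymptotic percent-correct of a one-up/n-down staircase: (1/2)^(1/n)."""
    if n_down < 1:
        raise ValueError("n_down >= 1 required")
    return 0.5 ** (1.0 / n_down)


@dataclass(frozen=True)
class ToneInNoiseObserver:
    """Cumulative-normal 3AFC observer for the tone-in-noise task.

    ``p(level) = guess + (1 - guess - lapse) * Phi((level - mu) / sigma)``
    with the condition-specific midpoint ``mu``; binaural unmasking enters
    only through ``mu_n0spi <= mu_n0s0``.
    """

    mu_n0s0: float
    mu_n0spi: float
    sigma: float
    guess_rate: float = 1.0 / 3.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma > 0 required")
        if self.mu_n0spi > self.mu_n0s0:
            raise ValueError("mu_n0spi <= mu_n0s0 required (binaural unmasking)")

    def mu(self, condition: str) -> float:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return self.mu_n0s0 if condition == "N0S0" else self.mu_n0spi

    def prob_correct(self, level: float, condition: str) -> float:
        z = (level - self.mu(condition)) / self.sigma
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * float(
            ndtr(z)
        )

    def threshold_at(self, p_target: float, condition: str) -> float:
        """Level where the psychometric function crosses ``p_target``."""
        q = (p_target - self.guess_rate) / (1.0 - self.guess_rate - self.lapse_rate)
        return self.mu(condition) + self.sigma * float(ndtri(q))


class TrackTrial(NamedTuple):
    level: float  # dB SPL presented
    correct: bool
    is_reversal: bool


@dataclass
class TrackRecord:
    """One adaptive-track run with its validity and extracted threshold."""

    condition: str
    run_index: int
    trials: list[TrackTrial]
    valid: bool
    threshold: float = NA  # dB SPL; NaN for invalid tracks

    @property
    def reversal_levels(self) -> list[float]:
        return [t.level for t in self.trials if t.is_reversal]


def run_staircase(
    observer: ToneInNoiseObserver,
    condition: str,
    rng: np.random.Generator,
    start_level: float | None = None,
    run_index: int = 1,
    max_trials: int = 1000,
) -> TrackRecord:
    """Simulate one one-up/three-down track and extract its threshold.

    Levels never exceed ``MAX_TONE_LEVEL``; a track requesting a level above
    the cap ``CAP_STRIKES`` times is stopped and marked invalid (the
    mechanical analogue of re-instruction followed by abandoning the run).
    Reversal levels are the levels presented on the reversal trials.
    """
    level = START_LEVELS[condition] if start_level is None else start_level
    if level > MAX_TONE_LEVEL:
        raise ValueError(f"start level {level} exceeds cap {MAX_TONE_LEVEL}")
    trials: list[TrackTrial] = []
    n_reversals = 0
    consecutive_correct = 0
    last_direction = 0  # -1 down, +1 up, 0 none yet
    cap_count = 0
    valid = True

    while n_reversals < TOTAL_REVERSALS and len(trials) < max_trials:
        correct = rng.random() < observer.prob_correct(level, condition)
        direction = 0
        if correct:
            consecutive_correct += 1
            if consecutive_correct == N_DOWN:
                direction = -1
                consecutive_correct = 0
        else:
            direction = +1
            consecutive_correct = 0

        is_reversal = direction != 0 and last_direction != 0 and direction != last_direction
        trials.append(TrackTrial(level, correct, is_reversal))

        if direction != 0:
            # the step in force before this trial's reversal is registered
            step = STEP_INITIAL if n_reversals < STEP_SWITCH_REVERSAL else STEP_FINAL
            if is_reversal:
                n_reversals += 1
            last_direction = direction
            requested = level + direction * step
            if requested > MAX_TONE_LEVEL:
                cap_count += 1
                requested = MAX_TONE_LEVEL
                if cap_count >= CAP_STRIKES:
                    valid = False
                    break
            level = requested

    if n_reversals < TOTAL_REVERSALS:
        valid = False
    track = TrackRecord(condition, run_index, trials, valid)
    track.threshold = extract_threshold(track)
    return track


def extract_threshold(track: TrackRecord) -> float:
    """Mean of the last ``REVERSALS_AVERAGED`` reversal levels; NaN if invalid."""
    if not track.valid:
        return NA
    levels = track.reversal_levels
    if len(levels) != TOTAL_REVERSALS:
        raise ValueError(
            f"valid track must have {TOTAL_REVERSALS} reversals, got {len(levels)}"
        )
    return float(np.mean(levels[-REVERSALS_AVERAGED:]))


@dataclass(frozen=True)
class BMLDResult:
    threshold_n0s0: float
    threshold_n0spi_run1: float
    threshold_n0spi_run2: float
    bmld: float  # dB; NaN when not computable


def compute_bmld(
    thr_n0s0: float, thr_pi_run1: float, thr_pi_run2: float
) -> BMLDResult:
    """BMLD = N0S0 threshold minus the better (lower) valid N0Spi threshold."""
    pi = [t for t in (thr_pi_run1, thr_pi_run2) if not is_na(t)]
    if is_na(thr_n0s0) or not pi:
        bmld = NA
    else:
        bmld = thr_n0s0 - min(pi)
    return BMLDResult(thr_n0s0, thr_pi_run1, thr_pi_run2, bmld)


def bmld_normal_range(control_bmlds: list[float]) -> tuple[float, float]:
    """Order-statistic normal range over the valid control BMLDs."""
    return normal_range([b for b in control_bmlds if not is_na(b)])


@dataclass(frozen=True)
class Pta3Result:
    pta3_left: float
    pta3_right: float
    pta3: float
    asymmetry: float  # left - right; positive = left ear worse


def pta3(records: list[AudiogramRecord]) -> Pta3Result:
    """Pure-tone average over 500/1000/3000 Hz per ear, overall, asymmetry."""
    by_ear: dict[str, dict[float, float]] = {"left": {}, "right": {}}
    for r in records:
        by_ear[r.ear][r.frequency] = r.threshold
    means = {}
    for ear in ("left", "right"):
        for f in PTA3_FREQUENCIES:
            if f not in by_ear[ear]:
                raise ValueError(f"missing {ear} ear threshold at {f:g} Hz")
        means[ear] = float(np.mean([by_ear[ear][f] for f in PTA3_FREQUENCIES]))
    return Pta3Result(
        pta3_left=means["left"],
        pta3_right=means["right"],
        pta3=(means["left"] + means["right"]) / 2.0,
        asymmetry=means["left"] - means["right"],
    )
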