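"""Shared test helpers: hand-built sessions and NaN-aware comparison."""

from __future__ import annotations

import math

from binlat.metrics import METRIC_NAMES
from binlat.schema import (
    ILD_SET,
    ITD_EXTREME,
    ITD_PHYSIOLOGICAL,
    LateralizationSession,
    StimulusDescriptor,
    Trial,
)

ALL_STIMULI = (
    [("itd", v) for v in ITD_PHYSIOLOGICAL + ITD_EXTREME]
    + [("ild", v) for v in ILD_SET]
    + [("mono_left", None), ("mono_right", None), ("diotic", None)]
)


def make_session(
    responses: dict[tuple[str, float | None], list[int]],
    participant_id: str = "T",
    group: str = "patient",
    phase: str = "acute",
) -> LateralizationSession:
    """Session from explicit per-stimulus response lists (presentation order)."""
    trials = []
    for (ct, cv), resp in responses.items():
        stim = StimulusDescriptor(ct, cv)
        for i, r in enumerate(resp, start=1):
            trials.append(Trial(stim, i, r))
    return LateralizationSession(participant_id, group, phase, trials)


def full_session_from_retained(
    retained: dict[tuple[str, float | None], list[int]],
    filler_first: int = 5,
) -> LateralizationSession:
    """Complete session whose retained responses equal ``retained`` exactly.

    A discardable first presentation (``filler_first``) is prepended to every
    stimulus; stimuli not mentioned get constant filler responses.
    """
    responses = {}
    for key in ALL_STIMULI:
        n_retained = 7 if key[0] == "diotic" else 5
        body = retained.get(key, [filler_first] * n_retained)
        assert len(body) == n_retained, key
        responses[key] = [filler_first] + list(body)
    return make_session(responses)


def assert_metrics_equal(a: dict, b: dict, tol: float = 1e-9) -> None:
    for name in METRIC_NAMES:
        va, vb = a[name], b[name]
        if math.isnan(va) or math.isnan(vb):
            assert math.isnan(va) and math.isnan(vb), f"{name}: {va} vs {vb}"
        else:
            assert abs(va - vb) <= tol, f"{name}: {va} vs {vb}"
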