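"""Independent brute-force re-implementation of the 31 session metrics.

Deliberately written from the definitions using only the standard library
(plain loops, ``statistics``, closed-form OLS sums) so it shares no code
path with the package implementation.
"""

from __future__ import annotations

import math
import statistics

NAN = float("nan")

ITD_PHYS = [-600.0, -400.0, -200.0, 200.0, 400.0, 600.0]
ILD_ALL = [-12.0, -8.0, -4.0, 4.0, 8.0, 12.0]
SIDES = {
    ("itd", "left"): [-600.0, -400.0, -200.0],
    ("itd", "right"): [200.0, 400.0, 600.0],
    ("ild", "left"): [-12.0, -8.0, -4.0],
    ("ild", "right"): [4.0, 8.0, 12.0],
}


def _discard_first(trials):
    """trials: list of (cue_type, cue_value, presentation_index, response)."""
    firsts = {}
    for ct, cv, pi, _ in trials:
        key = (ct, cv)
        if key not in firsts or pi < firsts[key]:
            firsts[key] = pi
    return [t for t in trials if t[2] != firsts[(t[0], t[1])]]


def _responses(trials, cue_type, cue_value=None):
    out = []
    for ct, cv, _, r in trials:
        if ct == cue_type and (cue_value is None or cv == cue_value):
            out.append(r)
    return out


def _family_points(trials, family):
    """(cue, response) pairs over the physiological set, diotic at cue 0."""
    cues = ITD_PHYS if family == "itd" else ILD_ALL
    pts = []
    for ct, cv, _, r in trials:
        if ct == family and cv in cues:
            pts.append((cv, r))
        elif ct == "diotic":
            pts.append((0.0, r))
    return pts


def _ols(points):
    # exact arithmetic via Fraction so that flat/balanced patterns give a
    # slope of exactly zero
    from fractions import Fraction

    n = len(points)
    xbar = Fraction(sum(int(x) for x, _ in points), n)
    ybar = Fraction(sum(int(y) for _, y in points), n)
    sxy = sum((Fraction(int(x)) - xbar) * (Fraction(int(y)) - ybar) for x, y in points)
    sxx = sum((Fraction(int(x)) - xbar) ** 2 for x, _ in points)
    slope = sxy / sxx
    return float(slope), float(ybar - slope * xbar)


def _log_ratio(num, den, floor):
    return math.log(max(num, floor) / max(den, floor))


def oracle_metrics(trials):
    """All 31 metrics of one session as a dict; NaN marks undefined."""
    kept = _discard_first(trials)
    out = {}

    for family in ("ild", "itd"):
        slopes = {}
        for side in ("left", "right"):
            pts = [
                (cv, r)
                for ct, cv, _, r in kept
                if ct == family and cv in SIDES[(family, side)]
            ]
            slope, icpt = _ols(pts)
            slopes[side] = slope
            mid = statistics.mean(SIDES[(family, side)])
            out[f"{family}_{side[0]}_slope"] = slope
            out[f"{family}_{side[0]}_fit"] = icpt + slope * mid
        q = slopes["left"] / slopes["right"] if slopes["right"] != 0 else NAN
        out[f"{family}_slope_ratio"] = math.log(q) if q > 0 else NAN

    for family in ("itd", "ild"):
        pts = _family_points(kept, family)
        out[f"{family}_mean"] = statistics.mean(r for _, r in pts)
        centers = [c for c, r in pts if r == 5]
        out[f"{family}_center"] = statistics.mean(centers) if centers else NAN
    out["diotic_percept"] = statistics.mean(_responses(kept, "diotic"))

    out["diotic_std"] = statistics.stdev(_responses(kept, "diotic"))
    for family in ("itd", "ild"):
        cues = (ITD_PHYS if family == "itd" else ILD_ALL) + [0.0]
        stds = {}
        for c in cues:
            rs = (
                _responses(kept, "diotic")
                if c == 0.0
                else _responses(kept, family, c)
            )
            stds[c] = statistics.stdev(rs)
        out[f"{family}_std"] = statistics.mean(stds.values())
        lstd = statistics.mean(stds[c] for c in SIDES[(family, "left")])
        rstd = statistics.mean(stds[c] for c in SIDES[(family, "right")])
        out[f"{family}_l_std"] = lstd
        out[f"{family}_r_std"] = rstd
        out[f"{family}_std_ratio"] = _log_ratio(lstd, rstd, 0.1)

    ranges = {}
    for family in ("itd", "ild"):
        cues = (ITD_PHYS if family == "itd" else ILD_ALL) + [0.0]
        means = []
        for c in cues:
            rs = (
                _responses(kept, "diotic")
                if c == 0.0
                else _responses(kept, family, c)
            )
            means.append(statistics.mean(rs))
        ranges[family] = max(means) - min(means)
        out[f"{family}_range"] = ranges[family]
    out["range_ratio"] = _log_ratio(ranges["ild"], ranges["itd"], 0.5)

    out["mon_left"] = statistics.mean(_responses(kept, "mono_left"))
    out["mon_right"] = statistics.mean(_responses(kept, "mono_right"))
    out["neg_1500"] = statistics.mean(_responses(kept, "itd", -1500.0))
    out["pos_1500"] = statistics.mean(_responses(kept, "itd", 1500.0))
    return out


def session_to_tuples(session):
    """Adapter: package session -> the oracle's plain-tuple trial list."""
    return [
        (t.stimulus.cue_type, t.stimulus.cue_value, t.presentation_index, t.response_key)
        for t in session.trials
    ]
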