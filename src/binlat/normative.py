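"""Order-statistic normative ranges and divergence classification.

For every metric the control cohort's values are sorted ascending and the
normal range spans the 2nd through the (n-1)th value (2nd to 11th for the
canonical 12-member cohort), bounds inclusive.  A patient metric outside
this range is a divergence; a participant with no more than
``NORMALITY_MAX_DIVERGENCES`` divergences across the 31 metrics has normal
lateralization.  By construction 2/n of the controls' own values lie
outside their range per metric, so ~5 of 31 divergences are expected even
for a normally performing participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .metrics import METRIC_NAMES, N_METRICS, MetricVector
from .schema import is_na

#: Maximum divergence count still classified as normal lateralization.
NORMALITY_MAX_DIVERGENCES = 5

#: Classification flags.
FLAG_NORMAL = "normal"
FLAG_DIVERGENT = "divergent"
FLAG_NA_DIVERGENT = "na_divergent"

MIN_VALID_CONTROLS = 4


@dataclass(frozen=True)
class NormRange:
    """Normative summary of one metric over the valid control values."""

    lo: float
    hi: float
    mean: float
    sd: float
    iqr: float
    n_controls: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("lo > hi")


class NormativeTable(dict):
    """Mapping metric name -> :class:`NormRange` for all 31 metrics."""

    @classmethod
    def from_control_vectors(
        cls, vectors: list[MetricVector]
    ) -> "NormativeTable":
        table = cls()
        for name in METRIC_NAMES:
            values = [v[name] for v in vectors if not is_na(v[name])]
            lo, hi = normal_range(values)
            arr = np.asarray(values, dtype=float)
            table[name] = NormRange(
                lo=lo,
                hi=hi,
                mean=float(arr.mean()),
                sd=float(arr.std(ddof=1)),
                iqr=float(np.percentile(arr, 75) - np.percentile(arr, 25)),
                n_controls=len(values),
            )
        return table


@dataclass
class DivergenceProfile:
    """Per-metric divergence flags and overall normality of one session."""

    participant_id: str
    phase: str
    flags: dict[str, str]
    count: int = field(init=False)
    is_normal_lateralization: bool = field(init=False)

    def __post_init__(self) -> None:
        self.count = sum(
            1 for f in self.flags.values() if f != FLAG_NORMAL
        )
        self.is_normal_lateralization = self.count <= NORMALITY_MAX_DIVERGENCES


def normal_range(control_values: list[float]) -> tuple[float, float]:
    """(2nd smallest, 2nd largest) of the finite control values, inclusive.

    Undefined control values are dropped first; at least
    ``MIN_VALID_CONTROLS`` finite values are required, otherwise the range
    would be degenerate.
    """
    finite = sorted(v for v in control_values if not is_na(v))
    if len(finite) < MIN_VALID_CONTROLS:
        raise ValueError(
            f"need >= {MIN_VALID_CONTROLS} finite control values, "
            f"got {len(finite)}"
        )
    return finite[1], finite[-2]


def classify_value(x: float, lo: float, hi: float) -> str:
    """Classify one metric value against a normal range (bounds inclusive).

    Undefined patient values count as divergent (``na_divergent``): a metric
    that cannot be computed for a patient whose controls all define it is
    itself a deviation.
    """
    if is_na(x):
        return FLAG_NA_DIVERGENT
    return FLAG_NORMAL if lo <= x <= hi else FLAG_DIVERGENT


def divergence_profile(
    metrics: MetricVector,
    table: NormativeTable,
    participant_id: str = "",
    phase: str = "",
) -> DivergenceProfile:
    """Flag all 31 metrics of one session against the normative table."""
    missing = [name for name in METRIC_NAMES if name not in table]
    if missing:
        raise ValueError(f"metrics missing from normative table: {missing}")
    flags = {
        name: classify_value(metrics[name], table[name].lo, table[name].hi)
        for name in METRIC_NAMES
    }
    return DivergenceProfile(participant_id, phase, flags)


@dataclass(frozen=True)
class ExpectedDivergences:
    expected: float
    rounded: int


def expected_false_divergences(
    n_metrics: int = N_METRICS, n_controls: int = 12
) -> ExpectedDivergences:
    """Expected divergences of an in-distribution participant: m * 2/n."""
    if n_metrics < 1:
        raise ValueError("n_metrics >= 1 required")
    if n_controls < MIN_VALID_CONTROLS:
        raise ValueError(f"n_controls >= {MIN_VALID_CONTROLS} required")
    expected = n_metrics * 2.0 / n_controls
    return ExpectedDivergences(expected, round(expected))
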