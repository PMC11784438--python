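"""Optical-density phenotype summaries.

Autoagglutinating cells sediment out of a standing suspension, so the drop
in OD660 after standing, relative to the initial value, measures
agglutination:  ratio (%) = 100 × (initial − after) / initial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class ODMeasurement:
    """A paired optical-density reading (OD660) before/after standing."""

    od_initial: float
    od_after: float
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        if self.od_initial <= 0:
            raise ValidationError("od_initial must be > 0")
        if self.od_after < 0:
            raise ValidationError("od_after must be >= 0")


def autoagglutination_ratio(m: ODMeasurement) -> float:
    """100 × (initial − after) / initial, in percent.

    May be negative when the suspension got denser (growth or mixing
    artifact); such values are returned as-is with a warning.
    """
    # parenthesized so od_after == 0 yields exactly 100.0
    ratio = 100.0 * ((m.od_initial - m.od_after) / m.od_initial)
    if ratio < 0:
        warnings.warn(
            f"negative autoagglutination ratio ({ratio:.3g}%): OD increased "
            f"after standing ({m.timepoint_label or 'unlabeled'})",
            stacklevel=2,
        )
    return ratio


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float | None
    n: int


def replicate_summary(values: Sequence[float]) -> ReplicateSummary:
    """Sample mean and sample standard deviation (n−1 denominator).

    The SD is undefined (``None``) for a single replicate.
    """
    if len(values) == 0:
        raise ValidationError("replicate_summary needs at least one value")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return ReplicateSummary(mean=mean, sd=None, n=1)
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return ReplicateSummary(mean=mean, sd=math.sqrt(var), n=n)


def group_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed two-sample Student's t-test (equal variances); returns
    (t statistic, p value).  Convenience for comparing strain groups."""
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least two replicates")
    result = stats.ttest_ind(a, b, equal_var=True)
    return float(result.statistic), float(result.pvalue)
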