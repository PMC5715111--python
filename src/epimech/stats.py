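"""Group-comparison statistics for mechanical measurements.

Groups are compared with unpaired two-tailed Welch t-tests (unequal
variances, Welch-Satterthwaite degrees of freedom), matching how the
per-condition tension/viscosity/force distributions are reported
(mean +/- SD, per-comparison tests at alpha = 0.05, no multiplicity
correction).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import GroupSummary
from .errors import ValidationError

logger = logging.getLogger(__name__)


def welch_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-tailed p).

    Two groups with zero variance and equal means are degenerate and return
    (0, n-2, 1) by convention; zero variance with unequal means is rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, x in (("a", a), ("b", b)):
        if len(x) < 2:
            raise ValidationError(f"group {name} needs at least 2 values")
        if not np.all(np.isfinite(x)):
            raise ValidationError(f"group {name} contains non-finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValidationError(
            "both groups have zero variance with different means; "
            "the t statistic is undefined"
        )
    result = sps.ttest_ind(a, b, equal_var=False)
    return float(result.statistic), float(result.df), float(result.pvalue)


def summarize_groups(
    samples: Mapping[str, Sequence[float]], unit: str = ""
) -> list[GroupSummary]:
    """Mean +/- SD (ddof=1) summaries, one per labelled group."""
    summaries = []
    for label, values in samples.items():
        x = np.asarray(values, dtype=float)
        if len(x) == 0:
            raise ValidationError(f"group {label!r} is empty")
        sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        summaries.append(
            GroupSummary(label=str(label), n=len(x), mean=float(x.mean()), sd=sd, unit=unit)
        )
    return summaries
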