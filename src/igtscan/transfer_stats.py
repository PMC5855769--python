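"""Summary statistics over transfer segments: ratio tables, OLS regressions,
Welch t-tests, and per-species union-bp totals.

The ratio table mirrors the published repeat-content layout: percent =
100 x numerator/denominator rounded half-up to two decimals, with species
under a threshold (default 20%) flagged.  The spermatophyte-vs-bryophyte
comparison uses a two-tailed Welch (unequal variance) t-test by default,
appropriate for wildly unequal group sizes; Student's pooled test is
switchable.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homology_search import TransferSegment
from .intervals import union_length


@dataclass
class RatioRow:
    species_id: str
    numerator: float
    denominator: float
    percent: float           # rounded half-up to 2 decimals
    below_threshold_flag: bool


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    degenerate_response: bool = False   # constant y: r_squared defined as 0


@dataclass
class GroupTestResult:
    group_a_label: str
    group_b_label: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def significance_marker(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ratio_table(
    rows: Iterable[tuple[str, float, float]], threshold_pct: float = 20.0
) -> tuple[list[RatioRow], int]:
    """Percent = 100*numerator/denominator per species, with a below-threshold flag.

    Returns (rows, number of flagged species).  Non-positive denominators
    reject the row with a message.
    """
    out: list[RatioRow] = []
    for species, num, den in rows:
        if den <= 0:
            raise ValueError(f"{species}: denominator must be positive, got {den}")
        pct = round_half_up(100.0 * num / den)
        out.append(RatioRow(species, num, den, pct, pct < threshold_pct))
    return out, sum(r.below_threshold_flag for r in out)


def fit_regression(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """Ordinary least squares y ~ x with r_squared = 1 - SSres/SStot.

    All-equal x is an error ("degenerate predictor"); constant y is returned
    with slope 0 and r_squared 0 by convention, flagged.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all x equal")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, len(points), degenerate_response=True)
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n=len(points),
    )


def group_t_test(
    a: Sequence[float],
    b: Sequence[float],
    group_a_label: str = "group_a",
    group_b_label: str = "group_b",
    welch: bool = True,
) -> GroupTestResult:
    """Two-tailed t-test between two groups (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(mean_a - mean_b)) * float("inf"), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    return GroupTestResult(
        group_a_label, group_b_label, mean_a, mean_b, t, p, len(a), len(b)
    )


def species_totals(
    segments: Iterable[TransferSegment],
    deviation_pct: float = 5.0,
) -> pd.DataFrame:
    """Per-species union-bp totals per segment class (overlaps counted once).

    Unions are taken within each recipient record.  The output carries +-
    ``deviation_pct`` whisker columns, mirroring the display convention of
    the bar-chart inputs it feeds.
    """
    buckets: dict[tuple[str, str], dict[str, list]] = {}
    for s in segments:
        key = (s.species_id, s.segment_class.value)
        buckets.setdefault(key, {}).setdefault(s.hsp.target_id, []).append(
            (s.hsp.t_start, s.hsp.t_end)
        )
    rows = []
    for (species, seg_class), by_target in sorted(buckets.items()):
        total = sum(union_length(ivs) for ivs in by_target.values())
        rows.append(
            {
                "species_id": species,
                "segment_class": seg_class,
                "total_bp": total,
                "whisker_low": total * (1 - deviation_pct / 100.0),
                "whisker_high": total * (1 + deviation_pct / 100.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species_id", "segment_class", "total_bp", "whisker_low", "whisker_high"],
    )
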