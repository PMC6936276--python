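"""Recompute p-values from reported statistics and classify consistency.

The central question is the one a statistical-reporting checker asks:
*could the reported p-value have resulted from correctly rounding the
p-value implied by the reported test statistic and degrees of freedom?*
Both the statistic and the reported p carry rounding uncertainty, so the
check intersects two intervals: the p-interval induced by the statistic's
rounding window, and the reported p's own rounding window (or threshold).

An inconsistency that flips the significance decision at alpha is a
*gross* inconsistency (a decision error); everything else that mismatches
is a general inconsistency.  Records whose p cannot be recomputed (family
"other", missing d.f. or statistic) are *unverifiable* and never counted
as inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special

from .records import ReportedTest, ThesisRecord

__all__ = [
    "PInterval",
    "ConsistencyVerdict",
    "CompletenessReport",
    "recompute_p",
    "recompute_p_interval",
    "classify",
    "classify_all",
    "completeness",
]

_SYMMETRIC_FAMILIES = ("t", "z", "r")  # halving p gives the one-tailed value


@dataclass(frozen=True)
class PInterval:
    """Closed interval of p-values induced by rounding of the statistic."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= self.hi <= 1.0):
            raise ValueError(f"invalid p interval [{self.lo}, {self.hi}]")

    def overlaps(self, lo: float, hi: float) -> bool:
        return self.lo <= hi and lo <= self.hi

    def halved(self) -> "PInterval":
        return PInterval(self.lo / 2.0, self.hi / 2.0)


@dataclass(frozen=True)
class ConsistencyVerdict:
    status: str  # consistent | inconsistency | gross_inconsistency | unverifiable
    p_recomputed: PInterval | None = None
    one_tailed_rescue: bool = False

    def __post_init__(self) -> None:
        if (self.status == "unverifiable") != (self.p_recomputed is None):
            raise ValueError("status=unverifiable iff p_recomputed is absent")

    @property
    def inconsistent(self) -> bool:
        return self.status in ("inconsistency", "gross_inconsistency")


class Unverifiable(ValueError):
    """The test cannot be recomputed (family or required fields missing)."""


def recompute_p(family: str, statistic: float, df1: float | None = None,
                df2: float | None = None, n: int | None = None,
                tails: str = "two") -> float:
    """Exact tail probability of the statistic under its null distribution.

    t -> Student t; F -> F(df1, df2) upper tail; chi2 -> chi-square upper
    tail; r -> via t = r*sqrt((n-2)/(1-r^2)) with df = n-2; z -> standard
    normal.  ``tails="one"`` halves the two-sided p for the symmetric
    families (t, z, r); F and chi2 are inherently one-sided.
    """
    one_tailed = tails == "one"
    if family == "t":
        if df1 is None:
            raise Unverifiable("t test requires df1")
        p = 2.0 * special.stdtr(df1, -abs(statistic))
    elif family == "F":
        if df1 is None or df2 is None:
            raise Unverifiable("F test requires df1 and df2")
        if statistic < 0:
            raise Unverifiable("F statistic must be non-negative")
        p = float(special.fdtrc(df1, df2, statistic))
        one_tailed = False
    elif family == "chi2":
        if df1 is None:
            raise Unverifiable("chi2 test requires df1")
        if statistic < 0:
            raise Unverifiable("chi2 statistic must be non-negative")
        p = float(special.chdtrc(df1, statistic))
        one_tailed = False
    elif family == "r":
        if n is None or n < 4:
            raise Unverifiable("correlation test requires n >= 4")
        rr = abs(statistic)
        if rr >= 1.0:
            return 0.0
        df = n - 2
        t = rr * np.sqrt(df / (1.0 - rr * rr))
        p = 2.0 * special.stdtr(df, -t)
    elif family == "z":
        p = 2.0 * special.ndtr(-abs(statistic))
    else:
        raise Unverifiable(f"family {family!r} is not recomputable")
    p = float(min(max(p, 0.0), 1.0))
    return p / 2.0 if one_tailed else p


def recompute_p_interval(test: ReportedTest) -> PInterval:
    """Interval of p-values consistent with the statistic's rounding window.

    All families are strictly monotone in |statistic|, so evaluating the
    two endpoints statistic +/- 0.5*10^(-stat_decimals) suffices.  An
    exact statistic (``stat_decimals=None``) gives a degenerate interval.
    """
    if not test.has_statistic:
        raise Unverifiable("statistic missing")
    stat = abs(test.statistic)
    kwargs = dict(family=test.family, df1=test.df1, df2=test.df2, n=test.n,
                  tails="one" if test.tails == "one" else "two")
    if test.stat_decimals is None:
        p = recompute_p(statistic=stat, **kwargs)
        return PInterval(p, p)
    half = 0.5 * 10.0 ** (-test.stat_decimals)
    lo_stat = max(stat - half, 0.0)
    hi_stat = stat + half
    if test.family == "r":
        hi_stat = min(hi_stat, 1.0)
    p_hi = recompute_p(statistic=lo_stat, **kwargs)
    p_lo = recompute_p(statistic=hi_stat, **kwargs)
    return PInterval(min(p_lo, p_hi), max(p_lo, p_hi))


def _reported_window(test: ReportedTest) -> tuple[float, float]:
    """Rounding window of an exact-style reported p.

    p reported as 0 (or 1) is read as "below the smallest representable
    value at that precision" (resp. above the largest), which the clipped
    window already expresses.
    """
    d = 3 if test.p_style == "exact3" else 2
    half = 0.5 * 10.0 ** (-d)
    return (max(test.p_reported - half, 0.0),
            min(test.p_reported + half, 1.0))


def _claims_significance(test: ReportedTest, alpha: float) -> bool | None:
    """The significance claim the reported p makes, if any."""
    if test.p_style in ("exact3", "exact2"):
        return test.p_reported < alpha
    if test.p_style == "less_than":
        return test.p_threshold <= alpha
    if test.p_style == "greater_than":
        return None if test.p_threshold < alpha else False
    return None


def classify(test: ReportedTest, alpha: float = 0.05,
             one_tailed_rescue: bool = True) -> ConsistencyVerdict:
    """Classify a reported p-value against its recomputation.

    Exact styles are consistent when the reported-p rounding window
    overlaps the recomputed interval; "<x" is consistent when the interval
    reaches below x, ">x" when it reaches above.  A mismatch is gross when
    the claim and the whole recomputed interval sit on opposite sides of
    alpha.  With ``one_tailed_rescue`` (default), a record whose tails are
    unknown and whose halved (one-tailed) recomputation would be
    consistent is counted consistent with the rescue flag set; pass
    ``False`` for strict two-tailed classification.
    """
    if not test.has_p:
        return ConsistencyVerdict("unverifiable")
    try:
        interval = recompute_p_interval(test)
    except Unverifiable:
        return ConsistencyVerdict("unverifiable")

    def _matches(iv: PInterval) -> bool:
        if test.p_style in ("exact3", "exact2"):
            lo, hi = _reported_window(test)
            return iv.overlaps(lo, hi)
        if test.p_style == "less_than":
            return iv.lo < test.p_threshold
        return iv.hi > test.p_threshold  # greater_than

    if _matches(interval):
        return ConsistencyVerdict("consistent", interval)

    if (one_tailed_rescue and test.tails == "unknown"
            and test.family in _SYMMETRIC_FAMILIES
            and _matches(interval.halved())):
        return ConsistencyVerdict("consistent", interval,
                                  one_tailed_rescue=True)

    claim = _claims_significance(test, alpha)
    gross = False
    if claim is True and interval.lo > alpha:
        gross = True
    elif claim is False and interval.hi < alpha:
        gross = True
    status = "gross_inconsistency" if gross else "inconsistency"
    return ConsistencyVerdict(status, interval)


def classify_all(records: Iterable[ThesisRecord], alpha: float = 0.05,
                 one_tailed_rescue: bool = True) -> list[ConsistencyVerdict]:
    return [classify(rec.test, alpha=alpha, one_tailed_rescue=one_tailed_rescue)
            for rec in records]


@dataclass(frozen=True)
class CompletenessReport:
    """Proportions of records with missing key statistics."""

    n_records: int
    missing_p: float
    missing_df: float
    missing_stat: float
    missing_any: float

    def __post_init__(self) -> None:
        for name in ("missing_p", "missing_df", "missing_stat", "missing_any"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.missing_any + 1e-12 < max(self.missing_p, self.missing_df,
                                          self.missing_stat):
            raise ValueError("union below a component proportion")


def completeness(records: Sequence[ThesisRecord]) -> CompletenessReport:
    """Share of records missing p-values, d.f., or test statistics."""
    if not records:
        raise ValueError("completeness of an empty collection is undefined")
    n = len(records)
    miss_p = sum(r.missing_p for r in records)
    miss_df = sum(r.missing_df for r in records)
    miss_stat = sum(r.missing_stat for r in records)
    miss_any = sum(r.missing_p or r.missing_df or r.missing_stat
                   for r in records)
    return CompletenessReport(
        n_records=n,
        missing_p=miss_p / n,
        missing_df=miss_df / n,
        missing_stat=miss_stat / n,
        missing_any=miss_any / n,
    )
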