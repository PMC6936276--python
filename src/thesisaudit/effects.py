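"""Standardize every focal result to Pearson's r and summarize the corpus.

Reported standardized effect sizes are converted from their native metric
(d, eta-squared, R-squared, standardized beta, Cramer's V, odds ratio);
when no effect size was reported, the test statistic itself is converted.
Summaries use effect magnitudes |r|, since sign conventions differ across
designs; signed values are retained on each estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._bootstrap import BootSpec, percentile_ci
from .records import EffectEstimate, ThesisRecord

__all__ = ["EffectSummary", "to_r", "convert_all", "summarize_effects"]

_UNAVAILABLE = EffectEstimate(None, "unavailable")


def _sign(x: float) -> float:
    return -1.0 if x < 0 else 1.0


def _r_from_statistic(rec: ThesisRecord) -> EffectEstimate:
    t = rec.test
    if not t.has_statistic:
        return _UNAVAILABLE
    stat = t.statistic
    fam = t.family
    n = rec.analysis_n
    if fam == "t":
        if t.df1 is None:
            return _UNAVAILABLE
        r = _sign(stat) * math.sqrt(stat * stat / (stat * stat + t.df1))
        return EffectEstimate(r, "converted")
    if fam == "F":
        if t.df1 is None or t.df2 is None or stat < 0:
            return _UNAVAILABLE
        if t.df1 == 1:
            r = math.sqrt(stat / (stat + t.df2))
            return EffectEstimate(r, "converted")
        # multi-d.f. F: effect of the whole term, flagged approximate
        r = math.sqrt(stat * t.df1 / (stat * t.df1 + t.df2))
        return EffectEstimate(min(r, 1.0), "converted", approximate=True)
    if fam == "chi2":
        if n is None or n < 1 or stat < 0:
            return _UNAVAILABLE
        r = math.sqrt(stat / n)
        approx = t.df1 is not None and t.df1 > 1
        return EffectEstimate(min(r, 1.0), "converted", approximate=approx)
    if fam == "r":
        return EffectEstimate(max(-1.0, min(1.0, stat)), "reported")
    if fam == "z":
        if n is None or n < 1:
            return _UNAVAILABLE
        r = stat / math.sqrt(n)
        return EffectEstimate(max(-1.0, min(1.0, r)), "converted",
                              approximate=True)
    return _UNAVAILABLE


def _r_from_reported(rec: ThesisRecord) -> EffectEstimate:
    metric, v = rec.effect_metric, rec.effect_value
    if metric == "r":
        return EffectEstimate(max(-1.0, min(1.0, v)), "reported")
    if metric == "d":
        return EffectEstimate(v / math.sqrt(v * v + 4.0), "reported")
    if metric in ("eta2", "partial_eta2", "R2"):
        vv = min(max(v, 0.0), 1.0)
        # R^2 with multiple predictors overstates a single association;
        # without predictor counts in the schema every R2 is flagged.
        return EffectEstimate(math.sqrt(vv), "reported",
                              approximate=(metric == "R2"))
    if metric == "beta_std":
        return EffectEstimate(max(-1.0, min(1.0, v)), "reported",
                              approximate=True)
    if metric == "V":
        # Cramer's V equals |r| for 2x2 tables; larger tables need the
        # table dimensions, which the schema lacks.
        return EffectEstimate(min(abs(v), 1.0), "reported", approximate=True)
    if metric == "odds_ratio":
        if v <= 0:
            return _UNAVAILABLE
        d = math.log(v) * math.sqrt(3.0) / math.pi
        return EffectEstimate(d / math.sqrt(d * d + 4.0), "reported",
                              approximate=True)
    return _UNAVAILABLE


def to_r(record: ThesisRecord) -> EffectEstimate:
    """Standardize one record's focal effect to Pearson's r.

    A reported standardized effect size takes precedence; otherwise the
    test statistic is converted.  Returns an unavailable estimate when
    neither route applies (e.g. family "other" without a reported effect).
    """
    if record.reports_focal_effect:
        est = _r_from_reported(record)
        if est.available:
            return est
    return _r_from_statistic(record)


def convert_all(records: Sequence[ThesisRecord]) -> list[EffectEstimate]:
    return [to_r(rec) for rec in records]


@dataclass(frozen=True)
class EffectSummary:
    """Corpus-level distribution of standardized effect magnitudes."""

    k: int
    mean_r: float
    mean_ci: tuple[float, float]
    median_r: float
    median_ci: tuple[float, float]
    prop_focal_reported: float
    prop_any_reported: float
    values: tuple[EffectEstimate, ...]

    def __post_init__(self) -> None:
        if not self.mean_ci[0] <= self.mean_r <= self.mean_ci[1]:
            raise ValueError("mean CI does not bracket the mean")
        if not self.median_ci[0] <= self.median_r <= self.median_ci[1]:
            raise ValueError("median CI does not bracket the median")


def summarize_effects(records: Sequence[ThesisRecord],
                      bootstrap: BootSpec | None = None) -> EffectSummary:
    """Mean and median |r| with percentile-bootstrap CIs.

    Also reports the share of records with a reported focal effect size
    and the share reporting standardized effect sizes at all.
    """
    if not records:
        raise ValueError("cannot summarize an empty collection")
    bootstrap = bootstrap or BootSpec()
    estimates = convert_all(records)
    mags = np.array([abs(e.r_value) for e in estimates if e.available])
    if mags.size == 0:
        raise ValueError("no record could be standardized to r")
    mean_ci = percentile_ci(mags, np.mean, bootstrap)
    median_ci = percentile_ci(mags, np.median, bootstrap)
    n = len(records)
    return EffectSummary(
        k=int(mags.size),
        mean_r=float(np.mean(mags)),
        mean_ci=mean_ci,
        median_r=float(np.median(mags)),
        median_ci=median_ci,
        prop_focal_reported=sum(r.reports_focal_effect for r in records) / n,
        prop_any_reported=sum(r.reports_any_effect for r in records) / n,
        values=tuple(estimates),
    )
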