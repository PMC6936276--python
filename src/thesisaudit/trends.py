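"""Bias probes: sample-size vs effect-size correlation and year trends.

A negative sample-size x effect-size correlation is the signature of
*further testing* (optional stopping) in a corpus free of publication
bias: studies of small effects end up with inflated samples because data
collection continued until significance.  Year trends track whether
reporting quality (effect-size reporting, completeness, consistency) and
study characteristics (sample size, effect magnitude, observed power)
changed over the corpus' time span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from ._bootstrap import BootSpec
from .consistency import ConsistencyVerdict
from .records import EffectEstimate, ThesisRecord

__all__ = ["CorrelationReport", "n_vs_effect", "year_trends"]


@dataclass(frozen=True)
class CorrelationReport:
    kind: str  # "spearman" | "pearson"
    estimate: float
    ci_lo: float
    ci_hi: float
    n_pairs: int
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.estimate <= 1.0:
            raise ValueError("estimate outside [-1, 1]")
        if not self.ci_lo <= self.estimate <= self.ci_hi:
            raise ValueError("CI does not bracket the estimate")


def _spearman_bootstrap_ci(x: np.ndarray, y: np.ndarray, spec: BootSpec
                           ) -> tuple[float, float]:
    rng = spec.rng()
    n = x.size
    idx = rng.integers(0, n, size=(spec.n_resamples, n))
    # rank within each resample, then Pearson on ranks
    rx = stats.rankdata(x[idx], axis=1)
    ry = stats.rankdata(y[idx], axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
    ok = denom > 0
    rs = np.full(spec.n_resamples, np.nan)
    rs[ok] = (rx * ry).sum(axis=1)[ok] / denom[ok]
    rs = rs[np.isfinite(rs)]
    q = (1.0 - spec.confidence) / 2.0
    lo, hi = np.quantile(rs, [q, 1.0 - q])
    return float(lo), float(hi)


def n_vs_effect(records: Sequence[ThesisRecord],
                effects: Sequence[EffectEstimate],
                bootstrap: BootSpec | None = None) -> CorrelationReport:
    """Spearman correlation of sample size with effect magnitude |r|."""
    if len(records) != len(effects):
        raise ValueError("records and effects must be paired")
    bootstrap = bootstrap or BootSpec()
    pairs = [(rec.sample_size, abs(est.r_value))
             for rec, est in zip(records, effects) if est.available]
    if len(pairs) < 3:
        raise ValueError("need at least 3 (n, r) pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    res = stats.spearmanr(x, y)
    lo, hi = _spearman_bootstrap_ci(x, y, bootstrap)
    est = float(res.statistic)
    return CorrelationReport(
        kind="spearman", estimate=est,
        ci_lo=min(lo, est), ci_hi=max(hi, est),
        n_pairs=x.size, p_value=float(res.pvalue),
    )


def _pearson_with_fisher_ci(x: np.ndarray, y: np.ndarray,
                            confidence: float = 0.95
                            ) -> CorrelationReport | None:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    r = float(r)
    z = math.atanh(max(-1 + 1e-15, min(1 - 1e-15, r)))
    se = 1.0 / math.sqrt(x.size - 3) if x.size > 3 else float("inf")
    c = special.ndtri(0.5 + confidence / 2.0)
    lo, hi = math.tanh(z - c * se), math.tanh(z + c * se)
    return CorrelationReport(
        kind="pearson", estimate=r, ci_lo=min(lo, r), ci_hi=max(hi, r),
        n_pairs=int(x.size), p_value=float(p),
    )


def year_trends(records: Sequence[ThesisRecord],
                effects: Sequence[EffectEstimate] | None = None,
                verdicts: Sequence[ConsistencyVerdict] | None = None,
                powers: Sequence[float | None] | None = None,
                confidence: float = 0.95
                ) -> dict[str, CorrelationReport | None]:
    """Pearson correlations of year with reporting-quality indicators.

    Indicator series (focal/any effect reported, inconsistency,
    incompleteness) are 0/1, making these point-biserial correlations;
    CIs via the Fisher z transform.  A degenerate (constant) series maps
    to ``None``.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records with a year")
    years = np.array([rec.year for rec in records], dtype=float)

    def _corr(values: Sequence[float | None],
              year_subset: np.ndarray | None = None) -> CorrelationReport | None:
        ys = years if year_subset is None else year_subset
        v = np.array([np.nan if val is None else float(val)
                      for val in values], dtype=float)
        return _pearson_with_fisher_ci(ys, v, confidence)

    out: dict[str, CorrelationReport | None] = {
        "focal_effect_reported": _corr(
            [rec.reports_focal_effect for rec in records]),
        "any_effect_reported": _corr(
            [rec.reports_any_effect for rec in records]),
        "incompleteness": _corr(
            [rec.missing_p or rec.missing_df or rec.missing_stat
             for rec in records]),
        "sample_size": _corr([rec.sample_size for rec in records]),
    }
    if verdicts is not None:
        pairs = [(rec.year, v.inconsistent)
                 for rec, v in zip(records, verdicts)
                 if v.status != "unverifiable"]
        if pairs:
            out["inconsistency"] = _corr(
                [p[1] for p in pairs],
                np.array([p[0] for p in pairs], dtype=float))
        else:
            out["inconsistency"] = None
    if effects is not None:
        out["effect_magnitude"] = _corr(
            [abs(e.r_value) if e.available else None for e in effects])
    if powers is not None:
        out["observed_power"] = _corr(powers)
    return out
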