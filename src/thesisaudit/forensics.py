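"""p-value forensics: the working p set, p-curve, and caliper tests.

The *working* p-values are the best available point values: the p
recomputed from the reported statistic where possible (reporting errors
do not propagate), otherwise the exactly reported p.  Threshold-only and
missing reports carry no point value and are excluded.

The p-curve asks whether the significant results carry evidential value:
under any true effect, significant p-values pile up near zero
(right-skew); under p-hacked nulls they pile up just under the
significance threshold (left-skew).  Each significant p is rescaled to a
pp-value, uniform on [0, 1] under H0 conditional on significance, and the
pp-values are combined with Stouffer's method.  Negative Z means
right-skew, i.e. evidential value.

The caliper test probes directly for a bump of just-significant results:
a one-sided binomial comparison of the counts in [0.045, 0.050) against
the neighbouring bins just below and just above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .consistency import ConsistencyVerdict, Unverifiable, recompute_p
from .records import ThesisRecord

__all__ = [
    "PCurveResult",
    "CaliperResult",
    "WorkingPValues",
    "working_pvalues",
    "p_curve",
    "caliper_test",
]


@dataclass(frozen=True)
class WorkingPValues:
    """Point p-values usable for distribution-level forensics."""

    pvalues: tuple[float, ...]
    record_ids: tuple[str, ...]
    n_excluded: int
    share_significant: float

    @property
    def n(self) -> int:
        return len(self.pvalues)


def working_pvalues(records: Sequence[ThesisRecord],
                    verdicts: Sequence[ConsistencyVerdict] | None = None,
                    alpha: float = 0.05) -> WorkingPValues:
    """Assemble the working p-value set.

    Per record: the p recomputed at the reported statistic when the test
    is recomputable, else the exactly reported p; records reporting only
    a threshold, or nothing, are excluded.  ``verdicts`` is accepted for
    interface symmetry with the audit pipeline but recomputation is done
    from the records themselves (verdict intervals carry rounding windows,
    not point values).
    """
    if verdicts is not None and len(verdicts) != len(records):
        raise ValueError("records and verdicts must be paired")
    ids, ps = [], []
    excluded = 0
    for rec in records:
        t = rec.test
        p = None
        if t.has_statistic:
            try:
                p = recompute_p(
                    t.family, t.statistic, df1=t.df1, df2=t.df2, n=t.n,
                    tails="one" if t.tails == "one" else "two")
            except Unverifiable:
                p = None
        if p is None and t.p_style in ("exact3", "exact2"):
            p = t.p_reported
        if p is None:
            excluded += 1
            continue
        ids.append(rec.record_id)
        ps.append(float(p))
    arr = np.array(ps) if ps else np.empty(0)
    share = float(np.mean(arr < alpha)) if arr.size else float("nan")
    return WorkingPValues(
        pvalues=tuple(ps), record_ids=tuple(ids),
        n_excluded=excluded, share_significant=share,
    )


@dataclass(frozen=True)
class PCurveResult:
    """Right-skew (evidential value) tests on the significant p-values."""

    k_full: int
    k_half: int
    z_full: float
    p_full: float
    z_half: float | None
    p_half: float | None
    binom_p: float | None

    def __post_init__(self) -> None:
        if self.k_half > self.k_full:
            raise ValueError("k_half cannot exceed k_full")
        for name in ("p_full", "p_half", "binom_p"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _stouffer(pp: np.ndarray) -> tuple[float, float]:
    """Stouffer Z over pp-values and its lower-tail probability.

    pp-values are uniform under the null of no evidential value, so
    Z = sum(Phi^-1(pp)) / sqrt(k) is standard normal; right-skewed input
    (small pp) drives Z negative, and the reported p is Phi(Z).
    """
    pp = np.clip(pp, 1e-300, 1.0 - 1e-16)
    z = float(np.sum(special.ndtri(pp)) / np.sqrt(pp.size))
    return z, float(special.ndtr(z))


def p_curve(pvalues: Sequence[float], alpha: float = 0.05) -> PCurveResult:
    """Full-curve and half-curve right-skew tests plus the binomial test.

    Full curve: pp = p/alpha for p < alpha.  Half curve: pp = p/(alpha/2)
    for p < alpha/2.  The binomial test asks whether more than half of the
    significant results fall in the lower half of the significance range.
    """
    ps = np.asarray(pvalues, dtype=float)
    full = ps[ps < alpha]
    if full.size == 0:
        raise ValueError("p-curve needs at least one significant p-value")
    half = ps[ps < alpha / 2.0]
    z_full, p_full = _stouffer(full / alpha)
    if half.size:
        z_half, p_half = _stouffer(half / (alpha / 2.0))
    else:
        z_half = p_half = None
    binom_p = float(stats.binomtest(
        int(half.size), int(full.size), 0.5, alternative="greater").pvalue)
    return PCurveResult(
        k_full=int(full.size), k_half=int(half.size),
        z_full=z_full, p_full=p_full, z_half=z_half, p_half=p_half,
        binom_p=binom_p,
    )


@dataclass(frozen=True)
class CaliperResult:
    """Counts and one-sided binomial tests around the 0.05 threshold."""

    n_target: int   # [0.045, 0.050)
    n_below: int    # [0.040, 0.045)
    n_above: int    # [0.050, 0.055)
    p_vs_below: float | None
    p_vs_above: float | None

    def __post_init__(self) -> None:
        if min(self.n_target, self.n_below, self.n_above) < 0:
            raise ValueError("bin counts must be non-negative")


# Half-open decimal bins at full precision; the conventional display
# "0.045-0.0499" is a 4-decimal rendering of [0.045, 0.050).
CALIPER_BINS = ((0.040, 0.045), (0.045, 0.050), (0.050, 0.055))


def caliper_test(pvalues: Sequence[float]) -> CaliperResult:
    """Binomial caliper comparisons of just-significant p-value counts.

    Tests whether [0.045, 0.050) holds more p-values than the bin just
    below and the bin just above, each via a one-sided exact binomial test
    at success probability one half.  A comparison with both bins empty
    has no defined probability and is reported as absent.
    """
    ps = np.asarray(pvalues, dtype=float)
    (b_lo, b_hi), (t_lo, t_hi), (a_lo, a_hi) = CALIPER_BINS
    n_below = int(np.sum((ps >= b_lo) & (ps < b_hi)))
    n_target = int(np.sum((ps >= t_lo) & (ps < t_hi)))
    n_above = int(np.sum((ps >= a_lo) & (ps < a_hi)))

    def _one_sided(k: int, other: int) -> float | None:
        trials = k + other
        if trials == 0:
            return None
        return float(stats.binomtest(k, trials, 0.5,
                                     alternative="greater").pvalue)

    return CaliperResult(
        n_target=n_target, n_below=n_below, n_above=n_above,
        p_vs_below=_one_sided(n_target, n_below),
        p_vs_above=_one_sided(n_target, n_above),
    )
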