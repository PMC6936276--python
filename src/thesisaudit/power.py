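"""Statistical power of the Pearson correlation test.

Every focal effect in the audit lives on the r scale, so one power
function covers the corpus: the two-sided test of H0: rho = 0 via the
Fisher z transformation, whose sampling distribution is approximately
normal with standard error 1/sqrt(n - 3).  With zeta = atanh(rho) *
sqrt(n - 3) and c the upper alpha/2 normal quantile,

    power = Phi(zeta - c) + Phi(-zeta - c).

At rho = 0 this reduces exactly to alpha.  An exact noncentral-t based
variant is provided as a cross-check oracle, and ``solve_n`` inverts the
power function for sample-size planning.

``observed_power`` evaluates each study at its own sample size and
observed effect (post-hoc power); ``hypothetical_curve`` asks instead
what power the corpus' sample sizes would have across the whole range of
candidate effect sizes, taking the median over studies at each grid
point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from ._bootstrap import BootSpec, percentile_ci
from .records import EffectEstimate, ThesisRecord

__all__ = [
    "PowerCurve",
    "ObservedPower",
    "power_r",
    "power_r_exact",
    "solve_n",
    "observed_power",
    "hypothetical_curve",
]


def power_r(n, rho, alpha: float = 0.05, tails: str = "two"):
    """Power of the correlation test (Fisher-z approximation).

    Vectorized over ``n`` and ``rho``.  ``rho`` values with magnitude 1
    return power 1 (the test always rejects a perfect correlation).
    """
    n = np.asarray(n, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(n < 4):
        raise ValueError("power of the correlation test requires n >= 4")
    if np.any(np.abs(rho) > 1.0):
        raise ValueError("|rho| must not exceed 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    saturated = np.abs(rho) >= 1.0
    zeta = np.arctanh(np.where(saturated, 0.0, rho)) * np.sqrt(n - 3.0)
    if tails == "one":
        c = special.ndtri(1.0 - alpha)
        pw = special.ndtr(np.abs(zeta) - c)
    else:
        c = special.ndtri(1.0 - alpha / 2.0)
        pw = special.ndtr(zeta - c) + special.ndtr(-zeta - c)
    pw = np.where(saturated, 1.0, pw)
    return float(pw) if pw.ndim == 0 else pw


def _sample_r_logpdf(r: float, rho: float, n: int) -> float:
    """Log density of the sample correlation under a bivariate normal."""
    return (math.log(n - 2) + special.gammaln(n - 1)
            - 0.5 * math.log(2 * math.pi) - special.gammaln(n - 0.5)
            + ((n - 1) / 2) * math.log1p(-rho * rho)
            + ((n - 4) / 2) * math.log1p(-r * r)
            - (n - 1.5) * math.log1p(-rho * r)
            + math.log(special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2)))


def power_r_exact(n: int, rho: float, alpha: float = 0.05) -> float:
    """Exact power of the correlation test (cross-check oracle).

    Integrates the exact sampling distribution of the correlation
    coefficient of a bivariate normal over the rejection region
    |r| > r_crit, where r_crit comes from the Student-t critical value
    with df = n - 2.
    """
    from scipy.integrate import quad

    if n < 4:
        raise ValueError("requires n >= 4")
    if abs(rho) >= 1.0:
        return 1.0
    df = n - 2
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    rcrit = tcrit / math.sqrt(df + tcrit * tcrit)
    pdf = lambda r: math.exp(_sample_r_logpdf(r, rho, n))
    upper, _ = quad(pdf, rcrit, 1.0, epsabs=1e-11, epsrel=1e-10, limit=200)
    lower, _ = quad(pdf, -1.0, -rcrit, epsabs=1e-11, epsrel=1e-10, limit=200)
    return float(upper + lower)


def solve_n(rho: float, target_power: float = 0.80, alpha: float = 0.05,
            n_max: int = 10_000_000) -> int:
    """Smallest n whose two-sided power at effect ``rho`` reaches the target."""
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must be non-zero with |rho| < 1")
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    lo, hi = 4, 8
    while power_r(hi, rho, alpha) < target_power:
        hi *= 2
        if hi > n_max:
            raise ValueError("required n exceeds n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_r(mid, rho, alpha) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


@dataclass(frozen=True)
class ObservedPower:
    """Post-hoc power of each study at its own n and observed |r|."""

    powers: tuple[float, ...]
    record_ids: tuple[str, ...]
    median: float
    median_ci: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.median_ci[0] <= self.median <= self.median_ci[1]:
            raise ValueError("median CI does not bracket the median")


def observed_power(records: Sequence[ThesisRecord],
                   effects: Sequence[EffectEstimate],
                   alpha: float = 0.05,
                   bootstrap: BootSpec | None = None) -> ObservedPower:
    """Post-hoc power per record, with a bootstrap CI for the median.

    Pairs each record's study sample size with its standardized effect
    magnitude; records without a usable effect (or n < 4) are skipped.
    """
    if len(records) != len(effects):
        raise ValueError("records and effects must be paired")
    bootstrap = bootstrap or BootSpec()
    ids, powers = [], []
    for rec, est in zip(records, effects):
        if not est.available or rec.sample_size < 4:
            continue
        ids.append(rec.record_id)
        powers.append(power_r(rec.sample_size, abs(est.r_value), alpha))
    if not powers:
        raise ValueError("no record has both a usable n and an effect size")
    arr = np.array(powers)
    ci = percentile_ci(arr, np.median, bootstrap)
    return ObservedPower(
        powers=tuple(powers), record_ids=tuple(ids),
        median=float(np.median(arr)), median_ci=ci,
    )


@dataclass(frozen=True)
class PowerCurve:
    """Median hypothetical power across an effect-size grid.

    ``reference`` holds the rows for conventional effect sizes (r = 0.10,
    0.20, 0.30 by default) for direct reading.
    """

    grid: tuple[float, ...]
    median_power: tuple[float, ...]
    ci_lo: tuple[float, ...]
    ci_hi: tuple[float, ...]
    alpha: float
    reference: dict[float, tuple[float, float, float]]

    def __post_init__(self) -> None:
        med = np.array(self.median_power)
        if np.any(np.diff(med) < -1e-12):
            raise ValueError("median power must be non-decreasing in r")
        if not (np.all(np.array(self.ci_lo) <= med + 1e-12)
                and np.all(med <= np.array(self.ci_hi) + 1e-12)):
            raise ValueError("CIs must bracket the median power")

    def at(self, r: float) -> float:
        """Median power at the grid point closest to ``r``."""
        i = int(np.argmin(np.abs(np.array(self.grid) - r)))
        return self.median_power[i]


REFERENCE_EFFECTS = (0.10, 0.20, 0.30)


def hypothetical_curve(sample_sizes: Sequence[int],
                       grid_step: float = 0.01,
                       alpha: float = 0.05,
                       bootstrap: BootSpec | None = None,
                       reference_effects: Sequence[float] = REFERENCE_EFFECTS,
                       ) -> PowerCurve:
    """Median power the given sample sizes would have at each effect size.

    For each r on the grid [0, 1], evaluates power_r(n, r) for every
    sample size and takes the median across studies; the CI comes from a
    percentile bootstrap over the sample-size collection.
    """
    ns = np.asarray([n for n in sample_sizes if n >= 4], dtype=float)
    if ns.size == 0:
        raise ValueError("need at least one sample size >= 4")
    bootstrap = bootstrap or BootSpec()
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2.0, grid_step), 10)
    grid[-1] = min(grid[-1], 1.0)
    # power matrix: studies x grid
    pw = power_r(ns[:, None], grid[None, :], alpha)
    med = np.median(pw, axis=0)
    if ns.size == 1:
        lo = hi = med.copy()
    else:
        rng = bootstrap.rng()
        idx = rng.integers(0, ns.size, size=(bootstrap.n_resamples, ns.size))
        boots = np.median(pw[idx, :], axis=1)  # resamples x grid
        q = (1.0 - bootstrap.confidence) / 2.0
        lo, hi = np.quantile(boots, [q, 1.0 - q], axis=0)
        lo, hi = np.minimum(lo, med), np.maximum(hi, med)
    reference = {}
    for r_ref in reference_effects:
        i = int(np.argmin(np.abs(grid - r_ref)))
        reference[float(grid[i])] = (float(med[i]), float(lo[i]), float(hi[i]))
    return PowerCurve(
        grid=tuple(float(g) for g in grid),
        median_power=tuple(float(v) for v in med),
        ci_lo=tuple(float(v) for v in lo),
        ci_hi=tuple(float(v) for v in hi),
        alpha=alpha,
        reference=reference,
    )
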