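"""Seeded percentile-bootstrap confidence intervals."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["BootSpec", "percentile_ci"]


@dataclass(frozen=True)
class BootSpec:
    """Resampling specification: number of resamples, level, and seed."""

    n_resamples: int = 10_000
    confidence: float = 0.95
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def percentile_ci(values: np.ndarray, statistic: Callable[..., float],
                  spec: BootSpec,
                  rng: np.random.Generator | None = None
                  ) -> tuple[float, float]:
    """Percentile-bootstrap CI of ``statistic`` over 1-d ``values``.

    ``statistic`` must accept an ``axis`` keyword (numpy reductions do),
    letting all resamples evaluate in one vectorized call.  A degenerate
    sample (size 1, or all values equal) yields a zero-width interval.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-d array")
    if values.size == 1 or np.all(values == values[0]):
        v = float(statistic(values))
        return (v, v)
    rng = rng if rng is not None else spec.rng()
    idx = rng.integers(0, values.size, size=(spec.n_resamples, values.size))
    stats = statistic(values[idx], axis=1)
    alpha = 1.0 - spec.confidence
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    point = float(statistic(values))
    # Guard against quantile grid effects on tiny samples: the percentile
    # interval must bracket the plug-in estimate.
    return (min(float(lo), point), max(float(hi), point))
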