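"""Synthetic thesis-corpus generator with known ground truth.

Each synthetic record is born from a two-component effect mixture: with
probability ``pi0`` the study investigates a true null (rho = 0),
otherwise a true effect drawn from the configured distribution.  The
observed correlation arises on the Fisher-z scale — z_obs ~ Normal(
atanh(rho), 1/sqrt(n-3)) — and is then transformed to the drawn test
family's native statistic and degrees of freedom, so a single rho-scale
ground truth underlies every family.  A reporting layer applies the
reporting style (exact at 2/3 decimals, thresholds, missing), statistic
rounding, per-field missingness, and injectable reporting errors.  Two
questionable-research-practice operators can be switched on:

* *p-hacking*: when the first analysis is non-significant, the study
  re-analyses the same data ``k_attempts`` times (correlated draws via a
  Gaussian copula) and reports the smallest p-value;
* *optional stopping*: observations are added in batches until the test
  is significant or ``n_max`` is reached, simulated on raw bivariate
  data so the dependence between looks is real.

Defaults emulate the audited corpus: 250 records, sample sizes with
median ~157 and IQR ~140 in [21, 3242], a mixture yielding median
observed |r| ~ 0.19 and roughly half significant results, and an 18%
reporting-error rate of which 1 in 8 crosses the significance boundary.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import special

from .consistency import PInterval, Unverifiable, recompute_p, \
    recompute_p_interval
from .records import ReportedTest, ThesisRecord

__all__ = [
    "EffectDist",
    "SampleSizeDist",
    "HackingSpec",
    "StoppingSpec",
    "GeneratorConfig",
    "generate",
    "inject_reporting_error",
    "injected_rates",
    "write_ground_truth",
]

_NORM_Q75 = 0.6744897501960817  # Phi^-1(0.75)


@dataclass(frozen=True)
class EffectDist:
    """Distribution of true |rho| for non-null studies.

    ``folded_normal`` (default): |Normal(mu, sigma)|, clipped below 1.
    ``fixed``: a point mass at ``mu``.  ``uniform``: on [lo, hi].
    """

    family: str = "folded_normal"
    mu: float = 0.28
    sigma: float = 0.15
    lo: float = 0.0
    hi: float = 0.6

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "folded_normal":
            vals = np.abs(rng.normal(self.mu, self.sigma, size=size))
        elif self.family == "fixed":
            vals = np.full(size, abs(self.mu))
        elif self.family == "uniform":
            vals = rng.uniform(self.lo, self.hi, size=size)
        else:
            raise ValueError(f"unknown effect distribution {self.family!r}")
        return np.clip(vals, 0.0, 0.97)

    def population_median(self, rng: np.random.Generator | None = None,
                          n_draws: int = 400_000) -> float:
        """Monte-Carlo median of the non-null |rho| distribution."""
        rng = rng or np.random.default_rng(12345)
        return float(np.median(self.draw(rng, n_draws)))


@dataclass(frozen=True)
class SampleSizeDist:
    """Log-normal sample sizes parameterized by target median and IQR,
    truncated to [n_min, n_max]."""

    median: float = 157.0
    iqr: float = 140.0
    n_min: int = 21
    n_max: int = 3242

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        # q3 - q1 = median * 2*sinh(q75 * sigma)  for lognormal
        return math.asinh(self.iqr / (2.0 * self.median)) / _NORM_Q75

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        vals = rng.lognormal(self.mu, self.sigma, size=size)
        return np.clip(np.rint(vals), self.n_min, self.n_max).astype(int)


@dataclass(frozen=True)
class HackingSpec:
    """Re-analyse the same data up to ``k_attempts`` times when the first
    look is non-significant, reporting the smallest p.  ``dependence`` is
    the Gaussian-copula correlation between attempts (shared data)."""

    enabled: bool = False
    k_attempts: int = 3
    dependence: float = 0.95


@dataclass(frozen=True)
class StoppingSpec:
    """Add observations in batches until p < alpha or ``n_max``."""

    enabled: bool = False
    batch: int = 50
    n_max: int = 1000


_DEFAULT_FAMILY_MIX = {
    "t": 0.25, "F": 0.25, "chi2": 0.10, "r": 0.20, "z": 0.05, "other": 0.15,
}
_DEFAULT_STYLE_MIX = {
    "exact3": 0.45, "exact2": 0.45, "less_than": 0.064,
    "greater_than": 0.02, "missing": 0.016,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic corpus."""

    n_records: int = 250
    seed: int = 0
    pi0: float = 0.30
    effect_dist: EffectDist = field(default_factory=EffectDist)
    n_dist: SampleSizeDist = field(default_factory=SampleSizeDist)
    family_mix: dict = field(
        default_factory=lambda: dict(_DEFAULT_FAMILY_MIX))
    style_mix: dict = field(default_factory=lambda: dict(_DEFAULT_STYLE_MIX))
    error_rate: float = 0.18
    gross_error_rate: float = 0.125  # fraction of corruptions that cross 0.05
    missing_df_rate: float = 0.09
    missing_stat_rate: float = 0.03
    effect_report_rate: float = 0.36
    any_effect_report_rate: float = 0.44
    effect_report_trend: float = 0.0  # additive per-year slope on reporting
    formal_power_rate: float = 1.0 / 250.0
    rule_of_thumb_rate: float = 5.0 / 250.0
    stat_decimals: int = 2
    alpha: float = 0.05
    hacking: HackingSpec = field(default_factory=HackingSpec)
    stopping: StoppingSpec = field(default_factory=StoppingSpec)
    year_range: tuple[int, int] = (2000, 2016)

    def __post_init__(self) -> None:
        for name, mix in (("family_mix", self.family_mix),
                          ("style_mix", self.style_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative probabilities")
        for name in ("pi0", "error_rate", "gross_error_rate",
                     "missing_df_rate", "missing_stat_rate",
                     "effect_report_rate", "any_effect_report_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.any_effect_report_rate < self.effect_report_rate:
            raise ValueError(
                "any_effect_report_rate must be >= effect_report_rate")
        if self.stopping.enabled and self.stopping.n_max < self.n_dist.n_min:
            raise ValueError("stopping n_max below the minimum sample size")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["year_range"] = list(self.year_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key, sub in (("effect_dist", EffectDist),
                         ("n_dist", SampleSizeDist),
                         ("hacking", HackingSpec),
                         ("stopping", StoppingSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "year_range" in d:
            d["year_range"] = tuple(d["year_range"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# family-native statistics


def _statistic_from_r(family: str, r_obs: float, n: int
                      ) -> tuple[float, float | None, float | None]:
    """Map an observed correlation to (statistic, df1, df2) for a family."""
    r_obs = float(np.clip(r_obs, -0.999999, 0.999999))
    df = n - 2
    t = r_obs * math.sqrt(df / (1.0 - r_obs * r_obs))
    if family in ("t", "other"):
        return t, float(df), None
    if family == "F":
        return t * t, 1.0, float(df)
    if family == "chi2":
        return n * r_obs * r_obs, 1.0, None
    if family == "r":
        return r_obs, None, None
    if family == "z":
        return math.atanh(r_obs) * math.sqrt(n - 3.0), None, None
    raise ValueError(f"unknown family {family!r}")


def _true_p(family: str, statistic: float, df1, df2, n: int) -> float:
    fam = "t" if family == "other" else family
    return recompute_p(fam, statistic, df1=df1, df2=df2, n=n, tails="two")


# ---------------------------------------------------------------------------
# reporting layer


def _round_style(p: float, style: str) -> tuple[float | None, float | None]:
    """Truthful rendering of p under a reporting style.

    Returns (p_reported, p_threshold); a threshold style flips to the
    side the true p actually lies on.
    """
    if style == "exact3":
        return round(p, 3), None
    if style == "exact2":
        return round(p, 2), None
    if style == "less_than":
        if p < 0.05:
            return None, 0.05
        return None, 0.05  # rendered as ">0.05" by the caller
    if style == "greater_than":
        return None, 0.05
    return None, None


def inject_reporting_error(p_true: float, style: str,
                           rng: np.random.Generator,
                           error_rate: float = 0.18,
                           gross_error_rate: float = 0.125,
                           window: PInterval | None = None,
                           alpha: float = 0.05,
                           ) -> tuple[float | None, bool, bool]:
    """Report an exact-style p, possibly corrupted.

    With probability ``error_rate`` the displayed value is perturbed away
    from the truthful rounding; conditionally with ``gross_error_rate``
    the perturbation is forced across the alpha boundary (a decision
    error).  ``window`` is the p-interval implied by the reported
    statistic's rounding; a corrupted value is drawn outside it so the
    error is a genuine inconsistency, and a non-gross corruption stays on
    the true side of alpha.  Returns (p_reported, corrupted, crossed).

    Only exact styles can be corrupted; other styles return the truthful
    rendering.
    """
    if style not in ("exact3", "exact2"):
        p_rep, _ = _round_style(p_true, style)
        return p_rep, False, False
    decimals = 3 if style == "exact3" else 2
    truthful = round(p_true, decimals)
    if rng.random() >= error_rate:
        return truthful, False, False
    if window is None:
        window = PInterval(p_true, p_true)
    half = 0.5 * 10.0 ** (-decimals)
    true_side_sig = p_true < alpha
    want_cross = rng.random() < gross_error_rate
    if want_cross and not (window.hi < alpha or window.lo > alpha):
        # the statistic's own rounding straddles alpha: a crossing could
        # never be classified as a decision error, demote to plain error
        want_cross = False
    target_sig = (not true_side_sig) if want_cross else true_side_sig
    lo, hi = (0.0, alpha) if target_sig else (alpha, 1.0)
    for _ in range(50):
        cand = round(float(rng.uniform(lo, hi)), decimals)
        if not (lo <= cand < hi or (not target_sig and cand == 1.0)):
            continue
        if cand == truthful:
            continue
        # must be a detectable mismatch: reported window disjoint from
        # the recomputation window
        if window.overlaps(max(cand - half, 0.0), min(cand + half, 1.0)):
            continue
        return cand, True, want_cross
    return truthful, False, False


# ---------------------------------------------------------------------------
# QRP operators


def _native_p(family: str, r_obs: float, n: int) -> float:
    """Family-native p-value implied by an observed correlation."""
    stat, df1, df2 = _statistic_from_r(family, r_obs, n)
    return _true_p(family, stat, df1, df2, n)


def _draw_observed_r(rng: np.random.Generator, family: str, rho: float,
                     n: int, hacking: HackingSpec, alpha: float
                     ) -> tuple[float, bool]:
    """Observed correlation, optionally p-hacked; returns (r_obs, hacked).

    The observation arises on the Fisher-z scale; the hacking decision is
    taken on the family-native p — the value the analyst actually sees.
    """
    se = 1.0 / math.sqrt(n - 3.0)
    zeta = math.atanh(rho)
    eps0 = rng.standard_normal()
    r_obs = math.tanh(zeta + se * eps0)
    if not hacking.enabled or hacking.k_attempts <= 1:
        return r_obs, False
    p_first = _native_p(family, r_obs, n)
    # first look significant: no incentive to re-analyse
    if p_first < alpha:
        return r_obs, False
    # Re-analyses of the same data: Gaussian copula around the first
    # look's noise.  The analyst stops at the FIRST attempt that crosses
    # alpha (which, being correlated with a non-significant first look,
    # tends to cross only barely — the just-significant bump); if none
    # crosses, the most significant attempt is reported.
    dep = hacking.dependence
    best, best_p = r_obs, p_first
    used_later = False
    for _ in range(hacking.k_attempts - 1):
        eps = dep * eps0 + math.sqrt(1.0 - dep * dep) * rng.standard_normal()
        r_try = math.tanh(zeta + se * eps)
        p_try = _native_p(family, r_try, n)
        if p_try < best_p:
            best, best_p = r_try, p_try
            used_later = True
        if p_try < alpha:
            break
    return best, used_later


def _stop_early(rng: np.random.Generator, rho: float, n0: int,
                stopping: StoppingSpec, alpha: float
                ) -> tuple[float, int, bool]:
    """Optional stopping on raw bivariate data.

    Returns (r_obs, n_final, stopped_late) where ``stopped_late`` marks
    records that added at least one batch.
    """
    n_max = max(n0, stopping.n_max)
    x = rng.standard_normal(n_max)
    y = rho * x + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n_max)
    n = n0
    while True:
        xs, ys = x[:n], y[:n]
        r = float(np.corrcoef(xs, ys)[0, 1])
        p = recompute_p("r", r, n=n)
        if p < alpha or n >= n_max:
            return r, n, n > n0
        n = min(n + stopping.batch, n_max)


# ---------------------------------------------------------------------------
# generation


_EFFECT_METRIC_BY_FAMILY = {
    "t": "d", "F": "partial_eta2", "chi2": "V", "r": "r", "z": "r",
    "other": "beta_std",
}


def _reported_effect(family: str, r_obs: float) -> tuple[str, float]:
    """Family-typical reported effect metric and its (rounded) value.

    All values derive from the observed correlation: d = 2r/sqrt(1-r^2)
    (the two-group t conversion inverted), partial eta^2 = r^2 (single
    d.f. term), Cramer's V = |r| (2x2 table).
    """
    metric = _EFFECT_METRIC_BY_FAMILY[family]
    if metric == "d":
        value = 2.0 * r_obs / math.sqrt(1.0 - r_obs * r_obs)
    elif metric == "partial_eta2":
        value = r_obs * r_obs
    elif metric == "V":
        value = abs(r_obs)
    else:  # r, beta_std
        value = r_obs
    return metric, round(float(value), 2)


def generate(config: GeneratorConfig, seed: int | None = None
             ) -> tuple[list[ThesisRecord], pd.DataFrame]:
    """Generate a corpus and its ground-truth table.

    All randomness flows from one seeded generator (``seed`` overrides
    ``config.seed``), so equal configurations give identical corpora.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fam_names = list(config.family_mix)
    fam_probs = np.array([config.family_mix[f] for f in fam_names])
    style_names = list(config.style_mix)
    style_probs = np.array([config.style_mix[s] for s in style_names])

    n_rec = config.n_records
    years = rng.integers(config.year_range[0], config.year_range[1] + 1,
                         size=n_rec)
    families = rng.choice(fam_names, size=n_rec, p=fam_probs)
    styles = rng.choice(style_names, size=n_rec, p=style_probs)
    nulls = rng.random(n_rec) < config.pi0
    rhos = np.where(nulls, 0.0, config.effect_dist.draw(rng, n_rec))
    ns = config.n_dist.draw(rng, n_rec)
    if config.stopping.enabled:
        ns = np.minimum(ns, config.stopping.n_max)

    records: list[ThesisRecord] = []
    truth_rows: list[dict] = []
    mid_year = (config.year_range[0] + config.year_range[1]) / 2.0

    for i in range(n_rec):
        family = str(families[i])
        style = str(styles[i])
        rho = float(rhos[i])
        n = int(ns[i])

        stopped = False
        hacked = False
        if config.stopping.enabled:
            r_obs, n, stopped = _stop_early(rng, rho, n, config.stopping,
                                            config.alpha)
        else:
            r_obs, hacked = _draw_observed_r(rng, family, rho, n,
                                             config.hacking, config.alpha)

        stat_exact, df1, df2 = _statistic_from_r(family, r_obs, n)
        p_true = _true_p(family, stat_exact, df1, df2, n)
        statistic = round(stat_exact, config.stat_decimals)

        # reporting layer ------------------------------------------------
        miss_stat = rng.random() < config.missing_stat_rate
        miss_df = rng.random() < config.missing_df_rate

        rep_df1, rep_df2, rep_n = df1, df2, n
        if miss_df:
            if family in ("t", "F", "chi2"):
                rep_df1, rep_df2 = None, None
            elif family == "r":
                rep_n = None

        # "recomputable" here means a consistency verdict is possible:
        # statistic and d.f. present, and some p (exact or threshold) to
        # compare against.
        recomputable = (family != "other" and not miss_stat
                        and not (miss_df and family in ("t", "F", "chi2", "r"))
                        and style != "missing")

        corrupted = crossed = False
        p_reported = p_threshold = None
        if style in ("exact3", "exact2"):
            window = None
            if recomputable:
                probe = ReportedTest(
                    family=family, statistic=statistic,
                    stat_decimals=config.stat_decimals,
                    df1=rep_df1, df2=rep_df2, n=rep_n, tails="two",
                    p_style="missing")
                try:
                    window = recompute_p_interval(probe)
                except Unverifiable:
                    window = None
            p_reported, corrupted, crossed = inject_reporting_error(
                p_true, style, rng,
                error_rate=config.error_rate if recomputable else 0.0,
                gross_error_rate=config.gross_error_rate,
                window=window, alpha=config.alpha)
        elif style in ("less_than", "greater_than"):
            style = "less_than" if p_true < config.alpha else "greater_than"
            p_threshold = config.alpha

        # effect-size reporting ------------------------------------------
        report_p = config.effect_report_rate \
            + config.effect_report_trend * (years[i] - mid_year)
        any_extra = config.any_effect_report_rate - config.effect_report_rate
        u = rng.random()
        metric, value = "none", None
        if u < report_p:
            metric, value = _reported_effect(family, r_obs)
        elif u < report_p + any_extra:
            metric = _EFFECT_METRIC_BY_FAMILY[family]

        upc = rng.random()
        if upc < config.formal_power_rate:
            power_consideration = "formal"
        elif upc < config.formal_power_rate + config.rule_of_thumb_rate:
            power_consideration = "rule_of_thumb"
        else:
            power_consideration = "none"

        needs_n = family in ("chi2", "r", "z")
        test = ReportedTest(
            family=family,
            statistic=None if miss_stat else statistic,
            stat_decimals=config.stat_decimals,
            df1=rep_df1, df2=rep_df2,
            n=(rep_n if needs_n else None),
            tails="two",
            p_style=style,
            p_reported=p_reported,
            p_threshold=p_threshold,
        )
        rec = ThesisRecord(
            record_id=f"S{i + 1:04d}",
            year=int(years[i]),
            test=test,
            sample_size=n,
            effect_metric=metric,
            effect_value=value,
            power_consideration=power_consideration,
        )
        records.append(rec)
        truth_rows.append({
            "record_id": rec.record_id,
            "true_rho": rho,
            "true_p": p_true,
            "observed_r": r_obs,
            "n_final": n,
            "null": bool(nulls[i]),
            "hacked": hacked,
            "stopped": stopped,
            "corrupted": corrupted,
            "crossed": crossed,
            "recomputable": recomputable,
            "family": family,
            "style": style,
        })
    return records, pd.DataFrame(truth_rows)


def injected_rates(ground_truth: pd.DataFrame) -> dict[str, float]:
    """Injected inconsistency and gross rates on the recomputable base."""
    recomp = ground_truth["recomputable"]
    n_recomp = int(recomp.sum())
    if n_recomp == 0:
        return {"inconsistency": float("nan"), "gross": float("nan"),
                "n_recomputable": 0}
    return {
        "inconsistency": float(ground_truth.loc[recomp, "corrupted"].mean()),
        "gross": float(ground_truth.loc[recomp, "crossed"].mean()),
        "n_recomputable": n_recomp,
    }


def write_ground_truth(ground_truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    ground_truth.to_csv(path, index=False)
    return path
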