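# Methods

This note documents the statistical procedures, the synthetic-data model,
the default calibration, and the numerical choices behind `thesisaudit`.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Record model

A corpus is a flat table, one row per focal inferential test. The
interchange schema is fixed (16 columns, UTF-8 CSV, `.` decimal
separator, empty string = absent). Two design points deserve note:

* **`stat_decimals`** records the precision at which the statistic was
  printed. It drives all rounding-interval logic; when absent in a file
  it is inferred from the literal cell text. `None` marks an exact
  statistic (degenerate rounding interval).
* **Effect-reporting encoding.** `effect_metric` set with `effect_value`
  absent encodes "the thesis reports standardized effects in general but
  omitted the focal one" — a real coding situation (focal effects are
  often omitted when non-significant). Focal-reported means the value is
  present; any-reported means the metric is present. This keeps both
  indicators in the fixed schema.
* Records of family `other` ("complex analysis") are retained but
  excluded from recomputation and statistic-based conversion; they can
  still contribute a reported effect size and an exact reported p.
* When a test-level `n` is coded it is used for recomputation and
  conversion (`analysis_n`); otherwise the study `sample_size` stands in.
  Power always uses the study `sample_size`.

## 2. Consistency classification

For a recomputable record the implied p-interval is obtained by
evaluating the exact tail probability at the endpoints
statistic ± 0.5·10^(−stat_decimals); all five families are strictly
monotone in |statistic|, so endpoints suffice. The reported p carries its
own rounding window (±0.0005 at three decimals, ±0.005 at two). The
verdict is:

* **consistent** — the two windows overlap (exact styles), or the
  interval reaches below/above the threshold ("<x" / ">x" styles);
* **inconsistency** — no overlap;
* **gross inconsistency** — no overlap *and* the reported claim and the
  whole recomputed interval sit on opposite sides of α (default 0.05):
  the error changes the statistical conclusion;
* **unverifiable** — family `other`, or a missing statistic, d.f., or p.
  Unverifiable records are never counted as inconsistent; rates use the
  recomputable base.

`p = 0` (or 1) at a given precision is read as "below the smallest
representable value", which the clipped rounding window expresses
naturally. When `tails` is unknown and the halved (one-tailed)
recomputation would be consistent, the record is counted consistent with
a `one_tailed_rescue` flag (strict mode disables the rescue); this
mirrors established checker behaviour and avoids inflating error rates.

Dual-interval overlap was chosen over emulating any specific checker
version bit-for-bit: it captures the intended semantics — *could the
reported p result from correct rounding?* — and provably produces zero
false alarms on truthfully rounded reports (a tested invariant).

## 3. Effect standardization

Conversion targets Pearson's r. Routes flagged `approximate` lose
information by construction: multi-d.f. F (whole-term effect), χ² with
df > 1 (table dimensions unknown, √(χ²/n) used), R² (predictor count
unknown), standardized β (taken as r without adjustment), odds ratios
(logit-normal d conversion). Signs are carried from signed statistics;
summaries use magnitudes |r| because sign conventions are not comparable
across designs. Mean and median come with percentile-bootstrap CIs
(default 10,000 resamples, seeded; bit-for-bit reproducible).

## 4. Power

Fisher-z power of the two-sided correlation test:
`power = Φ(ζ − c) + Φ(−ζ − c)`, ζ = atanh(ρ)√(n−3), c = Φ⁻¹(1−α/2).
At ρ = 0 this is exactly α. The choice reproduces the conventional
worked examples for N = 500 (10% at r = 0.03, 97% at r = 0.17).

`power_r_exact` integrates the exact sampling density of the correlation
coefficient (hypergeometric form, log-gamma stabilized) over the
rejection region and serves as the cross-check oracle. The Fisher-z
approximation tracks it within 0.02 absolute for n ≥ 30 across
|ρ| ≤ 0.6, degrading to ≈0.03 at n = 20 with large effects. (A
noncentral-t shortcut with ncp = ρ√n/√(1−ρ²) was evaluated and rejected
as an oracle: it overshoots the exact power by up to 0.07 at that same
corner.)

The hypothetical power curve evaluates, at every r on a [0, 1] grid
(step 0.01), the median over the corpus' sample sizes of power(n, r);
its CI is a percentile bootstrap over the sample-size collection, and
rows for the conventional effect sizes r = 0.10/0.20/0.30 are surfaced
directly. Observed power pairs each study's own n with its |r|. Whether
median-power CIs should bootstrap over studies is genuinely open; we
bootstrap over studies and say so here.

## 5. p-value forensics

The working set takes, per record, the p recomputed at the reported
statistic (reporting errors in p do not propagate), else the exact
reported p; threshold-only and missing reports are excluded.

*p*-curve: pp-values pp = p/α (full curve, p < α) and pp = p/(α/2) (half
curve, p < α/2) are combined with Stouffer's method,
Z = Σ Φ⁻¹(pp)/√k. Under no evidential value pp is uniform and Z is
standard normal; right-skew drives Z negative and the reported
probability is Φ(Z). A binomial test of the share p < α/2 among p < α
against one half completes the set. The published p-curve's "33% power"
flatness test is deliberately not implemented. Inclusion is strict
(p < α); p exactly at the boundary is excluded.

Caliper: half-open decimal bins [0.040, 0.045), [0.045, 0.050),
[0.050, 0.055) at full precision (the conventional display "0.045–0.0499"
is a 4-decimal rendering, not a true edge), compared by one-sided exact
binomial tests at success probability ½. Empty comparisons are reported
as absent, not as p = 1.

## 6. Bias probes

`n_vs_effect`: Spearman correlation of sample size with |r|, CI by
bootstrap over pairs (the rank statistic has no standard closed-form CI).
Year trends are Pearson correlations (point-biserial for 0/1 indicators)
with Fisher-z CIs; constant series yield an absent report rather than a
NaN.

## 7. The synthetic-corpus generator

The generator is the testbed's ground truth, not a fixture. Per record:
null vs non-null by `pi0`; true |ρ| from the effect distribution; n from
the sample-size distribution; observed effect via
z_obs ~ Normal(atanh ρ, 1/√(n−3)), transformed to the drawn family's
native statistic (t = r√((n−2)/(1−r²)); F = t² with df₁ = 1; χ² = n·r²
with df = 1; z = atanh(r)√(n−3); `other` carries a t-like statistic but
is not recomputable). The true p comes from the exact statistic; the
reporting layer then rounds the statistic (2 decimals by default),
renders p in the drawn style, applies per-field missingness, and may
corrupt the reported p.

**Defaults emulate the corpus the audit is designed for** (a 250-thesis
collection): sample sizes log-normal with target median 157 and IQR 140
(σ = asinh(IQR/2·median)/Φ⁻¹(0.75) ≈ 0.641), truncated to [21, 3242];
pi0 = 0.30 with non-null |ρ| ~ folded Normal(0.28, 0.15), which by
mixture arithmetic puts the median observed |r| near 0.19 and the share
of significant results near one half; reporting-error rate 0.18 with 1/8
of corruptions forced across the 0.05 boundary; missing d.f. 9%, missing
statistic 3%, missing p ≈ 1.6% (via the style mix); focal effect
reported 36%, any effect 44%; one formal power analysis and five rules
of thumb per 250 records; years 2000–2016. The family mix (t .25, F .25,
χ² .10, r .20, z .05, other .15) and style mix (exact3 .45, exact2 .45,
thresholds .084, missing .016) are stated assumptions — corpus-level
per-family counts are not published facts.

**Error injection** draws a corrupted displayed value uniformly on the
true side of α (plain errors) or the opposite side (gross errors),
rejection-sampled to lie outside the consistency window implied by the
statistic's rounding — so every injected error is detectable by
construction and the closed loop (injected rate vs audit-detected rate)
is exact up to eligibility. Only exact-style, recomputable records are
eligible; a forced crossing is demoted to a plain error when the
statistic's own rounding interval straddles α (no classification could
call it a decision error). Ground truth records eligibility, so injected
and detected rates share a denominator.

**p-hacking operator.** Re-analyses of the same data are modelled as a
Gaussian copula around the first look's noise (dependence 0.95 by
default; re-analyses of one dataset are highly correlated). The analyst
stops at the *first* attempt that crosses α — being correlated with a
non-significant first look, that attempt tends to cross only barely,
which is precisely what creates the just-significant caliper bump; if no
attempt crosses, the most significant one is reported. A pure
minimum-of-k rule was evaluated and rejected: it spreads hacked p-values
over the whole significance range and produces no caliper-detectable
excess, contradicting the operator's purpose. The hacking decision is
taken on the family-native p (the value the analyst sees), not the
latent Fisher-z p.

**Optional stopping** is simulated on raw bivariate normal data:
observations accumulate in batches until the correlation test is
significant or `n_max` is reached, so the dependence between looks is
real rather than approximated. Its signature — a negative n-vs-effect
Spearman correlation — is a tested detection property.

All randomness flows from one seeded `numpy` Generator; equal configs
give identical corpora, and the audit report is byte-identical across
runs with equal seeds (provenance deliberately carries no wall-clock
timestamp).

### What the generator does *not* emulate

Real coded corpora have features the generator omits: heterogeneous
designs within a family (the generator's F tests are all single-d.f.),
clustered or non-normal data, coder disagreement, HARKing and selective
outcome reporting, correlated missingness, and drift of reporting styles
over years (a linear reporting trend is available but off by default).
Passing tests therefore demonstrate that the audit machinery measures
what was injected — not that any particular real corpus is free of, or
afflicted by, these practices.

## 8. Problem sizes used by the test suite

The closed-loop recovery check pools 40 corpora of 250 records; median
parameter recovery uses 100 replications against a 300,000-draw
Monte-Carlo oracle; type-I control uses 2,500 p-curve replications and
12,000 null records; QRP detection uses 30 corpora of 5,000 records per
hacking intensity (paired seeds) and 6 stopping corpora of 150 records.
Bootstrap resample counts are reduced (200–1,000) in tests; library
defaults stay at 10,000.

## 9. Known limitations

* The one-tailed rescue can mask genuinely wrong two-tailed reports when
  tails are uncoded; strict mode exists for that reason.
* β is taken as r without distributional adjustment; χ² conversions with
  df > 1 are conservative approximations (flagged).
* The Fisher-z power function is an approximation; its error is bounded
  by the exact oracle but grows for n < 20 or |ρ| > 0.6.
* The caliper test has low power at realistic corpus sizes; a null
  caliper result is weak evidence of absence.
* The generator's significance landscape is driven by a single latent
  correlation scale; family-native exact sampling (noncentral t/F/χ²)
  is approximated through that scale.
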