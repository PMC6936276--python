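"""The audit model: a corpus of coded records in, an ``AuditResults`` out.

``ThesisAudit`` is constructed from a record table (CSV, DataFrame, or a
list of :class:`~thesisaudit.records.ThesisRecord`); ``fit()`` runs the
full audit — consistency classification, completeness, effect-size
standardization, observed and hypothetical power, p-value forensics, and
bias probes — and returns an ``AuditResults`` object carrying every
section with its uncertainties, a ``summary()`` table, JSON/CSV export,
and plotting helpers.  Sections whose inputs are degenerate (e.g. no
convertible effect sizes) are recorded as absent with a reason; the run
continues.

The report mirrors the five audit questions: (1) effect-size reporting
and magnitude, (2) power considerations and observed/hypothetical power,
(3) consistency and completeness of reported statistics, (4) p-value
distribution forensics, (5) sample-size vs effect-size bias — plus year
trends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from ._bootstrap import BootSpec
from .consistency import (CompletenessReport, ConsistencyVerdict,
                          classify_all, completeness)
from .effects import EffectSummary, convert_all, summarize_effects
from .forensics import (CaliperResult, PCurveResult, WorkingPValues,
                        caliper_test, p_curve, working_pvalues)
from .power import (ObservedPower, PowerCurve, hypothetical_curve,
                    observed_power)
from .records import ThesisRecord, read_records, write_records
from .trends import CorrelationReport, n_vs_effect, year_trends
from .simulate import GeneratorConfig, generate, injected_rates, \
    write_ground_truth

__all__ = ["ThesisAudit", "AuditResults", "run_audit", "simulate_and_audit"]


@dataclass
class ConsistencySection:
    n_recomputable: int
    n_inconsistent: int
    n_gross: int
    n_unverifiable: int
    n_rescued: int
    inconsistency_rate: float
    gross_rate: float
    completeness: CompletenessReport


@dataclass
class PowerSection:
    n_formal: int
    n_rule_of_thumb: int
    observed: ObservedPower | None
    curve: PowerCurve | None


@dataclass
class ForensicsSection:
    working: WorkingPValues
    histogram: dict[str, int]
    pcurve: PCurveResult | None
    caliper: CaliperResult | None


class ThesisAudit:
    """Audit model over a corpus of coded study records.

    Parameters
    ----------
    records
        The coded corpus, one row per focal test.
    alpha
        Significance level used for the gross-inconsistency decision,
        forensics binning and all power computations.
    """

    def __init__(self, records: Sequence[ThesisRecord], alpha: float = 0.05):
        if not records:
            raise ValueError("cannot audit an empty corpus")
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.records = list(records)
        self.alpha = alpha

    @classmethod
    def from_csv(cls, path: str | Path, alpha: float = 0.05) -> "ThesisAudit":
        return cls(read_records(path), alpha=alpha)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       alpha: float = 0.05) -> "ThesisAudit":
        """Build from a DataFrame with the interchange columns."""
        import io

        buffer = io.StringIO(frame.to_csv(index=False))
        return cls(read_records(buffer), alpha=alpha)

    def fit(self, seed: int = 0, n_bootstrap: int = 10_000,
            grid_step: float = 0.01, one_tailed_rescue: bool = True
            ) -> "AuditResults":
        """Run every audit stage and collect the results."""
        records = self.records
        alpha = self.alpha
        notes: dict[str, str] = {}

        verdicts = classify_all(records, alpha=alpha,
                                one_tailed_rescue=one_tailed_rescue)
        comp = completeness(records)
        statuses = [v.status for v in verdicts]
        n_recomp = sum(s != "unverifiable" for s in statuses)
        n_inc = sum(v.inconsistent for v in verdicts)
        n_gross = statuses.count("gross_inconsistency")
        cons = ConsistencySection(
            n_recomputable=n_recomp,
            n_inconsistent=n_inc,
            n_gross=n_gross,
            n_unverifiable=statuses.count("unverifiable"),
            n_rescued=sum(v.one_tailed_rescue for v in verdicts),
            inconsistency_rate=n_inc / n_recomp if n_recomp else float("nan"),
            gross_rate=n_gross / n_recomp if n_recomp else float("nan"),
            completeness=comp,
        )

        effects = convert_all(records)
        boot = lambda s: BootSpec(n_resamples=n_bootstrap, seed=seed + s)
        try:
            effect_summary = summarize_effects(records, boot(1))
        except ValueError as err:
            effect_summary = None
            notes["effects"] = str(err)

        n_formal = sum(r.power_consideration == "formal" for r in records)
        n_rot = sum(r.power_consideration == "rule_of_thumb" for r in records)
        try:
            obs_power = observed_power(records, effects, alpha=alpha,
                                       bootstrap=boot(2))
        except ValueError as err:
            obs_power = None
            notes["observed_power"] = str(err)
        try:
            curve = hypothetical_curve(
                [r.sample_size for r in records], grid_step=grid_step,
                alpha=alpha, bootstrap=boot(3))
        except ValueError as err:
            curve = None
            notes["hypothetical_curve"] = str(err)
        power_section = PowerSection(n_formal=n_formal, n_rule_of_thumb=n_rot,
                                     observed=obs_power, curve=curve)

        working = working_pvalues(records, verdicts, alpha=alpha)
        edges = np.round(np.arange(0.0, 1.0 + 0.01, 0.01), 10)
        counts, _ = np.histogram(np.asarray(working.pvalues), bins=edges)
        histogram = {f"{edges[i]:.2f}": int(counts[i])
                     for i in range(len(counts))}
        try:
            pcurve = p_curve(working.pvalues, alpha=alpha)
        except ValueError as err:
            pcurve = None
            notes["p_curve"] = str(err)
        caliper = caliper_test(working.pvalues) if working.n else None
        if caliper is None:
            notes["caliper"] = "no working p-values"
        forensics = ForensicsSection(working=working, histogram=histogram,
                                     pcurve=pcurve, caliper=caliper)

        try:
            nve = n_vs_effect(records, effects, bootstrap=boot(4))
        except ValueError as err:
            nve = None
            notes["n_vs_effect"] = str(err)

        power_by_record: list[float | None] = [None] * len(records)
        if obs_power is not None:
            by_id = dict(zip(obs_power.record_ids, obs_power.powers))
            power_by_record = [by_id.get(r.record_id) for r in records]
        try:
            trends = year_trends(records, effects=effects, verdicts=verdicts,
                                 powers=power_by_record)
        except ValueError as err:
            trends = {}
            notes["year_trends"] = str(err)

        return AuditResults(
            records=records, alpha=alpha, verdicts=verdicts, effects=effects,
            effect_summary=effect_summary, consistency=cons,
            power=power_section, forensics=forensics, n_vs_effect=nve,
            trends=trends, notes=notes,
            provenance={
                "seed": seed,
                "n_bootstrap": n_bootstrap,
                "alpha": alpha,
                "package_version": _version,
            },
        )


@dataclass
class AuditResults:
    """Everything the audit measured, with export and display helpers."""

    records: list[ThesisRecord]
    alpha: float
    verdicts: list[ConsistencyVerdict]
    effects: list
    effect_summary: EffectSummary | None
    consistency: ConsistencySection
    power: PowerSection
    forensics: ForensicsSection
    n_vs_effect: CorrelationReport | None
    trends: dict[str, CorrelationReport | None]
    notes: dict[str, str]
    provenance: dict

    # -- display ------------------------------------------------------------

    def summary(self) -> str:
        """Human-readable report mirroring the five audit questions."""
        lines: list[str] = []
        add = lines.append
        n = len(self.records)
        add("Statistical reporting audit")
        add("=" * 64)
        add(f"Corpus: {n} records; alpha = {self.alpha:g}")
        add("")
        add("[1] Effect sizes (standardized to Pearson's r)")
        es = self.effect_summary
        if es is None:
            add(f"    unavailable: {self.notes.get('effects', '')}")
        else:
            add(f"    focal effect reported:   {es.prop_focal_reported:6.1%}")
            add(f"    any effect reported:     {es.prop_any_reported:6.1%}")
            add(f"    standardized (k):        {es.k} of {n}"
                f" ({es.k / n:.0%})")
            add(f"    mean |r|   = {es.mean_r:.2f}"
                f"  95% CI [{es.mean_ci[0]:.2f}, {es.mean_ci[1]:.2f}]")
            add(f"    median |r| = {es.median_r:.2f}"
                f"  95% CI [{es.median_ci[0]:.2f}, {es.median_ci[1]:.2f}]")
        add("")
        add("[2] Statistical power")
        pw = self.power
        add(f"    formal power analyses:   {pw.n_formal}")
        add(f"    rule-of-thumb only:      {pw.n_rule_of_thumb}")
        if pw.observed is not None:
            o = pw.observed
            add(f"    median observed power = {o.median:.2f}"
                f"  95% CI [{o.median_ci[0]:.2f}, {o.median_ci[1]:.2f}]"
                f"  (k = {len(o.powers)})")
        if pw.curve is not None:
            for r_ref, (med, lo, hi) in sorted(pw.curve.reference.items()):
                add(f"    hypothetical power at r = {r_ref:.2f}: {med:.2f}"
                    f"  95% CI [{lo:.2f}, {hi:.2f}]")
        add("")
        add("[3] Consistency of reported p-values")
        c = self.consistency
        add(f"    recomputable:            {c.n_recomputable} of {n}")
        add(f"    inconsistent:            {c.n_inconsistent}"
            f" ({c.inconsistency_rate:.0%})")
        add(f"    gross (decision errors): {c.n_gross} ({c.gross_rate:.0%})")
        comp = c.completeness
        add(f"    missing p/d.f./stat:     {comp.missing_any:.0%}"
            f" (p {comp.missing_p:.0%}, d.f. {comp.missing_df:.0%},"
            f" stat {comp.missing_stat:.0%})")
        add("")
        add("[4] p-value forensics")
        f = self.forensics
        add(f"    working p-values:        {f.working.n}"
            f" ({f.working.n_excluded} excluded)")
        add(f"    share significant:       {f.working.share_significant:.0%}")
        if f.pcurve is not None:
            p = f.pcurve
            p_half = "n/a" if p.p_half is None else f"{p.p_half:.3g}"
            add(f"    p-curve: k = {p.k_full}, z_full = {p.z_full:.2f},"
                f" p_full = {p.p_full:.3g}, p_half = {p_half}")
        if f.caliper is not None:
            cal = f.caliper
            pvb = "n/a" if cal.p_vs_below is None else f"{cal.p_vs_below:.3f}"
            pva = "n/a" if cal.p_vs_above is None else f"{cal.p_vs_above:.3f}"
            add(f"    caliper bins (below/target/above): {cal.n_below}/"
                f"{cal.n_target}/{cal.n_above};"
                f" p_vs_below = {pvb}, p_vs_above = {pva}")
        add("")
        add("[5] Sample size vs effect size")
        if self.n_vs_effect is None:
            add(f"    unavailable: {self.notes.get('n_vs_effect', '')}")
        else:
            nv = self.n_vs_effect
            add(f"    Spearman r_s = {nv.estimate:.2f}"
                f"  95% CI [{nv.ci_lo:.2f}, {nv.ci_hi:.2f}]"
                f"  (n = {nv.n_pairs}, p = {nv.p_value:.3f})")
        if self.trends:
            add("")
            add("Year trends (Pearson r with year)")
            for name, rep in self.trends.items():
                if rep is None:
                    add(f"    {name:<24} constant series, no correlation")
                else:
                    add(f"    {name:<24} r = {rep.estimate:+.2f}"
                        f"  95% CI [{rep.ci_lo:.2f}, {rep.ci_hi:.2f}]")
        return "\n".join(lines)

    # -- export -------------------------------------------------------------

    def to_dict(self) -> dict:
        def corr(rep: CorrelationReport | None):
            if rep is None:
                return None
            return {"kind": rep.kind, "estimate": rep.estimate,
                    "ci": [rep.ci_lo, rep.ci_hi], "n_pairs": rep.n_pairs,
                    "p_value": rep.p_value}

        es = self.effect_summary
        pw = self.power
        c = self.consistency
        f = self.forensics
        d = {
            "corpus": {
                "n_records": len(self.records),
                "n_recomputable": c.n_recomputable,
                "n_convertible": es.k if es else 0,
                "n_working_pvalues": f.working.n,
            },
            "effects": None if es is None else {
                "k": es.k,
                "mean_r": es.mean_r, "mean_ci": list(es.mean_ci),
                "median_r": es.median_r, "median_ci": list(es.median_ci),
                "prop_focal_reported": es.prop_focal_reported,
                "prop_any_reported": es.prop_any_reported,
            },
            "power": {
                "n_formal": pw.n_formal,
                "n_rule_of_thumb": pw.n_rule_of_thumb,
                "observed_median": None if pw.observed is None
                else pw.observed.median,
                "observed_ci": None if pw.observed is None
                else list(pw.observed.median_ci),
                "reference_curve": None if pw.curve is None else {
                    f"{r:.2f}": {"median": med, "ci": [lo, hi]}
                    for r, (med, lo, hi) in sorted(pw.curve.reference.items())
                },
            },
            "consistency": {
                "n_recomputable": c.n_recomputable,
                "n_inconsistent": c.n_inconsistent,
                "n_gross": c.n_gross,
                "n_unverifiable": c.n_unverifiable,
                "n_rescued": c.n_rescued,
                "inconsistency_rate": c.inconsistency_rate,
                "gross_rate": c.gross_rate,
                "completeness": {
                    "missing_p": c.completeness.missing_p,
                    "missing_df": c.completeness.missing_df,
                    "missing_stat": c.completeness.missing_stat,
                    "missing_any": c.completeness.missing_any,
                },
            },
            "forensics": {
                "n_working": f.working.n,
                "n_excluded": f.working.n_excluded,
                "share_significant": f.working.share_significant,
                "histogram": f.histogram,
                "p_curve": None if f.pcurve is None else {
                    "k_full": f.pcurve.k_full, "k_half": f.pcurve.k_half,
                    "z_full": f.pcurve.z_full, "p_full": f.pcurve.p_full,
                    "z_half": f.pcurve.z_half, "p_half": f.pcurve.p_half,
                    "binom_p": f.pcurve.binom_p,
                },
                "caliper": None if f.caliper is None else {
                    "n_target": f.caliper.n_target,
                    "n_below": f.caliper.n_below,
                    "n_above": f.caliper.n_above,
                    "p_vs_below": f.caliper.p_vs_below,
                    "p_vs_above": f.caliper.p_vs_above,
                },
            },
            "bias": {"n_vs_effect": corr(self.n_vs_effect)},
            "trends": {k: corr(v) for k, v in self.trends.items()},
            "notes": self.notes,
            "provenance": self.provenance,
        }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def export_tables(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the per-module CSV artifacts and the JSON report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        verdict_rows = []
        for rec, v in zip(self.records, self.verdicts):
            verdict_rows.append({
                "record_id": rec.record_id, "status": v.status,
                "p_lo": None if v.p_recomputed is None else v.p_recomputed.lo,
                "p_hi": None if v.p_recomputed is None else v.p_recomputed.hi,
                "one_tailed_rescue": v.one_tailed_rescue,
            })
        paths["verdicts"] = out / "verdicts.csv"
        pd.DataFrame(verdict_rows).to_csv(paths["verdicts"], index=False)

        effect_rows = [{
            "record_id": rec.record_id,
            "r_value": e.r_value, "source": e.source,
            "approximate": e.approximate,
        } for rec, e in zip(self.records, self.effects)]
        paths["effects"] = out / "effects.csv"
        pd.DataFrame(effect_rows).to_csv(paths["effects"], index=False)

        if self.power.observed is not None:
            o = self.power.observed
            paths["observed_power"] = out / "observed_power.csv"
            pd.DataFrame({"record_id": o.record_ids, "power": o.powers}
                         ).to_csv(paths["observed_power"], index=False)
        if self.power.curve is not None:
            cv = self.power.curve
            paths["power_curve"] = out / "power_curve.csv"
            pd.DataFrame({"r": cv.grid, "median_power": cv.median_power,
                          "ci_lo": cv.ci_lo, "ci_hi": cv.ci_hi}
                         ).to_csv(paths["power_curve"], index=False)

        if self.trends:
            rows = []
            for name, rep in self.trends.items():
                if rep is None:
                    continue
                rows.append({"indicator": name, "estimate": rep.estimate,
                             "ci_lo": rep.ci_lo, "ci_hi": rep.ci_hi,
                             "n_pairs": rep.n_pairs})
            paths["trends"] = out / "trends.csv"
            pd.DataFrame(rows).to_csv(paths["trends"], index=False)

        # record-level warnings go to a sidecar, not stdout
        warn_rows = []
        for rec, v, e in zip(self.records, self.verdicts, self.effects):
            if v.status == "unverifiable":
                warn_rows.append({"record_id": rec.record_id,
                                  "warning": "unverifiable p-value"})
            if not e.available:
                warn_rows.append({"record_id": rec.record_id,
                                  "warning": "unconvertible effect size"})
        paths["warnings"] = out / "warnings.csv"
        pd.DataFrame(warn_rows, columns=["record_id", "warning"]).to_csv(
            paths["warnings"], index=False)

        paths["report"] = out / "report.json"
        self.to_json(paths["report"])
        return paths

    # -- plotting -----------------------------------------------------------

    def plot_p_distribution(self, ax=None):
        """Histogram of working p-values at 0.01-wide bins."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.forensics.working.pvalues,
                bins=np.arange(0.0, 1.01, 0.01), color="#4878a8",
                edgecolor="white")
        ax.axvline(self.alpha, color="crimson", linestyle="--", linewidth=1)
        ax.set_xlabel("p-value")
        ax.set_ylabel("count")
        return ax

    def plot_power_curve(self, ax=None):
        """Median hypothetical power with its CI band."""
        import matplotlib.pyplot as plt

        if self.power.curve is None:
            raise ValueError("no hypothetical power curve available")
        if ax is None:
            _, ax = plt.subplots()
        cv = self.power.curve
        ax.fill_between(cv.grid, cv.ci_lo, cv.ci_hi, alpha=0.25,
                        color="#4878a8")
        ax.plot(cv.grid, cv.median_power, color="#4878a8")
        ax.axhline(0.80, color="grey", linestyle=":", linewidth=1)
        ax.set_xlabel("effect size r")
        ax.set_ylabel("median power")
        ax.set_ylim(0, 1.02)
        return ax


def run_audit(records_path: str | Path, out_dir: str | Path | None = None,
              alpha: float = 0.05, seed: int = 0,
              n_bootstrap: int = 10_000) -> AuditResults:
    """Read a record table, run the full audit, optionally export artifacts."""
    results = ThesisAudit.from_csv(records_path, alpha=alpha).fit(
        seed=seed, n_bootstrap=n_bootstrap)
    if out_dir is not None:
        results.export_tables(out_dir)
    return results


def simulate_and_audit(config: GeneratorConfig | str | Path,
                       out_dir: str | Path | None = None,
                       seed: int | None = None,
                       n_bootstrap: int = 10_000
                       ) -> tuple[AuditResults, pd.DataFrame, pd.DataFrame]:
    """Generate a corpus, audit it, and join estimates with ground truth.

    Returns (results, ground_truth, recovery) where ``recovery`` is a
    one-row table comparing audit estimates with the generator's injected
    quantities.
    """
    if not isinstance(config, GeneratorConfig):
        config = GeneratorConfig.from_yaml(config)
    records, truth = generate(config, seed=seed)
    audit_seed = config.seed if seed is None else seed
    results = ThesisAudit(records, alpha=config.alpha).fit(
        seed=audit_seed, n_bootstrap=n_bootstrap)
    inj = injected_rates(truth)
    es = results.effect_summary
    recovery = pd.DataFrame([{
        "injected_inconsistency": inj["inconsistency"],
        "detected_inconsistency": results.consistency.inconsistency_rate,
        "injected_gross": inj["gross"],
        "detected_gross": results.consistency.gross_rate,
        "true_median_observed_r": float(np.median(np.abs(
            truth["observed_r"]))),
        "estimated_median_r": None if es is None else es.median_r,
        "share_hacked": float(truth["hacked"].mean()),
        "share_stopped": float(truth["stopped"].mean()),
        "caliper_p_vs_below": None if results.forensics.caliper is None
        else results.forensics.caliper.p_vs_below,
    }])
    results.provenance["config_digest"] = config.digest()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records(records, out / "corpus.csv")
        write_ground_truth(truth, out / "ground_truth.csv")
        recovery.to_csv(out / "recovery.csv", index=False)
        results.export_tables(out)
    return results, truth, recovery
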