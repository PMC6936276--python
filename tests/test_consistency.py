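"""p-value recomputation, consistency classification, completeness."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from thesisaudit import (GeneratorConfig, ReportedTest, classify,
                         classify_all, completeness, generate, recompute_p,
                         recompute_p_interval)
from thesisaudit.consistency import Unverifiable
from conftest import make_record


class TestRecomputeP:
    def test_standard_normal_quantile(self):
        assert recompute_p("z", 1.96) == pytest.approx(0.05, abs=5e-4)
        assert round(recompute_p("z", 1.959964), 4) == 0.05

    def test_f_equals_squared_t(self):
        for df in (5, 30, 200):
            for t in (0.5, 1.7, 3.2):
                assert recompute_p("F", t * t, df1=1, df2=df) == pytest.approx(
                    recompute_p("t", t, df1=df), rel=1e-12)

    def test_chi2_critical_value(self):
        assert recompute_p("chi2", 3.841, df1=1) == pytest.approx(
            0.0500, abs=1e-4)

    def test_r_family_via_t_transform(self):
        # r = 0.3, n = 30 maps to t = r*sqrt(28/(1-r^2)) on 28 d.f.
        t = 0.3 * np.sqrt(28 / (1 - 0.09))
        assert recompute_p("r", 0.3, n=30) == pytest.approx(
            recompute_p("t", t, df1=28), rel=1e-12)

    def test_one_tailed_halves_symmetric_families(self):
        for fam, kw in (("t", {"df1": 20.0}), ("z", {}), ("r", {"n": 25})):
            two = recompute_p(fam, 1.3, tails="two", **kw)
            one = recompute_p(fam, 1.3, tails="one", **kw)
            assert one == pytest.approx(two / 2, rel=1e-12)

    def test_strictly_decreasing_in_statistic(self):
        grid = np.linspace(0.1, 5.0, 40)
        for fam, kw in (("t", {"df1": 12.0}), ("F", {"df1": 3.0, "df2": 40.0}),
                        ("chi2", {"df1": 2.0}), ("z", {})):
            ps = [recompute_p(fam, float(s), **kw) for s in grid]
            assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_unverifiable_signals(self):
        with pytest.raises(Unverifiable):
            recompute_p("other", 1.0)
        with pytest.raises(Unverifiable):
            recompute_p("t", 1.0)  # missing df
        with pytest.raises(Unverifiable):
            recompute_p("r", 0.5, n=3)


class TestRecomputeInterval:
    def test_endpoints_of_rounding_window(self):
        test = ReportedTest(family="t", statistic=2.20, stat_decimals=2,
                            df1=28.0, p_style="missing")
        iv = recompute_p_interval(test)
        assert iv.lo == pytest.approx(recompute_p("t", 2.205, df1=28))
        assert iv.hi == pytest.approx(recompute_p("t", 2.195, df1=28))

    def test_exact_statistic_gives_degenerate_interval(self):
        test = ReportedTest(family="t", statistic=2.2, stat_decimals=None,
                            df1=28.0, p_style="missing")
        iv = recompute_p_interval(test)
        assert iv.lo == iv.hi == recompute_p("t", 2.2, df1=28)

    def test_interval_contains_known_p(self):
        test = ReportedTest(family="t", statistic=1.00, stat_decimals=2,
                            df1=28.0, p_style="missing")
        iv = recompute_p_interval(test)
        assert iv.lo < 0.326 < iv.hi


class TestClassify:
    def test_correct_rounding_is_consistent(self):
        # t(28) = 2.20 -> p ~ 0.0363, reported as 0.04 at 2 decimals
        v = classify(make_record(statistic=2.20, df1=28.0,
                                 p_reported=0.04).test)
        assert v.status == "consistent" and not v.one_tailed_rescue

    def test_decision_changing_error_is_gross(self):
        # t(28) = 1.00 -> p ~ 0.326 but claimed significant
        v = classify(make_record(statistic=1.00, df1=28.0,
                                 p_reported=0.03).test)
        assert v.status == "gross_inconsistency"

    def test_non_decision_error_is_general_inconsistency(self):
        # t(28) = 1.00 -> p ~ 0.326 reported as 0.20: wrong but same side
        v = classify(make_record(statistic=1.00, df1=28.0,
                                 p_reported=0.20).test)
        assert v.status == "inconsistency"

    def test_missing_p_is_unverifiable(self):
        v = classify(make_record(p_style="missing", p_reported=None).test)
        assert v.status == "unverifiable" and v.p_recomputed is None

    def test_threshold_styles(self):
        ok = classify(make_record(statistic=2.20, df1=28.0,
                                  p_style="less_than", p_reported=None,
                                  p_threshold=0.05).test)
        assert ok.status == "consistent"
        bad = classify(make_record(statistic=1.00, df1=28.0,
                                   p_style="less_than", p_reported=None,
                                   p_threshold=0.05).test)
        assert bad.status == "gross_inconsistency"
        ns = classify(make_record(statistic=1.00, df1=28.0,
                                  p_style="greater_than", p_reported=None,
                                  p_threshold=0.05).test)
        assert ns.status == "consistent"

    def test_one_tailed_rescue_when_tails_unknown(self):
        # t(28) = 1.80: two-tailed p ~ 0.0826, one-tailed ~ 0.0413
        rec = make_record(statistic=1.80, df1=28.0, tails="unknown",
                          p_reported=0.04)
        v = classify(rec.test)
        assert v.status == "consistent" and v.one_tailed_rescue
        strict = classify(rec.test, one_tailed_rescue=False)
        assert strict.inconsistent

    def test_no_rescue_when_tails_declared_two(self):
        rec = make_record(statistic=1.80, df1=28.0, tails="two",
                          p_reported=0.04)
        assert classify(rec.test).inconsistent

    def test_p_zero_read_as_below_resolution(self):
        rec = make_record(statistic=9.00, df1=100.0, p_style="exact3",
                          p_reported=0.0)
        assert classify(rec.test).status == "consistent"

    def test_gross_implies_inconsistent_and_partition(self, default_corpus):
        records, _ = default_corpus
        verdicts = classify_all(records)
        statuses = {v.status for v in verdicts}
        assert statuses <= {"consistent", "inconsistency",
                            "gross_inconsistency", "unverifiable"}
        for v in verdicts:
            if v.status == "gross_inconsistency":
                assert v.inconsistent

    def test_no_false_alarms_under_truthful_reporting(self):
        """Correctly rounded reports never classify as inconsistent."""
        config = GeneratorConfig(seed=11, n_records=800, error_rate=0.0)
        records, _ = generate(config)
        for rec, v in zip(records, classify_all(records)):
            assert not v.inconsistent, rec


class TestCompleteness:
    def test_all_present_gives_zero(self):
        recs = [make_record(record_id=f"R{i}") for i in range(10)]
        rep = completeness(recs)
        assert rep.missing_p == rep.missing_df == rep.missing_any == 0.0

    def test_single_missing_df(self):
        recs = [make_record(record_id=f"R{i}") for i in range(9)]
        recs.append(make_record(record_id="R9", df1=None))
        rep = completeness(recs)
        assert rep.missing_df == pytest.approx(0.10)
        assert rep.missing_any == pytest.approx(0.10)
        assert rep.missing_p == 0.0

    def test_independent_missingness_matches_closed_form(self):
        """5% independent missingness per field: union ~ 1 - 0.95^3."""
        rng = np.random.default_rng(5)
        recs = []
        for i in range(6000):
            mp, md, ms = rng.random(3) < 0.05
            recs.append(make_record(
                record_id=f"R{i}",
                statistic=None if ms else 2.0,
                df1=None if md else 30.0,
                p_style="missing" if mp else "exact2",
                p_reported=None if mp else 0.06))
        rep = completeness(recs)
        assert rep.missing_any == pytest.approx(1 - 0.95 ** 3, abs=0.012)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            completeness([])
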