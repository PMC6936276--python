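"""Synthetic-corpus generator: determinism, calibration, QRP operators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thesisaudit import (GeneratorConfig, HackingSpec, PInterval,
                         StoppingSpec, classify_all, generate,
                         inject_reporting_error, injected_rates)
from thesisaudit.simulate import EffectDist, SampleSizeDist


class TestDeterminism:
    def test_same_seed_same_corpus(self):
        cfg = GeneratorConfig(seed=13, n_records=120)
        recs_a, truth_a = generate(cfg)
        recs_b, truth_b = generate(cfg)
        assert recs_a == recs_b
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_different_seed_different_corpus(self):
        recs_a, _ = generate(GeneratorConfig(seed=1, n_records=50))
        recs_b, _ = generate(GeneratorConfig(seed=2, n_records=50))
        assert recs_a != recs_b

    def test_seed_argument_overrides_config(self):
        cfg = GeneratorConfig(seed=1, n_records=40)
        recs_a, _ = generate(cfg, seed=99)
        recs_b, _ = generate(GeneratorConfig(seed=99, n_records=40))
        assert recs_a == recs_b


class TestCalibration:
    def test_sample_size_distribution_targets(self):
        """Defaults reproduce the corpus' median ~157 and IQR ~140."""
        rng = np.random.default_rng(0)
        draws = SampleSizeDist().draw(rng, 40_000)
        assert np.median(draws) == pytest.approx(157, abs=6)
        q1, q3 = np.percentile(draws, [25, 75])
        assert q3 - q1 == pytest.approx(140, abs=12)
        assert draws.min() >= 21 and draws.max() <= 3242

    def test_null_only_corpus_shows_uniform_true_p(self):
        """Under pi0 = 1 the true p-values are uniform (goodness of fit)."""
        cfg = GeneratorConfig(seed=5, n_records=4000, pi0=1.0,
                              error_rate=0.0)
        _, truth = generate(cfg)
        res = stats.kstest(truth["true_p"], "uniform")
        assert res.pvalue > 0.01

    def test_null_only_share_significant_near_alpha(self):
        cfg = GeneratorConfig(seed=6, n_records=6000, pi0=1.0, error_rate=0.0)
        _, truth = generate(cfg)
        assert (truth["true_p"] < 0.05).mean() == pytest.approx(0.05,
                                                                abs=0.012)

    def test_observed_effect_median_near_configured_mixture(self):
        _, truth = generate(GeneratorConfig(seed=8, n_records=4000))
        med = np.median(np.abs(truth["observed_r"]))
        assert med == pytest.approx(0.19, abs=0.03)


class TestReportingLayer:
    def test_truthful_rounding_when_error_rate_zero(self):
        rng = np.random.default_rng(0)
        p, corrupted, crossed = inject_reporting_error(
            0.0377, "exact2", rng, error_rate=0.0)
        assert (p, corrupted, crossed) == (0.04, False, False)
        p, _, _ = inject_reporting_error(0.0377, "exact3", rng,
                                         error_rate=0.0)
        assert p == 0.038

    def test_forced_boundary_crossing(self):
        rng = np.random.default_rng(1)
        window = PInterval(0.29, 0.31)
        p, corrupted, crossed = inject_reporting_error(
            0.30, "exact3", rng, error_rate=1.0, gross_error_rate=1.0,
            window=window)
        assert corrupted and crossed and p < 0.05

    def test_non_gross_corruption_stays_on_true_side(self):
        rng = np.random.default_rng(2)
        window = PInterval(0.0095, 0.0105)
        for _ in range(50):
            p, corrupted, crossed = inject_reporting_error(
                0.01, "exact3", rng, error_rate=1.0, gross_error_rate=0.0,
                window=window)
            assert corrupted and not crossed
            assert p < 0.05
            assert not (0.009 <= p <= 0.011)  # detectably wrong

    def test_threshold_styles_never_corrupted(self):
        rng = np.random.default_rng(3)
        p, corrupted, _ = inject_reporting_error(0.3, "greater_than", rng,
                                                 error_rate=1.0)
        assert p is None and not corrupted

    def test_corruption_flags_match_audit_verdicts(self):
        """Every injected error is detected; no false alarms (closed loop)."""
        records, truth = generate(GeneratorConfig(seed=17, n_records=500))
        verdicts = classify_all(records)
        for v, (_, row) in zip(verdicts, truth.iterrows()):
            if not row["recomputable"]:
                continue
            assert v.inconsistent == row["corrupted"]
            assert (v.status == "gross_inconsistency") == row["crossed"]


class TestQRPOperators:
    def test_hacked_flag_only_when_enabled(self):
        _, truth = generate(GeneratorConfig(seed=3, n_records=200))
        assert not truth["hacked"].any()
        cfg = GeneratorConfig(seed=3, n_records=400, pi0=0.9,
                              hacking=HackingSpec(enabled=True, k_attempts=8))
        _, truth = generate(cfg)
        assert truth["hacked"].mean() > 0.05

    def test_hacking_inflates_significance(self):
        base_cfg = GeneratorConfig(seed=4, n_records=2000, pi0=1.0)
        _, base = generate(base_cfg)
        hack_cfg = GeneratorConfig(
            seed=4, n_records=2000, pi0=1.0,
            hacking=HackingSpec(enabled=True, k_attempts=10))
        _, hacked = generate(hack_cfg)
        assert (hacked["true_p"] < 0.05).mean() > \
            (base["true_p"] < 0.05).mean() + 0.05

    def test_stopping_respects_n_max_and_flags(self):
        cfg = GeneratorConfig(
            seed=5, n_records=150, pi0=0.7, error_rate=0.0,
            stopping=StoppingSpec(enabled=True, batch=30, n_max=500))
        _, truth = generate(cfg)
        assert truth["n_final"].max() <= 500
        stopped = truth[truth["stopped"]]
        assert len(stopped) > 0
        # a record that stopped before n_max must have crossed alpha
        early = stopped[stopped["n_final"] < 500]
        assert (early["true_p"] < 0.05).all()


class TestConfig:
    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(family_mix={"t": 0.5, "F": 0.2, "chi2": 0.1,
                                        "r": 0.1, "z": 0.05, "other": 0.0})

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(pi0=1.2)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=9, pi0=0.4,
                              hacking=HackingSpec(enabled=True, k_attempts=5))
        path = cfg.to_yaml(tmp_path / "gen.yaml")
        back = GeneratorConfig.from_yaml(path)
        assert back == cfg
        assert back.digest() == cfg.digest()

    def test_effect_dist_families(self):
        rng = np.random.default_rng(0)
        fixed = EffectDist(family="fixed", mu=0.3).draw(rng, 10)
        assert np.all(fixed == 0.3)
        uni = EffectDist(family="uniform", lo=0.1, hi=0.2).draw(rng, 100)
        assert np.all((uni >= 0.1) & (uni <= 0.2))
        with pytest.raises(ValueError):
            EffectDist(family="beta").draw(rng, 1)

    def test_injected_rates_accounting(self):
        _, truth = generate(GeneratorConfig(seed=19, n_records=400))
        rates = injected_rates(truth)
        assert 0 <= rates["gross"] <= rates["inconsistency"] <= 1
        assert rates["n_recomputable"] <= 400
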