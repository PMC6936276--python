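"""End-to-end audit model: wiring, determinism, export, CLI."""

from __future__ import annotations

import json

import pandas as pd
import pytest
from click.testing import CliRunner

from thesisaudit import (GeneratorConfig, ThesisAudit, generate, run_audit,
                         simulate_and_audit, write_records)
from thesisaudit.cli import main as cli_main
from conftest import make_record


class TestModelFit:
    def test_default_corpus_populates_every_section(self, default_corpus):
        records, _ = default_corpus
        res = ThesisAudit(records).fit(seed=0, n_bootstrap=400)
        assert res.effect_summary is not None
        assert res.power.observed is not None
        assert res.power.curve is not None
        assert res.forensics.pcurve is not None
        assert res.forensics.caliper is not None
        assert res.n_vs_effect is not None
        assert res.trends

    def test_counts_reconcile(self, default_corpus):
        records, _ = default_corpus
        res = ThesisAudit(records).fit(seed=0, n_bootstrap=400)
        n = len(records)
        c = res.consistency
        assert c.n_recomputable + c.n_unverifiable == n
        assert res.forensics.working.n + res.forensics.working.n_excluded == n
        statuses = [v.status for v in res.verdicts]
        assert (statuses.count("consistent") + c.n_inconsistent
                + c.n_unverifiable) == n

    def test_minimal_significant_corpus(self):
        rec = make_record()  # t(28) = 2.20, p ~ 0.036
        res = ThesisAudit([rec]).fit(seed=0, n_bootstrap=100)
        assert res.consistency.n_recomputable == 1
        assert res.forensics.pcurve.k_full == 1
        assert res.effect_summary.k == 1
        assert res.n_vs_effect is None  # fewer than 3 pairs
        assert "n_vs_effect" in res.notes

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            ThesisAudit([])

    def test_summary_renders(self, default_corpus):
        records, _ = default_corpus
        text = ThesisAudit(records).fit(seed=0, n_bootstrap=200).summary()
        assert "Effect sizes" in text and "p-value forensics" in text.lower()


class TestDeterminismAndIO:
    def test_fit_is_deterministic_given_seed(self, default_corpus):
        records, _ = default_corpus
        a = ThesisAudit(records).fit(seed=5, n_bootstrap=300).to_json()
        b = ThesisAudit(records).fit(seed=5, n_bootstrap=300).to_json()
        assert a == b

    def test_from_csv_equals_direct_construction(self, tmp_path,
                                                 default_corpus):
        records, _ = default_corpus
        path = write_records(records, tmp_path / "corpus.csv")
        via_csv = ThesisAudit.from_csv(path).fit(seed=1, n_bootstrap=200)
        direct = ThesisAudit(records).fit(seed=1, n_bootstrap=200)
        assert via_csv.to_json() == direct.to_json()

    def test_from_dataframe(self, tmp_path, default_corpus):
        records, _ = default_corpus
        path = write_records(records, tmp_path / "corpus.csv")
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        model = ThesisAudit.from_dataframe(frame)
        assert len(model.records) == len(records)

    def test_export_tables(self, tmp_path, default_corpus):
        records, _ = default_corpus
        res = ThesisAudit(records).fit(seed=0, n_bootstrap=200)
        paths = res.export_tables(tmp_path / "out")
        for key in ("verdicts", "effects", "observed_power", "power_curve",
                    "trends", "report"):
            assert paths[key].exists(), key
        report = json.loads(paths["report"].read_text())
        assert report["corpus"]["n_records"] == len(records)
        verdicts = pd.read_csv(paths["verdicts"])
        assert set(verdicts.columns) == {"record_id", "status", "p_lo",
                                         "p_hi", "one_tailed_rescue"}

    def test_simulate_and_audit_byte_identical_reports(self, tmp_path):
        cfg = GeneratorConfig(seed=23, n_records=80)
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        simulate_and_audit(cfg, out_dir=out_a, n_bootstrap=200)
        simulate_and_audit(cfg, out_dir=out_b, n_bootstrap=200)
        assert (out_a / "report.json").read_bytes() == \
            (out_b / "report.json").read_bytes()

    def test_simulate_and_audit_recovery_table(self, tmp_path):
        cfg = GeneratorConfig(seed=29, n_records=150)
        res, truth, recovery = simulate_and_audit(cfg, n_bootstrap=200)
        assert len(truth) == 150
        row = recovery.iloc[0]
        assert 0 <= row["injected_inconsistency"] <= 1
        assert 0 <= row["detected_inconsistency"] <= 1

    def test_run_audit_from_file(self, tmp_path, default_corpus):
        records, _ = default_corpus
        path = write_records(records, tmp_path / "corpus.csv")
        res = run_audit(path, out_dir=tmp_path / "report", seed=0,
                        n_bootstrap=200)
        assert (tmp_path / "report" / "report.json").exists()
        assert res.consistency.n_recomputable > 0


class TestPlots:
    def test_plot_helpers_return_axes(self, default_corpus):
        import matplotlib

        matplotlib.use("Agg")
        records, _ = default_corpus
        res = ThesisAudit(records).fit(seed=0, n_bootstrap=100)
        assert res.plot_p_distribution() is not None
        assert res.plot_power_curve() is not None


class TestCLI:
    def test_power_query(self):
        runner = CliRunner()
        out = runner.invoke(cli_main, ["power", "--n", "500", "--r", "0.17"])
        assert out.exit_code == 0
        assert "0.969" in out.output

    def test_solve_n_query(self):
        runner = CliRunner()
        out = runner.invoke(cli_main, ["power", "--r", "0.19",
                                       "--target", "0.8"])
        assert out.exit_code == 0 and "n required" in out.output

    def test_run_command(self, tmp_path, default_corpus):
        records, _ = default_corpus
        path = write_records(records, tmp_path / "corpus.csv")
        runner = CliRunner()
        out = runner.invoke(cli_main, [
            "run", "--input", str(path), "--out", str(tmp_path / "rep"),
            "--bootstrap", "200", "--seed", "1"])
        assert out.exit_code == 0, out.output
        assert (tmp_path / "rep" / "report.json").exists()

    def test_simulate_command(self, tmp_path):
        cfg_path = GeneratorConfig(seed=31, n_records=60).to_yaml(
            tmp_path / "gen.yaml")
        runner = CliRunner()
        out = runner.invoke(cli_main, [
            "simulate", "--config", str(cfg_path),
            "--out", str(tmp_path / "sim"), "--bootstrap", "200"])
        assert out.exit_code == 0, out.output
        assert (tmp_path / "sim" / "corpus.csv").exists()
        assert (tmp_path / "sim" / "ground_truth.csv").exists()
        assert "Recovery" in out.output
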