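"""Shared fixtures: small hand-built corpora and generator configs."""

from __future__ import annotations

import pytest

from thesisaudit import GeneratorConfig, ReportedTest, ThesisRecord, generate


def make_record(record_id: str = "R001", year: int = 2008, family: str = "t",
                statistic: float | None = 2.20, stat_decimals: int | None = 2,
                df1: float | None = 28.0, df2: float | None = None,
                n: int | None = None, tails: str = "two",
                p_style: str = "exact2", p_reported: float | None = 0.04,
                p_threshold: float | None = None, sample_size: int = 30,
                effect_metric: str = "none",
                effect_value: float | None = None,
                power_consideration: str = "none") -> ThesisRecord:
    """One coded record with sensible defaults (a consistent t test)."""
    test = ReportedTest(
        family=family, statistic=statistic, stat_decimals=stat_decimals,
        df1=df1, df2=df2, n=n, tails=tails, p_style=p_style,
        p_reported=p_reported, p_threshold=p_threshold)
    return ThesisRecord(
        record_id=record_id, year=year, test=test, sample_size=sample_size,
        effect_metric=effect_metric, effect_value=effect_value,
        power_consideration=power_consideration)


@pytest.fixture
def default_corpus():
    """A default synthetic corpus (250 records) with its ground truth."""
    return generate(GeneratorConfig(seed=42))


@pytest.fixture
def clean_config():
    """Generator config with no reporting errors or missingness."""
    return GeneratorConfig(
        seed=7, error_rate=0.0, missing_stat_rate=0.0, missing_df_rate=0.0,
        style_mix={"exact3": 0.5, "exact2": 0.5, "less_than": 0.0,
                   "greater_than": 0.0, "missing": 0.0})
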