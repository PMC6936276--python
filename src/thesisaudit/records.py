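"""Domain types for coded study records and lossless CSV interchange.

A *record* is one coded row per focal inferential test: the test family,
its statistic and degrees of freedom, the sample size, the reported p-value
together with its reporting style (exact at 2 or 3 decimals, a threshold
such as "<0.05", or missing), and the reported standardized effect size,
if any.  The fixed column schema is the interchange format between the
synthetic-corpus generator and every audit stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FAMILIES",
    "P_STYLES",
    "TAILS",
    "EFFECT_METRICS",
    "POWER_CONSIDERATIONS",
    "CSV_COLUMNS",
    "ReportedTest",
    "ThesisRecord",
    "EffectEstimate",
    "RecordError",
    "read_records",
    "write_records",
    "records_to_frame",
]

FAMILIES = ("t", "F", "chi2", "r", "z", "other")
P_STYLES = ("exact3", "exact2", "less_than", "greater_than", "missing")
TAILS = ("two", "one", "unknown")
EFFECT_METRICS = (
    "none", "r", "d", "eta2", "partial_eta2", "R2", "beta_std", "V",
    "odds_ratio",
)
POWER_CONSIDERATIONS = ("none", "formal", "rule_of_thumb")

#: Fixed interchange header.  Empty string encodes an absent value.
CSV_COLUMNS = (
    "record_id", "year", "family", "statistic", "stat_decimals",
    "df1", "df2", "n", "tails", "p_style", "p_reported", "p_threshold",
    "sample_size", "effect_metric", "effect_value", "power_consideration",
)


class RecordError(ValueError):
    """A malformed cell or invalid field combination, with row context."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        prefix = f"row {row}: " if row is not None else ""
        super().__init__(prefix + message)


@dataclass(frozen=True)
class ReportedTest:
    """One reported inferential result.

    ``stat_decimals`` is the number of decimal places at which the test
    statistic was printed; ``None`` means the statistic is exact (no
    rounding uncertainty).  ``p_reported`` is set only for exact styles,
    ``p_threshold`` only for threshold styles.
    """

    family: str
    statistic: float | None = None
    stat_decimals: int | None = 2
    df1: float | None = None
    df2: float | None = None
    n: int | None = None
    tails: str = "two"
    p_style: str = "missing"
    p_reported: float | None = None
    p_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise RecordError(f"unknown test family {self.family!r}")
        if self.p_style not in P_STYLES:
            raise RecordError(f"unknown p reporting style {self.p_style!r}")
        if self.tails not in TAILS:
            raise RecordError(f"unknown tails spec {self.tails!r}")
        exact = self.p_style in ("exact3", "exact2")
        threshold = self.p_style in ("less_than", "greater_than")
        if exact != (self.p_reported is not None):
            raise RecordError(
                "p_reported must be present iff p_style is exact2/exact3")
        if threshold != (self.p_threshold is not None):
            raise RecordError(
                "p_threshold must be present iff p_style is a threshold style")
        if self.p_reported is not None and not 0.0 <= self.p_reported <= 1.0:
            raise RecordError(f"p_reported {self.p_reported} outside [0, 1]")
        if self.statistic is not None and not math.isfinite(self.statistic):
            raise RecordError("statistic must be finite")
        for name in ("df1", "df2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise RecordError(f"{name} must be positive, got {v}")
        if self.n is not None and self.n < 1:
            raise RecordError(f"n must be a positive integer, got {self.n}")
        if self.stat_decimals is not None and self.stat_decimals < 0:
            raise RecordError("stat_decimals must be non-negative")

    @property
    def has_statistic(self) -> bool:
        return self.statistic is not None

    @property
    def has_df(self) -> bool:
        """Whether the degrees of freedom the family needs are present.

        z tests have no d.f.; chi2 and r tests additionally need a sample
        size, which stands in for (or determines) their d.f.
        """
        if self.family == "t":
            return self.df1 is not None
        if self.family == "F":
            return self.df1 is not None and self.df2 is not None
        if self.family == "chi2":
            return self.df1 is not None and self.n is not None
        if self.family == "r":
            return self.n is not None and self.n >= 4
        if self.family == "z":
            return True
        return False  # family "other" is never recomputable

    @property
    def has_p(self) -> bool:
        return self.p_style != "missing"


@dataclass(frozen=True)
class ThesisRecord:
    """A coded study row: one focal test plus study-level metadata."""

    record_id: str
    year: int
    test: ReportedTest
    sample_size: int
    effect_metric: str = "none"
    effect_value: float | None = None
    power_consideration: str = "none"

    def __post_init__(self) -> None:
        if self.effect_metric not in EFFECT_METRICS:
            raise RecordError(f"unknown effect metric {self.effect_metric!r}")
        if self.power_consideration not in POWER_CONSIDERATIONS:
            raise RecordError(
                f"unknown power consideration {self.power_consideration!r}")
        if self.sample_size < 2:
            raise RecordError(
                f"sample_size must be >= 2, got {self.sample_size}")
        if self.effect_value is not None and self.effect_metric == "none":
            raise RecordError("effect_value requires an effect_metric")

    # Missingness flags are derived, so they can never disagree with the
    # underlying fields.
    @property
    def missing_p(self) -> bool:
        return not self.test.has_p

    @property
    def missing_df(self) -> bool:
        if self.test.family in ("z", "other"):
            return False
        return not self.test.has_df

    @property
    def missing_stat(self) -> bool:
        return not self.test.has_statistic

    @property
    def reports_focal_effect(self) -> bool:
        """A standardized effect size is reported for the focal test."""
        return self.effect_value is not None

    @property
    def reports_any_effect(self) -> bool:
        """The thesis reports standardized effect sizes at all.

        A metric with no value encodes "effects reported in general, but
        omitted for the (non-significant) focal test".
        """
        return self.effect_metric != "none"

    @property
    def analysis_n(self) -> int:
        """Sample size used by the focal test: test-level n when coded,
        otherwise the study sample size."""
        return self.test.n if self.test.n is not None else self.sample_size


@dataclass(frozen=True)
class EffectEstimate:
    """A focal effect standardized to Pearson's r."""

    r_value: float | None
    source: str  # "reported" | "converted" | "unavailable"
    approximate: bool = False

    def __post_init__(self) -> None:
        if (self.source == "unavailable") != (self.r_value is None):
            raise RecordError("source='unavailable' iff r_value is absent")
        if self.r_value is not None and not -1.0 <= self.r_value <= 1.0:
            raise RecordError(f"r_value {self.r_value} outside [-1, 1]")

    @property
    def available(self) -> bool:
        return self.r_value is not None


# ---------------------------------------------------------------------------
# CSV interchange


def _fmt(value, decimals: int | None = None) -> str:
    if value is None:
        return ""
    if decimals is not None:
        return f"{value:.{decimals}f}"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_float(cell: str, name: str, row: int) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RecordError(f"malformed numeric cell {name}={cell!r}", row)


def _parse_int(cell: str, name: str, row: int) -> int | None:
    if cell == "":
        return None
    try:
        return int(float(cell))
    except ValueError:
        raise RecordError(f"malformed numeric cell {name}={cell!r}", row)


def _infer_decimals(cell: str) -> int | None:
    """Count decimal places in the literal statistic text."""
    cell = cell.strip()
    if "e" in cell.lower():
        return None
    if "." in cell:
        return len(cell.split(".", 1)[1])
    return 0


def _record_from_row(cells: dict[str, str], row: int) -> ThesisRecord:
    family = cells["family"].strip()
    if family not in FAMILIES:
        raise RecordError(f"unknown family token {family!r}", row)
    p_style = cells["p_style"].strip() or "missing"
    if p_style not in P_STYLES:
        raise RecordError(f"unknown p_style token {p_style!r}", row)
    tails = cells["tails"].strip() or "unknown"

    stat_cell = cells["statistic"]
    statistic = _parse_float(stat_cell, "statistic", row)
    dec_cell = cells["stat_decimals"].strip()
    if dec_cell == "":
        stat_decimals = _infer_decimals(stat_cell) if stat_cell else None
    elif dec_cell.lower() in ("exact", "inf"):
        stat_decimals = None
    else:
        stat_decimals = _parse_int(dec_cell, "stat_decimals", row)

    try:
        test = ReportedTest(
            family=family,
            statistic=statistic,
            stat_decimals=stat_decimals,
            df1=_parse_float(cells["df1"], "df1", row),
            df2=_parse_float(cells["df2"], "df2", row),
            n=_parse_int(cells["n"], "n", row),
            tails=tails,
            p_style=p_style,
            p_reported=_parse_float(cells["p_reported"], "p_reported", row),
            p_threshold=_parse_float(cells["p_threshold"], "p_threshold", row),
        )
        return ThesisRecord(
            record_id=cells["record_id"].strip(),
            year=_parse_int(cells["year"], "year", row) or 0,
            test=test,
            sample_size=_parse_int(cells["sample_size"], "sample_size", row)
            or 0,
            effect_metric=cells["effect_metric"].strip() or "none",
            effect_value=_parse_float(
                cells["effect_value"], "effect_value", row),
            power_consideration=cells["power_consideration"].strip() or "none",
        )
    except RecordError as err:
        if err.row is None:
            raise RecordError(str(err), row) from err
        raise


def read_records(path: str | Path) -> list[ThesisRecord]:
    """Read a record table, preserving row order.

    Absent cells (empty strings) map to absent fields; the derived
    ``missing_*`` flags follow.  Raises :class:`RecordError` with the
    offending row number for malformed cells or unknown tokens.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(CSV_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise RecordError(
            f"header mismatch, missing columns: {sorted(missing_cols)}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        cells = dict(zip(frame.columns, row))
        records.append(_record_from_row(cells, row=i + 2))
    return records


def write_records(records: Iterable[ThesisRecord], path: str | Path) -> Path:
    """Write records to CSV so that ``read_records`` reproduces them."""
    rows = []
    for rec in records:
        t = rec.test
        dec = t.stat_decimals
        # Print the statistic at its reported precision when it really is at
        # that precision; otherwise fall back to full repr so no digits are
        # lost on round-trip.
        if (t.statistic is not None and dec is not None
                and round(t.statistic, dec) == t.statistic):
            stat_cell = _fmt(t.statistic, dec)
        else:
            stat_cell = _fmt(t.statistic)
        rows.append({
            "record_id": rec.record_id,
            "year": str(rec.year),
            "family": t.family,
            "statistic": stat_cell,
            "stat_decimals": "exact" if dec is None else str(dec),
            "df1": _fmt(t.df1),
            "df2": _fmt(t.df2),
            "n": _fmt(t.n),
            "tails": t.tails,
            "p_style": t.p_style,
            "p_reported": _fmt(t.p_reported),
            "p_threshold": _fmt(t.p_threshold),
            "sample_size": str(rec.sample_size),
            "effect_metric": rec.effect_metric,
            "effect_value": _fmt(rec.effect_value),
            "power_consideration": rec.power_consideration,
        })
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def records_to_frame(records: Sequence[ThesisRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame (one row per record, typed columns)."""
    rows = []
    for rec in records:
        t = rec.test
        rows.append({
            "record_id": rec.record_id,
            "year": rec.year,
            "family": t.family,
            "statistic": t.statistic,
            "df1": t.df1,
            "df2": t.df2,
            "n": t.n,
            "tails": t.tails,
            "p_style": t.p_style,
            "p_reported": t.p_reported,
            "p_threshold": t.p_threshold,
            "sample_size": rec.sample_size,
            "effect_metric": rec.effect_metric,
            "effect_value": rec.effect_value,
            "power_consideration": rec.power_consideration,
            "missing_p": rec.missing_p,
            "missing_df": rec.missing_df,
            "missing_stat": rec.missing_stat,
        })
    return pd.DataFrame(rows)
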