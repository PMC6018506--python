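"""Ingestion of record-level condemnation data and slaughter denominators.

Inputs are delimited text files: one row per condemned carcass (date, state,
slaughterhouse, cattle type, condemnation reason) and one row per
(month, state, cattle type) for slaughter head counts.  This module validates
them against the closed vocabularies, aggregates events to calendar months,
forms monthly condemnation-rate series (condemned / slaughtered), and produces
the descriptive summaries used in surveillance reports: reason-by-cattle-type
cross-tabulations and annual rates per 10,000 head.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .vocab import CATTLE_TYPES, CONDEMNATION_REASONS

logger = logging.getLogger(__name__)

#: Default column names expected in a condemnation CSV.
CONDEMNATION_COLUMNS = ("date", "state", "slaughterhouse_id", "cattle_type", "reason")
#: Default column names expected in a slaughter-denominator CSV.
SLAUGHTER_COLUMNS = ("month", "state", "cattle_type", "head_count")


@dataclass(frozen=True)
class CondemnationRecord:
    """A single condemned carcass: when, where and why it was condemned."""

    date: pd.Timestamp
    state: str
    slaughterhouse_id: str
    cattle_type: str
    reason: str


@dataclass
class ParseResult:
    """Validated condemnation records plus the rows rejected at parse time.

    ``records`` is a tidy DataFrame with the canonical column names; each
    rejected row appears in ``rejected`` together with the reason it failed
    validation.
    """

    records: pd.DataFrame
    rejected: pd.DataFrame

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def iter_records(self) -> Iterable[CondemnationRecord]:
        for row in self.records.itertuples(index=False):
            yield CondemnationRecord(
                date=row.date,
                state=row.state,
                slaughterhouse_id=row.slaughterhouse_id,
                cattle_type=row.cattle_type,
                reason=row.reason,
            )


def _remap_columns(frame: pd.DataFrame, required: Sequence[str],
                   column_map: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename source columns to canonical names; hard error if any is absent."""
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"input file is missing required column(s): {missing}")
    return frame


def parse_condemnation_records(
    path,
    *,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
    cattle_types: Sequence[str] = CATTLE_TYPES,
    reasons: Sequence[str] = CONDEMNATION_REASONS,
    study_window: tuple[str, str] | None = None,
) -> ParseResult:
    """Read and validate a record-level condemnation file.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Optional mapping from canonical name to the header used in the file,
        e.g. ``{"date": "SlaughterDate"}``; unmapped columns must already use
        canonical names.
    cattle_types, reasons
        Closed vocabularies; rows with values outside them are rejected.
    study_window
        Optional ``(first_month, last_month)`` as ``YYYY-MM`` strings; records
        dated outside it are rejected.

    Returns
    -------
    ParseResult
        Every accepted row mapped to a validated record; the count and causes
        of rejected rows are retained and logged.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    raw = _remap_columns(raw, CONDEMNATION_COLUMNS, column_map)
    raw = raw.loc[:, list(CONDEMNATION_COLUMNS)].copy()

    reject_reason = pd.Series("", index=raw.index, dtype=object)

    dates = pd.to_datetime(raw["date"], format="ISO8601", errors="coerce")
    reject_reason[dates.isna()] = "unparseable date"
    if study_window is not None:
        lo = pd.Period(study_window[0], freq="M").start_time
        hi = pd.Period(study_window[1], freq="M").end_time
        outside = (dates < lo) | (dates > hi)
        reject_reason[outside.fillna(False) & (reject_reason == "")] = "date outside study window"

    bad_type = ~raw["cattle_type"].isin(cattle_types)
    reject_reason[bad_type & (reject_reason == "")] = "unknown cattle_type"
    bad_reason = ~raw["reason"].isin(reasons)
    reject_reason[bad_reason & (reject_reason == "")] = "unknown reason"

    keep = reject_reason == ""
    records = raw.loc[keep].copy()
    records["date"] = dates[keep]
    records["cattle_type"] = pd.Categorical(records["cattle_type"], categories=list(cattle_types))
    records["reason"] = pd.Categorical(records["reason"], categories=list(reasons))
    records = records.reset_index(drop=True)

    rejected = raw.loc[~keep].copy()
    rejected["reject_reason"] = reject_reason[~keep]
    rejected = rejected.reset_index(drop=True)
    if len(rejected):
        by_cause = rejected["reject_reason"].value_counts().to_dict()
        logger.warning("rejected %d of %d rows: %s", len(rejected), len(raw), by_cause)

    return ParseResult(records=records, rejected=rejected)


def parse_slaughter_counts(
    path,
    *,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
    cattle_types: Sequence[str] = CATTLE_TYPES,
) -> pd.DataFrame:
    """Read monthly slaughter head counts per state and cattle type.

    Enforces the denominator invariants: non-negative integer head counts and
    at most one row per (month, state, cattle_type).
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    raw = _remap_columns(raw, SLAUGHTER_COLUMNS, column_map)
    out = raw.loc[:, list(SLAUGHTER_COLUMNS)].copy()
    out["month"] = pd.PeriodIndex(out["month"], freq="M")
    out["head_count"] = pd.to_numeric(out["head_count"], errors="raise").astype(np.int64)
    if (out["head_count"] < 0).any():
        raise ValueError("head_count must be non-negative")
    dup = out.duplicated(subset=["month", "state", "cattle_type"])
    if dup.any():
        first = out.loc[dup, ["month", "state", "cattle_type"]].iloc[0].tolist()
        raise ValueError(f"duplicate slaughter-count row for {first}")
    unknown = ~out["cattle_type"].isin(cattle_types)
    if unknown.any():
        raise ValueError(f"unknown cattle_type in slaughter file: "
                         f"{sorted(out.loc[unknown, 'cattle_type'].unique())}")
    return out


def aggregate_monthly(
    records: pd.DataFrame,
    *,
    state: str | None = None,
    reason: str | None = None,
    cattle_type: str | None = None,
    window: tuple[str, str] | None = None,
) -> pd.Series:
    """Aggregate record-level events to per-month condemned counts.

    Returns a Series indexed by a contiguous monthly PeriodIndex spanning the
    selection (or the explicit ``window``); months with no events are present
    with count 0.  An empty selection yields an empty Series (with a logged
    notice), never an exception.
    """
    sel = records
    if state is not None:
        sel = sel[sel["state"] == state]
    if reason is not None:
        sel = sel[sel["reason"] == reason]
    if cattle_type is not None:
        sel = sel[sel["cattle_type"] == cattle_type]
    months = sel["date"].dt.to_period("M")
    if window is not None:
        lo, hi = pd.Period(window[0], "M"), pd.Period(window[1], "M")
    elif len(sel):
        lo, hi = months.min(), months.max()
    else:
        logger.info("aggregate_monthly: empty selection (state=%s reason=%s cattle_type=%s)",
                    state, reason, cattle_type)
        return pd.Series(dtype=np.int64, name="condemned",
                         index=pd.PeriodIndex([], freq="M", name="month"))
    full = pd.period_range(lo, hi, freq="M", name="month")
    counts = months.value_counts().reindex(full, fill_value=0).astype(np.int64)
    counts.name = "condemned"
    return counts.sort_index()


@dataclass
class RateSeries:
    """An evenly sampled monthly condemnation-rate series for one reason.

    ``values[k] = condemned[k] / slaughtered[k]``; months are contiguous.
    Months with a zero denominator carry a missing (NaN) rate and are excluded
    from modelling downstream.
    """

    reason: str
    months: pd.PeriodIndex
    condemned: np.ndarray
    slaughtered: np.ndarray
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.months)
        if not (len(self.condemned) == len(self.slaughtered) == len(self.values) == n):
            raise ValueError("RateSeries fields must have equal length")
        diffs = np.diff(self.months.asi8)
        if n > 1 and not np.all(diffs == 1):
            k = int(np.argmax(diffs != 1))
            raise ValueError(f"months must be contiguous; gap after {self.months[k]}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("rates must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.months)

    @property
    def t(self) -> np.ndarray:
        """Integer sample index, one unit per month."""
        return np.arange(len(self.months))

    def per(self, scale: float = 10_000.0) -> np.ndarray:
        """Rates rescaled for reporting, e.g. per 10,000 slaughtered head."""
        return self.values * scale

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": self.months.astype(str), "condemned": self.condemned,
             "slaughtered": self.slaughtered, "rate": self.values}
        )


def compute_rate_series(
    condemned: pd.Series,
    slaughtered: pd.Series,
    *,
    reason: str = "",
) -> RateSeries:
    """Divide aligned monthly condemned counts by slaughter denominators.

    Both inputs must share an identical monthly PeriodIndex; the first
    mismatched month is named in the error.  Zero denominators produce missing
    rates with a logged warning.
    """
    ci, si = condemned.index, slaughtered.index
    if len(ci) != len(si) or not (ci == si).all():
        for a, b in zip(ci, si):
            if a != b:
                raise ValueError(f"month misalignment: condemned has {a}, slaughtered has {b}")
        raise ValueError(f"month ranges differ in length ({len(ci)} vs {len(si)})")
    cond = np.asarray(condemned.values, dtype=np.int64)
    den = np.asarray(slaughtered.values, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(den > 0, cond / np.where(den > 0, den, 1), np.nan)
    if (den == 0).any():
        zero_months = list(ci[den == 0].astype(str))
        logger.warning("zero slaughter denominator in %s; rate set to missing", zero_months)
    return RateSeries(reason=reason, months=pd.PeriodIndex(ci, freq="M"),
                      condemned=cond, slaughtered=den, values=values)


def _round_half_up(x: np.ndarray, decimals: int = 2) -> np.ndarray:
    scale = 10.0 ** decimals
    return np.floor(x * scale + 0.5) / scale


@dataclass
class CrossTab:
    """Reason-by-cattle-type cross-tabulation with column percentages.

    Percentages are count / column total x 100, rounded half-up to two
    decimals for presentation; unrounded ratios are kept internally.
    """

    counts: pd.DataFrame
    column_totals: pd.Series
    percentages: pd.DataFrame
    raw_percentages: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: (cattle_type, reason, count, percentage)."""
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["cattle_type", "reason", "count"]
        long["percentage"] = self.percentages.stack().reset_index(drop=True)
        return long


def crosstab_by_type(
    records: pd.DataFrame,
    reasons: Sequence[str] | None = None,
    *,
    cattle_types: Sequence[str] = CATTLE_TYPES,
) -> CrossTab:
    """Tabulate condemned-carcass counts by cattle type for selected reasons."""
    if reasons is None:
        reasons = [r for r in CONDEMNATION_REASONS if (records["reason"] == r).any()]
    unknown = set(reasons) - set(CONDEMNATION_REASONS)
    if unknown:
        raise ValueError(f"reasons outside the closed vocabulary: {sorted(unknown)}")
    sel = records[records["reason"].isin(reasons)]
    counts = (
        pd.crosstab(sel["cattle_type"], sel["reason"])
        .reindex(index=list(cattle_types), columns=list(reasons), fill_value=0)
        .astype(np.int64)
    )
    counts.index.name = "cattle_type"
    counts.columns.name = "reason"
    totals = counts.sum(axis=0)
    raw = counts / totals.replace(0, np.nan) * 100.0
    zero_cols = totals.index[totals == 0].tolist()
    if zero_cols:
        logger.warning("crosstab: zero total for reason(s) %s; percentages undefined", zero_cols)
    rounded = raw.apply(lambda col: _round_half_up(col.to_numpy(dtype=float)), axis=0)
    rounded = pd.DataFrame(rounded, index=raw.index, columns=raw.columns)
    return CrossTab(counts=counts, column_totals=totals,
                    percentages=rounded, raw_percentages=raw)


def annual_rate_by_group(
    records: pd.DataFrame,
    slaughter: pd.DataFrame,
    *,
    group: str = "cattle_type",
    scale: float = 10_000.0,
) -> pd.DataFrame:
    """Annual condemnation rates per ``scale`` head, by cattle type or state.

    rate(year, g) = condemned(year, g) / slaughtered(year, g) x scale.
    Missing denominators yield missing cells with a logged notice; a group-year
    with a denominator but no events is an explicit 0.
    """
    if group not in ("cattle_type", "state"):
        raise ValueError("group must be 'cattle_type' or 'state'")
    ev = records.copy()
    ev["year"] = ev["date"].dt.year
    num = ev.groupby(["year", group], observed=True).size().rename("condemned")
    den_frame = slaughter.copy()
    den_frame["year"] = den_frame["month"].dt.year
    den = den_frame.groupby(["year", group], observed=True)["head_count"].sum()
    rate = (num.reindex(den.index, fill_value=0) / den.replace(0, np.nan)) * scale
    no_den = num.index.difference(den.index)
    if len(no_den):
        logger.warning("annual_rate_by_group: no denominator for %s; cells missing",
                       list(no_den))
    table = rate.unstack(group)
    table.index.name = "year"
    return table
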