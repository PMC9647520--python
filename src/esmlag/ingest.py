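"""Diary ingestion and cleaning.

Pipeline order is fixed: dedupe -> composites -> subject exclusion ->
person-standardization.  Duplicate subject-dates keep the first (earliest)
entry.  Composites are arithmetic means of their constituent items and are
left absent (never imputed) when a constituent is missing.  Subjects are
excluded for short enrolment (< ``min_days`` span) or for showing no
variability across the composite variables.  Standardization produces
person-centred z-scores using the subject's own mean and n-1 standard
deviation over observed days.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .items import (
    ANALYSIS_VARIABLES,
    COMPOSITES,
    IngestError,
    SLEEP_FIELDS,
    SYMPTOM_ITEMS,
    TIME_FIELDS,
    VALUE_RANGES,
)

_NUMERIC_FIELDS = SLEEP_FIELDS + SYMPTOM_ITEMS


@dataclass
class CleaningReport:
    """Counts and reasons accumulated while reading and cleaning a panel."""

    n_rows_read: int = 0
    n_rows_rejected: int = 0
    reject_reasons: dict[str, int] = field(default_factory=dict)
    duplicates_removed: int = 0
    subjects_excluded: dict[str, str] = field(default_factory=dict)
    variables_dropped: list[str] = field(default_factory=list)

    def reject(self, reason: str, n: int = 1) -> None:
        self.n_rows_rejected += n
        self.reject_reasons[reason] = self.reject_reasons.get(reason, 0) + n

    def to_dict(self) -> dict:
        return {
            "rows_read": self.n_rows_read,
            "rows_rejected": self.n_rows_rejected,
            "reject_reasons": dict(self.reject_reasons),
            "duplicates_removed": self.duplicates_removed,
            "subjects_excluded": dict(self.subjects_excluded),
            "variables_dropped": list(self.variables_dropped),
        }

    def write_json(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class DiaryPanel:
    """One row per subject-date, sorted within subject by calendar date."""

    data: pd.DataFrame
    report: CleaningReport = field(default_factory=CleaningReport)

    def __post_init__(self) -> None:
        df = self.data
        if "subject_id" not in df.columns or "date" not in df.columns:
            raise IngestError("panel requires subject_id and date columns")
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        self.data = df.sort_values(["subject_id", "date"], kind="stable").reset_index(
            drop=True
        )

    @property
    def subjects(self) -> list[str]:
        return list(self.data["subject_id"].unique())

    def subject_summary(self) -> pd.DataFrame:
        """Per-subject enrolment span, submitted diaries and response rate."""
        g = self.data.groupby("subject_id")["date"]
        out = pd.DataFrame(
            {
                "first": g.min(),
                "last": g.max(),
                "submitted": g.count(),
            }
        )
        out["span_days"] = (out["last"] - out["first"]).dt.days + 1
        out["response_rate"] = out["submitted"] / out["span_days"]
        return out.reset_index()


@dataclass
class StandardizedPanel:
    """Panel whose analysis variables are person-centred z-scores.

    ``stats`` records the (mean, sd) used per subject and variable so the raw
    scale can be recovered.
    """

    data: pd.DataFrame
    stats: pd.DataFrame
    variables: list[str]
    report: CleaningReport = field(default_factory=CleaningReport)

    @property
    def subjects(self) -> list[str]:
        return list(self.data["subject_id"].unique())


def _validate_wide(df: pd.DataFrame, report: CleaningReport) -> pd.DataFrame:
    known = {"subject_id", "date", *TIME_FIELDS, *_NUMERIC_FIELDS}
    unknown = [c for c in df.columns if c not in known and c not in COMPOSITES]
    if unknown:
        raise IngestError(f"unknown column(s): {unknown}")

    dates = pd.to_datetime(df["date"], errors="coerce")
    bad_date = dates.isna()
    report.reject("unparseable date", int(bad_date.sum()))

    bad_range = pd.Series(False, index=df.index)
    for col in _NUMERIC_FIELDS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        present = df[col].notna()
        lo, hi = VALUE_RANGES[col]
        invalid = present & (vals.isna() | (vals < lo) | (vals > hi))
        if invalid.any():
            report.reject(f"{col} out of range", int((invalid & ~bad_range & ~bad_date).sum()))
            bad_range |= invalid
        df[col] = vals

    keep = ~(bad_date | bad_range)
    df = df.loc[keep].copy()
    df["date"] = dates[keep]
    return df


def read_diary_csv(path: "str | Path", dialect: str = "wide") -> DiaryPanel:
    """Read a raw diary CSV (``wide``: one row per subject-date; ``long``:
    subject_id,date,item,value rows) into a typed :class:`DiaryPanel`.

    Rows failing range checks are rejected and counted in the cleaning
    report; the read fails outright only if more than half the rows are
    invalid (or no valid record remains).
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError:
        raise IngestError("no records") from None
    report = CleaningReport(n_rows_read=len(raw))
    if raw.empty:
        raise IngestError("no records")

    if dialect == "long":
        required = {"subject_id", "date", "item", "value"}
        if not required.issubset(raw.columns):
            raise IngestError(f"long dialect requires columns {sorted(required)}")
        bad_item = ~raw["item"].isin(_NUMERIC_FIELDS)
        if bad_item.any():
            report.reject("unknown item", int(bad_item.sum()))
            raw = raw.loc[~bad_item]
        wide = raw.pivot_table(
            index=["subject_id", "date"], columns="item", values="value", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        df = _validate_wide(wide, report)
    elif dialect == "wide":
        df = _validate_wide(raw.copy(), report)
    else:
        raise IngestError(f"unknown dialect {dialect!r} (use 'wide' or 'long')")

    if df.empty:
        raise IngestError("no records (all rows rejected)")
    if report.n_rows_rejected > 0.5 * report.n_rows_read:
        raise IngestError(
            f"{report.n_rows_rejected}/{report.n_rows_read} rows invalid (>50%)"
        )
    return DiaryPanel(df, report)


def write_diary_csv(panel: DiaryPanel, path: "str | Path", dialect: str = "wide") -> None:
    """Write a panel back to CSV; lossless at diary granularity."""
    df = panel.data.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    if dialect == "wide":
        df.to_csv(path, index=False)
    elif dialect == "long":
        value_cols = [c for c in _NUMERIC_FIELDS if c in df.columns]
        long = df.melt(
            id_vars=["subject_id", "date"],
            value_vars=value_cols,
            var_name="item",
            value_name="value",
        ).dropna(subset=["value"])
        long.to_csv(path, index=False)
    else:
        raise IngestError(f"unknown dialect {dialect!r}")


def dedupe_daily(panel: DiaryPanel) -> DiaryPanel:
    """Keep exactly one record per subject-date (first entry wins)."""
    df = panel.data
    before = len(df)
    deduped = df.drop_duplicates(subset=["subject_id", "date"], keep="first")
    report = panel.report
    report.duplicates_removed += before - len(deduped)
    return DiaryPanel(deduped.reset_index(drop=True), report)


def compute_composites(panel: DiaryPanel) -> DiaryPanel:
    """Add the six composite columns (means of items; single-item copy)."""
    df = panel.data.copy()
    for name, items in COMPOSITES.items():
        missing = [c for c in items if c not in df.columns]
        if missing:
            df[name] = np.nan
            continue
        block = df[items]
        # any absent constituent -> composite absent for that record
        df[name] = block.mean(axis=1).where(block.notna().all(axis=1))
    return DiaryPanel(df, panel.report)


def exclude_subjects(
    panel: DiaryPanel, min_days: int = 30, variability_epsilon: float = 0.0
) -> DiaryPanel:
    """Remove short-enrolment and no-variability subjects.

    Variability is the pooled within-person standard deviation across the
    composite variables: sqrt of the mean of the per-composite variances.
    """
    df = panel.data
    report = panel.report
    composite_cols = [c for c in COMPOSITES if c in df.columns]
    keep_ids = []
    for sid, g in df.groupby("subject_id"):
        span = (g["date"].max() - g["date"].min()).days + 1
        if span < min_days:
            report.subjects_excluded[str(sid)] = "duration"
            continue
        if composite_cols:
            variances = [
                float(np.nanvar(g[c].to_numpy(dtype=float), ddof=1))
                if g[c].notna().sum() > 1
                else 0.0
                for c in composite_cols
            ]
            pooled_sd = float(np.sqrt(np.nanmean(variances)))
            if pooled_sd <= variability_epsilon:
                report.subjects_excluded[str(sid)] = "no variability"
                continue
        keep_ids.append(sid)
    if not keep_ids:
        raise IngestError("all subjects excluded")
    return DiaryPanel(df[df["subject_id"].isin(keep_ids)].reset_index(drop=True), report)


def standardize(
    panel: DiaryPanel, variables: "list[str] | None" = None
) -> StandardizedPanel:
    """Person-centred z-scores per subject and variable (n-1 denominator).

    Zero-variance subject-variables are dropped (set absent) with a warning.
    Raw sleep scales are preserved in ``*_raw`` columns.
    """
    df = panel.data.copy()
    if variables is None:
        variables = [v for v in ANALYSIS_VARIABLES if v in df.columns]
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise IngestError(f"variables absent from panel: {missing}")

    stats_rows = []
    for var in variables:
        raw_col = f"{var}_raw"
        if raw_col not in df.columns:
            df[raw_col] = df[var]
        df[var] = df[var].astype(float)
        for sid, g in df.groupby("subject_id"):
            vals = g[var].to_numpy(dtype=float)
            obs = ~np.isnan(vals)
            n = int(obs.sum())
            mu = float(np.mean(vals[obs])) if n else np.nan
            sd = float(np.std(vals[obs], ddof=1)) if n > 1 else 0.0
            if n == 0:
                continue
            if sd == 0.0:
                warnings.warn(
                    f"subject {sid}: variable {var!r} constant; dropped",
                    stacklevel=2,
                )
                panel.report.variables_dropped.append(f"{sid}:{var}")
                df.loc[g.index, var] = np.nan
            else:
                df.loc[g.index, var] = (vals - mu) / sd
            stats_rows.append(
                {"subject_id": sid, "variable": var, "mean": mu, "sd": sd, "n": n}
            )
    stats = pd.DataFrame(stats_rows, columns=["subject_id", "variable", "mean", "sd", "n"])
    return StandardizedPanel(df, stats, list(variables), panel.report)


def preprocess(
    panel: DiaryPanel, min_days: int = 30, variability_epsilon: float = 0.0
) -> StandardizedPanel:
    """Full cleaning pipeline: dedupe -> composites -> exclusion -> z-scores."""
    panel = dedupe_daily(panel)
    panel = compute_composites(panel)
    panel = exclude_subjects(panel, min_days=min_days, variability_epsilon=variability_epsilon)
    return standardize(panel)
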