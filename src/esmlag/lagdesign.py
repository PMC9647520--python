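"""Within-subject calendar-aligned lagged predictor/outcome structures.

Lags are calendar-day differences, never observation-index differences: a
predictor at lag ``l`` is the value exactly ``l`` days before the outcome day,
absent (NaN) if that day was not observed.  Days skipped in the diary
therefore create genuinely missing lagged values rather than silently
shifting the lag semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import StandardizedPanel
from .items import FitError


@dataclass
class PanelData:
    """Dense per-subject calendar arrays for a set of variables.

    ``values`` is (n_subjects, T_max, n_variables) with NaN for unobserved
    days; ``lengths`` holds each subject's span in days.
    """

    subjects: list[str]
    variables: list[str]
    values: np.ndarray
    lengths: np.ndarray
    start_dates: list[pd.Timestamp]

    def var_index(self, name: str) -> int:
        return self.variables.index(name)


def panel_arrays(panel: StandardizedPanel, variables: list[str]) -> PanelData:
    """Lay a standardized panel onto per-subject daily calendar grids."""
    df = panel.data
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise FitError(f"variables absent from panel: {missing}")
    subjects = list(df["subject_id"].unique())
    per_subject = []
    lengths = []
    starts = []
    for sid in subjects:
        g = df[df["subject_id"] == sid]
        t0, t1 = g["date"].min(), g["date"].max()
        T = (t1 - t0).days + 1
        arr = np.full((T, len(variables)), np.nan)
        idx = (g["date"] - t0).dt.days.to_numpy()
        for j, var in enumerate(variables):
            arr[idx, j] = g[var].to_numpy(dtype=float)
        per_subject.append(arr)
        lengths.append(T)
        starts.append(t0)
    T_max = max(lengths)
    values = np.full((len(subjects), T_max, len(variables)), np.nan)
    for i, arr in enumerate(per_subject):
        values[i, : arr.shape[0]] = arr
    return PanelData(subjects, list(variables), values, np.asarray(lengths), starts)


@dataclass
class LagDesign:
    """Lagged views of an ordered (predictor, outcome) pair over 1..max_lag.

    ``wide``: one row per observed outcome day with columns ``x_lag1`` ..
    ``x_lag{L}``; ``long``: stacked rows (subject, date, lag, y, x) keeping
    only observed predictor values.
    """

    predictor: str
    outcome: str
    max_lag: int
    wide: pd.DataFrame
    long: pd.DataFrame
    pair_counts: pd.Series
    arrays: PanelData

    @property
    def n_outcome_days(self) -> int:
        return len(self.wide)

    def to_csv(self, path) -> None:
        """Dump the long-stacked view for external verification."""
        self.long.to_csv(path, index=False)


def build_lag_design(
    panel: StandardizedPanel, predictor: str, outcome: str, max_lag: int = 20
) -> LagDesign:
    """Build wide and long lagged views for one predictor/outcome pair.

    The predictor may equal the outcome (auto-regression design), in which
    case lagged columns are calendar-shifted copies of the outcome itself.
    """
    if max_lag < 1:
        raise FitError("max_lag must be >= 1")
    variables = [predictor] if predictor == outcome else [predictor, outcome]
    arrays = panel_arrays(panel, variables)
    xj = arrays.var_index(predictor)
    yj = arrays.var_index(outcome)

    rows = []
    for i, sid in enumerate(arrays.subjects):
        T = int(arrays.lengths[i])
        x = arrays.values[i, :T, xj]
        y = arrays.values[i, :T, yj]
        t_obs = np.where(~np.isnan(y))[0]
        if t_obs.size == 0:
            continue
        lagged = np.full((t_obs.size, max_lag), np.nan)
        for l in range(1, max_lag + 1):
            ok = t_obs - l >= 0
            lagged[ok, l - 1] = x[t_obs[ok] - l]
        block = pd.DataFrame(
            lagged, columns=[f"x_lag{l}" for l in range(1, max_lag + 1)]
        )
        block.insert(0, "y", y[t_obs])
        block.insert(0, "date", arrays.start_dates[i] + pd.to_timedelta(t_obs, unit="D"))
        block.insert(0, "subject_id", sid)
        rows.append(block)
    if not rows:
        raise FitError(f"no observed outcome days for {outcome!r}")
    wide = pd.concat(rows, ignore_index=True)

    long = wide.melt(
        id_vars=["subject_id", "date", "y"],
        value_vars=[f"x_lag{l}" for l in range(1, max_lag + 1)],
        var_name="lag",
        value_name="x",
    ).dropna(subset=["x", "y"])
    long["lag"] = long["lag"].str.removeprefix("x_lag").astype(int)
    long = long.sort_values(["subject_id", "date", "lag"]).reset_index(drop=True)

    pair_counts = (
        long["lag"].value_counts().reindex(range(1, max_lag + 1), fill_value=0).sort_index()
    )
    return LagDesign(predictor, outcome, max_lag, wide, long, pair_counts, arrays)
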