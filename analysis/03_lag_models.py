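"""Two-stage lag models for every sleep/psychopathology pair.

For each ordered pair the exploratory penalized-spline screen proposes
candidate lags over the 1-20-day window and the confirmatory state-space fit
retains the significant ones; results are grouped as in the study layout:
sleep -> psychopathology, the reciprocal direction, and auto-regressions.
Writes the pair table (run-notation lags, summed beta, BIC) and beta(l)
curves under results/.

Run after 02_preprocess.py:  python analysis/03_lag_models.py
"""

from pathlib import Path

import pandas as pd

from esmlag import (
    DiaryPanel,
    build_lag_design,
    fit_smooth_lag,
    iterate_two_stage,
    standardize,
    summed_effect,
)
from esmlag.lagsets import format_lag_runs
from esmlag.plots import plot_lag_fit

IN = Path("results/cohort/standardized_panel.csv")
OUT = Path("results/lag_models")

SLEEP = ["sleep_quality", "sleep_duration"]
PSYCHO = ["psychosis", "negative_affect", "positive_affect", "cognitive"]


def load_panel():
    df = pd.read_csv(IN, parse_dates=["date"])
    return standardize(DiaryPanel(df))  # idempotent on an already-z panel


def main() -> None:
    panel = load_panel()
    OUT.mkdir(parents=True, exist_ok=True)
    blocks = (
        [("sleep->psychopathology", s, p) for s in SLEEP for p in PSYCHO]
        + [("reciprocal", p, s) for s in SLEEP for p in PSYCHO]
        + [("auto-regression", v, v) for v in SLEEP + PSYCHO]
    )
    rows = []
    for block, pred, outc in blocks:
        model = iterate_two_stage(panel, pred, outc)
        fit = model.fit
        rows.append(
            {
                "block": block,
                "predictor": pred,
                "outcome": outc,
                "significant_lags": format_lag_runs(fit.cross["lag"]),
                "summed_beta": round(summed_effect(fit), 3),
                "bic": round(fit.bic, 1),
                "n_obs": fit.n_obs,
            }
        )
        print(f"[{block}] {pred} -> {outc}: lags "
              f"{rows[-1]['significant_lags']}  summed beta "
              f"{rows[-1]['summed_beta']:+.3f}")
        if block == "sleep->psychopathology":
            design = build_lag_design(panel, pred, outc, 20)
            plot_lag_fit(
                fit_smooth_lag(design), OUT / f"lagcurve_{pred}__{outc}.png",
                title=f"{pred} -> {outc}",
            )
    pd.DataFrame(rows).to_csv(OUT / "pair_table.csv", index=False)
    print(f"\nwrote {OUT / 'pair_table.csv'}")


if __name__ == "__main__":
    main()
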