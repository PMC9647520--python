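"""End-to-end orchestration: simulate -> preprocess -> lag models -> mediation.

A run is driven by a single :class:`RunConfig` (flat keys + nested sections,
YAML-friendly).  Outputs under the run directory: cleaning report, per-pair
results JSON, a publication-style pair table (predictor->outcome, reciprocal
and auto-regression blocks), mediation table and path diagrams, and a
machine-readable manifest (config hash, seeds, library versions) sufficient
to regenerate every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .confirm import FinalLagModel, iterate_two_stage, summed_effect
from .ingest import StandardizedPanel, preprocess, read_diary_csv, write_diary_csv
from .items import EsmlagError
from .lagsets import format_lag_runs
from .mediate import MediationComparison, path_diagram, run_mediation
from .synth import (
    LagKernel,
    SimulationConfig,
    apply_missingness,
    discretize_to_likert,
    simulate_panel,
    write_ground_truth,
)

log = logging.getLogger("esmlag")


def study_scale_kernels() -> LagKernel:
    """A study-scale kernel preset: medium summed effects of sleep on
    psychopathology over 1-12 day windows, weaker short reciprocal effects,
    and short-memory autocorrelation in every variable."""
    auto = {
        (v, v): [0.25, 0.15, 0.08]
        for v in (
            "sleep_quality",
            "sleep_duration",
            "positive_affect",
            "negative_affect",
            "cognitive",
            "psychosis",
        )
    }
    cross = {
        ("sleep_quality", "psychosis"): [-0.05] * 8,
        ("sleep_duration", "psychosis"): [-0.025] * 12,
        ("sleep_quality", "negative_affect"): [-0.04] * 8,
        ("psychosis", "sleep_quality"): [-0.05] * 3,
        ("negative_affect", "psychosis"): [0.08] * 3,
    }
    return LagKernel({**auto, **cross})


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str
    seed: int = 0
    input_path: str | None = None  # mutually exclusive with simulation
    input_format: str = "wide"
    simulation: dict | None = None  # SimulationConfig fields (kernels as dict)
    preset: str | None = None  # "study-scale" fills simulation defaults
    pairs: list[tuple[str, str]] = field(default_factory=list)
    triples: list[tuple[str, str, str]] = field(default_factory=list)
    max_lag: int = 20
    alpha: float = 0.05
    k: int = 19
    include_auto: bool = True
    min_days: int = 30
    variability_epsilon: float = 0.0

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation or {})
        kernels = sim.pop("kernels", None)
        if self.preset == "study-scale" and kernels is None:
            kernel = study_scale_kernels()
        elif isinstance(kernels, dict):
            kernel = LagKernel.from_dict(kernels)
        elif isinstance(kernels, LagKernel):
            kernel = kernels
        else:
            kernel = LagKernel({})
        sim.setdefault("seed", self.seed)
        return SimulationConfig(kernels=kernel, **sim)


def _load_panel(config: RunConfig, out: Path) -> StandardizedPanel:
    if config.input_path:
        raw = read_diary_csv(config.input_path, config.input_format)
    else:
        sim_cfg = config.simulation_config()
        tp = simulate_panel(sim_cfg)
        tp = discretize_to_likert(tp, sim_cfg)
        raw = apply_missingness(tp, sim_cfg)
        write_ground_truth(tp, out / "ground_truth.json")
        write_diary_csv(raw, out / "simulated_diary.csv")
    panel = preprocess(
        raw, min_days=config.min_days, variability_epsilon=config.variability_epsilon
    )
    panel.report.write_json(out / "cleaning_report.json")
    return panel


def _pair_row(pred: str, outc: str, model: FinalLagModel) -> dict:
    fit = model.fit
    return {
        "predictor": pred,
        "outcome": outc,
        "significant_lags": format_lag_runs(fit.cross["lag"]),
        "summed_beta": round(summed_effect(fit), 4),
        "auto_lags": format_lag_runs(fit.auto["lag"]),
        "bic": round(fit.bic, 2),
        "n_obs": fit.n_obs,
        "n_cycles": model.n_cycles,
        "converged": model.converged,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute all requested stages; returns the run directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "esmlag_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    try:
        panel = _load_panel(config, out)
        manifest["stages"].append({"stage": "preprocess", "seconds": round(time.time() - t0, 2)})

        pair_rows = []
        pair_results = {}
        for pred, outc in config.pairs:
            ts = time.time()
            model = iterate_two_stage(
                panel, pred, outc,
                max_lag=config.max_lag, alpha=config.alpha, k=config.k,
                include_auto=config.include_auto,
            )
            pair_rows.append(_pair_row(pred, outc, model))
            pair_results[f"{pred}->{outc}"] = {
                **model.fit.to_dict(),
                "trace": [list(map(list, cycle)) for cycle in model.trace],
                "converged": model.converged,
                "oscillation_resolved": model.oscillation_resolved,
            }
            manifest["stages"].append(
                {"stage": f"dtve {pred}->{outc}", "seconds": round(time.time() - ts, 2)}
            )
        if pair_rows:
            pd.DataFrame(pair_rows).to_csv(out / "pair_table.csv", index=False)
            (out / "pair_results.json").write_text(
                json.dumps(pair_results, indent=2, default=float)
            )

        med_rows = []
        diagrams = []
        for x, m, y in config.triples:
            ts = time.time()
            cmp_ = run_mediation(
                panel, x, m, y,
                max_lag=config.max_lag, alpha=config.alpha, k=config.k,
                include_auto=config.include_auto,
            )
            for label, res in (("forward", cmp_.forward), ("oppositional", cmp_.oppositional)):
                row = res.to_dict()
                row["model"] = label
                row["preferred"] = cmp_.preferred
                med_rows.append(row)
                diagrams.append(f"[{label}] {row['triple']}\n{path_diagram(res)}\n")
            manifest["stages"].append(
                {"stage": f"mediate {x}|{m}|{y}", "seconds": round(time.time() - ts, 2)}
            )
        if med_rows:
            pd.DataFrame(med_rows).to_csv(out / "mediation_table.csv", index=False)
            (out / "path_diagrams.txt").write_text("\n".join(diagrams))

        _write_summary(out, pair_rows, med_rows)
    except EsmlagError as err:
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["total_seconds"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _write_summary(out: Path, pair_rows: list[dict], med_rows: list[dict]) -> None:
    lines = ["esmlag run summary", "==================", ""]
    if pair_rows:
        lines.append("Lag relationships (predictor -> outcome):")
        for r in pair_rows:
            lines.append(
                f"  {r['predictor']} -> {r['outcome']}: lags {r['significant_lags']}"
                f"  summed beta {r['summed_beta']:+.3f}  (BIC {r['bic']})"
            )
        lines.append("")
    if med_rows:
        lines.append("Mediation analyses:")
        for r in med_rows:
            lines.append(
                f"  [{r['model']}] {r['triple']}: verdict {r['verdict']}"
                f"  total {r['total_effect']:+.3f} = direct {r['direct_effect']:+.3f}"
                f" + indirect {r['indirect_effect']:+.3f}  (preferred: {r['preferred']})"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
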