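"""End-to-end orchestration of the audit stages.

``run_all`` executes, in order: synthetic-data simulation, collinearity
screen, site-selection modelling, success scoring and modelling,
past-exposure summaries, future DHW exceedance and the cost curves.
Stages communicate only through their serialized table interfaces; a
single seed fans out deterministically (via ``numpy.random.SeedSequence``
spawning) into per-stage seeds, all echoed into the summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import cost_model, site_selection, success_analysis, thermal_exposure
from .brt_engine import BRTConfig
from .site_selection import SiteSelectionConfig
from .success_analysis import SuccessConfig
from .success_metric import default_curve
from .synthetic_data import SimulationConfig, generate_dataset

log = logging.getLogger("reefrestore")

STAGES = ("simulate", "collinearity", "select_sites", "success",
          "exposure", "future", "costs")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "reefrestore_out"
    stages: tuple = STAGES
    fast: bool = False
    scale: float = 1.0                     # locality-count scale factor
    n_replicates: int = 1000
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    degraded_area_km2: float = 11700.0
    restore_fraction: float = 0.10

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.fast:
            self.scale = min(self.scale, 0.2)
            self.n_replicates = min(self.n_replicates, 30)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        cfg = cls(**{k: v for k, v in raw.items() if k != "stages"},
                  stages=tuple(raw.get("stages", STAGES)))
        cfg.simulation = dataclasses.replace(cfg.simulation, **sim)
        return cfg


def _stage_seeds(seed: int) -> dict[str, int]:
    states = np.random.SeedSequence(seed).generate_state(len(STAGES), dtype=np.uint32)
    return {name: int(s % (2 ** 31)) for name, s in zip(STAGES, states)}


def _fast_brt(loss: str) -> BRTConfig:
    # reduced tree grid for the scaled-down pipeline runs
    lr = 0.01
    return BRTConfig(learning_rate=lr, bag_fraction=0.5 if loss == "bernoulli" else 0.7,
                     tree_complexity=3 if loss == "bernoulli" else 5,
                     n_trees_range=(50, 500), n_trees_step=10,
                     n_folds=3, loss=loss)


def run_all(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns (and writes) the summary dict."""
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed, "stage_seeds": seeds,
                     "stages_run": list(config.stages), "timings_s": {}}
    dataset = None

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, *exc):
                summary["timings_s"][name] = round(time.perf_counter() - self.t0, 3)
                log.info("stage %s finished in %.1fs", name, summary["timings_s"][name])
        return _T()

    if "simulate" in config.stages:
        with timed("simulate"):
            sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
            if config.scale != 1.0:
                sim = sim.scaled(config.scale)
            dataset = generate_dataset(sim)
            dataset.write_csv(out / "data")
            summary["simulate"] = {
                "n_localities": int(len(dataset.localities)),
                "n_restored": int(dataset.localities["restored"].sum()),
                "n_records": int(len(dataset.records)) if dataset.records is not None else 0,
            }

    if dataset is None and set(config.stages) - {"costs"}:
        raise RuntimeError("stages beyond 'costs' require the simulate stage")

    curve = default_curve()

    if "collinearity" in config.stages:
        with timed("collinearity"):
            feats = dataset.localities[["gravity", "remoteness", "impact_mean",
                                        "impact_trend", "coral_richness"]]
            screen = site_selection.collinearity_screen(feats)
            screen.to_csv(out / "collinearity.csv", index=False)
            summary["collinearity"] = {
                "n_pairs": int(len(screen)),
                "n_flagged": int(screen["flagged"].sum()),
                "max_r2": float(screen["r2"].max()),
            }

    if "select_sites" in config.stages:
        with timed("select_sites"):
            table = site_selection.build_site_table(
                dataset.localities, dataset.alerts, dataset.records)
            # thinning scale adapted to the (possibly scaled) grid density
            sel_cfg = SiteSelectionConfig(
                n_replicates=config.n_replicates, seed=seeds["select_sites"],
                brt=_fast_brt("bernoulli") if config.fast else BRTConfig(loss="bernoulli"))
            if config.fast:
                sel_cfg.thinning_km = 150.0
            res = site_selection.run_site_selection(table, sel_cfg)
            res.replicates.to_csv(out / "site_selection_replicates.csv", index=False)
            res.influence.to_csv(out / "site_selection_influence.csv",
                                 header=["relative_influence_pct"])
            for var, curve_df in res.partial_dependence.items():
                curve_df.to_csv(out / f"pd_site_{var}.csv", index=False)
            summary["select_sites"] = res.aggregate

    if "success" in config.stages:
        with timed("success"):
            table = success_analysis.build_success_table(
                dataset.records, dataset.localities, dataset.alerts, curve)
            suc_cfg = SuccessConfig(
                n_replicates=config.n_replicates, seed=seeds["success"],
                brt=_fast_brt("squared") if config.fast else BRTConfig(
                    learning_rate=0.001, bag_fraction=0.7, tree_complexity=5,
                    loss="squared"))
            res = success_analysis.run_success_model(table, suc_cfg)
            res.replicates.to_csv(out / "success_replicates.csv", index=False)
            summary["success"] = {**res.aggregate, "pooled_r2": res.pooled_r2,
                                  "suppressed": res.suppressed,
                                  "message": res.message}

    if "exposure" in config.stages:
        with timed("exposure"):
            exp = thermal_exposure.post_restoration_exposure(
                dataset.records, dataset.alerts)
            exp.to_csv(out / "post_restoration_exposure.csv", index=False)
            fr = thermal_exposure.restored_vs_control_fractions(
                dataset.localities, dataset.records, dataset.alerts)
            fr.to_csv(out / "restored_vs_control_bins.csv", index=False)
            summary["exposure"] = thermal_exposure.exposure_group_stats(exp)

    if "future" in config.stages:
        with timed("future"):
            summ = thermal_exposure.dhw_exceedance(dataset.dhw)
            summ.to_csv(out / "dhw_exceedance.csv", index=False)
            summary["future"] = thermal_exposure.dhw_group_summary(
                summ, dataset.localities)

    if "costs" in config.stages:
        with timed("costs"):
            schemes = cost_model.load_cost_schemes()
            area = cost_model.area_for_fraction(config.degraded_area_km2,
                                                config.restore_fraction)
            rows = []
            for name, scheme in schemes.items():
                c = cost_model.cost_curve(scheme, [area]).iloc[0]
                rows.append({"technique": name, "area_ha": area,
                             "low_usd": c["low_usd"], "median_usd": c["median_usd"],
                             "high_usd": c["high_usd"]})
            import pandas as pd
            pd.DataFrame(rows).to_csv(out / "cost_totals.csv", index=False)
            summary["costs"] = {
                "area_ha": area,
                "upper_bound_usd": float(schemes["all_techniques"].high * area),
                "lower_bound_usd": float(schemes["all_techniques"].low * area),
                "gardening_median_usd": float(schemes["coral_gardening"].median * area),
            }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
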