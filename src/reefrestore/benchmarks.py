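"""Reference experiments exercising the whole pipeline on planted truth.

These are the package's standing benchmarks: a null-calibration run
(randomized restoration status; the site model should show no skill and
the success model should suppress variable importance), a planted-truth
recovery run (gravity drives restoration probability up, remoteness
down; the pipeline must rank gravity first and produce an increasing
gravity partial-dependence curve), and spatial-machinery calibration
(thinning distances, type-I error of the join-count and Moran tests).
The problem sizes are scaled to run a benchmark in minutes on one core;
docs/methods.md records the choices.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import site_selection as ss
from . import spatial_stats as sp
from . import success_analysis as sa
from .brt_engine import BRTConfig, fit_brt, partial_dependence, relative_influence
from .synthetic_data import SimulationConfig, generate_grid


def _fast_classifier(seed: int = 0) -> BRTConfig:
    return BRTConfig(learning_rate=0.01, bag_fraction=0.5, tree_complexity=3,
                     n_trees_range=(50, 300), n_trees_step=10, n_folds=3,
                     loss="bernoulli", seed=seed)


def null_site_selection_tss(seed: int, n_localities: int = 4000,
                            n_replicates: int = 12) -> dict:
    """Mean cross-validated TSS when restoration status is pure noise.

    Balanced classes and a thinning threshold just above the grid
    spacing keep the test splits large (so the threshold-scan optimism
    stays small) while still letting each rethinning attempt draw a
    different subset.  Replicates whose subset sampler exhausts its
    tries are skipped and counted.
    """
    cfg = SimulationConfig(n_localities=n_localities, restored_fraction=0.5,
                           seed=seed, spatial_range_km=0.0, spatial_sd=0.0,
                           coef_gravity=0.0, coef_remoteness=0.0,
                           coef_impact_mean=0.0, coef_impact_trend=0.0,
                           coef_richness=0.0)
    ds = generate_grid(cfg)
    table = ss.build_site_table(ds.localities, ds.alerts, None,
                                reference_year=2016)
    sel = ss.SiteSelectionConfig(thinning_km=60.0, n_replicates=n_replicates,
                                 seed=seed, brt=_fast_classifier(seed),
                                 on_exhausted="skip")
    res = ss.run_site_selection(table, sel, fit_full_model=False)
    return {"tss_mean": res.aggregate["tss_mean"],
            "tss_sd": res.aggregate["tss_sd"],
            "n_replicates": res.aggregate["n_replicates"],
            "n_localities": n_localities}


def noise_success_model(seed: int, n_records: int = 400,
                        n_replicates: int = 6) -> dict:
    """Cross-validated R^2 and suppression with a pure-noise success response."""
    rng = np.random.default_rng(seed)
    n = n_records
    table = pd.DataFrame({
        "lon": rng.uniform(-170, 170, n), "lat": rng.uniform(-25, 25, n),
        "gardening": rng.integers(0, 2, n),
        "transplantation": rng.integers(0, 2, n),
        "artificial_reef": rng.integers(0, 2, n),
        "larval_enhancement": rng.integers(0, 2, n),
        "n_genera": rng.integers(1, 6, n),
        "gravity": rng.lognormal(1, 1, n),
        "remoteness": rng.uniform(0, 8, n),
        "impact_mean": rng.gamma(4, 1, n),
        "impact_trend": rng.normal(0, 0.3, n),
        "coral_richness": rng.integers(50, 400, n),
        "alerts_pre": rng.poisson(1.0, n).astype(float),
        "alerts_post": rng.poisson(1.0, n).astype(float),
        "s_r": rng.standard_normal(n),
    })
    # records sit at fixed scattered coordinates, so rethinning cannot vary
    # the 1 km-deduplicated subset: replicates whose i.i.d. response is
    # by chance Moran-significant are skipped rather than retried forever
    cfg = sa.SuccessConfig(
        n_replicates=n_replicates, seed=seed, on_exhausted="skip",
        brt=BRTConfig(learning_rate=0.05, bag_fraction=0.7, tree_complexity=5,
                      n_trees_range=(20, 150), n_trees_step=10, n_folds=3,
                      loss="squared"))
    res = sa.run_success_model(table, cfg)
    return {"r2_mean": res.aggregate["r2_mean"],
            "suppressed": res.suppressed, "n_records": n}


def planted_truth_config(seed: int, n_localities: int = 1200) -> SimulationConfig:
    """Gravity strongly positive, remoteness negative, weak everything else."""
    return SimulationConfig(n_localities=n_localities, restored_fraction=0.12,
                            seed=seed, spatial_range_km=250.0, spatial_sd=0.8,
                            coef_gravity=1.5, coef_remoteness=-1.0,
                            coef_impact_mean=0.3, coef_impact_trend=0.0,
                            coef_richness=-0.2)


def planted_truth_recovery(seed: int, n_replicates: int = 50) -> dict:
    """How often gravity ranks first in influence across replicate fits,
    plus the monotonicity (Spearman) of the gravity partial-dependence
    curve of the full-data model."""
    cfg = planted_truth_config(seed)
    ds = generate_grid(cfg)
    table = ss.build_site_table(ds.localities, ds.alerts, None,
                                reference_year=2016)
    y = table["restored"].astype(bool).to_numpy()
    gravity_first = 0
    rep_seeds = np.random.SeedSequence(seed).generate_state(
        n_replicates, dtype=np.uint32) % (2 ** 31)
    completed = 0
    for rs in rep_seeds:
        rs = int(rs)
        try:
            sub = sp.sample_independent_subset(table, y, 150.0, test="join_count",
                                               alpha=0.05, max_tries=100, seed=rs)
        except RuntimeError:
            continue
        st = table.set_index("id").loc[sub.ids].reset_index()
        ys = st["restored"].astype(bool).to_numpy()
        if ys.sum() < 5 or (~ys).sum() < 5:
            continue
        completed += 1
        w = np.where(ys, 1.0 / ys.mean(), 1.0 / (1.0 - ys.mean()))
        model = fit_brt(st[ss.PREDICTORS], ys,
                        dataclasses.replace(_fast_classifier(), seed=rs),
                        sample_weight=w / w.mean())
        infl = relative_influence(model)
        gravity_first += infl.index[0] == "gravity"

    w = np.where(y, 1.0 / y.mean(), 1.0 / (1.0 - y.mean()))
    full = fit_brt(table[ss.PREDICTORS], y, _fast_classifier(seed),
                   sample_weight=w / w.mean())
    curve = partial_dependence(full, "gravity")
    rho = float(spearmanr(curve["value"], curve["yhat"]).statistic)
    if completed == 0:
        raise RuntimeError("no replicate produced a usable independent subset")
    return {"gravity_first_fraction": gravity_first / completed,
            "n_replicates": completed,
            "gravity_pd_spearman": rho,
            "full_influence": relative_influence(full)}


def thinning_min_distance(seed: int, threshold_km: float = 150.0,
                          n_subsets: int = 20) -> dict:
    """Smallest pairwise distance over repeatedly thinned subsets."""
    cfg = planted_truth_config(seed, n_localities=800)
    loc = generate_grid(cfg).localities
    min_d = np.inf
    for s in range(n_subsets):
        sub = sp.thin_by_distance(loc, threshold_km, seed=seed + s)
        min_d = min(min_d, sub.min_pairwise_km)
    return {"min_pairwise_km": float(min_d), "threshold_km": threshold_km,
            "n_subsets": n_subsets}


def _rook_lattice(n_side: int) -> np.ndarray:
    n = n_side * n_side
    adj = np.zeros((n, n))
    for r in range(n_side):
        for c in range(n_side):
            i = r * n_side + c
            if c + 1 < n_side:
                adj[i, i + 1] = adj[i + 1, i] = 1
            if r + 1 < n_side:
                adj[i, i + n_side] = adj[i + n_side, i] = 1
    return adj


def join_count_type1_rate(seed: int, n_sims: int = 500,
                          n_side: int = 7, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the analytic same-class join-count test."""
    rng = np.random.default_rng(seed)
    adj = _rook_lattice(n_side)
    rejections = 0
    for _ in range(n_sims):
        labels = rng.integers(0, 2, n_side * n_side)
        if len(np.unique(labels)) < 2:
            continue
        res = sp.join_count_test(labels, adj)
        p = res.stats[(res.stats.class_a == 1) & (res.stats.class_b == 1)].p.iloc[0]
        rejections += p < alpha
    return {"type1_rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}


def moran_type1_rate(seed: int, n_sims: int = 500, n_points: int = 30,
                     alpha: float = 0.05) -> dict:
    """Empirical type-I error of the analytic Moran's I test on i.i.d. noise."""
    rng = np.random.default_rng(seed)
    lon = rng.uniform(-40, 40, n_points)
    lat = rng.uniform(-20, 20, n_points)
    w = sp.inverse_distance_weights(lon, lat)
    rejections = sum(sp.morans_i(rng.standard_normal(n_points), w).p < alpha
                     for _ in range(n_sims))
    return {"type1_rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}
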