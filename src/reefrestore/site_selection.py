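"""Stage 1 — modelling where restoration happens.

The response is the binary restored flag of each reef locality; the
predictors are gravity, remoteness, cumulative-impact mean and trend,
coral richness and the mean and trend of severe bleaching-alert counts
in the five years preceding a reference year.  Each replicate draws a
spatially independent locality subset (greedy 150 km thinning validated
by join-count statistics), splits it 80/20 stratified by class, weights
the classes inversely to their prevalence, fits a boosted-tree
classifier with cross-validated tree-count selection and evaluates the
true skill statistic at the TSS-maximizing probability threshold.
Replicate evaluations are aggregated (mean +/- s.d. of TSS and error
rates) and a full-data model provides relative influence and partial
dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import spatial_stats
from .brt_engine import BRTConfig, BRTModel, fit_brt, partial_dependence, relative_influence

PREDICTORS = ["gravity", "remoteness", "impact_mean", "impact_trend",
              "coral_richness", "alert_mean_pre", "alert_trend_pre"]


@dataclass
class ClassifierEval:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    @property
    def false_positive_rate(self) -> float:
        return 1.0 - self.specificity

    @property
    def false_negative_rate(self) -> float:
        return 1.0 - self.sensitivity


def tss_threshold_scan(probabilities, labels,
                       start: float = 0.001, stop: float = 0.900,
                       step: float = 0.001) -> ClassifierEval:
    """Evaluation at the TSS-maximizing probability threshold.

    Scans thresholds ``start, start+step, ..., stop`` (default the
    900-point grid 0.001...0.900); a probability at or above the
    threshold predicts the positive class.  Ties in TSS go to the
    smallest threshold.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(bool)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    thresholds = np.round(np.arange(start, stop + step / 2.0, step), 10)
    pos, neg = p[y], p[~y]
    # counts via sorted search: sensitivity = P(p >= t | y=1)
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / len(pos)
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / len(neg)
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # first max = smallest threshold on ties
    return ClassifierEval(threshold=float(thresholds[best]),
                          sensitivity=float(sens[best]),
                          specificity=float(spec[best]))


def collinearity_screen(features: pd.DataFrame,
                        r2_threshold: float = 0.7) -> pd.DataFrame:
    """All pairwise squared Pearson correlations, flagged at the threshold.

    Zero-variance features yield undefined (NaN) R-squared for their
    pairs and are flagged.  The analysis proceeds regardless; the table
    is a report, not a filter.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 features")
    corr = features.corr(numeric_only=True)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r2 = corr.iloc[i, j] ** 2
            rows.append({"feature_a": cols[i], "feature_b": cols[j],
                         "r2": float(r2) if pd.notna(r2) else np.nan,
                         "flagged": bool(pd.isna(r2) or r2 >= r2_threshold)})
    return pd.DataFrame(rows)


def alert_window_stats(alerts: pd.DataFrame, reference_years: pd.Series,
                       window: int = 5) -> pd.DataFrame:
    """Mean and OLS trend of severe-alert counts in the ``window`` years
    preceding each locality's reference year (years ref-window ... ref-1).
    """
    sev = alerts.assign(severe=alerts["level1_events"] + alerts["level2_events"])
    out = []
    for loc_id, ref in reference_years.items():
        sub = sev[(sev["locality_id"] == loc_id)
                  & (sev["year"] >= ref - window) & (sev["year"] <= ref - 1)]
        counts = sub.sort_values("year")["severe"].to_numpy(dtype=float)
        if len(counts) == 0:
            mean = trend = np.nan
        else:
            mean = float(counts.mean())
            trend = float(np.polyfit(np.arange(len(counts)), counts, 1)[0]) \
                if len(counts) > 1 else 0.0
        out.append({"id": loc_id, "alert_mean_pre": mean, "alert_trend_pre": trend})
    return pd.DataFrame(out)


def build_site_table(localities: pd.DataFrame, alerts: pd.DataFrame,
                     records: pd.DataFrame | None = None,
                     reference_year: int | None = None,
                     window: int = 5) -> pd.DataFrame:
    """Locality table augmented with pre-restoration alert predictors.

    Restored localities use their earliest restoration year as the
    reference; non-restored localities (and all localities when no
    records are given) use ``reference_year``, defaulting to the median
    restoration year of the records, or the last alert year when no
    records exist.  Rows with missing predictors are dropped.
    """
    loc = localities.copy()
    if records is not None and len(records) > 0:
        first_year = records.groupby("locality_id")["year"].min()
        default_year = int(records["year"].median()) if reference_year is None \
            else reference_year
    else:
        first_year = pd.Series(dtype=int)
        default_year = int(alerts["year"].max()) if reference_year is None \
            else reference_year
    refs = pd.Series(
        [int(first_year.get(i, default_year)) for i in loc["id"]],
        index=loc["id"].to_numpy())
    stats = alert_window_stats(alerts, refs, window=window)
    table = loc.merge(stats, on="id", how="left")
    n0 = len(table)
    table = table.dropna(subset=PREDICTORS)
    table.attrs["n_dropped"] = n0 - len(table)
    return table.reset_index(drop=True)


@dataclass
class SiteSelectionConfig:
    predictors: list[str] = field(default_factory=lambda: list(PREDICTORS))
    thinning_km: float = 150.0
    band_km: float | None = None         # join-count band; default 2x thinning
    alpha: float = 0.05
    max_tries: int = 200
    train_fraction: float = 0.8
    n_replicates: int = 1000
    brt: BRTConfig = field(default_factory=lambda: BRTConfig(
        learning_rate=0.001, bag_fraction=0.5, tree_complexity=3,
        loss="bernoulli"))
    seed: int = 0
    # "raise": a replicate whose subset sampler exhausts max_tries aborts the
    # run; "skip": it is dropped and counted in the aggregate
    on_exhausted: str = "raise"


@dataclass
class SelectionRunResult:
    replicates: pd.DataFrame          # one row per replicate evaluation
    aggregate: dict
    influence: pd.Series | None
    partial_dependence: dict[str, pd.DataFrame] | None
    full_model: BRTModel | None = None


def _prevalence_weights(y: np.ndarray) -> np.ndarray:
    prev_pos = y.mean()
    w = np.where(y, 1.0 / prev_pos, 1.0 / (1.0 - prev_pos))
    return w / w.mean()


def run_site_selection(table: pd.DataFrame,
                       config: SiteSelectionConfig,
                       fit_full_model: bool = True) -> SelectionRunResult:
    """Replicated spatially independent cross-validation of site choice."""
    missing = [c for c in config.predictors if c not in table.columns]
    if missing:
        raise ValueError(f"missing predictors: {missing}")
    y_all = table["restored"].astype(bool).to_numpy()
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.generate_state(config.n_replicates, dtype=np.uint32) % (2 ** 31)

    rows = []
    n_exhausted = 0
    for r in range(config.n_replicates):
        rs = int(rep_seeds[r])
        try:
            subset = spatial_stats.sample_independent_subset(
                table, y_all, config.thinning_km, test="join_count",
                alpha=config.alpha, max_tries=config.max_tries, seed=rs,
                band_km=config.band_km)
        except RuntimeError:
            if config.on_exhausted == "skip":
                n_exhausted += 1
                continue
            raise
        sub = table.set_index("id").loc[subset.ids].reset_index()
        y = sub["restored"].astype(bool).to_numpy()
        if y.sum() < 2 or (~y).sum() < 2:
            continue  # subset too lopsided to split by class
        X = sub[config.predictors]
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=config.train_fraction, stratify=y, random_state=rs)
        w_tr = _prevalence_weights(y_tr)
        brt = replace(config.brt, seed=rs)
        model = fit_brt(X_tr, y_tr, brt, sample_weight=w_tr)
        ev = tss_threshold_scan(model.predict(X_te), y_te)
        rows.append({"replicate": r, "seed": rs, "n_subset": len(sub),
                     "n_attempts": subset.n_attempts, "n_trees": model.n_trees,
                     "threshold": ev.threshold, "sensitivity": ev.sensitivity,
                     "specificity": ev.specificity, "tss": ev.tss,
                     "fpr": ev.false_positive_rate, "fnr": ev.false_negative_rate})
    reps = pd.DataFrame(rows)
    agg = {}
    for col in ("tss", "fpr", "fnr"):
        agg[f"{col}_mean"] = float(reps[col].mean()) if len(reps) else float("nan")
        agg[f"{col}_sd"] = float(reps[col].std(ddof=1)) if len(reps) > 1 else 0.0
    agg["n_replicates"] = int(len(reps))
    agg["n_exhausted"] = n_exhausted

    influence = pd_curves = full_model = None
    if fit_full_model:
        brt = replace(config.brt, seed=config.seed)
        w = _prevalence_weights(y_all)
        full_model = fit_brt(table[config.predictors], y_all, brt, sample_weight=w)
        influence = relative_influence(full_model)
        pd_curves = {v: partial_dependence(full_model, v)
                     for v in config.predictors}
    return SelectionRunResult(replicates=reps, aggregate=agg,
                              influence=influence,
                              partial_dependence=pd_curves,
                              full_model=full_model)
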