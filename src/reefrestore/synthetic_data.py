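"""Synthetic reef-grid, restoration-record and climate-series generator.

Everything downstream — site-selection modelling, success analysis,
thermal-exposure summaries — runs on four tables:

* ``localities``: one row per 0.5-degree grid cell with covariates
  (gravity, remoteness, cumulative-impact mean and trend, coral
  richness) and a restored flag,
* ``alerts``: annual counts of severe bleaching-alert events (levels I
  and II) per locality for 1986-2021,
* ``records``: restoration actions with technique flags, number of
  genera, monitoring duration and observed percent survival,
* ``dhw``: annual maximum degree-heating-weeks projections per locality
  for 2015-2100.

The generator plants a known truth in each table.  Restoration status
follows a logistic model of the covariates plus a spatially
autocorrelated Gaussian random field (exponential covariance over
great-circle distance), so restored cells are both covariate-driven and
spatially clustered, mirroring real siting behaviour.  Observed
survival follows the expected decay curve times multiplicative
log-normal noise, optionally shifted by technique effects.  DHW series
are a baseline plus a per-locality linear warming trend plus noise,
truncated at zero.

Default sizes mirror the global audit that motivated the package:
~3,900 reef localities of which ~6.5% are restored, and enough records
that ~130-250 survive scoring; tests and the fast pipeline mode scale
these down through a single ``scale`` factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .spatial_stats import pairwise_haversine_km
from .success_metric import DecayCurve

ALERT_YEARS = (1986, 2021)
DHW_YEARS = (2015, 2100)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; one integer seed governs everything."""

    n_localities: int = 3900
    restored_fraction: float = 0.065
    lat_range: tuple[float, float] = (-32.0, 32.0)

    # logistic coefficients on standardized covariates (planted truth)
    coef_gravity: float = 1.2
    coef_remoteness: float = -0.8
    coef_impact_mean: float = 0.5
    coef_impact_trend: float = 0.0
    coef_richness: float = -0.3

    # spatial random field on the logit scale
    spatial_range_km: float = 300.0
    spatial_sd: float = 1.0

    # covariate distribution parameters
    gravity_lognorm: tuple[float, float] = (1.0, 1.2)      # (mu, sigma) of log
    remoteness_norm: tuple[float, float] = (4.5, 1.5)      # log-minutes, floored at 0
    impact_gamma: tuple[float, float] = (4.0, 1.0)         # (shape, scale)
    impact_trend_sd: float = 0.3
    richness_mean: float = 250.0

    # restoration records
    records_per_locality_mean: float = 0.3                 # extra records beyond the first
    restoration_year_range: tuple[int, int] = (1992, 2016)
    monitoring_lognorm: tuple[float, float] = (2.3, 1.1)   # log-months
    monitoring_range: tuple[float, float] = (0.8, 144.0)
    technique_probs: tuple[float, float, float, float] = (0.55, 0.35, 0.15, 0.05)
    genera_mean: float = 1.2                               # n_genera = 1 + Poisson
    decay_rate_k: float = 0.08
    decay_asymptote: float = 20.0
    survival_noise_sd: float = 0.35
    survival_cap: float = 120.0
    technique_effects: dict = field(default_factory=dict)  # log-scale survival shifts

    # alert histories
    alert1_rate: float = 0.20                              # level-I events / year
    alert2_rate: float = 0.07                              # level-II events / year

    # DHW projections
    dhw_baseline: float = 2.0
    dhw_trend_mean: float = 0.30                           # deg-C-weeks / year
    dhw_trend_sd: float = 0.08
    dhw_noise_sd: float = 1.5

    seed: int = 0

    def validate(self) -> None:
        if self.n_localities <= 0:
            raise ValueError("n_localities must be positive")
        if not (0.0 <= self.restored_fraction <= 1.0):
            raise ValueError("restored_fraction must be in [0, 1]")
        if self.gravity_lognorm[1] <= 0 or self.impact_gamma[0] <= 0:
            raise ValueError("degenerate covariate variance")
        if self.survival_noise_sd < 0 or self.dhw_noise_sd < 0:
            raise ValueError("noise s.d. must be non-negative")
        if self.spatial_range_km < 0 or self.spatial_sd < 0:
            raise ValueError("spatial field parameters must be non-negative")

    def scaled(self, scale: float) -> "SimulationConfig":
        """Copy with the locality count scaled down by ``scale`` (for fast runs)."""
        return replace(self, n_localities=max(int(self.n_localities * scale), 20))

    def decay_curve(self) -> DecayCurve:
        return DecayCurve(rate_k=self.decay_rate_k, asymptote=self.decay_asymptote)


@dataclass
class ReefDataset:
    """The four synthetic tables plus the config that produced them."""

    localities: pd.DataFrame
    alerts: pd.DataFrame
    records: pd.DataFrame | None
    dhw: pd.DataFrame | None
    config: SimulationConfig

    def write_csv(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.localities.to_csv(out / "localities.csv", index=False)
        self.alerts.to_csv(out / "alerts.csv", index=False)
        if self.records is not None:
            self.records.to_csv(out / "records.csv", index=False)
        if self.dhw is not None:
            self.dhw.to_csv(out / "dhw.csv", index=False)
        (out / "seed.txt").write_text(f"seed={self.config.seed}\n")


def _child_rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _grid_cells(n: int, lat_range, rng) -> tuple[np.ndarray, np.ndarray]:
    # unique 0.5-degree cells, centres at x.25 / x.75
    lo, hi = lat_range
    n_lat = int((hi - lo) / 0.5)
    n_lon = 720
    total = n_lat * n_lon
    if n > total:
        raise ValueError("n_localities exceeds available grid cells")
    flat = rng.choice(total, size=n, replace=False)
    lat = lo + 0.25 + 0.5 * (flat // n_lon)
    lon = -180.0 + 0.25 + 0.5 * (flat % n_lon)
    return lon, lat


def _spatial_field(lon, lat, range_km, sd, rng) -> np.ndarray:
    n = len(lon)
    if range_km <= 0 or sd <= 0:
        return np.zeros(n)
    dm = pairwise_haversine_km(lon, lat)
    cov = sd * sd * np.exp(-dm / range_km)
    cov[np.diag_indices(n)] += 1e-8
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(n)


def generate_grid(config: SimulationConfig) -> ReefDataset:
    """Generate the locality table and its alert history.

    Restored flags are Bernoulli draws from a logistic model whose
    linear predictor combines standardized covariates (with the planted
    coefficients) and the spatial Gaussian field; the intercept is
    solved so the expected prevalence matches ``restored_fraction``.
    """
    config.validate()
    rng_cov, rng_field, rng_flag, rng_alert = _child_rngs(config.seed, 4)

    n = config.n_localities
    lon, lat = _grid_cells(n, config.lat_range, rng_cov)
    gravity = rng_cov.lognormal(*config.gravity_lognorm, n)
    remoteness = np.maximum(rng_cov.normal(*config.remoteness_norm, n), 0.0)
    impact_mean = rng_cov.gamma(config.impact_gamma[0], config.impact_gamma[1], n)
    impact_trend = rng_cov.normal(0.0, config.impact_trend_sd, n)
    richness = rng_cov.poisson(config.richness_mean, n).astype(int)

    def z(x):
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    eta = (config.coef_gravity * z(np.log(gravity))
           + config.coef_remoteness * z(remoteness)
           + config.coef_impact_mean * z(impact_mean)
           + config.coef_impact_trend * z(impact_trend)
           + config.coef_richness * z(richness.astype(float)))
    eta = eta + _spatial_field(lon, lat, config.spatial_range_km,
                               config.spatial_sd, rng_field)

    if config.restored_fraction == 0.0:
        restored = np.zeros(n, dtype=bool)
    elif config.restored_fraction == 1.0:
        restored = np.ones(n, dtype=bool)
    else:
        target = config.restored_fraction
        c = brentq(lambda b: expit(b + eta).mean() - target, -60.0, 60.0)
        restored = rng_flag.random(n) < expit(c + eta)

    localities = pd.DataFrame({
        "id": np.arange(n, dtype=int), "lon": lon, "lat": lat,
        "restored": restored, "gravity": gravity, "remoteness": remoteness,
        "impact_mean": impact_mean, "impact_trend": impact_trend,
        "coral_richness": richness,
    })

    years = np.arange(ALERT_YEARS[0], ALERT_YEARS[1] + 1)
    n_years = len(years)
    lvl1 = rng_alert.poisson(config.alert1_rate, (n, n_years))
    lvl2 = rng_alert.poisson(config.alert2_rate, (n, n_years))
    alerts = pd.DataFrame({
        "locality_id": np.repeat(np.arange(n), n_years),
        "year": np.tile(years, n),
        "level1_events": lvl1.ravel(),
        "level2_events": lvl2.ravel(),
    })
    return ReefDataset(localities=localities, alerts=alerts, records=None,
                       dhw=None, config=config)


def generate_records(localities: pd.DataFrame,
                     config: SimulationConfig) -> pd.DataFrame:
    """Generate restoration records for every restored locality.

    Observed survival is the decay-curve expectation at the monitoring
    time, times exp(technique effects + log-normal noise), capped at
    ``survival_cap`` percent.  With zero noise and no planted effects
    the observed survival equals the expectation exactly.
    """
    config.validate()
    restored = localities[localities["restored"].astype(bool)]
    if len(restored) == 0:
        raise ValueError("generate_records requires at least one restored locality")
    rng, = _child_rngs(config.seed + 1, 1)
    curve = config.decay_curve()
    names = ("gardening", "transplantation", "artificial_reef", "larval_enhancement")

    rows = []
    for _, loc in restored.iterrows():
        n_rec = 1 + rng.poisson(config.records_per_locality_mean)
        for _ in range(n_rec):
            year = int(rng.integers(config.restoration_year_range[0],
                                    config.restoration_year_range[1] + 1))
            months = float(np.clip(rng.lognormal(*config.monitoring_lognorm),
                                   *config.monitoring_range))
            flags = rng.random(4) < np.asarray(config.technique_probs)
            if not flags.any():
                flags[0] = True  # at least one technique per record
            shift = sum(config.technique_effects.get(nm, 0.0)
                        for nm, f in zip(names, flags) if f)
            noise = rng.normal(0.0, config.survival_noise_sd) \
                if config.survival_noise_sd > 0 else 0.0
            s_e = curve(months)
            s_o = min(s_e * np.exp(shift + noise), config.survival_cap)
            rows.append({
                "locality_id": int(loc["id"]), "year": year,
                "gardening": bool(flags[0]), "transplantation": bool(flags[1]),
                "artificial_reef": bool(flags[2]), "larval_enhancement": bool(flags[3]),
                "n_genera": int(1 + rng.poisson(config.genera_mean)),
                "monitoring_months": months,
                "observed_survival": float(s_o),
            })
    return pd.DataFrame(rows)


def generate_dhw_series(localities: pd.DataFrame,
                        config: SimulationConfig) -> pd.DataFrame:
    """Annual-maximum DHW projections 2015-2100 per locality.

    value(year) = baseline + trend * (year - 2015) + noise, truncated at
    zero; the warming trend varies across localities.
    """
    config.validate()
    rng, = _child_rngs(config.seed + 2, 1)
    n = len(localities)
    years = np.arange(DHW_YEARS[0], DHW_YEARS[1] + 1)
    trends = np.maximum(rng.normal(config.dhw_trend_mean, config.dhw_trend_sd, n), 0.0)
    vals = (config.dhw_baseline
            + trends[:, None] * (years[None, :] - DHW_YEARS[0]))
    if config.dhw_noise_sd > 0:
        vals = vals + rng.normal(0.0, config.dhw_noise_sd, vals.shape)
    vals = np.maximum(vals, 0.0)
    return pd.DataFrame({
        "locality_id": np.repeat(localities["id"].to_numpy(), len(years)),
        "year": np.tile(years, n),
        "dhw_max": vals.ravel(),
    })


def generate_dataset(config: SimulationConfig) -> ReefDataset:
    """Full synthetic world: grid + alerts + records + DHW projections."""
    ds = generate_grid(config)
    if ds.localities["restored"].any():
        ds.records = generate_records(ds.localities, config)
    ds.dhw = generate_dhw_series(ds.localities, config)
    return ds
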