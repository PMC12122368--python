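"""Standardized restoration-success statistic.

Short-term restoration outcomes are reported as percent survival of
outplanted colonies after widely varying monitoring durations (roughly
one month to twelve years), which makes raw survival values
incomparable across projects.  The statistic computed here standardizes
observed survival S_o against the survival S_e expected from a
calibrated decay curve at the same monitoring time:

    S_r = ln(1 + 100 - (S_e - S_o) / S_e * 100) = ln(1 + 100 * S_o / S_e)

so S_r = 0 for total mortality, and S_r = ln(101) ~= 4.6151 when the
observed survival exactly matches the expectation.

The expectation follows a shifted exponential decay

    S_e(t) = a + (100 - a) * exp(-k t)

with early mortality high and decreasing as colonies grow; the
asymptote a keeps S_e bounded away from zero at long monitoring times.
The default curve shipped with the package is fitted to a synthetic
stand-in calibration point set (see ``data/synthetic_decay_calibration.csv``);
analyses of real data should supply their own calibration points.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

LN_101 = float(np.log(101.0))


@dataclass
class DecayCurve:
    """Expected-survival curve S_e(t) = a + (100 - a) exp(-k t).

    Parameters
    ----------
    rate_k : decay rate per month, > 0 (0 allowed as the no-mortality limit)
    asymptote : long-term survival percent in [0, 100)
    """

    rate_k: float
    asymptote: float
    residual_ss: float = 0.0

    def __post_init__(self):
        if self.rate_k < 0:
            raise ValueError("decay rate must be non-negative")
        if not (0 <= self.asymptote < 100):
            raise ValueError("asymptote must be in [0, 100)")

    def __call__(self, months):
        return expected_survival(self, months)

    def to_json(self) -> str:
        return json.dumps({"rate_k": self.rate_k, "asymptote": self.asymptote,
                           "residual_ss": self.residual_ss})

    @classmethod
    def from_json(cls, s: str) -> "DecayCurve":
        d = json.loads(s)
        return cls(rate_k=d["rate_k"], asymptote=d["asymptote"],
                   residual_ss=d.get("residual_ss", 0.0))


def _curve(t, k, a):
    return a + (100.0 - a) * np.exp(-k * t)


def fit_decay_curve(points: pd.DataFrame) -> DecayCurve:
    """Least-squares fit of the shifted exponential to (months, survival) pairs.

    ``points`` needs columns ``months`` (>= 0) and ``survival_percent``
    (in [0, 100]).  At least 3 points are required.  An all-100% point
    set returns the no-mortality limit (k = 0, curve constant at 100).
    """
    t = np.asarray(points["months"], dtype=float)
    s = np.asarray(points["survival_percent"], dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 calibration points")
    if np.any(t < 0) or np.any(s < 0) or np.any(s > 100):
        raise ValueError("calibration points out of range")
    if np.allclose(s, 100.0):
        return DecayCurve(rate_k=0.0, asymptote=0.0, residual_ss=0.0)
    try:
        popt, _ = curve_fit(_curve, t, s, p0=(0.1, max(s.min() - 1.0, 0.0)),
                            bounds=([0.0, 0.0], [np.inf, 99.999]), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise RuntimeError(f"decay-curve fit did not converge: {exc}") from exc
    k, a = popt
    resid = float(np.sum((_curve(t, k, a) - s) ** 2))
    return DecayCurve(rate_k=float(k), asymptote=float(a), residual_ss=resid)


def default_curve() -> DecayCurve:
    """Curve fitted to the bundled synthetic stand-in calibration points."""
    return fit_decay_curve(load_default_calibration())


def load_default_calibration() -> pd.DataFrame:
    """Bundled synthetic stand-in calibration point set (months, survival_percent)."""
    ref = importlib.resources.files("reefrestore.data") / "synthetic_decay_calibration.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def expected_survival(curve: DecayCurve, months):
    """Expected percent survival after ``months`` of monitoring; in (0, 100]."""
    t = np.asarray(months, dtype=float)
    if np.any(t < 0):
        raise ValueError("months must be >= 0")
    out = _curve(t, curve.rate_k, curve.asymptote)
    return float(out) if out.ndim == 0 else out


def success_score(s_o, s_e):
    """Standardized success S_r = ln(1 + 100 * S_o / S_e).

    Identical to the expanded form ln(1 + 100 - (S_e - S_o)/S_e * 100).
    Requires S_o >= 0 and S_e > 0; S_r = 0 iff S_o = 0.
    """
    s_o = np.asarray(s_o, dtype=float)
    s_e = np.asarray(s_e, dtype=float)
    if np.any(s_e <= 0):
        raise ValueError("expected survival must be > 0")
    if np.any(s_o < 0):
        raise ValueError("observed survival must be >= 0")
    out = np.log1p(100.0 * s_o / s_e)
    return float(out) if out.ndim == 0 else out


@dataclass
class ScoredRecords:
    """Success scores plus a log of the records that could not be scored."""

    scores: pd.DataFrame  # record_id, locality_id, year, months, s_o, s_e, s_r
    n_excluded: int


def score_records(records: pd.DataFrame, curve: DecayCurve) -> ScoredRecords:
    """Compute S_r for every scorable record.

    Records missing ``observed_survival`` or ``monitoring_months`` (or
    with non-positive duration) are excluded and counted, mirroring the
    fact that standardized survival cannot be computed for every entry
    of a heterogeneous monitoring database.
    """
    rec = records.reset_index(drop=True)
    ok = rec["observed_survival"].notna() & rec["monitoring_months"].notna()
    ok &= rec["monitoring_months"] > 0
    usable = rec[ok]
    s_e = expected_survival(curve, usable["monitoring_months"].to_numpy())
    s_o = usable["observed_survival"].to_numpy(dtype=float)
    out = pd.DataFrame({
        "record_id": usable.index.to_numpy(),
        "locality_id": usable["locality_id"].to_numpy(),
        "year": usable["year"].to_numpy(),
        "monitoring_months": usable["monitoring_months"].to_numpy(dtype=float),
        "s_o": s_o,
        "s_e": np.atleast_1d(s_e),
        "s_r": np.atleast_1d(success_score(s_o, s_e)),
    })
    return ScoredRecords(scores=out, n_excluded=int((~ok).sum()))
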