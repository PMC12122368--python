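"""Stage 3 — past bleaching-alert exposure and future DHW exceedance.

Past exposure: for each locality and year window, counts of event-years
(years with at least one recorded event) at bleaching-alert level I or
worse and at level II, plus total event counts.  A rolling
restored-versus-control comparison reproduces the recently-restored
framing: for each target year, localities restored in the five
preceding years form the restored group and every other locality is a
control; the fraction of each group exposed that year is aggregated in
five-year bins labelled by their upper boundary.

Future exposure: annual-maximum projected DHW series (2015-2100) are
reduced per locality to the number of years at or above a mass-
mortality threshold (default 20 degC-weeks, where near-complete coral
mortality is expected) and the first year the threshold is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ALERT_YEARS = (1986, 2021)
DHW_YEARS = (2015, 2100)


@dataclass
class ExposureSummary:
    locality_id: int
    window: tuple[int, int]
    level1_or_worse_years: int   # event-years at level I or worse
    level2_years: int            # event-years at level II
    level1_or_worse_events: int  # total events, multiplicity kept
    level2_events: int


def count_alert_events(alerts: pd.DataFrame, locality_id: int,
                       window: tuple[int, int], level: int = 1) -> int:
    """Event-years in ``window`` (inclusive) at the given severity or worse.

    ``level=1`` counts years with any level-I or level-II event;
    ``level=2`` counts years with any level-II event.  The window must
    lie within the alert data coverage (1986-2021).
    """
    lo, hi = window
    if lo > hi:
        return 0
    if lo < ALERT_YEARS[0] or hi > ALERT_YEARS[1]:
        raise ValueError(f"window {window} outside alert coverage {ALERT_YEARS}")
    sub = alerts[(alerts["locality_id"] == locality_id)
                 & (alerts["year"] >= lo) & (alerts["year"] <= hi)]
    if level == 1:
        per_year = sub["level1_events"] + sub["level2_events"]
    elif level == 2:
        per_year = sub["level2_events"]
    else:
        raise ValueError("level must be 1 or 2")
    return int((per_year > 0).sum())


def exposure_summary(alerts: pd.DataFrame, locality_id: int,
                     window: tuple[int, int]) -> ExposureSummary:
    lo, hi = window
    sub = alerts[(alerts["locality_id"] == locality_id)
                 & (alerts["year"] >= lo) & (alerts["year"] <= hi)]
    sev = sub["level1_events"] + sub["level2_events"]
    return ExposureSummary(
        locality_id=locality_id, window=window,
        level1_or_worse_years=count_alert_events(alerts, locality_id, window, 1),
        level2_years=count_alert_events(alerts, locality_id, window, 2),
        level1_or_worse_events=int(sev.sum()),
        level2_events=int(sub["level2_events"].sum()))


def post_restoration_exposure(records: pd.DataFrame, alerts: pd.DataFrame,
                              window: int = 5) -> pd.DataFrame:
    """Per restored locality: exposure in the ``window`` years after its
    first restoration (restoration year excluded), clipped to data coverage.
    """
    first = records.groupby("locality_id")["year"].min()
    rows = []
    for lid, yr in first.items():
        lo = int(yr) + 1
        hi = min(int(yr) + window, ALERT_YEARS[1])
        if lo > ALERT_YEARS[1]:
            continue
        s = exposure_summary(alerts, int(lid), (max(lo, ALERT_YEARS[0]), hi))
        rows.append({"locality_id": int(lid), "restoration_year": int(yr),
                     "window_start": s.window[0], "window_end": s.window[1],
                     "level1_or_worse_years": s.level1_or_worse_years,
                     "level2_years": s.level2_years,
                     "level1_or_worse_events": s.level1_or_worse_events,
                     "level2_events": s.level2_events})
    return pd.DataFrame(rows)


def exposure_group_stats(exposure: pd.DataFrame) -> dict:
    """Headline fractions/means over restored localities' post windows."""
    n = len(exposure)
    ge1 = exposure["level1_or_worse_years"] >= 1
    ge2 = exposure["level2_years"] >= 1
    out = {"n_localities": int(n),
           "frac_level1_or_worse": float(ge1.mean()) if n else float("nan"),
           "frac_level2": float(ge2.mean()) if n else float("nan")}
    ev1 = exposure.loc[ge1, "level1_or_worse_events"]
    ev2 = exposure.loc[ge2, "level2_events"]
    out["events_mean_level1"] = float(ev1.mean()) if len(ev1) else float("nan")
    out["events_sd_level1"] = float(ev1.std(ddof=1)) if len(ev1) > 1 else 0.0
    out["events_mean_level2"] = float(ev2.mean()) if len(ev2) else float("nan")
    out["events_sd_level2"] = float(ev2.std(ddof=1)) if len(ev2) > 1 else 0.0
    return out


def restored_membership(records: pd.DataFrame, target_year: int,
                        lookback: int = 5) -> set:
    """Localities restored in the ``lookback`` years preceding ``target_year``
    (years target-lookback ... target-1)."""
    m = records[(records["year"] >= target_year - lookback)
                & (records["year"] <= target_year - 1)]
    return set(m["locality_id"].astype(int))


def yearly_group_fractions(localities: pd.DataFrame,
                           records: pd.DataFrame,
                           alerts: pd.DataFrame,
                           years=None, level: int = 1,
                           lookback: int = 5) -> pd.DataFrame:
    """Per target year: exposed fraction of recently restored vs control.

    A locality restored in year y belongs to the restored group for
    target years y+1 ... y+lookback only; every other locality is a
    control, so the two groups partition the locality set each year.
    Years with an empty restored group get an undefined (NaN) restored
    fraction.
    """
    if years is None:
        years = range(ALERT_YEARS[0], ALERT_YEARS[1] + 1)
    years = list(years)
    if min(years) < ALERT_YEARS[0] or max(years) > ALERT_YEARS[1]:
        raise ValueError("requested years outside alert coverage")
    all_ids = set(localities["id"].astype(int))
    per_year = []
    for y in years:
        sub = alerts[alerts["year"] == y]
        if level == 1:
            exposed = set(sub.loc[(sub["level1_events"] + sub["level2_events"]) > 0,
                                  "locality_id"].astype(int))
        else:
            exposed = set(sub.loc[sub["level2_events"] > 0, "locality_id"].astype(int))
        restored = restored_membership(records, y, lookback) & all_ids
        control = all_ids - restored
        fr = len(exposed & restored) / len(restored) if restored else np.nan
        fc = len(exposed & control) / len(control) if control else np.nan
        per_year.append({"year": y, "n_restored": len(restored),
                         "n_control": len(control),
                         "frac_restored": fr, "frac_control": fc})
    return pd.DataFrame(per_year)


def restored_vs_control_fractions(localities: pd.DataFrame,
                                  records: pd.DataFrame,
                                  alerts: pd.DataFrame,
                                  years=None, bin_width: int = 5,
                                  level: int = 1) -> pd.DataFrame:
    """Yearly exposed fractions of recently restored vs control localities,
    aggregated in ``bin_width``-year bins labelled by the upper boundary
    (1990 = 1986-1990).

    Years with an empty restored group have an undefined restored
    fraction and are excluded from that bin's restored mean; the
    excluded-year count is recorded per bin.
    """
    df = yearly_group_fractions(localities, records, alerts, years, level)
    df["bin"] = ALERT_YEARS[0] - 1 + bin_width * np.ceil(
        (df["year"] - (ALERT_YEARS[0] - 1)) / bin_width).astype(int)
    out = df.groupby("bin").agg(
        frac_restored_mean=("frac_restored", "mean"),
        frac_restored_sd=("frac_restored", lambda s: s.std(ddof=1) if s.notna().sum() > 1 else 0.0),
        frac_control_mean=("frac_control", "mean"),
        frac_control_sd=("frac_control", lambda s: s.std(ddof=1) if s.notna().sum() > 1 else 0.0),
        n_years=("year", "size"),
        n_undefined_restored=("frac_restored", lambda s: int(s.isna().sum())),
    ).reset_index()
    return out


@dataclass
class DHWSummary:
    locality_id: int
    n_exceedance_years: int
    first_exceedance_year: int | None


def dhw_exceedance(dhw: pd.DataFrame, threshold: float = 20.0,
                   years: tuple[int, int] = DHW_YEARS) -> pd.DataFrame:
    """Per-locality exceedance summary of annual-max DHW projections.

    Counts years with dhw_max >= threshold (inclusive comparison) and
    the first such year.  Localities with no series in the window are
    excluded.
    """
    lo, hi = years
    sub = dhw[(dhw["year"] >= lo) & (dhw["year"] <= hi)]
    rows = []
    for lid, grp in sub.groupby("locality_id"):
        vals = grp.sort_values("year")
        hit = vals.loc[vals["dhw_max"] >= threshold, "year"]
        rows.append({"locality_id": int(lid),
                     "n_exceedance_years": int(len(hit)),
                     "first_exceedance_year": int(hit.iloc[0]) if len(hit) else np.nan})
    return pd.DataFrame(rows)


def dhw_group_summary(summaries: pd.DataFrame,
                      localities: pd.DataFrame) -> dict:
    """Restored-vs-other aggregates of the exceedance summaries."""
    merged = summaries.merge(localities[["id", "restored"]],
                             left_on="locality_id", right_on="id")
    out = {}
    for name, grp in (("all", merged),
                      ("restored", merged[merged["restored"].astype(bool)]),
                      ("control", merged[~merged["restored"].astype(bool)])):
        if len(grp) == 0:
            out[name] = {"n": 0}
            continue
        first = grp["first_exceedance_year"].dropna()
        out[name] = {
            "n": int(len(grp)),
            "frac_with_exceedance": float((grp["n_exceedance_years"] >= 1).mean()),
            "events_mean": float(grp["n_exceedance_years"].mean()),
            "events_sd": float(grp["n_exceedance_years"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "first_year_mean": float(first.mean()) if len(first) else float("nan"),
            "first_year_sd": float(first.std(ddof=1)) if len(first) > 1 else 0.0,
        }
    return out
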