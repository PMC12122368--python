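"""Great-circle geometry and spatial-independence machinery.

Reef localities live on a 0.5-degree grid, so all geometry is spherical:
distances are haversine great-circle distances on a sphere of radius
6,371 km.  The module provides the greedy distance-thinning sampler used
to build spatially independent locality subsets, join-count statistics
for categorical labels (restored / non-restored), Moran's I for
continuous values (restoration success), and a rejection sampler that
repeats the thinning until the chosen independence test is
non-significant.

Join-count and Moran null distributions follow the classical
randomization (non-free sampling) moments of Cliff & Ord: labels are
held fixed and permuted over positions.  Both tests also expose a
Monte-Carlo permutation p-value, which the test suite uses as an
independent oracle for the analytic formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# great-circle geometry
# ---------------------------------------------------------------------------

def _check_lonlat(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(lon < -180.0) or np.any(lon >= 180.0 + 1e-9):
        raise ValueError("longitude out of range [-180, 180)")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in kilometres between points in degrees.

    Accepts scalars or broadcastable arrays.  Symmetric, non-negative and
    zero only for identical points; Earth radius fixed at 6,371 km.
    """
    _check_lonlat(lon1, lat1)
    _check_lonlat(lon2, lat2)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    if np.isscalar(lon1) or d.ndim == 0:
        return float(d)
    return d


def pairwise_haversine_km(lons, lats) -> np.ndarray:
    """Full pairwise great-circle distance matrix (km)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


# ---------------------------------------------------------------------------
# spatial thinning
# ---------------------------------------------------------------------------

@dataclass
class SpatialSubset:
    """A distance-thinned subset of localities plus its independence test."""

    ids: np.ndarray
    threshold_km: float
    min_pairwise_km: float
    independence_p: float | None = None
    accepted: bool = False
    n_attempts: int = 0
    test_detail: object = None

    def __len__(self) -> int:
        return len(self.ids)


def thin_by_distance(localities: pd.DataFrame, threshold_km: float,
                     seed: int | np.random.Generator | None = 0) -> SpatialSubset:
    """Greedy sequential distance thinning.

    Iterates through the localities in a seeded random order, starting
    from a randomly selected one, and keeps a locality only if it lies
    strictly more than ``threshold_km`` (haversine) from every locality
    already kept.

    ``localities`` needs columns ``id``, ``lon``, ``lat``.
    """
    if len(localities) == 0:
        raise ValueError("thin_by_distance: empty locality table")
    if threshold_km <= 0:
        raise ValueError("threshold_km must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = rng.permutation(len(localities))
    lon = localities["lon"].to_numpy(dtype=float)[order]
    lat = localities["lat"].to_numpy(dtype=float)[order]
    ids = localities["id"].to_numpy()[order]

    kept_idx: list[int] = [0]
    kept_lon = [lon[0]]
    kept_lat = [lat[0]]
    for i in range(1, len(lon)):
        d = haversine_km(np.array(kept_lon), np.array(kept_lat), lon[i], lat[i])
        if np.min(d) > threshold_km:
            kept_idx.append(i)
            kept_lon.append(lon[i])
            kept_lat.append(lat[i])
    kept_idx = np.asarray(kept_idx)
    if len(kept_idx) > 1:
        dm = pairwise_haversine_km(np.asarray(kept_lon), np.asarray(kept_lat))
        min_pair = float(np.min(dm[np.triu_indices(len(kept_idx), k=1)]))
    else:
        min_pair = float("inf")
    return SpatialSubset(ids=ids[kept_idx], threshold_km=float(threshold_km),
                         min_pairwise_km=min_pair)


# ---------------------------------------------------------------------------
# neighbour graphs / weights
# ---------------------------------------------------------------------------

def distance_band_adjacency(lons, lats, band_km: float) -> np.ndarray:
    """Symmetric 0/1 adjacency: neighbours iff 0 < distance <= band_km."""
    dm = pairwise_haversine_km(lons, lats)
    adj = (dm > 0) & (dm <= band_km)
    np.fill_diagonal(adj, False)
    return adj.astype(float)


def inverse_distance_weights(lons, lats, min_km: float = 1.0) -> np.ndarray:
    """Inverse great-circle-distance weights, distances floored at min_km."""
    dm = pairwise_haversine_km(lons, lats)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(dm, min_km)
    np.fill_diagonal(w, 0.0)
    return w


# ---------------------------------------------------------------------------
# join-count statistics
# ---------------------------------------------------------------------------

@dataclass
class JoinCountResult:
    """Join counts against the random-labelling (non-free sampling) null.

    ``stats`` has one row per class pair (same-class pairs as
    ``("a","a")`` and the pooled cross-class row as ``("a","b")``) with
    observed and expected counts, variance, z-score and two-sided p.
    """

    stats: pd.DataFrame
    n_edges: int
    degenerate: bool = False

    def same_class_p(self) -> float:
        """Smallest two-sided p over same-class join rows."""
        if self.degenerate:
            return float("nan")
        same = self.stats[self.stats["class_a"] == self.stats["class_b"]]
        return float(same["p"].min())


def _pair_probs(counts: np.ndarray, n: int):
    # falling-factorial label-draw probabilities under permutation
    def ff(m, k):
        out = 1.0
        for j in range(k):
            out *= (m - j)
        return out
    return ff, float(ff(n, 2)), float(ff(n, 3)), float(ff(n, 4))


def join_count_test(labels, adjacency: np.ndarray,
                    n_permutations: int = 0,
                    seed: int | None = 0) -> JoinCountResult:
    """Join-count test for categorical labels on a neighbour graph.

    Same-class join counts are compared with their expectation and
    variance under random relabelling with the class counts held fixed.
    With ``n_permutations > 0`` a permutation p-value column ``p_perm``
    is added (same-class rows only).

    Single-class labellings yield a degenerate (flagged) result rather
    than an error.
    """
    labels = np.asarray(labels)
    adjacency = np.asarray(adjacency, dtype=float)
    n = len(labels)
    if adjacency.shape != (n, n):
        raise ValueError("adjacency shape does not match labels")
    iu, ju = np.where(np.triu(adjacency > 0, k=1))
    m = len(iu)
    if m == 0:
        raise ValueError("neighbour graph has no edges")
    classes, inv = np.unique(labels, return_inverse=True)
    deg = adjacency.sum(axis=1)
    # pairs of distinct edges sharing a vertex
    D = float(np.sum(deg * (deg - 1)) / 2.0)

    if len(classes) < 2:
        row = {"class_a": classes[0], "class_b": classes[0], "observed": float(m),
               "expected": float(m), "variance": 0.0, "z": np.nan, "p": np.nan}
        return JoinCountResult(stats=pd.DataFrame([row]), n_edges=m, degenerate=True)

    ff, f2, f3, f4 = _pair_probs(None, n)
    rows = []
    la, lb = inv[iu], inv[ju]
    for c, cls in enumerate(classes):
        n1 = int(np.sum(inv == c))
        obs = float(np.sum((la == c) & (lb == c)))
        p2 = ff(n1, 2) / f2
        p3 = ff(n1, 3) / f3
        p4 = ff(n1, 4) / f4
        e = m * p2
        e2 = m * p2 + 2.0 * D * p3 + (m * (m - 1.0) - 2.0 * D) * p4
        var = max(e2 - e * e, 0.0)
        z = (obs - e) / np.sqrt(var) if var > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"class_a": cls, "class_b": cls, "observed": obs,
                     "expected": e, "variance": var, "z": z, "p": p})

    # pooled cross-class joins (complement of all same-class joins)
    same_obs = sum(r["observed"] for r in rows)
    same_e = sum(r["expected"] for r in rows)
    bw_obs = m - same_obs
    bw_e = m - same_e
    if len(classes) == 2:
        n1 = int(np.sum(inv == 0))
        n2 = n - n1
        e_bw = m * 2.0 * n1 * n2 / f2
        share = (n1 * n2 * (n2 - 1.0) + n2 * n1 * (n1 - 1.0)) / f3
        disjoint = 4.0 * n1 * n2 * (n1 - 1.0) * (n2 - 1.0) / f4
        e2_bw = m * (2.0 * n1 * n2 / f2) + 2.0 * D * share \
            + (m * (m - 1.0) - 2.0 * D) * disjoint
        var_bw = max(e2_bw - e_bw * e_bw, 0.0)
        z_bw = (bw_obs - e_bw) / np.sqrt(var_bw) if var_bw > 0 else np.nan
        p_bw = 2.0 * stats.norm.sf(abs(z_bw)) if np.isfinite(z_bw) else np.nan
    else:
        var_bw = z_bw = p_bw = np.nan
    rows.append({"class_a": classes[0], "class_b": classes[-1], "observed": bw_obs,
                 "expected": bw_e, "variance": var_bw, "z": z_bw, "p": p_bw})
    table = pd.DataFrame(rows)

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        same_counts = np.zeros((n_permutations, len(classes)))
        for b in range(n_permutations):
            perm = rng.permutation(inv)
            pa, pb = perm[iu], perm[ju]
            for c in range(len(classes)):
                same_counts[b, c] = np.sum((pa == c) & (pb == c))
        p_perm = np.full(len(table), np.nan)
        for c in range(len(classes)):
            obs = table.loc[c, "observed"]
            e = table.loc[c, "expected"]
            # two-sided: permuted count at least as far from expectation
            p_perm[c] = (1.0 + np.sum(np.abs(same_counts[:, c] - e) >=
                                      abs(obs - e) - 1e-12)) / (n_permutations + 1.0)
        table["p_perm"] = p_perm
    return JoinCountResult(stats=table, n_edges=m)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float
    p_perm: float | None = None


def morans_i(values, weights: np.ndarray,
             n_permutations: int = 0,
             seed: int | None = 0) -> MoranResult:
    """Moran's I with the randomization-null normal approximation.

    ``weights`` is any non-negative spatial weight matrix; rows are
    standardized to sum to one internally (isolated rows stay zero).
    Set ``n_permutations`` for an additional permutation p-value.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 observations")
    if np.var(x) == 0:
        raise ValueError("Moran's I undefined for constant values")
    w = np.asarray(weights, dtype=float).copy()
    if w.shape != (n, n):
        raise ValueError("weights shape does not match values")
    np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1)
    nz = rs > 0
    w[nz] = w[nz] / rs[nz, None]

    z = x - x.mean()
    s0 = w.sum()
    num = z @ w @ z
    I = (n / s0) * num / (z @ z)

    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    e_i = -1.0 / (n - 1)
    b2 = n * np.sum(z ** 4) / (np.sum(z ** 2) ** 2)
    var = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)) \
        / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i * e_i
    zscore = (I - e_i) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(n_permutations)
        for b in range(n_permutations):
            zp = rng.permutation(z)
            sims[b] = (n / s0) * (zp @ w @ zp) / (zp @ zp)
        p_perm = float((1.0 + np.sum(np.abs(sims - e_i) >= abs(I - e_i) - 1e-15))
                       / (n_permutations + 1.0))
    return MoranResult(I=float(I), expected=float(e_i), variance=float(var),
                       z=float(zscore), p=float(p), p_perm=p_perm)


# ---------------------------------------------------------------------------
# rejection sampler for independent subsets
# ---------------------------------------------------------------------------

def sample_independent_subset(localities: pd.DataFrame, labels,
                              threshold_km: float,
                              test: str = "join_count",
                              alpha: float = 0.05,
                              max_tries: int = 100,
                              seed: int | np.random.Generator | None = 0,
                              band_km: float | None = None) -> SpatialSubset:
    """Draw distance-thinned subsets until the independence test passes.

    ``test`` is ``"join_count"`` for a categorical label (accepted when
    every same-class join count is consistent with random labelling at
    ``alpha``) or ``"morans_i"`` for a continuous label (accepted when
    the Moran p-value exceeds ``alpha``).  The join-count neighbour
    graph is a distance band of ``band_km`` (default twice the thinning
    threshold).  Raises ``RuntimeError`` when ``max_tries`` is
    exhausted.
    """
    if test not in ("join_count", "morans_i"):
        raise ValueError(f"unknown independence test: {test!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if band_km is None:
        band_km = 2.0 * threshold_km
    labels = np.asarray(labels)
    loc = localities.reset_index(drop=True)
    id_to_row = pd.Series(np.arange(len(loc)), index=loc["id"].to_numpy())

    for attempt in range(1, max_tries + 1):
        subset = thin_by_distance(loc, threshold_km, rng)
        rows = id_to_row[subset.ids].to_numpy()
        sub_lab = labels[rows]
        lons = loc["lon"].to_numpy()[rows]
        lats = loc["lat"].to_numpy()[rows]
        if test == "join_count":
            if len(np.unique(sub_lab)) < 2:
                continue
            adj = distance_band_adjacency(lons, lats, band_km)
            if adj.sum() == 0:
                continue
            res = join_count_test(sub_lab, adj)
            pval = res.same_class_p()
        else:
            if len(rows) < 4 or np.var(sub_lab.astype(float)) == 0:
                continue
            w = inverse_distance_weights(lons, lats)
            res = morans_i(sub_lab.astype(float), w)
            pval = res.p
        if np.isfinite(pval) and pval > alpha:
            subset.independence_p = float(pval)
            subset.accepted = True
            subset.n_attempts = attempt
            subset.test_detail = res
            return subset
    raise RuntimeError(
        f"no spatially independent subset at alpha={alpha} within {max_tries} tries")
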