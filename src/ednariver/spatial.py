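"""Spatial structure: network distances, the Moran correlogram, the
distance-weighted autocovariate, and the AutoCor residual covariate.

The correlogram and autocovariate operate on great-circle (haversine)
coordinates; network distances along the drainage tree serve the
upstream–downstream gradient analyses.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import RiverNetwork

EARTH_RADIUS_KM = 6371.0088


def distance_to_outlet(net: RiverNetwork, site: str) -> float:
    """Sum of edge lengths along the unique path from ``site`` to the outlet."""
    if site not in net.graph:
        raise KeyError(f"site {site!r} not in network")
    total = 0.0
    node = site
    while node != net.outlet:
        parent = net.parent_of(node)
        total += net.graph.edges[node, parent]["length_km"]
        node = parent
    return total


def haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) from degree coordinates."""
    phi = np.radians(np.asarray(lat, float))[:, None]
    lam = np.radians(np.asarray(lon, float))[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    a = np.sin(dphi / 2) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with an explicit (symmetric, zero-diagonal) weight matrix."""
    z = np.asarray(values, float)
    z = z - z.mean()
    denom = (z**2).sum()
    if denom == 0:
        raise ValueError("constant values: Moran's I undefined")
    w_sum = weights.sum()
    if w_sum == 0:
        return float("nan")
    n = len(z)
    return float(n / w_sum * (weights * np.outer(z, z)).sum() / denom)


@dataclass
class CorrelogramClass:
    lower_km: float
    upper_km: float
    midpoint_km: float
    n_pairs: int
    moran_i: float
    p_value: float


@dataclass
class Correlogram:
    classes: list[CorrelogramClass]
    first_significant_km: float | None  # smallest significant class midpoint

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lower_km": c.lower_km,
                    "upper_km": c.upper_km,
                    "midpoint_km": c.midpoint_km,
                    "n_pairs": c.n_pairs,
                    "moran_i": c.moran_i,
                    "p": c.p_value,
                }
                for c in self.classes
            ]
        )


def moran_correlogram(
    values: np.ndarray | pd.Series,
    coords: pd.DataFrame,
    n_classes: int = 8,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> Correlogram:
    """Moran correlogram over equal-count great-circle distance classes.

    Per class, binary weights select the pairs falling in the class;
    significance is a two-sided permutation test (add-one rule) of the
    distance of I from its null mean −1/(n−1).  Also reports the smallest
    significant class midpoint, or None.
    """
    y = np.asarray(values, float)
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 sites for a correlogram")
    if np.ptp(y) == 0:
        raise ValueError("constant values: zero variance")
    dist = haversine_matrix(coords["lat"].values, coords["lon"].values)
    iu = np.triu_indices(n, k=1)
    pair_d = dist[iu]
    edges = np.quantile(pair_d, np.linspace(0, 1, n_classes + 1))
    edges[0] = 0.0
    edges[-1] = pair_d.max() + 1e-9
    rng = np.random.default_rng(seed)
    null_mean = -1.0 / (n - 1)
    classes = []
    first_sig = None
    for c in range(n_classes):
        in_class = (dist > edges[c]) & (dist <= edges[c + 1])
        np.fill_diagonal(in_class, False)
        w = in_class.astype(float)
        n_pairs = int(w.sum() // 2)
        if n_pairs == 0:
            continue
        i_obs = morans_i(y, w)
        stat_obs = abs(i_obs - null_mean)
        exceed = 0
        for _ in range(n_perm):
            i_perm = morans_i(rng.permutation(y), w)
            if abs(i_perm - null_mean) >= stat_obs:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
        mid = (edges[c] + edges[c + 1]) / 2
        classes.append(CorrelogramClass(edges[c], edges[c + 1], mid, n_pairs, i_obs, p))
        if p < alpha and first_sig is None:
            first_sig = mid
    return Correlogram(classes, first_sig)


def autocovariate(
    values: np.ndarray | pd.Series,
    coords: pd.DataFrame,
    radius_km: float,
    weighting: str = "inverse_distance",
) -> np.ndarray:
    """Distance-weighted mean of neighbouring values within ``radius_km``.

    a_i = Σ_j w_ij · y_j / Σ_j w_ij over neighbours 0 < d_ij ≤ radius, with
    w_ij = 1/d_ij (default) or 1.  Sites with no neighbour get 0, with a warning.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    y = np.asarray(values, float)
    dist = haversine_matrix(coords["lat"].values, coords["lon"].values)
    n = len(y)
    out = np.zeros(n)
    isolated = []
    for i in range(n):
        mask = (dist[i] > 0) & (dist[i] <= radius_km)
        if not mask.any():
            isolated.append(i)
            continue
        if weighting == "inverse_distance":
            w = 1.0 / dist[i, mask]
        elif weighting == "equal":
            w = np.ones(mask.sum())
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        out[i] = float((w * y[mask]).sum() / w.sum())
    if isolated:
        warnings.warn(f"{len(isolated)} isolated site(s) got autocovariate 0", stacklevel=2)
    return out


def autocor_covariate(auto: np.ndarray, response: np.ndarray | pd.Series) -> np.ndarray:
    """Residuals of an intercept+slope fit of the response on the autocovariate.

    When the autocovariate has zero variance the centred response is returned
    with a warning.
    """
    a = np.asarray(auto, float)
    y = np.asarray(response, float)
    if len(a) != len(y):
        raise ValueError("length mismatch")
    if np.ptp(a) == 0:
        warnings.warn("zero-variance autocovariate: AutoCor = centred response", stacklevel=2)
        return y - y.mean()
    X = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def spatial_covariates(
    response: pd.Series,
    footprint: pd.Series,
    coords: pd.DataFrame,
    n_classes: int = 8,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[np.ndarray, Correlogram]:
    """AutoCor covariate per the coupled recipe.

    The correlogram of the footprint gradient supplies the radius (first
    significant distance, falling back to the first class upper bound); the
    autocovariate of the response within that radius is regressed out of the
    response, and the residuals are returned as AutoCor.
    """
    corr = moran_correlogram(footprint, coords, n_classes=n_classes, n_perm=n_perm, seed=seed)
    if corr.first_significant_km is not None:
        radius = corr.first_significant_km
    elif corr.classes:
        radius = corr.classes[0].upper_km
    else:
        raise ValueError("correlogram produced no distance classes")
    auto = autocovariate(response, coords, radius)
    return autocor_covariate(auto, response), corr
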