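"""The three biodiversity facets — taxonomic richness, convex-hull functional
richness in a PCoA trait space, and per-order nucleotide diversity — plus
Chao2 incidence-based richness extrapolation.

Functional richness follows the Villéger framework: raw morphological
measurements are combined into unitless ratios, scale-centred, embedded by
PCoA (Euclidean distances, hence equivalent to PCA), and each site's hull
volume is normalised by the species-pool hull so FD ∈ [0, 1].
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io_formats import SequenceRecord
from .taxonomy import TaxonAssignment

#: Default 9-ratio catalogue over the 11 raw measurements (numerator, denominator).
#: Bl/Bd is body elongation, CFd/CPd caudal throttling; the remainder are the
#: standard feeding/locomotion ratios built from head, eye, jaw and fin measures.
DEFAULT_RATIOS: tuple[tuple[str, str], ...] = (
    ("Bl", "Bd"),   # body elongation
    ("CFd", "CPd"),  # caudal-propulsion throttling
    ("Hd", "Bd"),   # relative head depth
    ("Ed", "Hd"),   # relative eye size
    ("Eh", "Hd"),   # eye position
    ("Jl", "Hd"),   # relative jaw length
    ("Om", "Bd"),   # oral gape position
    ("PFl", "Bl"),  # pectoral fin length
    ("PFp", "Bd"),  # pectoral fin position
)

RAW_TRAITS = ("Bl", "Bd", "Hd", "CPd", "CFd", "Ed", "Eh", "Om", "Jl", "PFl", "PFp")


def taxonomic_richness(incidence: pd.DataFrame) -> pd.Series:
    """ASV count per site (row sums of the curated incidence table)."""
    return incidence.sum(axis=1).astype(int)


def trait_ratios(
    raw: pd.DataFrame,
    catalogue: Sequence[tuple[str, str]] = DEFAULT_RATIOS,
) -> pd.DataFrame:
    """Unitless trait ratios from raw measurements (asv × measurement).

    Zero denominators yield explicit missing values, to be filled by
    :func:`impute_traits`.  Ratios are invariant to uniform rescaling of the
    underlying image.
    """
    out = {}
    for num, den in catalogue:
        d = raw[den].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = raw[num].astype(float) / d
        out[f"{num}/{den}"] = r.where(d != 0, np.nan)
    return pd.DataFrame(out, index=raw.index)


def impute_traits(traits: pd.DataFrame, lineage: pd.DataFrame) -> pd.DataFrame:
    """Fill missing ratios with nearest-taxonomic-group means.

    For each gap, the mean of that column over the ASV's genus is used; if no
    genus-mate has a value the family mean is used, then the order mean, then
    the global column mean.  ``lineage`` is indexed by asv_id with genus /
    family / order columns.  A column with no observed value at all is an error.
    """
    filled = traits.copy().astype(float)
    for col in filled.columns:
        if filled[col].isna().all():
            raise ValueError(f"trait column {col!r} has no observed values")
    for col in filled.columns:
        missing = filled.index[filled[col].isna()]
        for asv in missing:
            value = np.nan
            for rank in ("genus", "family", "order"):
                group = lineage.index[lineage[rank] == lineage.loc[asv, rank]]
                vals = traits.loc[traits.index.intersection(group), col].dropna()
                if len(vals):
                    value = float(vals.mean())
                    break
            if np.isnan(value):
                value = float(traits[col].mean())
            filled.loc[asv, col] = value
    return filled


@dataclass
class FunctionalSpace:
    """PCoA embedding of the scale-centred trait matrix."""

    coords: pd.DataFrame           # asv × axes, ordered by decreasing eigenvalue
    variance_explained: np.ndarray  # fraction per axis
    k: int                          # retained axes: cumulative variance ≥ 0.95,
    #                                 floored at 2 (capped by the matrix rank)

    @property
    def retained(self) -> pd.DataFrame:
        return self.coords.iloc[:, : self.k]


def functional_space(traits: pd.DataFrame, min_cum_variance: float = 0.95) -> FunctionalSpace:
    """Scale-centre columns and embed by PCoA on Euclidean distances.

    For Euclidean input PCoA coincides with PCA, so the embedding is computed
    from the SVD of the standardised matrix; variance fractions are the
    eigenvalue ratios.
    """
    if traits.shape[0] < 3:
        raise ValueError("need at least 3 ASVs for a functional space")
    X = traits.astype(float).values
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    nonconstant = sd > 0
    X = X[:, nonconstant] / sd[nonconstant]
    if X.shape[1] == 0:
        raise ValueError("trait matrix has rank 0 after scaling")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    eig = s**2
    keep = eig > eig[0] * 1e-12 if eig[0] > 0 else np.zeros_like(eig, bool)
    if not keep.any():
        raise ValueError("trait matrix has rank 0")
    eig = eig[keep]
    coords = u[:, keep] * s[keep]
    frac = eig / eig.sum()
    k = max(2, int(np.searchsorted(np.cumsum(frac), min_cum_variance) + 1))
    k = min(k, coords.shape[1])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return FunctionalSpace(pd.DataFrame(coords, index=traits.index, columns=cols), frac, k)


def _hull_volume(points: np.ndarray) -> float:
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0


def functional_richness(space: FunctionalSpace, incidence: pd.DataFrame) -> pd.Series:
    """Per-site convex-hull volume in the retained axes, pool-normalised.

    FD(site) = hull(site ASVs) / hull(all ASVs) ∈ [0, 1].  Sites with fewer
    than k+1 ASVs, or whose points are degenerate (flat) in the retained
    space, get FD = 0 with a warning.
    """
    coords = space.retained
    pool_volume = _hull_volume(coords.values)
    if pool_volume <= 0:
        raise ValueError("degenerate ASV pool: zero hull volume")
    k = space.k
    fd = {}
    degenerate = []
    for site in incidence.index:
        present = incidence.columns[incidence.loc[site] > 0]
        present = coords.index.intersection(present)
        if len(present) < k + 1:
            fd[site] = 0.0
            degenerate.append(site)
            continue
        vol = _hull_volume(coords.loc[present].values)
        if vol <= 0:
            fd[site] = 0.0
            degenerate.append(site)
        else:
            fd[site] = vol / pool_volume
    if degenerate:
        warnings.warn(
            f"FD set to 0 for degenerate sites: {degenerate}", stacklevel=2
        )
    return pd.Series(fd, name="FD")


# ---------------------------------------------------------------------------
# Genetic diversity


def nucleotide_diversity(seqs: Sequence[str]) -> float:
    """Mean pairwise proportion of differing positions (π).

    Sequences must be aligned to equal length.  A gap opposite a base counts
    as a difference; columns where both sequences are gapped are excluded
    from that pair's length.  Undefined (NaN) for fewer than two sequences.
    """
    if len(seqs) < 2:
        return float("nan")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    total = 0.0
    npairs = 0
    for a, b in itertools.combinations(seqs, 2):
        diffs = valid = 0
        for x, y in zip(a, b):
            if x == "-" and y == "-":
                continue
            valid += 1
            if x != y:
                diffs += 1
        if valid == 0:
            raise ValueError("a sequence pair shares no ungapped column")
        total += diffs / valid
        npairs += 1
    return total / npairs


def site_genetic_diversity(
    incidence: pd.DataFrame,
    sequences: Mapping[str, SequenceRecord],
    assignments: Sequence[TaxonAssignment],
    order_of: Mapping[str, str] | None = None,
) -> pd.Series:
    """Per-site mean of within-order nucleotide diversity.

    For each site, π is computed within every order that has ≥ 2 ASVs
    present; GD is the unweighted mean over those orders.  Orders with fewer
    than two present ASVs are ignored; a site with no eligible order is
    missing (NaN).  ``order_of`` can override the order lookup (defaults to
    the assignment's order-rank name resolution being supplied externally).
    """
    if order_of is None:
        order_of = {a.asv_id: a.name for a in assignments if a.rank == "order"}
        # species/genus/family-rank assignments must be resolved by the caller
        resolved = {a.asv_id for a in assignments}
        missing = resolved - set(order_of)
        if missing:
            raise ValueError(
                "order_of mapping required for ASVs not assigned at order rank"
            )
    gd = {}
    for site in incidence.index:
        present = [a for a in incidence.columns if incidence.loc[site, a] > 0]
        groups: dict[str, list[str]] = {}
        for asv in present:
            order = order_of.get(asv)
            if order and asv in sequences:
                groups.setdefault(order, []).append(asv)
        pis = [
            nucleotide_diversity([sequences[a].seq for a in members])
            for members in groups.values()
            if len(members) >= 2
        ]
        gd[site] = float(np.mean(pis)) if pis else float("nan")
    return pd.Series(gd, name="GD")


# ---------------------------------------------------------------------------
# Incidence-based extrapolation


def incidence_extrapolation(incidence: pd.DataFrame) -> tuple[int, float, float]:
    """Chao2 asymptotic richness from a site × ASV incidence table.

    Returns (S_obs, S_asymptote, coverage_fraction) where coverage_fraction
    = S_obs / S_asymptote.  With Q1 unique and Q2 duplicate incidences over
    T sampling units: S_hat = S_obs + ((T−1)/T)·Q1²/(2·Q2) when Q2 > 0, else
    the bias-corrected S_obs + ((T−1)/T)·Q1·(Q1−1)/2.
    """
    if incidence.size == 0:
        raise ValueError("empty incidence table")
    occupancy = (incidence > 0).sum(axis=0)
    s_obs = int((occupancy > 0).sum())
    t = incidence.shape[0]
    if t < 2:
        raise ValueError("need at least 2 sampling units")
    q1 = int((occupancy == 1).sum())
    q2 = int((occupancy == 2).sum())
    if q2 > 0:
        s_hat = s_obs + (t - 1) / t * q1**2 / (2 * q2)
    else:
        s_hat = s_obs + (t - 1) / t * q1 * (q1 - 1) / 2
    coverage = s_obs / s_hat if s_hat > 0 else float("nan")
    return s_obs, float(s_hat), float(coverage)


def facet_table(td: pd.Series, fd: pd.Series, gd: pd.Series) -> pd.DataFrame:
    """Assemble the per-site facet table (TD, FD, GD)."""
    out = pd.DataFrame({"TD": td, "FD": fd, "GD": gd})
    out.index.name = "site"
    return out
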