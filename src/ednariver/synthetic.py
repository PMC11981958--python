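"""Synthetic montane-river inputs with known ground truth for every stage.

The generator emulates the study system: a dendritic drainage tree with an
upstream–downstream elevation gradient and a humped mid-basin human-footprint
gradient; water quality and biodiversity driven by the structural path
equations; and eDNA-style per-replicate ASV read tables with planted
erroneous daughter sequences, morphological trait measurements, and
order-labelled amplicons with controlled pairwise divergence.

All randomness flows through a single ``numpy.random.Generator`` seeded from
``SimConfig.seed``, so a fixed seed reproduces every table byte-for-byte.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    RiverNetwork,
    SequenceRecord,
    build_network,
    write_count_table,
    write_fasta,
    write_network,
)

#: Structural path coefficients of the reference model (standardized scale).
DEFAULT_PATH_COEFFICIENTS: dict[str, float] = {
    "elevation->footprint": -0.5452,
    "elevation->water_quality": 0.4739,
    "footprint->water_quality": 0.5485,
    "elevation->biodiversity": -0.7056,
    "footprint->biodiversity": -0.1779,
    "water_quality->biodiversity": -0.0626,
}

#: ASV counts per order in the reference community: two dominant orders
#: (Cypriniformes + Perciformes ≈ 78% of variants) over 11 orders, 232 total.
DEFAULT_ORDER_COUNTS: dict[str, int] = {
    "Cypriniformes": 133,
    "Perciformes": 49,
    "Siluriformes": 12,
    "Cyprinodontiformes": 8,
    "Anabantiformes": 6,
    "Gobiiformes": 6,
    "Salmoniformes": 5,
    "Synbranchiformes": 4,
    "Beloniformes": 4,
    "Osmeriformes": 3,
    "Anguilliformes": 2,
}

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic basin.

    Defaults follow the reference system: 33 sites sampled in 3 replicates,
    richness spanning 13–79 variants per site, FD in [0.049, 0.793], genetic
    diversity up to 0.087 substitutions/site and opposing the downstream
    richness gradient, and the six structural coefficients above.
    """

    seed: int = 0
    n_sites: int = 33
    branching_prob: float = 0.35          # chance a new node starts a tributary
    elevation_range: tuple[float, float] = (330.0, 1400.0)  # m, outlet → headwater
    elevation_noise_sd: float = 40.0      # m
    footprint_peak: float = 25.0          # unitless index at the mid-basin hump
    footprint_noise_sd: float = 2.0
    path_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATH_COEFFICIENTS)
    )
    indicator_noise_sd: float = 0.1       # formative indicator noise (std scale)
    facet_noise_sd: float = 0.1           # extra noise on TD/FD/GD maps
    richness_range: tuple[int, int] = (13, 79)
    fd_range: tuple[float, float] = (0.049, 0.793)
    gd_range: tuple[float, float] = (0.005, 0.087)
    n_replicates: int = 3
    p_detect: float = 0.9                 # per-replicate detection probability
    error_rate: float = 0.2               # fraction of ASVs spawning a daughter
    daughter_distance: int = 1            # substitutions separating a daughter
    n_asv_pool: int = 232
    amplicon_length: int = 170            # bp
    mean_reads: float = 800.0             # lognormal read depth per ASV-site
    reads_sd_log: float = 0.6
    trait_missing_rate: float = 0.05
    order_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ORDER_COUNTS)
    )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Network and covariates


def generate_network(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[RiverNetwork, pd.DataFrame]:
    """Random dendritic tree with ~2/3 of sites on the mainstem.

    Edge lengths are Uniform(5, 30) km; node coordinates are laid out in the
    plane with each edge drawn as a straight segment of its own length, then
    converted to lat/lon around a reference point, so straight-line and edge
    distances agree per edge.  Returns the network and a per-site frame with
    lat, lon and Type (1 mainstem, 0 tributary).
    """
    if cfg.n_sites < 3:
        raise ValueError("need at least 3 sites")
    rng = rng or cfg.rng()
    n_main = max(2, round(cfg.n_sites * 2 / 3))
    mainstem = [f"Y{i + 1:02d}" for i in range(n_main)]
    tributaries = [f"T{i + 1:02d}" for i in range(cfg.n_sites - n_main)]

    base_lat, base_lon = 23.0, 101.8
    pos: dict[str, np.ndarray] = {mainstem[0]: np.zeros(2)}  # km east/north
    heading: dict[str, float] = {mainstem[0]: 0.0}           # radians from north
    edges: list[tuple[str, str, float]] = []

    for child, parent in zip(mainstem[1:], mainstem[:-1]):
        length = rng.uniform(5, 30)
        h = heading[parent] + rng.uniform(-0.3, 0.3)
        pos[child] = pos[parent] + length * np.array([np.sin(h), np.cos(h)])
        heading[child] = h
        edges.append((child, parent, length))

    attach_pool = list(mainstem)
    for trib in tributaries:
        parent = attach_pool[rng.integers(0, len(attach_pool))]
        length = rng.uniform(5, 30)
        side = rng.choice([-1.0, 1.0])
        h = heading[parent] + side * rng.uniform(0.6, 1.2)
        pos[trib] = pos[parent] + length * np.array([np.sin(h), np.cos(h)])
        heading[trib] = h
        edges.append((trib, parent, length))
        if rng.random() < cfg.branching_prob:
            attach_pool.append(trib)

    net = build_network(edges)
    rows = []
    for node in mainstem + tributaries:
        east, north = pos[node]
        lat = base_lat + north / 110.574
        lon = base_lon + east / (111.320 * np.cos(np.radians(base_lat)))
        rows.append(
            {"site": node, "lat": lat, "lon": lon, "Type": 1 if node in mainstem else 0}
        )
    coords = pd.DataFrame(rows).set_index("site")
    return net, coords


def generate_covariates(
    net: RiverNetwork,
    coords: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site covariates: elevation rises with distance to the outlet, the
    footprint index follows a mid-basin quadratic hump, and the four water
    quality indicators (mg/L) are driven by the latent water-quality equation
    plus indicator noise, truncated at zero."""
    from .spatial import distance_to_outlet

    rng = rng or cfg.rng()
    sites = list(coords.index)
    dist = np.array([distance_to_outlet(net, s) for s in sites])
    lo, hi = cfg.elevation_range
    span = dist.max() if dist.max() > 0 else 1.0
    elevation = lo + (hi - lo) * dist / span + rng.normal(0, cfg.elevation_noise_sd, len(sites))

    d_peak = span / 2
    hump = cfg.footprint_peak * (1 - ((dist - d_peak) / d_peak) ** 2)
    footprint = np.clip(hump + rng.normal(0, cfg.footprint_noise_sd, len(sites)), 0, None)

    coefs = cfg.path_coefficients
    elev_z = (elevation - elevation.mean()) / elevation.std(ddof=1)
    foot_z = (footprint - footprint.mean()) / footprint.std(ddof=1)
    b_ew = coefs["elevation->water_quality"]
    b_fw = coefs["footprint->water_quality"]
    explained = (
        b_ew**2 + b_fw**2 + 2 * b_ew * b_fw * float(np.corrcoef(elev_z, foot_z)[0, 1])
    )
    sd = np.sqrt(max(1 - explained, 0.05))
    wq = b_ew * elev_z + b_fw * foot_z + rng.normal(0, sd, len(sites))

    bases = {"TP": 0.15, "TN": 1.8, "BOD5": 2.5, "TOC": 3.0}
    out = pd.DataFrame(
        {
            "distance_km": dist,
            "elevation": elevation,
            "footprint": footprint,
            "Type": coords["Type"].values,
            "lat": coords["lat"].values,
            "lon": coords["lon"].values,
        },
        index=pd.Index(sites, name="site"),
    )
    for name, base in bases.items():
        raw = base * (1 + 0.4 * (wq + rng.normal(0, cfg.indicator_noise_sd, len(sites))))
        out[name] = np.clip(raw, 0.001, None)
    return out


# ---------------------------------------------------------------------------
# Structural latents, indicators and facets


def _disturbance_sd(explained_variance: float, context: str) -> float:
    resid = 1.0 - explained_variance
    if resid <= 0:
        raise ValueError(
            f"inconsistent structural coefficients: implied disturbance variance "
            f"{resid:.4f} ≤ 0 for {context}"
        )
    return float(np.sqrt(resid))


def simulate_structural(
    cfg: SimConfig, n: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw n sites from the structural equations, unit-variance latents.

    elevation* ~ N(0,1); footprint* = b_ef·elev* + e1; water_quality* and
    biodiversity* follow with disturbances scaled so every endogenous latent
    has variance exactly 1 in expectation.
    """
    rng = rng or cfg.rng()
    c = cfg.path_coefficients
    b_ef = c["elevation->footprint"]
    b_ew = c["elevation->water_quality"]
    b_fw = c["footprint->water_quality"]
    b_eb = c["elevation->biodiversity"]
    b_fb = c["footprint->biodiversity"]
    b_wb = c["water_quality->biodiversity"]

    elev = rng.normal(0, 1, n)
    sd_f = _disturbance_sd(b_ef**2, "footprint")
    foot = b_ef * elev + rng.normal(0, sd_f, n)

    cov_ef = b_ef
    expl_w = b_ew**2 + b_fw**2 + 2 * b_ew * b_fw * cov_ef
    sd_w = _disturbance_sd(expl_w, "water_quality")
    wq = b_ew * elev + b_fw * foot + rng.normal(0, sd_w, n)

    cov_ew = b_ew + b_fw * cov_ef
    cov_fw = b_fw + b_ew * cov_ef
    expl_b = (
        b_eb**2
        + b_fb**2
        + b_wb**2
        + 2 * b_eb * b_fb * cov_ef
        + 2 * b_eb * b_wb * cov_ew
        + 2 * b_fb * b_wb * cov_fw
    )
    sd_b = _disturbance_sd(expl_b, "biodiversity")
    biodiv = b_eb * elev + b_fb * foot + b_wb * wq + rng.normal(0, sd_b, n)

    return pd.DataFrame(
        {"elevation": elev, "footprint": foot, "water_quality": wq, "biodiversity": biodiv}
    )


def indicators_from_latents(
    latents: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed indicator table for the path model.

    Single indicators for elevation and footprint; TP/TN/BOD5/TOC load on
    water quality; TD and FD load positively and GD negatively on
    biodiversity (the opposing upstream gradient).  Each indicator adds
    N(0, indicator_noise_sd) noise.  Facets are then mapped monotonically
    (affinely, so correlations are untouched) into the observed ranges.
    """
    rng = rng or cfg.rng()
    n = len(latents)
    sd = cfg.indicator_noise_sd
    noise = lambda: rng.normal(0, sd, n)  # noqa: E731

    out = pd.DataFrame(index=latents.index)
    out["elevation"] = latents["elevation"] + noise()
    out["footprint"] = latents["footprint"] + noise()
    for col in ("TP", "TN", "BOD5", "TOC"):
        out[col] = latents["water_quality"] + noise()

    td_score = latents["biodiversity"] + rng.normal(0, cfg.facet_noise_sd, n)
    fd_score = latents["biodiversity"] + rng.normal(0, cfg.facet_noise_sd, n)
    gd_score = -latents["biodiversity"] + rng.normal(0, cfg.facet_noise_sd, n)
    out["TD"] = _affine_to_range(td_score, cfg.richness_range).round().astype(int)
    out["FD"] = _affine_to_range(fd_score, cfg.fd_range)
    out["GD"] = _affine_to_range(gd_score, cfg.gd_range)
    return out


def _affine_to_range(x: pd.Series | np.ndarray, rng_pair: tuple[float, float]) -> np.ndarray:
    x = np.asarray(x, float)
    lo, hi = rng_pair
    if np.ptp(x) == 0:
        return np.full_like(x, (lo + hi) / 2)
    return lo + (hi - lo) * (x - x.min()) / (x.max() - x.min())


def generate_facets(
    covariates: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    footprint_mode: str = "structural",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Facet table (TD, FD, GD per site) plus the latent record.

    With ``footprint_mode='structural'`` (default) the latent footprint is
    regenerated from the structural equation footprint* = b_ef·elev* + e1 and
    the returned latents carry it; with ``'observed'`` the covariate table's
    (humped) footprint is standardized and used as the latent.  Water quality
    and biodiversity always follow the structural equations with disturbances
    scaled for unit variance.
    """
    rng = rng or cfg.rng()
    c = cfg.path_coefficients
    n = len(covariates)
    elev = np.asarray(
        (covariates["elevation"] - covariates["elevation"].mean())
        / covariates["elevation"].std(ddof=1)
    )
    b_ef = c["elevation->footprint"]
    if footprint_mode == "structural":
        foot = b_ef * elev + rng.normal(0, _disturbance_sd(b_ef**2, "footprint"), n)
    elif footprint_mode == "observed":
        foot = np.asarray(
            (covariates["footprint"] - covariates["footprint"].mean())
            / covariates["footprint"].std(ddof=1)
        )
    else:
        raise ValueError(f"unknown footprint_mode {footprint_mode!r}")

    b_ew, b_fw = c["elevation->water_quality"], c["footprint->water_quality"]
    cov_ef = float(np.corrcoef(elev, foot)[0, 1])
    sd_w = _disturbance_sd(b_ew**2 + b_fw**2 + 2 * b_ew * b_fw * cov_ef, "water_quality")
    wq = b_ew * elev + b_fw * foot + rng.normal(0, sd_w, n)

    b_eb, b_fb, b_wb = (
        c["elevation->biodiversity"],
        c["footprint->biodiversity"],
        c["water_quality->biodiversity"],
    )
    cov_ew = float(np.cov(elev, wq, ddof=1)[0, 1])
    cov_fw = float(np.cov(foot, wq, ddof=1)[0, 1])
    expl_b = (
        b_eb**2 + b_fb**2 + b_wb**2
        + 2 * b_eb * b_fb * cov_ef
        + 2 * b_eb * b_wb * cov_ew
        + 2 * b_fb * b_wb * cov_fw
    )
    sd_b = _disturbance_sd(min(expl_b, 0.999), "biodiversity")
    biodiv = b_eb * elev + b_fb * foot + b_wb * wq + rng.normal(0, sd_b, n)

    latents = pd.DataFrame(
        {"elevation": elev, "footprint": foot, "water_quality": wq, "biodiversity": biodiv},
        index=covariates.index,
    )
    td = _affine_to_range(
        biodiv + rng.normal(0, cfg.facet_noise_sd, n), cfg.richness_range
    ).round().astype(int)
    fd = _affine_to_range(biodiv + rng.normal(0, cfg.facet_noise_sd, n), cfg.fd_range)
    gd = _affine_to_range(-biodiv + rng.normal(0, cfg.facet_noise_sd, n), cfg.gd_range)
    facets = pd.DataFrame({"TD": td, "FD": fd, "GD": gd}, index=covariates.index)
    facets.index.name = "site"
    return facets, latents


# ---------------------------------------------------------------------------
# ASV tables, sequences, traits


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    """Apply exactly k substitutions at distinct positions."""
    chars = list(seq)
    for pos in rng.choice(len(chars), size=k, replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the ground truth."""

    counts: pd.DataFrame                    # ASV(+daughters) × site_rep reads
    sequences: dict[str, SequenceRecord]
    traits_raw: pd.DataFrame                # asv × 11 measurements
    lineage: pd.DataFrame                   # asv × species/genus/family/order/native
    reference_lineage: pd.DataFrame         # reference id keyed lineage table
    reference_records: list[SequenceRecord]
    true_incidence: pd.DataFrame            # site × true ASV, 0/1
    truth: dict                             # manifest: daughters, per-order pi, ...


def generate_asv_data(
    facets: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticBundle:
    """Per-replicate read tables with planted errors, traits and sequences.

    A pool of true ASVs is distributed over orders with the reference
    community's proportions; per site, the TD facet sets how many (commonness-
    weighted) pool members are present.  Reads per present ASV are lognormal;
    each replicate detects a present ASV with probability ``p_detect``.  A
    fraction ``error_rate`` of ASVs spawns an erroneous daughter at
    ``daughter_distance`` substitutions and < 10% of the parent's reads in a
    random half of the parent's sites.  Totals are floored so every true ASV
    clears the global relative-abundance filter (a generator guarantee that
    makes the truth recoverable).  Per-order sequence divergence is set so
    nucleotide diversity within each order matches a known target.
    """
    rng = rng or cfg.rng()
    # --- pool composition
    counts_by_order = dict(cfg.order_counts)
    total_ref = sum(counts_by_order.values())
    pool_sizes = {
        o: max(1, round(c / total_ref * cfg.n_asv_pool)) for o, c in counts_by_order.items()
    }
    # adjust the largest order so the pool size is exact
    drift = cfg.n_asv_pool - sum(pool_sizes.values())
    largest = max(pool_sizes, key=pool_sizes.get)
    pool_sizes[largest] += drift

    orders = list(pool_sizes)
    pi_targets = {
        o: float(t) for o, t in zip(orders, np.linspace(0.03, 0.09, len(orders)))
    }

    # --- sequences: per-order ancestor, ASVs at controlled divergence
    sequences: dict[str, SequenceRecord] = {}
    asv_order: dict[str, str] = {}
    asv_ids: list[str] = []
    for order in orders:
        ancestor = "".join(rng.choice(BASES, size=cfg.amplicon_length))
        mu = pi_targets[order] / 2  # per-lineage divergence from the ancestor
        members: list[str] = []
        i = 0
        while len(members) < pool_sizes[order]:
            k = max(1, int(rng.binomial(cfg.amplicon_length, mu)))
            seq = _mutate(ancestor, k, rng)
            # keep true ASVs ≥ 3 substitutions apart so d=1 clustering cannot
            # merge two distinct true variants
            if all(_hamming(seq, m) >= 3 for m in members):
                members.append(seq)
            i += 1
            if i > pool_sizes[order] * 200:
                raise RuntimeError("could not place sufficiently distinct sequences")
        for seq in members:
            asv_id = f"sp{len(asv_ids) + 1:04d}"
            asv_ids.append(asv_id)
            sequences[asv_id] = SequenceRecord(asv_id, seq)
            asv_order[asv_id] = order

    # --- lineage (one genus per ~3 ASVs, one family per ~2 genera)
    rows = []
    for order in orders:
        members = [a for a in asv_ids if asv_order[a] == order]
        for j, asv in enumerate(members):
            genus = f"{order[:4]}Genus{j // 3 + 1}"
            family = f"{order[:4]}idae{j // 6 + 1}"
            rows.append(
                {
                    "id": asv,
                    "species": f"{genus}_{asv}",
                    "genus": genus,
                    "family": family,
                    "order": order,
                    "native": int(rng.random() < 0.3),
                }
            )
    lineage = pd.DataFrame(rows).set_index("id")

    # --- incidence truth: commonness-weighted presence per site; every pool
    # member occupies at least one site so the pool is fully observable
    sites = list(facets.index)
    weights = rng.lognormal(0, 1.0, len(asv_ids))
    weights /= weights.sum()
    true_incidence = pd.DataFrame(0, index=sites, columns=asv_ids, dtype=int)
    for site in sites:
        td = int(min(facets.loc[site, "TD"], len(asv_ids)))
        chosen = rng.choice(asv_ids, size=td, replace=False, p=weights)
        true_incidence.loc[site, chosen] = 1
    unplaced = [a for a in asv_ids if true_incidence[a].sum() == 0]
    for asv in unplaced:
        true_incidence.loc[sites[rng.integers(0, len(sites))], asv] = 1

    # --- reads per (ASV, site) and per replicate
    rep_cols = [f"{s}_r{k + 1}" for s in sites for k in range(cfg.n_replicates)]
    counts = pd.DataFrame(0, index=asv_ids, columns=rep_cols, dtype=int)
    detected_reps: dict[tuple[str, str], list[str]] = {}
    for site in sites:
        present = true_incidence.columns[true_incidence.loc[site] > 0]
        for asv in present:
            base = rng.lognormal(np.log(cfg.mean_reads), cfg.reads_sd_log)
            reps = [
                f"{site}_r{k + 1}"
                for k in range(cfg.n_replicates)
                if rng.random() < cfg.p_detect
            ]
            detected_reps[(asv, site)] = reps
            for col in reps:
                counts.loc[asv, col] = max(1, int(rng.poisson(base)))

    # --- floor rare ASVs above the global frequency threshold
    for _ in range(8):
        grand = counts.values.sum()
        floor = 0.001 * grand
        too_rare = counts.sum(axis=1) < floor * 1.1
        if not too_rare.any():
            break
        for asv in counts.index[too_rare]:
            total = counts.loc[asv].sum()
            if total == 0:
                continue
            scale = float(np.ceil(floor * 1.2 / total))
            counts.loc[asv] = counts.loc[asv] * int(scale)

    # --- planted erroneous daughters
    n_err = int(round(cfg.error_rate * len(asv_ids)))
    parents = list(rng.choice(asv_ids, size=n_err, replace=False)) if n_err else []
    daughters: dict[str, str] = {}
    for parent in parents:
        pseq = sequences[parent].seq
        for _ in range(100):
            dseq = _mutate(pseq, cfg.daughter_distance, rng)
            others = [
                s.seq for a, s in sequences.items() if a != parent
            ] + [sequences[d].seq for d in daughters]
            if all(_hamming(dseq, o) >= 3 for o in others) and dseq not in {
                sequences[a].seq for a in asv_ids
            }:
                break
        else:
            continue
        parent_sites = [s for s in sites if true_incidence.loc[s, parent] > 0]
        if not parent_sites:
            continue
        did = f"err{len(daughters) + 1:03d}"
        daughters[did] = parent
        sequences[did] = SequenceRecord(did, dseq)
        n_sub = max(1, len(parent_sites) // 2)
        sub = list(rng.choice(parent_sites, size=n_sub, replace=False))
        counts.loc[did] = 0
        frac = rng.uniform(0.03, 0.08)
        for site in sub:
            for col in detected_reps.get((parent, site), []):
                counts.loc[did, col] = max(1, int(frac * counts.loc[parent, col]))

    # --- niche-separation guarantee: every true ASV must be distinguishable
    # from an erroneous daughter of a more abundant order-mate.  Whenever one
    # ASV's occupied sites are (near-)fully covered by a higher-abundance,
    # high-identity ASV that also out-numbers it in every shared site, the
    # rarer one receives a private site (or, failing that, a site of local
    # dominance).  Real communities show the same structure — distinct taxa
    # hold distinct ecological niches — and without it a curation step cannot,
    # even in principle, separate rare taxa from errors.  Evaluated on
    # daughter-folded counts (the post-clustering view) with conservative
    # margins on the identity, co-occurrence and ratio rules.
    groups = pd.Series({c: c.rsplit("_r", 1)[0] for c in counts.columns})
    L = cfg.amplicon_length
    high_identity: dict[str, set[str]] = {a: set() for a in asv_ids}
    for order in orders:
        members = [a for a in asv_ids if asv_order[a] == order]
        arr = np.array([list(sequences[a].seq) for a in members])
        dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        close = 1 - dist / L >= 0.82  # margin below the 0.84 merge threshold
        for i, a in enumerate(members):
            high_identity[a] = {members[j] for j in np.nonzero(close[i])[0] if j != i}
    for _ in range(15):
        eff = counts.loc[asv_ids].copy()
        for did, parent in daughters.items():
            eff.loc[parent] += counts.loc[did].values
        site_counts = eff.T.groupby(groups).sum().T
        occ = site_counts > 0
        totals = eff.sum(axis=1)
        changed = False
        by_total = sorted(asv_ids, key=lambda a: totals[a])
        for d in by_total:
            d_sites = list(occ.columns[occ.loc[d]])
            if not d_sites:
                continue
            for p in sorted(high_identity[d], key=lambda a: -totals[a]):
                if totals[p] <= totals[d]:
                    continue
                shared = [s for s in d_sites if occ.loc[p, s]]
                if len(shared) / len(d_sites) < 0.93:
                    continue
                if any(site_counts.loc[p, s] < 0.95 * site_counts.loc[d, s] for s in shared):
                    continue
                free = [s for s in sites if not occ.loc[p, s] and s not in d_sites]
                typical = max(1, int(site_counts.loc[d, d_sites].mean()))
                if free:
                    s_new = free[rng.integers(0, len(free))]
                    for k in range(cfg.n_replicates):
                        counts.loc[d, f"{s_new}_r{k + 1}"] = max(
                            1, int(rng.poisson(typical / cfg.n_replicates))
                        )
                    true_incidence.loc[s_new, d] = 1
                else:
                    s_boost = shared[rng.integers(0, len(shared))]
                    boost = int(2 * site_counts.loc[p, s_boost]) + typical
                    col = f"{s_boost}_r1"
                    counts.loc[d, col] = counts.loc[d, col] + boost
                changed = True
                break
        if not changed:
            break

    # --- raw traits: two shape factors behind 11 measurements
    trait_bases = {
        "Bl": 100.0, "Bd": 25.0, "Hd": 18.0, "CPd": 8.0, "CFd": 14.0, "Ed": 5.0,
        "Eh": 10.0, "Om": 12.0, "Jl": 9.0, "PFl": 20.0, "PFp": 15.0,
    }
    load1 = {
        "Bl": 0.25, "Bd": -0.20, "Hd": -0.10, "CPd": -0.25, "CFd": 0.10, "Ed": 0.0,
        "Eh": 0.05, "Om": 0.0, "Jl": 0.05, "PFl": 0.15, "PFp": -0.05,
    }
    load2 = {
        "Bl": 0.0, "Bd": 0.05, "Hd": 0.20, "CPd": 0.05, "CFd": -0.10, "Ed": 0.30,
        "Eh": 0.20, "Om": 0.15, "Jl": 0.25, "PFl": -0.05, "PFp": 0.10,
    }
    order_shift = {o: rng.normal(0, 0.6, 2) for o in orders}
    trait_rows = {}
    for asv in asv_ids:
        f1, f2 = order_shift[asv_order[asv]] + rng.normal(0, 1, 2)
        size = rng.normal(0, 0.3)  # common size factor, cancels in ratios
        trait_rows[asv] = {
            t: trait_bases[t]
            * float(np.exp(size + load1[t] * f1 + load2[t] * f2 + rng.normal(0, 0.03)))
            for t in trait_bases
        }
    traits_raw = pd.DataFrame(trait_rows).T
    traits_raw.index.name = "asv_id"
    if cfg.trait_missing_rate > 0:
        mask = rng.random(traits_raw.shape) < cfg.trait_missing_rate
        traits_raw = traits_raw.mask(mask)

    # --- reference database: the true pool with its lineages
    reference_records = [
        SequenceRecord(f"ref_{a}", sequences[a].seq) for a in asv_ids
    ]
    ref_rows = lineage.reset_index().rename(columns={"id": "asv"})
    ref_rows["id"] = "ref_" + ref_rows["asv"]
    reference_lineage = ref_rows[["id", "species", "genus", "family", "order", "native"]]

    truth = {
        "asv_ids": asv_ids,
        "daughters": daughters,
        "pi_targets": pi_targets,
        "order_of": asv_order,
        "fish_orders": orders,
    }
    counts = counts.astype(int)
    return SyntheticBundle(
        counts=counts,
        sequences=sequences,
        traits_raw=traits_raw,
        lineage=lineage,
        reference_lineage=reference_lineage,
        reference_records=reference_records,
        true_incidence=true_incidence,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Full bundle


def simulate_bundle(cfg: SimConfig) -> dict:
    """Generate the complete input set with one RNG stream.

    The facet stage regenerates the footprint from the structural equation;
    the covariate table's footprint column is replaced by an affine,
    non-negative rescaling of that structural footprint so every downstream
    stage (GLM, PLS) sees covariates coherent with the facets it analyses.
    """
    rng = cfg.rng()
    net, coords = generate_network(cfg, rng)
    covariates = generate_covariates(net, coords, cfg, rng)
    facets, latents = generate_facets(covariates, cfg, rng)
    half_peak = cfg.footprint_peak / 2
    covariates["footprint"] = np.clip(
        half_peak + (half_peak / 2.5) * latents["footprint"].values, 0, None
    )
    wq = latents["water_quality"].values
    for name, base in (("TP", 0.15), ("TN", 1.8), ("BOD5", 2.5), ("TOC", 3.0)):
        raw = base * (1 + 0.4 * (wq + rng.normal(0, cfg.indicator_noise_sd, len(wq))))
        covariates[name] = np.clip(raw, 0.001, None)
    bundle = generate_asv_data(facets, cfg, rng)
    return {
        "network": net,
        "coords": coords,
        "covariates": covariates,
        "facets_true": facets,
        "latents": latents,
        "asv": bundle,
    }


def write_bundle(sim: dict, outdir: str | Path, cfg: SimConfig) -> dict:
    """Write the bundle as plain-text files; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: SyntheticBundle = sim["asv"]
    write_network(sim["network"], out / "network.tsv")
    cov = sim["covariates"].copy()
    cov.index.name = "site"
    cov.to_csv(out / "covariates.tsv", sep="\t")
    write_count_table(bundle.counts, out / "asv_counts.tsv")
    write_fasta(bundle.sequences.values(), out / "asv_sequences.fasta")
    write_fasta(bundle.reference_records, out / "reference.fasta")
    bundle.reference_lineage.to_csv(out / "reference_lineage.tsv", sep="\t", index=False)
    lin = bundle.lineage.copy()
    lin.index.name = "id"
    lin.to_csv(out / "lineage.tsv", sep="\t")
    tr = bundle.traits_raw.copy()
    tr.to_csv(out / "traits_raw.tsv", sep="\t")
    inc = bundle.true_incidence.copy()
    inc.index.name = "site"
    inc.to_csv(out / "true_incidence.tsv", sep="\t")
    sim["facets_true"].to_csv(out / "facets_true.tsv", sep="\t")
    manifest = {
        "seed": cfg.seed,
        "n_sites": cfg.n_sites,
        "files": sorted(p.name for p in out.iterdir()),
        "truth": {
            "daughters": bundle.truth["daughters"],
            "pi_targets": bundle.truth["pi_targets"],
            "fish_orders": bundle.truth["fish_orders"],
        },
        "config": {
            k: v for k, v in asdict(cfg).items() if not isinstance(v, dict)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
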