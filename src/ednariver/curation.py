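"""ASV curation: dereplication, d=1 clustering, the filter cascade, LULU-style
post-clustering and the replicate retention rule.

The end product is a curated site × ASV incidence table.  All steps are
deterministic: ties are broken by total abundance (descending) and then by
lexicographic ASV id.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import RunConfig, SequenceRecord, parse_sample_label


@dataclass
class ASVTable:
    """Per-(site, replicate) read counts for a set of ASVs.

    ``counts`` is indexed by asv_id with ``<site>_r<k>`` columns.
    ``sequences`` maps asv_id to its representative sequence.
    """

    counts: pd.DataFrame
    sequences: dict[str, SequenceRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        for col in self.counts.columns:
            parse_sample_label(col)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for col in self.counts.columns:
            seen.setdefault(parse_sample_label(col)[0])
        return list(seen)

    def replicate_columns(self, site: str) -> list[str]:
        return [c for c in self.counts.columns if parse_sample_label(c)[0] == site]

    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def freq(self) -> pd.Series:
        """Relative abundance over the table's own grand total."""
        total = self.grand_total
        if total == 0:
            return self.total_reads().astype(float)
        return self.total_reads() / total

    def site_counts(self) -> pd.DataFrame:
        """ASV × site reads summed over replicates."""
        groups = {c: parse_sample_label(c)[0] for c in self.counts.columns}
        return self.counts.T.groupby(pd.Series(groups)).sum().T

    def _ordering(self) -> list[str]:
        totals = self.total_reads()
        return sorted(self.counts.index, key=lambda a: (-totals[a], a))

    def sorted(self) -> "ASVTable":
        order = self._ordering()
        return ASVTable(self.counts.loc[order], dict(self.sequences))


def dereplicate(
    reads: Iterable[tuple[SequenceRecord, str, int]],
    id_prefix: str = "ASV",
) -> ASVTable:
    """Collapse identical sequences, summing multiplicities per (site, replicate).

    ``reads`` yields (record, sample_label, count) with sample labels in the
    ``<site>_r<k>`` dialect.  Output ids are assigned by decreasing total
    abundance (ties: lexicographic sequence).
    """
    per_seq: dict[str, dict[str, int]] = {}
    for rec, sample, count in reads:
        parse_sample_label(sample)
        cell = per_seq.setdefault(rec.seq, {})
        cell[sample] = cell.get(sample, 0) + int(count)
    order = sorted(per_seq, key=lambda s: (-sum(per_seq[s].values()), s))
    width = max(4, len(str(len(order))))
    ids = [f"{id_prefix}_{i + 1:0{width}d}" for i in range(len(order))]
    columns = sorted({c for cell in per_seq.values() for c in cell})
    counts = pd.DataFrame(0, index=ids, columns=columns, dtype=int)
    sequences = {}
    for asv_id, seq in zip(ids, order):
        for sample, count in per_seq[seq].items():
            counts.loc[asv_id, sample] = count
        sequences[asv_id] = SequenceRecord(asv_id, seq)
    return ASVTable(counts, sequences)


def _within_one_edit(a: str, b: str) -> bool:
    """True iff Hamming distance ≤ 1 (equal length) or a single indel apart."""
    la, lb = len(a), len(b)
    if la == lb:
        mism = 0
        for x, y in zip(a, b):
            if x != y:
                mism += 1
                if mism > 1:
                    return False
        return True
    if abs(la - lb) != 1:
        return False
    if la > lb:
        a, b = b, a
        la, lb = lb, la
    # a is shorter; allow one deletion in b
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def cluster_d1(table: ASVTable) -> ASVTable:
    """Single-linkage agglomeration of sequences at edit distance ≤ 1.

    Clusters are seeded from the most abundant sequence; the representative
    of each cluster is its most abundant member (ties: lexicographic id) and
    counts are summed, so the grand total is conserved.
    """
    ids = table.sorted().asv_ids  # most-abundant-first seeding
    seqs = {a: table.sequences[a].seq for a in ids}
    parent = {a: a for a in ids}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if find(a) != find(b) and _within_one_edit(seqs[a], seqs[b]):
                parent[find(b)] = find(a)

    clusters: dict[str, list[str]] = {}
    for a in ids:
        clusters.setdefault(find(a), []).append(a)

    totals = table.total_reads()
    rows, sequences = {}, {}
    for members in clusters.values():
        rep = min(members, key=lambda m: (-totals[m], m))
        rows[rep] = table.counts.loc[members].sum(axis=0)
        sequences[rep] = table.sequences[rep]
    merged = pd.DataFrame(rows).T.astype(int)
    merged = merged.loc[sorted(rows, key=lambda a: (-totals[a], a))]
    return ASVTable(merged, sequences)


def filter_asvs(
    table: ASVTable,
    is_fish: Mapping[str, bool] | Callable[[str], bool],
    cfg: RunConfig | None = None,
) -> ASVTable:
    """Single-pass deletion filter.

    Retains exactly the ASVs with total reads ≥ ``min_reads``, length within
    [``min_len``, ``max_len``], a fish assignment, and relative abundance
    ≥ ``min_freq`` over the pre-filter grand total.
    """
    cfg = cfg or RunConfig()
    t = cfg.thresholds
    fish = is_fish if callable(is_fish) else (lambda a: bool(is_fish.get(a, False)))
    totals = table.total_reads()
    freqs = table.freq()  # pre-filter denominator
    keep = []
    for asv in table.asv_ids:
        length = table.sequences[asv].length
        if (
            totals[asv] >= t["min_reads"]
            and t["min_len"] <= length <= t["max_len"]
            and fish(asv)
            and freqs[asv] >= t["min_freq"]
        ):
            keep.append(asv)
    if not keep:
        warnings.warn("filter_asvs removed every ASV", stacklevel=2)
    return ASVTable(
        table.counts.loc[keep].copy(),
        {a: table.sequences[a] for a in keep},
    )


def lulu_curate(
    table: ASVTable,
    identity: pd.DataFrame | Mapping[frozenset, float],
    cfg: RunConfig | None = None,
) -> ASVTable:
    """Merge erroneous daughter ASVs into their parents (LULU-style).

    A daughter merges into the most abundant qualifying parent for which
    (i) pairwise identity ≥ ``lulu_min_match``, (ii) the fraction of the
    daughter's occupied sites where the parent also occurs is
    ≥ ``lulu_cooccur``, and (iii) the parent/daughter read ratio is
    ≥ ``lulu_min_ratio`` in every shared site.  Daughters are processed in
    increasing abundance; merged counts are added to the parent, so reads
    are conserved.  Deterministic under the stated tie-breaking.
    """
    cfg = cfg or RunConfig()
    t = cfg.thresholds

    def ident(a: str, b: str) -> float:
        if isinstance(identity, pd.DataFrame):
            return float(identity.loc[a, b])
        return float(identity.get(frozenset((a, b)), 0.0))

    counts = table.counts.copy()
    totals = table.total_reads()
    # increasing abundance; ties resolved by reverse-lexicographic id so that
    # the ordering is the exact mirror of the parent ordering
    order = sorted(table.asv_ids, key=lambda a: (-totals[a], a))[::-1]
    merged_into: dict[str, str] = {}

    def resolve(a: str) -> str:
        while a in merged_into:
            a = merged_into[a]
        return a

    groups = pd.Series({c: parse_sample_label(c)[0] for c in counts.columns})
    site_counts = counts.T.groupby(groups).sum().T  # ASV × site, kept up to date

    for daughter in order:
        if daughter in merged_into:
            continue
        d_sites = site_counts.loc[daughter]
        d_occ = d_sites[d_sites > 0]
        if d_occ.empty:
            continue
        d_total = int(counts.loc[daughter].sum())
        candidates = []
        for other in table.asv_ids:
            p = resolve(other)
            if p == daughter or p in merged_into:
                continue
            p_total = int(counts.loc[p].sum())
            if p_total <= d_total:
                continue
            if ident(daughter, other) < t["lulu_min_match"]:
                continue
            p_sites = site_counts.loc[p]
            shared = d_occ.index[p_sites[d_occ.index] > 0]
            cooccur = len(shared) / len(d_occ)
            if cooccur < t["lulu_cooccur"]:
                continue
            if len(shared) == 0 or (p_sites[shared] / d_occ[shared] < t["lulu_min_ratio"]).any():
                continue
            candidates.append((p_total, p))
        if candidates:
            parent = min(candidates, key=lambda c: (-c[0], c[1]))[1]
            counts.loc[parent] += counts.loc[daughter]
            site_counts.loc[parent] += site_counts.loc[daughter]
            counts = counts.drop(index=daughter)
            merged_into[daughter] = parent

    keep = [a for a in table.asv_ids if a not in merged_into]
    return ASVTable(counts.loc[keep], {a: table.sequences[a] for a in keep})


def replicate_filter(table: ASVTable, min_replicates: int = 2) -> pd.DataFrame:
    """Collapse replicates to a site × ASV incidence table.

    An ASV is present at a site iff it was detected (reads > 0) in at least
    ``min_replicates`` of that site's replicates.  Sites with a single
    replicate cannot support the rule and raise ``ValueError``.
    """
    sites = table.sites
    incidence = pd.DataFrame(0, index=sites, columns=table.asv_ids, dtype=int)
    for site in sites:
        cols = table.replicate_columns(site)
        if len(cols) < 2:
            raise ValueError(f"site {site!r} has {len(cols)} replicate(s); need ≥ 2")
        detected = (table.counts[cols] > 0).sum(axis=1)
        incidence.loc[site] = (detected >= min_replicates).astype(int).values
    return incidence


def identity_matrix(sequences: Mapping[str, SequenceRecord]) -> pd.DataFrame:
    """All-vs-all global-alignment identity (matched / aligned columns)."""
    from .taxonomy import pairwise_identity

    ids = list(sequences)
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            v = pairwise_identity(sequences[a].seq, sequences[b].seq)
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def curate(
    table: ASVTable,
    is_fish: Mapping[str, bool] | Callable[[str], bool],
    cfg: RunConfig | None = None,
    identity: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ASVTable]:
    """Full curation cascade: d=1 clustering → filter → LULU → replicate rule.

    Returns (incidence, curated ASV table).
    """
    cfg = cfg or RunConfig()
    clustered = cluster_d1(table)
    filtered = filter_asvs(clustered, is_fish, cfg)
    if identity is None:
        identity = identity_matrix(filtered.sequences)
    curated = lulu_curate(filtered, identity, cfg)
    incidence = replicate_filter(curated)
    return incidence, curated
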