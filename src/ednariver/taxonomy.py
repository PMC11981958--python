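"""Hierarchical, identity-banded taxonomic assignment against a reference
database trimmed by in-silico PCR.

Assignment logic: a first pass prioritises exact (100%) matches to native
species; otherwise the best global hit is assigned at species, genus, family
or order rank according to identity bands [0.98, 1], [0.96, 0.98), [0.90,
0.96) and [0, 0.90), with ties resolved by the lowest common ancestor of the
tied lineages at or above the band's rank.  Band boundaries are closed below.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib

from .io_formats import SequenceRecord

RANKS = ("species", "genus", "family", "order")

#: IUPAC nucleotide code → the set of concrete bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Lineage:
    species: str
    genus: str
    family: str
    order: str

    def name_at(self, rank: str) -> str:
        return getattr(self, rank)


@dataclass
class ReferenceDB:
    """Reference sequences with complete 4-rank lineages and native flags."""

    records: list[SequenceRecord]
    lineage: dict[str, Lineage]
    native: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.id not in self.lineage:
                raise ValueError(f"reference {rec.id!r} lacks a lineage")
        unknown = set(self.native) - {lin.species for lin in self.lineage.values()}
        if unknown:
            raise ValueError(f"native flags for absent species: {sorted(unknown)}")

    def is_native(self, record_id: str) -> bool:
        return bool(self.native.get(self.lineage[record_id].species, False))


@dataclass(frozen=True)
class TaxonAssignment:
    asv_id: str
    rank: str  # species | genus | family | order | unassigned
    name: str
    identity: float
    source: str  # native | global


# ---------------------------------------------------------------------------
# In-silico PCR


def _primer_mismatches(primer: str, window: str) -> int:
    mism = 0
    for p, b in zip(primer, window):
        if b not in IUPAC_SETS.get(p, frozenset()):
            mism += 1
    return mism


def _scan_strand(
    seq: str, fwd: str, rev_rc: str, min_len: int, max_len: int, max_mismatch: int
) -> tuple[int, int, str] | None:
    """Best (fewest mismatches, then longest) amplicon on one strand."""
    best: tuple[int, int, str] | None = None
    n, lf, lr = len(seq), len(fwd), len(rev_rc)
    fwd_hits = [
        (i, _primer_mismatches(fwd, seq[i : i + lf]))
        for i in range(n - lf + 1)
    ]
    fwd_hits = [(i, m) for i, m in fwd_hits if m <= max_mismatch]
    for i, mf in fwd_hits:
        start = i + lf
        for j in range(start, n - lr + 1):
            amp_len = j - start
            if amp_len > max_len:
                break
            if amp_len < min_len:
                continue
            mr = _primer_mismatches(rev_rc, seq[j : j + lr])
            if mf + mr > max_mismatch:
                continue
            key = (mf + mr, -amp_len)
            if best is None or key < (best[0], -best[1]):
                best = (mf + mr, amp_len, seq[start:j])
    return best


def insilico_pcr(
    refs: Sequence[SequenceRecord],
    fwd: str,
    rev: str,
    min_len: int = 150,
    max_len: int = 220,
    max_mismatch: int = 3,
) -> list[SequenceRecord]:
    """Extract the would-be amplicon from each reference.

    Both strands are scanned for a forward-primer site followed by a
    reverse-complemented reverse-primer site, each IUPAC-aware and within the
    shared mismatch budget; the inter-primer segment is emitted when its
    length lies in [min_len, max_len].  At most one (best) amplicon per
    reference; references shorter than the primers are skipped.
    """
    fwd, rev = fwd.upper(), rev.upper()
    rev_rc = reverse_complement(rev)
    out = []
    for rec in refs:
        if len(rec.seq) < len(fwd) + len(rev):
            continue
        hits = []
        for strand in (rec.seq, reverse_complement(rec.seq)):
            h = _scan_strand(strand, fwd, rev_rc, min_len, max_len, max_mismatch)
            if h is not None:
                hits.append(h)
        if not hits:
            continue
        _, _, amplicon = min(hits, key=lambda h: (h[0], -h[1]))
        out.append(SequenceRecord(rec.id, amplicon))
    return out


# ---------------------------------------------------------------------------
# Identity and assignment

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_aligner = None


def _get_aligner():
    global _aligner
    if _aligner is None:
        from Bio import Align

        _aligner = Align.PairwiseAligner()
        _aligner.mode = "global"
        _aligner.match_score = 1
        _aligner.mismatch_score = -1
        _aligner.open_gap_score = -2.5
        _aligner.extend_gap_score = -0.5
    return _aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched columns / total alignment columns.

    Equal-length sequences are compared column-by-column (a substitution is
    never explained away as a pair of gaps); length-differing pairs go
    through an affine-gap global alignment.  A fast edit-distance bound from
    edlib short-circuits clearly distant pairs.
    """
    if not a or not b:
        return 0.0
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        return matches / len(a)
    # cheap lower bound on dissimilarity before the full alignment
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    if 1 - dist / max(len(a), len(b)) < 0.5:
        return max(0.0, 1 - dist / max(len(a), len(b)))
    aln = _get_aligner().align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return matches / len(sa) if sa else 0.0


def best_identity(
    asv: SequenceRecord, refs: ReferenceDB | Sequence[SequenceRecord]
) -> tuple[str, float]:
    """Best-hit (record id, identity); ties broken by lexicographic id."""
    records = refs.records if isinstance(refs, ReferenceDB) else list(refs)
    if not records:
        raise ValueError("empty reference set")
    best_id, best_v = None, -1.0
    for rec in sorted(records, key=lambda r: r.id):
        v = pairwise_identity(asv.seq, rec.seq)
        if v > best_v + 1e-12:
            best_id, best_v = rec.id, v
    return best_id, best_v


def _tied_hits(asv: SequenceRecord, refs: ReferenceDB, tol: float = 1e-9) -> tuple[float, list[str]]:
    best_v, hits = -1.0, []
    for rec in sorted(refs.records, key=lambda r: r.id):
        v = pairwise_identity(asv.seq, rec.seq)
        if v > best_v + tol:
            best_v, hits = v, [rec.id]
        elif abs(v - best_v) <= tol:
            hits.append(rec.id)
    return best_v, hits


def _lca_rank_name(lineages: list[Lineage], floor_rank: str) -> tuple[str, str]:
    """Lowest common ancestor at or above ``floor_rank``; ('unassigned', '')
    when even the orders disagree."""
    start = RANKS.index(floor_rank)
    for rank in RANKS[start:]:
        names = {lin.name_at(rank) for lin in lineages}
        if len(names) == 1:
            return rank, names.pop()
    return "unassigned", ""


def band_rank(identity: float, species: float = 0.98, genus: float = 0.96, family: float = 0.90) -> str:
    """Map a best-hit identity to its assignment rank (closed lower bounds)."""
    if identity >= species:
        return "species"
    if identity >= genus:
        return "genus"
    if identity >= family:
        return "family"
    return "order"


def assign_taxonomy(asv: SequenceRecord, refs: ReferenceDB) -> TaxonAssignment:
    """Two-pass banded assignment (native exact pass, then global bands)."""
    # pass 1: exact native-species match
    native_records = [r for r in refs.records if refs.is_native(r.id)]
    for rec in sorted(native_records, key=lambda r: r.id):
        if pairwise_identity(asv.seq, rec.seq) >= 1.0 - 1e-12:
            return TaxonAssignment(
                asv.id, "species", refs.lineage[rec.id].species, 1.0, "native"
            )
    # pass 2: banded best hit with LCA on ties
    best_v, hits = _tied_hits(asv, refs)
    rank = band_rank(best_v)
    lineages = [refs.lineage[h] for h in hits]
    final_rank, name = _lca_rank_name(lineages, rank)
    return TaxonAssignment(asv.id, final_rank, name, best_v, "global")


def assign_all(
    asvs: Sequence[SequenceRecord], refs: ReferenceDB
) -> list[TaxonAssignment]:
    return [assign_taxonomy(a, refs) for a in asvs]


def fish_gate(
    assignments: Sequence[TaxonAssignment],
    refs: ReferenceDB,
    fish_orders: Sequence[str],
) -> dict[str, bool]:
    """ASV → fish flag: true iff the best-hit order is in ``fish_orders``.

    Replaces a live fish-species registry lookup with a supplied order list.
    """
    orders = set(fish_orders)
    flags = {}
    for a in assignments:
        if a.rank == "unassigned":
            flags[a.asv_id] = False
        elif a.rank == "order":
            flags[a.asv_id] = a.name in orders
        else:
            # find the order through any reference carrying this name at rank
            order_names = {
                lin.order
                for lin in refs.lineage.values()
                if lin.name_at(a.rank) == a.name
            }
            flags[a.asv_id] = bool(order_names & orders)
    return flags


def lineage_table_to_db(
    records: Sequence[SequenceRecord], table
) -> ReferenceDB:
    """Build a ReferenceDB from records plus a lineage DataFrame with columns
    id, species, genus, family, order, native (0/1)."""
    lineage = {}
    native = {}
    for row in table.itertuples(index=False):
        lineage[str(row.id)] = Lineage(str(row.species), str(row.genus), str(row.family), str(row.order))
        if bool(getattr(row, "native", False)):
            native[str(row.species)] = True
    return ReferenceDB(list(records), lineage, native)
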