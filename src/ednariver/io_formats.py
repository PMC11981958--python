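"""Readers and writers for the tabular and sequence formats the pipeline touches.

Every downstream module consumes the types defined here (sequences, count
tables, river networks, run configuration); no module re-parses files.
Column dialect for count/incidence tables is fixed as ``<site>_r<k>`` —
sites and replicates are never inferred from column order.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger("ednariver")

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

_REPLICATE_RE = re.compile(r"^(?P<site>.+)_r(?P<rep>\d+)$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with a unique identifier.

    The sequence is stored uppercase and must use IUPAC nucleotide codes.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord` in file order.

    Lowercase bases are normalised to uppercase.  Malformed headers, empty
    sequences and duplicated identifiers raise :class:`FormatError` naming
    the offending line.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: empty sequence for {header!r} (line {header_line})")
        if header in seen:
            raise FormatError(f"{path}: duplicate id {header!r} (line {header_line})")
        seen.add(header)
        records.append(SequenceRecord(header, seq))
        header, chunks = None, []

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(i)
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FormatError(f"{path}: malformed header at line {i}")
                header_line = i
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence before header at line {i}")
                chunks.append(line)
        _flush(-1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Count / incidence tables


def parse_sample_label(label: str) -> tuple[str, int]:
    """Split a ``<site>_r<k>`` column label into (site, replicate)."""
    m = _REPLICATE_RE.match(label)
    if not m:
        raise FormatError(f"column {label!r} does not match '<site>_r<k>'")
    return m.group("site"), int(m.group("rep"))


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read an ASV × sample TSV of integer read counts.

    First column is ``asv_id``; remaining columns follow the ``<site>_r<k>``
    dialect.  Blank cells are zeros; negative or non-integer counts and
    duplicated ASV ids raise :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "asv_id":
        raise FormatError(f"{path}: first column must be 'asv_id', got {df.columns[0]!r}")
    if df["asv_id"].duplicated().any():
        dup = df.loc[df["asv_id"].duplicated(), "asv_id"].iloc[0]
        raise FormatError(f"{path}: duplicated asv_id {dup!r}")
    df = df.set_index("asv_id")
    for col in df.columns:
        parse_sample_label(col)
    values = df.fillna(0)
    for col in values.columns:
        v = pd.to_numeric(values[col], errors="coerce")
        if v.isna().any():
            row = values.index[v.isna()][0]
            raise FormatError(f"{path}: non-numeric count at ({row}, {col})")
        if (v < 0).any():
            row = values.index[v < 0][0]
            raise FormatError(f"{path}: negative count at ({row}, {col})")
        if (v % 1 != 0).any():
            row = values.index[v % 1 != 0][0]
            raise FormatError(f"{path}: non-integer count at ({row}, {col})")
        values[col] = v.astype(int)
    return values


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.copy()
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def read_incidence_table(path: str | Path) -> pd.DataFrame:
    """Read a site × ASV 0/1 incidence TSV (sites in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise FormatError(f"{path}: incidence values must be 0/1")
    return df.astype(int)


def write_incidence_table(incidence: pd.DataFrame, path: str | Path) -> None:
    out = incidence.astype(int).copy()
    out.index.name = "site"
    out.to_csv(path, sep="\t")


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    """Generic TSV reader (traits, covariates, lineages)."""
    df = pd.read_csv(path, sep="\t")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


# ---------------------------------------------------------------------------
# River network


@dataclass
class RiverNetwork:
    """A drainage tree: directed edges child → parent, rooted at the outlet.

    ``graph`` is a :class:`networkx.DiGraph` whose edges carry ``length_km``.
    """

    graph: nx.DiGraph
    outlet: str

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def parent_of(self, node: str) -> str | None:
        succ = list(self.graph.successors(node))
        return succ[0] if succ else None


def build_network(edges: Iterable[tuple[str, str, float]]) -> RiverNetwork:
    """Assemble and validate a rooted drainage tree from (child, parent, km)."""
    g = nx.DiGraph()
    for child, parent, length in edges:
        if g.has_edge(str(child), str(parent)):
            raise FormatError(f"duplicate edge {child}->{parent}")
        g.add_edge(str(child), str(parent), length_km=float(length))
    if g.number_of_nodes() != g.number_of_edges() + 1:
        raise FormatError(
            f"not a tree: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges"
        )
    if not nx.is_directed_acyclic_graph(g):
        raise FormatError("network contains a cycle")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise FormatError(f"expected a single outlet, found {len(roots)}: {roots}")
    multi_parent = [n for n in g.nodes if g.out_degree(n) > 1]
    if multi_parent:
        raise FormatError(f"nodes with multiple parents: {multi_parent}")
    return RiverNetwork(graph=g, outlet=roots[0])


def read_network(path: str | Path) -> RiverNetwork:
    """Read a TSV edge list (child_node, parent_node, length_km)."""
    df = pd.read_csv(path, sep="\t")
    required = {"child_node", "parent_node", "length_km"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    return build_network(
        df[["child_node", "parent_node", "length_km"]].itertuples(index=False, name=None)
    )


def write_network(net: RiverNetwork, path: str | Path) -> None:
    rows = [
        {"child_node": c, "parent_node": p, "length_km": d["length_km"]}
        for c, p, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration

#: Named cutoffs with defaults equal to the published values.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "min_reads": 10,          # ASVs with fewer total reads are deleted
    "min_len": 160,           # bp
    "max_len": 200,           # bp
    "min_freq": 0.001,        # global relative-abundance floor
    "species_identity": 0.98, # identity bands, closed lower bounds
    "genus_identity": 0.96,
    "family_identity": 0.90,
    "lulu_min_match": 0.84,
    "lulu_min_ratio": 1.0,
    "lulu_cooccur": 0.95,
    "pcr_min_len": 150,       # in-silico PCR amplicon bounds
    "pcr_max_len": 220,
    "pcr_max_mismatch": 3,
    "moran_classes": 8,
    "moran_permutations": 999,
    "sem_permutations": 100,
}


@dataclass
class RunConfig:
    """Flat run configuration: seed, named thresholds, and file locations."""

    seed: int = 0
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        for key, value in self.thresholds.items():
            if key not in DEFAULT_THRESHOLDS:
                warnings.warn(f"unknown threshold {key!r} ignored", stacklevel=2)
                continue
            merged[key] = value
        self.thresholds = merged

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key in set(doc) - known:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
        return cls(
            seed=int(doc.get("seed", 0)),
            thresholds=dict(doc.get("thresholds", {})),
            paths={k: str(v) for k, v in dict(doc.get("paths", {})).items()},
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def log_stage(stage: str, seed: int | None = None, **counts: int) -> None:
    """Emit one structured log line per pipeline stage."""
    parts = [f"stage={stage}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in counts.items())
    logger.info(" ".join(parts))
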