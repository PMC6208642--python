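"""MEGAN-style lowest-common-ancestor (LCA) taxonomic assignment of reads
from tabular alignment hits.

Hits are first thresholded (bitscore, e-value, query coverage), then per
read only hits within a "top percent" band of the best bitscore are kept;
the read is assigned to the LCA of the retained hits' taxa.  Per-rank count
tables aggregate reads whose assignment lies at or below that rank; reads
resolved only above a rank are "unassigned" at it, and reads with no
retained hit are "unaligned".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable

__all__ = [
    "TaxonomyTree",
    "HitRecord",
    "AssignmentResult",
    "filter_hits",
    "lca",
    "assign_reads",
    "read_blast_tabular",
    "read_taxonomy_tsv",
]

# Ordered from root downwards; assignment depth is compared along this axis.
RANK_ORDER = (
    "root", "kingdom", "phylum", "class", "order", "family", "genus", "species",
)


@dataclass
class TaxonomyTree:
    """Rooted taxonomy: node id -> (parent id, rank, name).

    The root is its own parent.  Ranks come from :data:`RANK_ORDER`;
    intermediate clades may carry the pseudo-rank ``"no rank"``.
    """

    parent: dict[str, str]
    rank: dict[str, str]
    name: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p == n]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for node in self.parent:
            if not self._reaches_root(node):
                raise ValueError(f"node {node!r} does not reach the root")

    def _reaches_root(self, node: str) -> bool:
        seen = set()
        while node != self.parent[node]:
            if node in seen:
                return False
            seen.add(node)
            node = self.parent.get(node, node)
            if node not in self.parent:
                return False
        return True

    def path_to_root(self, node: str) -> list[str]:
        """Node and all ancestors, deepest first."""
        if node not in self.parent:
            raise KeyError(f"unknown taxon id: {node!r}")
        path = [node]
        while node != self.parent[node]:
            node = self.parent[node]
            path.append(node)
        return path

    def ancestor_at_rank(self, node: str, rank: str) -> str | None:
        """The ancestor (or the node itself) carrying ``rank``, if any."""
        for anc in self.path_to_root(node):
            if self.rank.get(anc) == rank:
                return anc
        return None


@dataclass
class HitRecord:
    """One alignment hit of a read against a reference taxon."""

    read_id: str
    taxon_id: str
    bitscore: float
    evalue: float
    qcov: float = 100.0

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for read {self.read_id}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue for read {self.read_id}")
        if not 0 <= self.qcov <= 100:
            raise ValueError(f"query coverage outside [0, 100] for read {self.read_id}")


def filter_hits(
    hits: list[HitRecord],
    min_score: float = 100.0,
    max_evalue: float = 1e-10,
    min_qcov: float = 60.0,
    top_percent: float = 10.0,
) -> dict[str, list[HitRecord]]:
    """Threshold hits, then keep per read only those within the top-percent
    bitscore band of the best hit (inclusive: score >= (1 - tp/100)*best).

    Returns read id -> retained hits.  Reads whose hits all fail the
    thresholds are absent from the result.
    """
    by_read: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        if h.bitscore < min_score or h.evalue > max_evalue or h.qcov < min_qcov:
            continue
        by_read[h.read_id].append(h)
    retained: dict[str, list[HitRecord]] = {}
    band = 1.0 - top_percent / 100.0
    for read, hs in by_read.items():
        best = max(h.bitscore for h in hs)
        kept = [h for h in hs if h.bitscore >= band * best]
        if kept:
            retained[read] = kept
    return retained


def lca(tree: TaxonomyTree, taxon_ids) -> str:
    """Deepest node ancestral to (or equal to) every input taxon.

    Commutative and associative in its input set; ``lca({x}) == x``.
    """
    ids = list(taxon_ids)
    if not ids:
        raise ValueError("lca of an empty taxon set is undefined")
    common = None
    for t in ids:
        path = tree.path_to_root(t)  # raises KeyError naming unknown ids
        if common is None:
            common = path
        else:
            anc = set(path)
            common = [n for n in common if n in anc]
    return common[0]


@dataclass
class AssignmentResult:
    """Per-read LCA assignments plus per-rank aggregate tables."""

    assignments: dict[str, str]           # read id -> taxon id
    unaligned: list[str]                  # reads with no retained hit
    tables: dict[str, AbundanceTable]     # rank -> counts table
    unassigned_at_rank: dict[str, int]    # reads resolved only above a rank
    rates: pd.DataFrame                   # per-rank assigned fraction


def assign_reads(
    tree: TaxonomyTree,
    hits: list[HitRecord],
    read_ids: list[str] | None = None,
    sample_of_read: dict[str, str] | None = None,
    min_score: float = 100.0,
    max_evalue: float = 1e-10,
    min_qcov: float = 60.0,
    top_percent: float = 10.0,
    ranks: tuple[str, ...] = ("phylum", "genus", "species"),
) -> AssignmentResult:
    """Assign each read to the LCA of its retained hits and aggregate counts
    per rank.

    ``read_ids`` may list the full read universe (so reads with no hit at
    all are counted as unaligned); by default the universe is the reads
    appearing in ``hits``.  ``sample_of_read`` maps reads to sample ids for
    the aggregate tables (default: a single sample ``"S1"``).

    A read contributes to a rank's table through its ancestor at that rank;
    a read whose assignment sits *above* the rank is unassigned there.  For
    every rank, assigned + unassigned + unaligned = number of reads.
    """
    retained = filter_hits(hits, min_score=min_score, max_evalue=max_evalue,
                           min_qcov=min_qcov, top_percent=top_percent)
    universe = list(read_ids) if read_ids is not None else sorted(
        {h.read_id for h in hits})
    assignments: dict[str, str] = {}
    unaligned: list[str] = []
    for read in universe:
        hs = retained.get(read)
        if not hs:
            unaligned.append(read)
            continue
        # HSP multiplicity against one taxon is not extra evidence: dedupe.
        taxa = sorted({h.taxon_id for h in hs})
        assignments[read] = lca(tree, taxa)

    sample_of_read = sample_of_read or {}
    samples = sorted(set(sample_of_read.values())) or ["S1"]
    tables: dict[str, AbundanceTable] = {}
    unassigned_at_rank: dict[str, int] = {}
    rate_rows = {}
    n_reads = len(universe)
    for rank in ranks:
        cell: dict[tuple[str, str], int] = defaultdict(int)
        unassigned = 0
        for read, node in assignments.items():
            anc = tree.ancestor_at_rank(node, rank)
            if anc is None:
                unassigned += 1
                continue
            cell[(anc, sample_of_read.get(read, samples[0]))] += 1
        taxa = sorted({t for t, _ in cell})
        counts = pd.DataFrame(0, index=taxa, columns=samples, dtype=np.int64)
        for (t, s), c in cell.items():
            counts.loc[t, s] = c
        if counts.to_numpy().sum() > 0:
            tables[rank] = AbundanceTable(counts, rank=rank)
        unassigned_at_rank[rank] = unassigned
        assigned = len(assignments) - unassigned
        rate_rows[rank] = {
            "assigned": assigned,
            "unassigned": unassigned,
            "unaligned": len(unaligned),
            "fraction_assigned": assigned / n_reads if n_reads else 0.0,
        }
    return AssignmentResult(
        assignments=assignments,
        unaligned=unaligned,
        tables=tables,
        unassigned_at_rank=unassigned_at_rank,
        rates=pd.DataFrame.from_dict(rate_rows, orient="index"),
    )


# Default column order of BLAST tabular output (-outfmt 6), optionally
# followed by qcovhsp.  ``column_map`` can rename/reorder.
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_blast_tabular(
    path,
    taxon_of_subject: dict[str, str] | None = None,
    column_map: tuple[str, ...] | None = None,
) -> list[HitRecord]:
    """Parse BLAST tabular hits into :class:`HitRecord` objects.

    ``taxon_of_subject`` maps subject ids to taxon ids (identity map by
    default).  A 13th column, when present, is taken as qcovhsp.
    Malformed rows raise with their line number.
    """
    cols = column_map or BLAST6_COLUMNS
    qi, si = cols.index("qseqid"), cols.index("sseqid")
    ei, bi = cols.index("evalue"), cols.index("bitscore")
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                subject = parts[si]
                taxon = taxon_of_subject.get(subject, subject) \
                    if taxon_of_subject else subject
                qcov = float(parts[len(cols)]) if len(parts) > len(cols) else 100.0
                hits.append(HitRecord(
                    read_id=parts[qi], taxon_id=taxon,
                    bitscore=float(parts[bi]), evalue=float(parts[ei]),
                    qcov=qcov,
                ))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed BLAST tabular row at line {lineno}: {exc}")
    return hits


def read_taxonomy_tsv(nodes_path, names_path=None) -> TaxonomyTree:
    """Read a taxonomy from TSVs mirroring the NCBI dump semantics:
    nodes (id, parent, rank) and optionally names (id, name)."""
    nodes = pd.read_csv(nodes_path, sep="\t", header=None,
                        names=["id", "parent", "rank"], dtype=str)
    parent = dict(zip(nodes["id"], nodes["parent"]))
    rank = dict(zip(nodes["id"], nodes["rank"]))
    name = {}
    if names_path is not None:
        names = pd.read_csv(names_path, sep="\t", header=None,
                            names=["id", "name"], dtype=str)
        name = dict(zip(names["id"], names["name"]))
    return TaxonomyTree(parent=parent, rank=rank, name=name)
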