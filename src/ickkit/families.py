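"""Gene-family grouping: pairwise identity, homology network, single linkage.

Venom-gland ICK toxins occur as multi-copy gene families.  Families are
defined operationally as connected components of a homology network whose
edges join peptide pairs exceeding identity and overlap thresholds — the
single-linkage criterion used by SiLiX-style clustering of all-against-all
search results.  Edges can be ingested from external search output or
computed with the built-in global aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "HomologyEdge",
    "FamilyPartition",
    "pairwise_identity",
    "build_network",
    "single_linkage_families",
    "dedupe_cds",
]


@dataclass(frozen=True)
class HomologyEdge:
    """Undirected similarity edge; (a, b) and (b, a) are the same edge."""

    id_a: str
    id_b: str
    identity: float  # fraction of aligned (non-gap) columns that match, 0-1
    overlap: float  # aligned span / length of shorter sequence, 0-1

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 1 and 0 <= self.overlap <= 1):
            raise ValueError("identity and overlap must be fractions in [0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.id_a, self.id_b)))


@dataclass(frozen=True)
class FamilyPartition:
    """Assignment of every sequence to exactly one family, ids dense from 1."""

    assignments: dict[str, int]

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for fam in self.assignments.values():
            out[fam] = out.get(fam, 0) + 1
        return out

    def members(self, family_id: int) -> list[str]:
        return sorted(i for i, f in self.assignments.items() if f == family_id)

    @property
    def n_families(self) -> int:
        return len(set(self.assignments.values()))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Identity and overlap of a global alignment with affine gaps.

    Identity is matches over aligned (non-gap) columns; overlap is the
    aligned span over the length of the shorter sequence.  Symmetric by
    construction of the global alignment score.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return 0.0, 0.0
    identity = counts.identities / aligned
    overlap = aligned / min(len(seq_a), len(seq_b))
    return identity, min(overlap, 1.0)


def build_network(
    peptides: Mapping[str, str],
    edges: Iterable[HomologyEdge] | None = None,
    min_identity: float = 0.35,
    min_overlap: float = 0.8,
) -> list[HomologyEdge]:
    """Thresholded homology edge set over *peptides*.

    Keeps edges with ``identity >= min_identity`` and ``overlap >=
    min_overlap``.  When *edges* is not supplied, all pairs are scored with
    :func:`pairwise_identity` (quadratic; intended for modest datasets).
    """
    if edges is None:
        ids = list(peptides)
        edges = [
            HomologyEdge(a, b, *pairwise_identity(peptides[a], peptides[b]))
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        ]
    return [
        e
        for e in edges
        if e.identity >= min_identity and e.overlap >= min_overlap
    ]


def single_linkage_families(
    nodes: Iterable[str],
    edges: Iterable[HomologyEdge],
) -> FamilyPartition:
    """Partition nodes into families = connected components of the network.

    Singletons form their own family.  Family ids are dense from 1, ordered
    by descending size, ties by smallest member id.
    """
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for e in edges:
        if e.id_a not in graph or e.id_b not in graph:
            raise ValueError(f"edge references unknown node: {e.key}")
        graph.add_edge(e.id_a, e.id_b)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    assignments = {
        node: fam for fam, comp in enumerate(components, start=1) for node in comp
    }
    return FamilyPartition(assignments=assignments)


def dedupe_cds(
    records: Sequence[tuple[str, str]] | Mapping[str, str],
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Collapse records sharing an identical CDS string.

    Returns the non-redundant records (first occurrence by input order wins)
    and a map from each collapsed id to its surviving representative.
    """
    items = list(records.items()) if isinstance(records, Mapping) else list(records)
    survivors: list[tuple[str, str]] = []
    rep_by_cds: dict[str, str] = {}
    duplicates: dict[str, str] = {}
    for sid, cds in items:
        key = cds.upper()
        if key in rep_by_cds:
            duplicates[sid] = rep_by_cds[key]
        else:
            rep_by_cds[key] = sid
            survivors.append((sid, cds))
    return survivors, duplicates
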