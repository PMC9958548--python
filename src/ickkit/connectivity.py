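"""Disulfide connectivity: pairing enumeration, prediction ensembles, consensus.

Disulfide connectivity in cysteine-rich peptides cannot be read off the
sequence: the number of complete pairings of ``n`` cysteines is the double
factorial ``(n-1)!!`` and explodes combinatorially.  External predictors give
conflicting answers, so this module ingests an ensemble of predicted maps per
peptide (plus optional experimentally established reference maps), tallies
per-cysteine partner votes for chord-diagram rendering, and computes a
deterministic consensus for the three disulfide bridges that are homologous
across all ICK framework classes — the bridges that anchor the loop
alignment downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .loops import LoopSchema

__all__ = [
    "DisulfideMap",
    "PredictionEnsemble",
    "enumerate_pairings",
    "read_predictions",
    "consensus_connectivity",
    "chord_export",
]

Bond = tuple[int, int]


@dataclass(frozen=True)
class DisulfideMap:
    """A partial perfect matching over cysteine ordinals (1-based).

    ``bonds`` holds unordered pairs, stored sorted; no ordinal may appear in
    more than one bond.
    """

    n_cys: int
    bonds: frozenset[Bond]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"bond pairs a cysteine with itself: ({a},{b})")
            if not (1 <= a <= self.n_cys and 1 <= b <= self.n_cys):
                raise ValueError(f"bond ({a},{b}) outside 1..{self.n_cys}")
            if a > b:
                raise ValueError(f"bonds must be stored as (low, high): ({a},{b})")
            if a in seen or b in seen:
                raise ValueError(f"ordinal used twice in {sorted(self.bonds)}")
            seen.update((a, b))

    @classmethod
    def from_pairs(cls, n_cys: int, pairs: Iterable[Bond]) -> "DisulfideMap":
        return cls(n_cys, frozenset(tuple(sorted(p)) for p in pairs))

    def partner_of(self, ordinal: int) -> int | None:
        for a, b in self.bonds:
            if ordinal == a:
                return b
            if ordinal == b:
                return a
        return None


@dataclass
class PredictionEnsemble:
    """Predicted disulfide maps for one peptide, from multiple sources."""

    peptide_id: str
    n_cys: int
    predictions: list[tuple[str, DisulfideMap]] = field(default_factory=list)
    references: list[tuple[str, DisulfideMap]] = field(default_factory=list)

    def add(self, source: str, dmap: DisulfideMap, reference: bool = False) -> None:
        if dmap.n_cys != self.n_cys:
            raise ValueError(
                f"map n_cys {dmap.n_cys} != ensemble n_cys {self.n_cys}"
            )
        (self.references if reference else self.predictions).append((source, dmap))

    @property
    def all_maps(self) -> list[tuple[str, DisulfideMap]]:
        return self.predictions + self.references


def enumerate_pairings(n_cys: int, max_n: int = 8) -> list[frozenset[Bond]]:
    """All complete pairings (perfect matchings) of ``n_cys`` ordinals.

    There are ``(n_cys - 1)!!`` such pairings; enumeration is refused above
    *max_n* because the count grows double-factorially.
    """
    if n_cys % 2 != 0 or n_cys < 2:
        raise ValueError(f"n_cys must be a positive even number, got {n_cys}")
    if n_cys > max_n:
        raise ValueError(f"n_cys={n_cys} exceeds enumeration limit max_n={max_n}")

    def _match(ordinals: tuple[int, ...]) -> list[frozenset[Bond]]:
        if not ordinals:
            return [frozenset()]
        first, rest = ordinals[0], ordinals[1:]
        out = []
        for i, partner in enumerate(rest):
            remaining = rest[:i] + rest[i + 1 :]
            for sub in _match(remaining):
                out.append(sub | {(first, partner)})
        return out

    return _match(tuple(range(1, n_cys + 1)))


def _parse_bond_list(text: str, n_cys: int) -> DisulfideMap:
    pairs = []
    for chunk in text.strip().split(","):
        a_s, _, b_s = chunk.partition("-")
        pairs.append((int(a_s), int(b_s)))
    return DisulfideMap.from_pairs(n_cys, pairs)


def read_predictions(
    files: Sequence[str | Path],
    dialect: str = "tsv",
    reference_sources: Sequence[str] = (),
) -> dict[str, PredictionEnsemble]:
    """Read normalized prediction tables into per-peptide ensembles.

    The ``tsv`` dialect has four tab-separated columns and no header::

        peptide_id    n_cys    source    bond_list

    where *bond_list* is e.g. ``1-4,2-5,3-6``.  Rows whose source tag appears
    in *reference_sources* are stored as reference maps (they later break
    consensus ties).  Malformed rows raise with their file and line number.
    """
    if dialect != "tsv":
        raise ValueError(f"unrecognized dialect {dialect!r}")
    ensembles: dict[str, PredictionEnsemble] = {}
    for path in files:
        path = Path(path)
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            pid, n_s, source, bond_list = fields
            try:
                n_cys = int(n_s)
                dmap = _parse_bond_list(bond_list, n_cys)
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from None
            ens = ensembles.setdefault(pid, PredictionEnsemble(pid, n_cys))
            ens.add(source, dmap, reference=source in reference_sources)
    return ensembles


def consensus_connectivity(
    ensemble: PredictionEnsemble,
    schema: LoopSchema | Sequence[int] | None = None,
    framework_id: str | None = None,
) -> DisulfideMap:
    """Consensus map for the three bridges homologous to all frameworks.

    For each of the three bridge slots — anchored at the first three bounding
    cysteines of the loop schema (C1, C2 and the left bound of loop 2's right
    side vary by class; ``(1, 2, 3)`` when no schema is given) — the partner
    is chosen by majority vote over all submitted maps.  Ties are broken
    first by the reference maps' votes, then by the lowest partner ordinal.
    Partners already consumed by an earlier slot are skipped so the result is
    always a valid matching.
    """
    if not ensemble.all_maps:
        raise ValueError(f"{ensemble.peptide_id}: empty ensemble, no consensus")
    if isinstance(schema, LoopSchema):
        if framework_id is None:
            raise ValueError("framework_id required when a schema is given")
        anchors = schema.core_bridge_anchors(framework_id)
    elif schema is None:
        anchors = (1, 2, 3)
    else:
        anchors = tuple(schema)
        if len(anchors) != 3:
            raise ValueError("expected exactly three bridge anchors")

    bonds: list[Bond] = []
    used: set[int] = set()
    for anchor in anchors:
        votes: dict[int, int] = {}
        ref_votes: dict[int, int] = {}
        for _, dmap in ensemble.predictions:
            p = dmap.partner_of(anchor)
            if p is not None:
                votes[p] = votes.get(p, 0) + 1
        for _, dmap in ensemble.references:
            p = dmap.partner_of(anchor)
            if p is not None:
                votes[p] = votes.get(p, 0) + 1
                ref_votes[p] = ref_votes.get(p, 0) + 1
        candidates = [p for p in votes if p not in used and p not in anchors]
        if not candidates:
            raise ValueError(
                f"{ensemble.peptide_id}: no usable vote for bridge anchored at "
                f"C{anchor}"
            )
        best = min(
            candidates,
            key=lambda p: (-votes[p], -ref_votes.get(p, 0), p),
        )
        bonds.append(tuple(sorted((anchor, best))))
        used.update((anchor, best))
    return DisulfideMap.from_pairs(ensemble.n_cys, bonds)


def chord_export(ensemble: PredictionEnsemble, path: str | Path | None = None) -> dict:
    """Tally per-cysteine partner votes as chord-diagram data.

    Returns (and optionally writes as JSON) a mapping with one entry per
    cysteine ordinal listing ``[partner, votes]`` pairs.  Votes are conserved:
    they sum to twice the total number of bonds across the ensemble.
    """
    if not ensemble.all_maps:
        raise ValueError(f"{ensemble.peptide_id}: empty ensemble")
    tally: dict[int, dict[int, int]] = {i: {} for i in range(1, ensemble.n_cys + 1)}
    n_bonds = 0
    for _, dmap in ensemble.all_maps:
        for a, b in dmap.bonds:
            n_bonds += 1
            tally[a][b] = tally[a].get(b, 0) + 1
            tally[b][a] = tally[b].get(a, 0) + 1
    data = {
        "peptide_id": ensemble.peptide_id,
        "n_cys": ensemble.n_cys,
        "total_predictions": len(ensemble.all_maps),
        "total_votes": 2 * n_bonds,
        "chords": {
            str(i): sorted([p, v] for p, v in partners.items())
            for i, partners in tally.items()
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(data, indent=2) + "\n")
    return data
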