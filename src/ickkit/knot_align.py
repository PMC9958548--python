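"""Cysteine-anchored knot alignment and codon back-translation.

Aligning cysteine-rich peptides naively invites non-homologous cysteines to
pair up.  This module instead aligns the four inner-cysteine loops shared by
all ICK classes *independently*, under barcode protection: each loop is
extracted with its bounding cysteines replaced by the decoy string
``WWYHWYYHMM`` so inner cysteines cannot migrate onto the flanks during
alignment.  The aligned loops are then reassembled around single, gap-free
anchor cysteine columns, screened with a per-sequence amino-acid composition
chi-squared test (failures removed, survivors realigned), and finally
back-translated to a codon alignment for selection analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .frameworks import cysteine_positions
from .loops import LoopDef, LoopSchema, load_default_schema

__all__ = [
    "BARCODE",
    "LoopSet",
    "KnotAlignment",
    "CodonAlignment",
    "CompositionTestResult",
    "extract_loops",
    "barcode_wrap",
    "barcode_unwrap",
    "align_loops",
    "composition_filter",
    "assemble_alignment",
    "back_translate",
    "build_knot_alignment",
]

#: Decoy string standing in for each flanking cysteine during loop alignment.
BARCODE = "WWYHWYYHMM"

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODON_TO_AA = dict(standard_dna_table.forward_table)


@dataclass(frozen=True)
class LoopSet:
    """The four extracted loops of one peptide, with coordinate bookkeeping.

    ``anchor_positions`` holds the 1-based mature-peptide positions of the
    six distinct bounding cysteines in assembly order (loop1 left, shared
    loop1/2 bound, loop2 right, loop3 left, shared loop3/4 bound, loop4
    right).  ``mature_offset`` is the 0-based offset of the mature peptide
    within the precursor protein (and, times three, within the CDS).
    """

    sequence_id: str
    loops: tuple[str, str, str, str]
    anchor_positions: tuple[int, int, int, int, int, int]
    mature: str
    mature_offset: int = 0

    def reconstructed_spans(self) -> tuple[str, str]:
        """The two contiguous mature regions covered by loops+anchors."""
        p = self.anchor_positions
        left = "C" + self.loops[0] + "C" + self.loops[1] + "C"
        right = "C" + self.loops[2] + "C" + self.loops[3] + "C"
        return left, right


def extract_loops(
    mature_peptide: str,
    framework_id: str,
    schema: LoopSchema | None = None,
    sequence_id: str = "",
    mature_offset: int = 0,
) -> LoopSet:
    """Extract the four homologous loops of *mature_peptide*.

    Loop strings contain the residues strictly between the bounding
    cysteines, with inner (elaboration) cysteines retained in place.
    Residues outside the four loops — N- and C-tails and the linker between
    loop 2 and loop 3 — are excluded.
    """
    schema = schema or load_default_schema()
    loops_def = schema.loops(framework_id)
    mature_peptide = mature_peptide.upper()
    cys = cysteine_positions(mature_peptide)
    max_ord = max(ld.right for ld in loops_def)
    if len(cys) < max_ord:
        raise ValueError(
            f"{sequence_id or 'peptide'}: {len(cys)} cysteines but schema for "
            f"{framework_id} needs ordinal {max_ord}"
        )

    def loop_str(ld: LoopDef) -> str:
        return mature_peptide[cys[ld.left - 1] : cys[ld.right - 1] - 1]

    loops = tuple(loop_str(ld) for ld in loops_def)
    if loops_def[0].right != loops_def[1].left or loops_def[2].right != loops_def[3].left:
        raise ValueError(f"schema row for {framework_id} lacks shared bounds")
    anchor_ords = (
        loops_def[0].left,
        loops_def[0].right,
        loops_def[1].right,
        loops_def[2].left,
        loops_def[2].right,
        loops_def[3].right,
    )
    positions = tuple(cys[o - 1] for o in anchor_ords)
    return LoopSet(
        sequence_id=sequence_id,
        loops=loops,  # type: ignore[arg-type]
        anchor_positions=positions,  # type: ignore[arg-type]
        mature=mature_peptide,
        mature_offset=mature_offset,
    )


def barcode_wrap(loop: str) -> str:
    """Flank *loop* with the barcode standing in for each bounding cysteine."""
    return BARCODE + loop + BARCODE


def barcode_unwrap(aligned: str) -> str:
    """Strip the barcode flanks from an aligned, wrapped loop row.

    The barcode columns must be intact (no gaps, exact barcode residues);
    anything else means the aligner corrupted the protection and is an error.
    """
    if len(aligned) < 2 * len(BARCODE):
        raise ValueError("aligned string shorter than two barcodes")
    head, tail = aligned[: len(BARCODE)], aligned[-len(BARCODE) :]
    if head != BARCODE or tail != BARCODE:
        raise ValueError(
            f"barcode columns corrupted: head={head!r} tail={tail!r}"
        )
    return aligned[len(BARCODE) : -len(BARCODE)]


# --- built-in progressive (center-star) aligner ----------------------------


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def _kmer_profile(s: str, k: int = 3) -> set[str]:
    return {s[i : i + k] for i in range(max(len(s) - k + 1, 1))}


def _pairwise_rows(aligner: PairwiseAligner, a: str, b: str) -> tuple[str, str]:
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def center_star_align(strings: Mapping[str, str]) -> dict[str, str]:
    """Multiple alignment by the center-star heuristic.

    The center sequence (largest summed k-mer similarity, ties by id) is
    aligned pairwise against every other sequence; the pairwise alignments
    are merged on center coordinates with the usual once-a-gap-always-a-gap
    rule.  Exact for identical-length gap-free inputs, adequate for the
    short barcode-wrapped loops it is applied to.
    """
    ids = sorted(strings)
    if not ids:
        return {}
    if len(ids) == 1:
        return {ids[0]: strings[ids[0]]}
    profiles = {i: _kmer_profile(strings[i]) for i in ids}
    center = max(
        ids,
        key=lambda i: (
            sum(len(profiles[i] & profiles[j]) for j in ids if j != i),
            i,
        ),
    )
    c = strings[center]
    aligner = _make_aligner()
    pairwise = {
        i: _pairwise_rows(aligner, c, strings[i]) for i in ids if i != center
    }

    # max insertions before each center position (and after the last)
    ins = np.zeros(len(c) + 1, dtype=int)
    for ca, _ in pairwise.values():
        pos = run = 0
        for ch in ca:
            if ch == "-":
                run += 1
            else:
                ins[pos] = max(ins[pos], run)
                run, pos = 0, pos + 1
        ins[len(c)] = max(ins[len(c)], run)

    def rebuild(ca: str, sa: str) -> str:
        out: list[str] = []
        buf: list[str] = []
        pos = 0
        for ca_ch, sa_ch in zip(ca, sa):
            if ca_ch == "-":
                buf.append(sa_ch)
            else:
                out.append("-" * (ins[pos] - len(buf)) + "".join(buf))
                out.append(sa_ch)
                buf, pos = [], pos + 1
        out.append("-" * (ins[len(c)] - len(buf)) + "".join(buf))
        return "".join(out)

    result = {center: rebuild(c, c)}
    for i, (ca, sa) in pairwise.items():
        result[i] = rebuild(ca, sa)
    widths = {len(r) for r in result.values()}
    assert len(widths) == 1, "merged rows have unequal widths"
    return result


def align_loops(
    loop_sets: Sequence[LoopSet],
) -> list[dict[str, str]]:
    """Align each of the four loops independently under barcode protection.

    Returns four id -> aligned-loop mappings (gaps as ``-``), one per loop.
    Raises if fewer than two sequences are given or a loop row's barcode is
    corrupted by the aligner.
    """
    if len(loop_sets) < 2:
        raise ValueError("need at least 2 sequences to align")
    ids = [ls.sequence_id for ls in loop_sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in loop sets")
    by_id = {ls.sequence_id: ls for ls in loop_sets}
    out: list[dict[str, str]] = []
    for k in range(4):
        wrapped = {sid: barcode_wrap(by_id[sid].loops[k]) for sid in by_id}
        aligned = center_star_align(wrapped)
        out.append({sid: barcode_unwrap(row) for sid, row in aligned.items()})
    return out


# --- composition filter ----------------------------------------------------


@dataclass(frozen=True)
class CompositionTestResult:
    sequence_id: str
    statistic: float
    df: int
    pvalue: float
    passed: bool


def _composition_test(
    residues: Mapping[str, str], alpha: float
) -> list[CompositionTestResult]:
    """Chi-squared test of each sequence's composition against the pool.

    Expected counts come from the gap-excluded composition of all sequences
    pooled; df is fixed at 19 (20 amino-acid classes).
    """
    pooled = np.zeros(len(_AMINO_ACIDS))
    per_seq: dict[str, np.ndarray] = {}
    for sid, seq in residues.items():
        counts = np.array([seq.count(aa) for aa in _AMINO_ACIDS], dtype=float)
        per_seq[sid] = counts
        pooled += counts
    freqs = pooled / pooled.sum()
    results = []
    for sid in sorted(residues):
        obs = per_seq[sid]
        exp = freqs * obs.sum()
        mask = exp > 0
        stat = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
        p = float(stats.chi2.sf(stat, df=19))
        results.append(
            CompositionTestResult(sid, stat, 19, p, passed=p >= alpha)
        )
    return results


def composition_filter(
    loop_sets: Sequence[LoopSet],
    alpha: float = 0.05,
    max_rounds: int = 5,
) -> tuple[list[CompositionTestResult], list[LoopSet], list[dict[str, str]]]:
    """Remove composition outliers and realign the surviving loops.

    Each round tests every remaining sequence's residue composition (all
    four loops pooled, gaps excluded) against the composition of the
    remaining set; sequences with ``p < alpha`` are removed and the expected
    composition is recomputed.  Rounds stop when nothing fails or after
    *max_rounds*.  Returns the last round's test results, the surviving loop
    sets, and their fresh per-loop alignments.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not loop_sets:
        raise ValueError("empty alignment")
    survivors = list(loop_sets)
    results: list[CompositionTestResult] = []
    for _ in range(max_rounds):
        residues = {ls.sequence_id: "".join(ls.loops) for ls in survivors}
        results = _composition_test(residues, alpha)
        failed = {r.sequence_id for r in results if not r.passed}
        if not failed:
            break
        survivors = [ls for ls in survivors if ls.sequence_id not in failed]
        if len(survivors) < 2:
            raise ValueError("composition filter left fewer than 2 sequences")
    return results, survivors, align_loops(survivors)


# --- assembly and back-translation ----------------------------------------


@dataclass
class KnotAlignment:
    """Assembled knot alignment: rows, column labels and position maps.

    Column labels are ``anchor1..anchor6`` for the single-cysteine anchor
    columns and ``loop1..loop4`` for loop columns.  ``position_maps`` gives,
    for every row and column, the 0-based position within the precursor
    protein of the residue there (or ``None`` on a gap), which is what makes
    codon back-translation exact.
    """

    rows: dict[str, str]
    column_labels: list[str]
    position_maps: dict[str, list[int | None]] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return sorted(self.rows)

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def anchor_columns(self) -> list[int]:
        return [
            i for i, lab in enumerate(self.column_labels) if lab.startswith("anchor")
        ]

    def validate(self) -> None:
        for sid, row in self.rows.items():
            if len(row) != len(self.column_labels):
                raise ValueError(f"{sid}: row width != column labels")
        for col in self.anchor_columns():
            bad = [sid for sid, row in self.rows.items() if row[col] != "C"]
            if bad:
                raise ValueError(
                    f"anchor column {col} not all-cysteine (e.g. {bad[0]})"
                )

    def to_fasta(self, path) -> None:
        from pathlib import Path

        text = "".join(f">{sid}\n{self.rows[sid]}\n" for sid in self.ids)
        Path(path).write_text(text)


@dataclass
class CodonAlignment:
    """Codon-level twin of a knot alignment; gap codon ``---``."""

    rows: dict[str, str]

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def to_fasta(self, path) -> None:
        from pathlib import Path

        text = "".join(f">{sid}\n{row}\n" for sid, row in sorted(self.rows.items()))
        Path(path).write_text(text)


def assemble_alignment(
    loop_alignments: Sequence[Mapping[str, str]],
    loop_sets: Sequence[LoopSet],
) -> KnotAlignment:
    """Concatenate the four aligned loops around single anchor-C columns.

    Layout: ``A1 loop1 A2 loop2 A3 | A4 loop3 A5 loop4 A6`` where the six
    anchors are the distinct bounding cysteines (shared bounds emitted
    once).  Every anchor column is all-cysteine and gap-free by
    construction; :meth:`KnotAlignment.validate` re-checks it.
    """
    if len(loop_alignments) != 4:
        raise ValueError("expected exactly four loop alignments")
    by_id = {ls.sequence_id: ls for ls in loop_sets}
    idsets = [set(la) for la in loop_alignments]
    if any(s != set(by_id) for s in idsets):
        raise ValueError("sequence sets differ between loop alignments")

    widths = [len(next(iter(la.values()))) for la in loop_alignments]
    labels: list[str] = []
    layout = [
        ("anchor1", None), ("loop1", 0), ("anchor2", None), ("loop2", 1),
        ("anchor3", None), ("anchor4", None), ("loop3", 2), ("anchor5", None),
        ("loop4", 3), ("anchor6", None),
    ]
    for lab, k in layout:
        labels.extend([lab] if k is None else [f"loop{k+1}"] * widths[k])

    rows: dict[str, str] = {}
    pos_maps: dict[str, list[int | None]] = {}
    anchor_idx = {f"anchor{i+1}": i for i in range(6)}
    for sid, ls in by_id.items():
        row: list[str] = []
        pmap: list[int | None] = []
        loop_cursors = []
        for k in range(4):
            aligned = loop_alignments[k][sid]
            if len(aligned) != widths[k]:
                raise ValueError(f"{sid}: loop {k+1} width mismatch")
            loop_cursors.append(iter(aligned))
        # mature positions of loop residues follow each loop's left anchor
        next_pos = [ls.anchor_positions[i] for i in (0, 1, 3, 4)]  # 1-based
        for lab, k in layout:
            if k is None:
                a = anchor_idx[lab]
                row.append("C")
                pmap.append(ls.mature_offset + ls.anchor_positions[a] - 1)
            else:
                for ch in loop_cursors[k]:
                    row.append(ch)
                    if ch == "-":
                        pmap.append(None)
                    else:
                        pmap.append(ls.mature_offset + next_pos[k])
                        next_pos[k] += 1
        rows[sid] = "".join(row)
        pos_maps[sid] = pmap
    alignment = KnotAlignment(rows=rows, column_labels=labels,
                              position_maps=pos_maps)
    alignment.validate()
    return alignment


def back_translate(
    knot_alignment: KnotAlignment,
    cds_map: Mapping[str, str],
) -> CodonAlignment:
    """Reverse-translate a knot alignment into a codon alignment.

    Every non-gap residue is replaced by its source codon (located via the
    alignment's position maps); gaps become ``---``.  A codon that does not
    translate to the aligned residue raises, so codon/protein consistency is
    guaranteed on every output.
    """
    rows: dict[str, str] = {}
    for sid, row in knot_alignment.rows.items():
        cds = cds_map[sid].upper()
        pmap = knot_alignment.position_maps[sid]
        codons: list[str] = []
        for ch, pos in zip(row, pmap):
            if ch == "-":
                codons.append("---")
                continue
            codon = cds[3 * pos : 3 * pos + 3]
            if _CODON_TO_AA.get(codon) != ch:
                raise ValueError(
                    f"{sid}: codon {codon!r} at protein position {pos} does "
                    f"not encode aligned residue {ch!r}"
                )
            codons.append(codon)
        rows[sid] = "".join(codons)
    return CodonAlignment(rows=rows)


def build_knot_alignment(
    matures: Mapping[str, str],
    framework_ids: Mapping[str, str],
    schema: LoopSchema | None = None,
    mature_offsets: Mapping[str, int] | None = None,
    alpha: float | None = 0.05,
) -> tuple[KnotAlignment, list[CompositionTestResult]]:
    """End-to-end: extract, filter, align and assemble the knot alignment."""
    schema = schema or load_default_schema()
    offsets = mature_offsets or {}
    loop_sets = [
        extract_loops(
            seq,
            framework_ids[sid],
            schema,
            sequence_id=sid,
            mature_offset=offsets.get(sid, 0),
        )
        for sid, seq in matures.items()
    ]
    if alpha is not None:
        results, loop_sets, aligned = composition_filter(loop_sets, alpha)
    else:
        results, aligned = [], align_loops(loop_sets)
    return assemble_alignment(aligned, loop_sets), results
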