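"""ICK candidate screening: the precursor filter cascade and expression summary.

Candidate toxin precursors pass the screen only if they satisfy every enabled
rule: a complete coding sequence (start codon, terminal stop, no internal
stop), a detected N-terminal signal peptide, total length under the length
bound, at least the minimum number of cysteines in the mature peptide, and a
homology match to a knottin reference set at the e-value cutoff.  Rejections
are recorded per rule in a fixed order so the screen is fully auditable.

Signal peptides are normally called by an external predictor whose table is
ingested as :class:`SignalCall` rows; a deterministic built-in heuristic
(N-terminal Met, hydrophobic core, small residues at the -3/-1 positions
before cleavage) is provided for self-contained runs.  Likewise homology
hits are normally ingested from external search output; a built-in seeded
ungapped search against a bundled reference set serves as fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "RULE_ORDER",
    "ScreenCriteria",
    "HomologyHit",
    "SignalCall",
    "ScreenReport",
    "check_complete_cds",
    "call_signal_heuristic",
    "builtin_homology_search",
    "screen_candidates",
    "summarize_expression",
]

#: Fixed audit order of the screen rules.
RULE_ORDER = ("complete_cds", "signal", "max_len", "min_cys", "homology")

_STOP_CODONS = set(standard_dna_table.stop_codons)
_START_CODON = "ATG"
_NT_ALPHABET = set("ACGTN")

# Signal-peptide heuristic geometry: a 22-residue signal with a hydrophobic
# core at positions 6-15 and small residues at the -3/-1 positions.
SIGNAL_LENGTH = 22
_HYDROPHOBIC = set("LVIAFMW")
_SMALL = set("ASG")
_CORE_START, _CORE_END = 6, 15  # 1-based, inclusive
_MIN_CORE_HYDROPHOBIC = 8


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds and switches of the filter cascade.

    ``max_length`` is exclusive and, by default, applies to the full
    precursor (``length_scope="mature"`` restricts it to the post-cleavage
    region).  ``min_cysteines`` is counted on the mature peptide.
    """

    max_length: int = 200
    min_cysteines: int = 6
    evalue_cutoff: float = 1e-3
    require_signal: bool = True
    require_complete_cds: bool = True
    require_homology: bool = True
    length_scope: str = "precursor"

    def __post_init__(self) -> None:
        if self.max_length <= 0:
            raise ValueError("max_length must be positive")
        if self.min_cysteines < 0:
            raise ValueError("min_cysteines must be >= 0")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.length_scope not in ("precursor", "mature"):
            raise ValueError(f"unknown length_scope {self.length_scope!r}")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    evalue: float
    identity: float = 0.0  # percent, 0-100
    overlap: float = 0.0  # fraction of shorter sequence, 0-1
    source: str = "builtin"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be within [0, 100]")


@dataclass(frozen=True)
class SignalCall:
    sequence_id: str
    has_signal: bool
    cleavage: int = 0  # 1-based last residue of the signal region
    source: str = "heuristic"

    def __post_init__(self) -> None:
        if self.has_signal and self.cleavage < 1:
            raise ValueError("cleavage position must be >= 1 when has_signal")


@dataclass
class ScreenReport:
    """Outcome of the cascade: kept ids, per-id rejection reasons, tallies."""

    kept: list[str]
    rejected: dict[str, list[str]]
    rule_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.rejected)
        if overlap:
            raise ValueError(f"ids both kept and rejected: {sorted(overlap)}")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": i, "kept": True, "reasons": ""} for i in self.kept]
        rows += [
            {"id": i, "kept": False, "reasons": ";".join(r)}
            for i, r in self.rejected.items()
        ]
        return pd.DataFrame(rows).set_index("id").sort_index()


def check_complete_cds(cds: str) -> bool:
    """True iff *cds* is a complete coding sequence.

    Complete means: length divisible by three, begins with the start codon,
    ends with a stop codon and contains no internal stop.  Non-nucleotide
    characters raise ``ValueError``.
    """
    seq = cds.upper().replace("U", "T")
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in CDS: {sorted(bad)}")
    if len(seq) < 6 or len(seq) % 3 != 0:
        return False
    if seq[:3] != _START_CODON:
        return False
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] not in _STOP_CODONS:
        return False
    return not any(c in _STOP_CODONS for c in codons[:-1])


def call_signal_heuristic(protein: str, sequence_id: str = "") -> SignalCall:
    """Deterministic signal-peptide call.

    Detects the canonical construction: Met start, a hydrophobic core
    (>= 8 of positions 6-15 in LVIAFMW), small residues (A/S/G) at the -3 and
    -1 positions before a cleavage site after residue 22, and no cysteine in
    the signal region.  Mimics the decision surface of neural predictors on
    textbook signal peptides without claiming their generality.
    """
    protein = protein.upper()
    if not protein:
        raise ValueError("empty protein sequence")
    region = protein[:SIGNAL_LENGTH]
    has = (
        len(protein) > SIGNAL_LENGTH
        and protein[0] == "M"
        and sum(aa in _HYDROPHOBIC for aa in protein[_CORE_START - 1 : _CORE_END])
        >= _MIN_CORE_HYDROPHOBIC
        and protein[SIGNAL_LENGTH - 3] in _SMALL
        and protein[SIGNAL_LENGTH - 1] in _SMALL
        and "C" not in region
    )
    return SignalCall(
        sequence_id=sequence_id,
        has_signal=has,
        cleavage=SIGNAL_LENGTH if has else 0,
        source="heuristic",
    )


# --- built-in homology fallback -------------------------------------------

# Ungapped Karlin-Altschul parameters for BLOSUM62.
_KA_LAMBDA = 0.3176
_KA_K = 0.134
_SEED_LEN = 3


def _load_reference() -> dict[str, str]:
    from Bio import SeqIO

    ref_path = resources.files("ickkit.data").joinpath(
        "synthetic_knottin_reference.fasta"
    )
    with ref_path.open() as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def _best_ungapped_score(query: str, subject: str, matrix) -> int:
    """Best seeded ungapped local alignment score (word size 3)."""
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - _SEED_LEN + 1):
        index.setdefault(subject[j : j + _SEED_LEN], []).append(j)
    best = 0
    seen: set[int] = set()  # diagonals already extended
    for i in range(len(query) - _SEED_LEN + 1):
        for j in index.get(query[i : i + _SEED_LEN], ()):
            diag = i - j
            if diag in seen:
                continue
            seen.add(diag)
            # extend the full diagonal and take its best segment
            qi, sj = (diag, 0) if diag >= 0 else (0, -diag)
            score = run = 0
            while qi < len(query) and sj < len(subject):
                pair = (query[qi], subject[sj])
                run = max(0, run + matrix[pair])
                score = max(score, run)
                qi += 1
                sj += 1
            best = max(best, score)
    return int(best)


def builtin_homology_search(
    proteins: Mapping[str, str],
    reference: Mapping[str, str] | None = None,
    search_space: float | None = None,
) -> list[HomologyHit]:
    """Seeded ungapped search of *proteins* against a knottin reference set.

    A stand-in producing BLAST-like e-values from ungapped Karlin-Altschul
    statistics; used only when no external hit tables are supplied.  The
    bundled reference is a synthetic knottin set generated by this package.
    """
    if reference is None:
        reference = _load_reference()
    matrix = substitution_matrices.load("BLOSUM62")
    n_db = sum(len(s) for s in reference.values())
    hits: list[HomologyHit] = []
    for qid, qseq in proteins.items():
        qseq = qseq.upper()
        best_e, best_sid = math.inf, None
        for sid, sseq in reference.items():
            score = _best_ungapped_score(qseq, sseq.upper(), matrix)
            if score <= 0:
                continue
            m_n = search_space if search_space is not None else len(qseq) * n_db
            evalue = _KA_K * m_n * math.exp(-_KA_LAMBDA * score)
            if evalue < best_e:
                best_e, best_sid = evalue, sid
        if best_sid is not None:
            hits.append(HomologyHit(qid, best_sid, best_e, source="builtin"))
    return hits


def screen_candidates(
    proteins: Mapping[str, str],
    cds_map: Mapping[str, str] | None = None,
    hits: Iterable[HomologyHit] | None = None,
    signal_calls: Mapping[str, SignalCall] | None = None,
    criteria: ScreenCriteria | None = None,
) -> ScreenReport:
    """Run the full filter cascade over candidate precursors.

    A sequence is kept iff it passes every enabled rule; rejection reasons
    are recorded in the fixed order :data:`RULE_ORDER`.  When *signal_calls*
    is absent the built-in heuristic is used; when *hits* is absent and the
    homology rule is enabled, the built-in reference search is run.
    """
    criteria = criteria or ScreenCriteria()
    ids = list(proteins)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in input")

    if criteria.require_complete_cds:
        if cds_map is None:
            raise ValueError("CDS rule enabled but no cds_map given")
        missing = [i for i in ids if i not in cds_map]
        if missing:
            raise ValueError(f"missing CDS for: {missing[:5]}")

    if signal_calls is None:
        signal_calls = {
            i: call_signal_heuristic(proteins[i], sequence_id=i) for i in ids
        }
    if hits is None and criteria.require_homology:
        hits = builtin_homology_search(proteins)
    best_evalue: dict[str, float] = {}
    for h in hits or ():
        if h.query_id not in best_evalue or h.evalue < best_evalue[h.query_id]:
            best_evalue[h.query_id] = h.evalue

    kept: list[str] = []
    rejected: dict[str, list[str]] = {}
    rule_counts = {rule: 0 for rule in RULE_ORDER}
    for sid in ids:
        protein = proteins[sid].upper().rstrip("*")
        call = signal_calls.get(sid, SignalCall(sid, False))
        mature = protein[call.cleavage :] if call.has_signal else protein
        scope = protein if criteria.length_scope == "precursor" else mature
        reasons = []
        if criteria.require_complete_cds and not check_complete_cds(cds_map[sid]):
            reasons.append("complete_cds")
        if criteria.require_signal and not call.has_signal:
            reasons.append("signal")
        if len(scope) >= criteria.max_length:
            reasons.append("max_len")
        if mature.count("C") < criteria.min_cysteines:
            reasons.append("min_cys")
        if criteria.require_homology and not (
            sid in best_evalue and best_evalue[sid] <= criteria.evalue_cutoff
        ):
            reasons.append("homology")
        if reasons:
            rejected[sid] = reasons
            for r in reasons:
                rule_counts[r] += 1
        else:
            kept.append(sid)
    return ScreenReport(kept=kept, rejected=rejected, rule_counts=rule_counts)


def summarize_expression(
    peptide_ids: Mapping[str, Sequence[str]],
    ick_flags: Mapping[str, bool],
    tpm_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample peptide/ICK composition and expression share.

    *peptide_ids* maps sample -> peptide ids detected in that sample;
    *ick_flags* marks which ids are ICKs; *tpm_table* holds TPM values with
    peptide ids as index and samples as columns.  Returns one row per sample
    with peptide and ICK counts, %ICK, summed TPM, ICK TPM and %TPM.
    """
    if (tpm_table < 0).any().any():
        raise ValueError("negative TPM values")
    rows = []
    for sample, ids in peptide_ids.items():
        ids = list(ids)
        icks = [i for i in ids if ick_flags.get(i, False)]
        missing = [i for i in icks if i not in tpm_table.index]
        if missing:
            raise ValueError(f"flagged ids missing from TPM table: {missing[:5]}")
        col = tpm_table[sample]
        sum_tpm = float(col.loc[[i for i in ids if i in tpm_table.index]].sum())
        ick_tpm = float(col.loc[icks].sum()) if icks else 0.0
        rows.append(
            {
                "sample": sample,
                "peptides": len(ids),
                "icks": len(icks),
                "pct_ick": 100.0 * len(icks) / len(ids) if ids else 0.0,
                "sum_tpm": sum_tpm,
                "ick_tpm": ick_tpm,
                "pct_tpm": 100.0 * ick_tpm / sum_tpm if sum_tpm > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("sample")
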