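"""Synthetic venom-gland-like datasets with full ground truth.

Every downstream stage of the pipeline (screen, framework classification,
family clustering, loop alignment, selection summaries) is testable without
any downloads because this module fabricates the inputs with known answers:

* toxin precursors = a constructed signal peptide (Met start, hydrophobic
  core, small -3/-1 residues) followed by a mature cysteine-rich peptide
  realizing a chosen framework motif exactly;
* multi-copy gene families related by codon substitution along a random
  tree, with per-site dN/dS (omega) drawn from a site-class profile —
  mostly purifying, a few episodic positively selected sites — and the
  structural cysteine codons held invariant so descendants keep their
  framework;
* decoy precursors that each violate exactly one screen rule while
  satisfying all the others.

No indels are simulated, so the true alignment is the ungapped homology map
and the dN/dS oracle is exact.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .connectivity import DisulfideMap
from .frameworks import (
    TOKEN_CC,
    TOKEN_CXC,
    TOKEN_LOOP,
    FrameworkCatalog,
    load_default_catalog,
)
from .loops import LoopSchema, load_default_schema
from .screen import RULE_ORDER, SIGNAL_LENGTH

__all__ = [
    "GeneratorConfig",
    "ToxinPrecursor",
    "TruthRecord",
    "Dataset",
    "make_precursor",
    "evolve_family",
    "make_decoys",
    "generate_dataset",
    "emit_dataset",
]

_MAX_SEED = 2**31 - 1

# Codon machinery from the standard table (61 sense codons).
_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, ())
    _AA_TO_CODONS[_aa] += (_codon,)

_NON_CYS_AAS = sorted(set(_AA_TO_CODONS) - {"C"})
_HYDRO_CORE = "LVIAF"
_SMALL = "ASG"
# neutral filler for signal positions outside the core (no C, not hydrophobic)
_SIGNAL_FILLER = "DEKNQRST"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for dataset generation.

    ``framework_mix`` defaults to the relative class abundances observed in
    lycosoid venom-gland surveys (the 8-cysteine class dominates).
    ``omega_profile`` maps site-class name -> (omega, proportion): mostly
    purifying sites, a thin neutral band, and a small positively selected
    class.  ``substitution_rate`` is the mean branch length in expected
    substitutions per codon site; the default keeps within-family protein
    identity around 0.9-0.95, matching recently duplicated venom gene
    families and the divergence range where pairwise counting estimators
    are informative.
    """

    seed: int = 0
    n_families: int = 3
    framework_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "6.0": 0.128,
            "8.0": 0.560,
            "10.0": 0.122,
            "10.1": 0.024,
            "12.0": 0.104,
            "12.1": 0.028,
            "14.0": 0.034,
        }
    )
    loop_length_range: tuple[int, int] = (2, 10)
    family_size_range: tuple[int, int] = (4, 12)
    substitution_rate: float = 0.05
    omega_profile: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "conserved": (0.1, 0.85),
            "neutral": (1.0, 0.10),
            "positive": (5.0, 0.05),
        }
    )
    n_decoys: int = 10
    decoy_violation_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "complete_cds": 0.2,
            "signal": 0.2,
            "max_len": 0.2,
            "min_cys": 0.2,
            "homology": 0.2,
        }
    )
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        for name, mix in (
            ("framework_mix", dict(self.framework_mix)),
            ("decoy_violation_mix", dict(self.decoy_violation_mix)),
        ):
            total = sum(mix.values())
            if mix and abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {total}, expected 1")
        total = sum(p for _, p in self.omega_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"omega_profile proportions sum to {total}, expected 1")
        if any(w <= 0 for w, _ in self.omega_profile.values()):
            raise ValueError("omega values must be > 0")
        for name, rng_pair in (
            ("loop_length_range", self.loop_length_range),
            ("family_size_range", self.family_size_range),
        ):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"empty range {name}={rng_pair}")
        if self.loop_length_range[0] < 2:
            raise ValueError("loop lengths below 2 would change the spacing class")


@dataclass(frozen=True)
class ToxinPrecursor:
    """A precursor protein (signal + mature) with its source CDS."""

    sequence_id: str
    protein: str
    signal_end: int  # 1-based last residue of the signal; 0 = none
    cds: str

    @property
    def mature(self) -> str:
        return self.protein[self.signal_end :]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth attached to one generated sequence."""

    sequence_id: str
    framework_id: str = ""
    signal_span: tuple[int, int] = (0, 0)  # 1-based inclusive; (0,0) = none
    family_id: int = 0
    disulfide: DisulfideMap | None = None
    omega_per_site: tuple[float, ...] = ()  # mature codon sites; 0 = invariant
    tip_label: str = ""
    violations: tuple[str, ...] = ()


@dataclass
class Dataset:
    """In-memory synthetic dataset: records, truth, and per-family trees."""

    precursors: list[ToxinPrecursor]
    truth: dict[str, TruthRecord]
    trees: dict[int, str]  # family id -> newick
    hits_evalue: dict[str, float]  # id -> e-value against the toy reference

    @property
    def proteins(self) -> dict[str, str]:
        return {p.sequence_id: p.protein for p in self.precursors}

    @property
    def cds_map(self) -> dict[str, str]:
        return {p.sequence_id: p.cds for p in self.precursors}


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, _MAX_SEED))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS for *protein* with codons drawn uniformly among synonyms."""
    codons = [
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in protein
    ]
    return "".join(codons)


def _make_signal(rng: np.random.Generator) -> str:
    """22-residue signal: M + filler + hydrophobic core (6-15) + A/S/G at -3/-1."""
    out = ["M"]
    for pos in range(2, SIGNAL_LENGTH + 1):
        if 6 <= pos <= 15:
            out.append(_HYDRO_CORE[rng.integers(len(_HYDRO_CORE))])
        elif pos in (SIGNAL_LENGTH - 2, SIGNAL_LENGTH):
            out.append(_SMALL[rng.integers(len(_SMALL))])
        else:
            out.append(_SIGNAL_FILLER[rng.integers(len(_SIGNAL_FILLER))])
    return "".join(out)


def _true_disulfide(framework_id: str, n_cys: int, schema: LoopSchema) -> DisulfideMap:
    """Ground-truth connectivity: core knot bridges + consecutive extra pairs."""
    bounds = schema.bounding_ordinals(framework_id)
    bonds = [(bounds[i], bounds[i + 3]) for i in range(3)]
    used = set(bounds)
    extras = [i for i in range(1, n_cys + 1) if i not in used]
    bonds += [(a, b) for a, b in zip(extras[::2], extras[1::2])]
    return DisulfideMap.from_pairs(n_cys, bonds)


def make_precursor(
    framework_id: str,
    loop_lengths: Sequence[int],
    seed: int,
    *,
    sequence_id: str = "synthetic",
    catalog: FrameworkCatalog | None = None,
    schema: LoopSchema | None = None,
    ntail: int = 1,
    ctail: int = 2,
) -> tuple[ToxinPrecursor, TruthRecord]:
    """Build one precursor realizing *framework_id* exactly.

    *loop_lengths* gives the residue gap for each ``C-C`` token of the
    framework, in order (``CC`` and ``CXC`` gaps are fixed at 0 and 1 by the
    grammar).  The mature peptide is *ntail* residues, the cysteine scaffold
    with random non-cysteine loop residues, then *ctail* residues.  The CDS
    begins with the start codon (the signal Met) and ends with a stop.
    """
    catalog = catalog or load_default_catalog()
    fw = catalog.get(framework_id)
    loop_tokens = [t for t in fw.tokens if t == TOKEN_LOOP]
    if len(loop_lengths) != len(loop_tokens):
        raise ValueError(
            f"framework {framework_id} has {len(loop_tokens)} C-C gaps, "
            f"got {len(loop_lengths)} loop lengths"
        )
    if any(n < 2 for n in loop_lengths):
        raise ValueError("C-C gaps need at least 2 residues")
    rng = np.random.default_rng(seed)

    def fill(n: int) -> str:
        return "".join(
            _NON_CYS_AAS[i] for i in rng.integers(len(_NON_CYS_AAS), size=n)
        )

    gaps = iter(loop_lengths)
    mature = [fill(ntail), "C"]
    for tok in fw.tokens:
        if tok == TOKEN_CC:
            mature.append("C")
        elif tok == TOKEN_CXC:
            mature.append(fill(1) + "C")
        else:
            mature.append(fill(next(gaps)) + "C")
    mature.append(fill(ctail))
    mature_str = "".join(mature)
    signal = _make_signal(rng)
    protein = signal + mature_str
    if len(protein) >= 200:
        raise ValueError(
            f"loop lengths force precursor length {len(protein)} >= 200"
        )
    cds = _reverse_translate(protein, rng)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    schema = schema or load_default_schema()
    disulfide = (
        _true_disulfide(framework_id, fw.n_cys, schema)
        if framework_id in schema
        else None
    )
    precursor = ToxinPrecursor(
        sequence_id=sequence_id,
        protein=protein,
        signal_end=SIGNAL_LENGTH,
        cds=cds + stop,
    )
    truth = TruthRecord(
        sequence_id=sequence_id,
        framework_id=framework_id,
        signal_span=(1, SIGNAL_LENGTH),
        disulfide=disulfide,
    )
    return precursor, truth


# --- codon evolution -------------------------------------------------------


def _codon_neighbors(codon: str) -> list[tuple[str, bool]]:
    """Single-nucleotide neighbors of *codon*: (neighbor, is_synonymous)."""
    aa = _CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            out.append((alt, _CODON_TO_AA[alt] == aa))
    return out


def _evolve_codon(
    codon: str,
    omega: float,
    t: float,
    rng: np.random.Generator,
    forbid_aas: frozenset[str],
) -> str:
    """Gillespie simulation of one codon site for duration *t*.

    Per-neighbor base rate is 1/9 so the total neutral rate is about one
    substitution per unit branch length; nonsynonymous rates are scaled by
    *omega*.  Mutations creating an amino acid in *forbid_aas* are rejected
    (used to keep the cysteine scaffold intact).
    """
    while t > 0:
        moves = []
        rates = []
        for alt, syn in _codon_neighbors(codon):
            if not syn and _CODON_TO_AA[alt] in forbid_aas:
                continue
            moves.append(alt)
            rates.append((1.0 if syn else omega) / 9.0)
        total = sum(rates)
        if total == 0:
            break
        t -= rng.exponential(1.0 / total)
        if t <= 0:
            break
        probs = np.asarray(rates) / total
        codon = moves[rng.choice(len(moves), p=probs)]
    return codon


def evolve_family(
    root_cds: str,
    tree: "dendropy.Tree | str",
    omega_per_site: Sequence[float],
    seed: int,
    *,
    protected_codons: Iterable[int] = (),
    forbid_aas: frozenset[str] = frozenset({"C"}),
) -> tuple[dict[str, str], dict[str, str]]:
    """Evolve *root_cds* along *tree* with per-codon-site omega.

    Returns ``(tip_cds, tip_protein)`` keyed by tip label.  *protected_codons*
    (0-based codon indices, e.g. the structural cysteines and the signal
    region) never change; elsewhere substitutions are drawn from a
    continuous-time codon model whose nonsynonymous rates are scaled by
    ``omega_per_site[i]``.  Because no indels are simulated, the returned
    sequences are the true (ungapped) alignment.
    """
    root_cds = root_cds.upper()
    if len(root_cds) % 3 != 0:
        raise ValueError("root CDS length must be divisible by 3")
    codons = [root_cds[i : i + 3] for i in range(0, len(root_cds), 3)]
    has_stop = codons and codons[-1] in _STOPS
    sense = codons[:-1] if has_stop else codons
    if any(c in _STOPS for c in sense):
        raise ValueError("internal stop codon in root CDS")
    if len(omega_per_site) != len(sense):
        raise ValueError(
            f"omega_per_site has {len(omega_per_site)} entries for "
            f"{len(sense)} sense codons"
        )
    if any(w < 0 for w in omega_per_site):
        raise ValueError("omega must be >= 0")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tips = tree.leaf_nodes()
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")

    protected = set(protected_codons)
    rng = np.random.default_rng(seed)
    states: dict[int, list[str]] = {id(tree.seed_node): list(sense)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        child = list(parent)
        if t > 0:
            for i, codon in enumerate(parent):
                if i in protected:
                    continue
                child[i] = _evolve_codon(
                    codon, omega_per_site[i], t, rng, forbid_aas
                )
        states[id(node)] = child

    stop = codons[-1] if has_stop else ""
    tip_cds: dict[str, str] = {}
    tip_protein: dict[str, str] = {}
    for leaf in tips:
        label = leaf.taxon.label if leaf.taxon else str(id(leaf))
        seq = states[id(leaf)]
        tip_cds[label] = "".join(seq) + stop
        tip_protein[label] = "".join(_CODON_TO_AA[c] for c in seq)
    return tip_cds, tip_protein


def random_tree(n_tips: int, rng: np.random.Generator, mean_branch: float) -> str:
    """Random bifurcating newick over ``t1..tn`` with exponential branches."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    nodes = [f"t{i+1}" for i in range(n_tips)]

    def blen() -> str:
        return f"{rng.exponential(mean_branch):.6f}"

    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({a}:{blen()},{b}:{blen()})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


# --- decoys ----------------------------------------------------------------


def make_decoys(
    n: int,
    violation_mix: Mapping[str, float],
    seed: int,
    *,
    catalog: FrameworkCatalog | None = None,
) -> list[tuple[ToxinPrecursor, TruthRecord]]:
    """Decoy precursors, each violating exactly one screen rule.

    Rule names follow the screen module's audit order; counts per rule follow
    *violation_mix* proportions (largest remainders resolve rounding).  Each
    decoy satisfies every rule it was not assigned to violate; the
    ``homology`` violation is realized downstream by the emitted hit table,
    which gives such decoys only an above-cutoff e-value.
    """
    unknown = set(violation_mix) - set(RULE_ORDER)
    if unknown:
        raise ValueError(f"unknown screen rule(s): {sorted(unknown)}")
    catalog = catalog or load_default_catalog()
    rng = np.random.default_rng(seed)

    # integer apportionment by largest remainder
    rules = sorted(violation_mix)
    quotas = {r: violation_mix[r] * n for r in rules}
    counts = {r: int(quotas[r]) for r in rules}
    short = n - sum(counts.values())
    for r in sorted(rules, key=lambda r: quotas[r] - counts[r], reverse=True)[:short]:
        counts[r] += 1

    out: list[tuple[ToxinPrecursor, TruthRecord]] = []
    idx = 0
    for rule in rules:
        for _ in range(counts[rule]):
            idx += 1
            sid = f"D{idx:04d}"
            base_seed = _child_seed(rng)
            n_loops = sum(1 for t in catalog.get("8.0").tokens if t == TOKEN_LOOP)
            lengths = [3] * n_loops
            if rule == "min_cys":
                # 5 cysteines, well spaced; cannot realize any 6+ framework
                base_rng = np.random.default_rng(base_seed)
                signal = _make_signal(base_rng)
                mature = "".join(
                    "C".join(
                        "".join(
                            _NON_CYS_AAS[i]
                            for i in base_rng.integers(len(_NON_CYS_AAS), size=4)
                        )
                        for _ in range(6)
                    )
                )
                protein = signal + mature
                cds = _reverse_translate(protein, base_rng) + "TAA"
                prec = ToxinPrecursor(sid, protein, SIGNAL_LENGTH, cds)
            else:
                prec, _ = make_precursor(
                    "8.0", lengths, base_seed, sequence_id=sid, catalog=catalog
                )
                if rule == "complete_cds":
                    prec = ToxinPrecursor(
                        sid, prec.protein, prec.signal_end, prec.cds[:-3]
                    )
                elif rule == "signal":
                    # destroy the hydrophobic core; keep everything else legal
                    broken = prec.protein[:5] + "K" * 10 + prec.protein[15:]
                    sub_rng = np.random.default_rng(base_seed + 1)
                    cds = _reverse_translate(broken, sub_rng) + prec.cds[-3:]
                    prec = ToxinPrecursor(sid, broken, 0, cds)
                elif rule == "max_len":
                    pad_rng = np.random.default_rng(base_seed + 2)
                    pad = "".join(
                        _NON_CYS_AAS[i]
                        for i in pad_rng.integers(
                            len(_NON_CYS_AAS), size=250 - len(prec.protein)
                        )
                    )
                    protein = prec.protein + pad
                    cds = prec.cds[:-3] + _reverse_translate(pad, pad_rng) + prec.cds[-3:]
                    prec = ToxinPrecursor(sid, protein, prec.signal_end, cds)
                # rule == "homology": sequence is a perfectly good ICK; the
                # hit table simply never grants it a significant match
            truth = TruthRecord(sequence_id=sid, violations=(rule,))
            out.append((prec, truth))
    return out


# --- whole datasets --------------------------------------------------------

#: e-values written to the emitted hit table
HIT_EVALUE_GOOD = 1e-30
HIT_EVALUE_WEAK = 1e-2


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate families of evolved ICK precursors plus decoys, with truth."""
    rng = np.random.default_rng(config.seed)
    catalog = load_default_catalog()
    schema = load_default_schema()
    fw_ids = sorted(config.framework_mix)
    fw_probs = np.asarray([config.framework_mix[f] for f in fw_ids])
    classes = sorted(config.omega_profile)
    class_probs = np.asarray([config.omega_profile[c][1] for c in classes])

    precursors: list[ToxinPrecursor] = []
    truth: dict[str, TruthRecord] = {}
    trees: dict[int, str] = {}
    hits: dict[str, float] = {}

    for fam in range(1, config.n_families + 1):
        framework_id = fw_ids[rng.choice(len(fw_ids), p=fw_probs / fw_probs.sum())]
        fw = catalog.get(framework_id)
        n_loops = sum(1 for t in fw.tokens if t == TOKEN_LOOP)
        lo, hi = config.loop_length_range
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_loops)]
        root, root_truth = make_precursor(
            framework_id,
            lengths,
            _child_seed(rng),
            sequence_id=f"F{fam:03d}_root",
            catalog=catalog,
            schema=schema,
        )
        size = int(rng.integers(config.family_size_range[0],
                                config.family_size_range[1] + 1))
        newick = random_tree(size, rng, config.substitution_rate)
        trees[fam] = newick

        n_codons = len(root.cds) // 3 - 1  # minus stop
        # protect the signal and every cysteine codon of the mature region
        mature_offset = SIGNAL_LENGTH
        protected = set(range(mature_offset))
        protected |= {
            mature_offset + i for i, aa in enumerate(root.mature) if aa == "C"
        }
        omega = np.empty(n_codons)
        for i in range(n_codons):
            cls = classes[rng.choice(len(classes), p=class_probs / class_probs.sum())]
            omega[i] = config.omega_profile[cls][0]
        omega[sorted(protected)] = 0.0

        tip_cds, tip_protein = evolve_family(
            root.cds,
            newick,
            omega,
            _child_seed(rng),
            protected_codons=protected,
        )
        mature_omega = tuple(float(w) for w in omega[mature_offset:])
        for tip in sorted(tip_cds):
            sid = f"F{fam:03d}_{tip}"
            prec = ToxinPrecursor(
                sequence_id=sid,
                protein=tip_protein[tip],
                signal_end=SIGNAL_LENGTH,
                cds=tip_cds[tip],
            )
            precursors.append(prec)
            truth[sid] = TruthRecord(
                sequence_id=sid,
                framework_id=framework_id,
                signal_span=(1, SIGNAL_LENGTH),
                family_id=fam,
                disulfide=root_truth.disulfide,
                omega_per_site=mature_omega,
                tip_label=tip,
            )
            hits[sid] = HIT_EVALUE_GOOD

    for prec, rec in make_decoys(
        config.n_decoys, dict(config.decoy_violation_mix), _child_seed(rng),
        catalog=catalog,
    ):
        precursors.append(prec)
        truth[prec.sequence_id] = rec
        hits[prec.sequence_id] = (
            HIT_EVALUE_WEAK if "homology" in rec.violations else HIT_EVALUE_GOOD
        )

    # optional forced duplicates for the deduplication oracle
    ick_ids = [p.sequence_id for p in precursors if not truth[p.sequence_id].violations]
    for d in range(config.n_duplicates):
        src_id = ick_ids[int(rng.integers(len(ick_ids)))]
        src = next(p for p in precursors if p.sequence_id == src_id)
        sid = f"DUP{d:03d}_{src_id}"
        precursors.append(
            ToxinPrecursor(sid, src.protein, src.signal_end, src.cds)
        )
        rec = truth[src_id]
        truth[sid] = TruthRecord(
            sequence_id=sid,
            framework_id=rec.framework_id,
            signal_span=rec.signal_span,
            family_id=rec.family_id,
            disulfide=rec.disulfide,
            omega_per_site=rec.omega_per_site,
            tip_label=rec.tip_label,
        )
        hits[sid] = HIT_EVALUE_GOOD

    return Dataset(precursors=precursors, truth=truth, trees=trees,
                   hits_evalue=hits)


def emit_dataset(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a generated dataset to *outdir* as plain-text files.

    Emits protein and CDS FASTA, a truth table (TSV), a homology hit table
    (TSV: query, subject, evalue), per-family newick trees and a uniform toy
    TPM table.  Identical configs produce byte-identical files.
    """
    ds = generate_dataset(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.fasta",
        "cds": outdir / "cds.fasta",
        "truth": outdir / "truth.tsv",
        "hits": outdir / "hits.tsv",
        "trees": outdir / "trees.nwk",
        "tpm": outdir / "tpm.tsv",
    }
    with paths["proteins"].open("w") as fh:
        for p in ds.precursors:
            fh.write(f">{p.sequence_id}\n{p.protein}\n")
    with paths["cds"].open("w") as fh:
        for p in ds.precursors:
            fh.write(f">{p.sequence_id}\n{p.cds}\n")
    with paths["truth"].open("w") as fh:
        fh.write(
            "sequence_id\tframework_id\tsignal_start\tsignal_end\tfamily_id\t"
            "bonds\tomega_per_site\ttip_label\tviolations\n"
        )
        for p in ds.precursors:
            r = ds.truth[p.sequence_id]
            bonds = (
                ",".join(f"{a}-{b}" for a, b in sorted(r.disulfide.bonds))
                if r.disulfide
                else ""
            )
            omega = ",".join(f"{w:g}" for w in r.omega_per_site)
            fh.write(
                f"{r.sequence_id}\t{r.framework_id}\t{r.signal_span[0]}\t"
                f"{r.signal_span[1]}\t{r.family_id}\t{bonds}\t{omega}\t"
                f"{r.tip_label}\t{';'.join(r.violations)}\n"
            )
    with paths["hits"].open("w") as fh:
        fh.write("query_id\tsubject_id\tevalue\n")
        for p in ds.precursors:
            fh.write(
                f"{p.sequence_id}\tknottin_ref\t{ds.hits_evalue[p.sequence_id]:g}\n"
            )
    with paths["trees"].open("w") as fh:
        for fam in sorted(ds.trees):
            fh.write(f"[family {fam}] {ds.trees[fam]}\n")
    with paths["tpm"].open("w") as fh:
        fh.write("sequence_id\tS1\n")
        for p in ds.precursors:
            fh.write(f"{p.sequence_id}\t10.0\n")
    return paths
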