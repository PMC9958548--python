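"""Cysteine-framework grammar: tokenization, motif parsing and catalog assignment.

A *cysteine framework* is the ordered spacing pattern of the cysteines in a
mature peptide.  Consecutive cysteines are classified by the number of
intervening residues:

* gap 0  -> ``CC``   (directly adjacent)
* gap 1  -> ``CXC``  (one residue apart)
* gap >1 -> ``C-C``  (more than one residue apart)

A framework with *n* cysteines therefore carries ``n - 1`` spacing tokens and
renders to a motif string such as ``C1-C2-C3C4-C5XC6-C7XC8``.  Frameworks are
named ``"n.k"`` where *n* is the cysteine count and *k* a variant index that
distinguishes frameworks with equal cysteine counts but different spacing.

The packaged catalog holds the seven framework classes recovered from
lycosoid-spider venom-gland transcriptomes, keyed both by identifier and,
where one exists, by the Roman-numeral designation used in earlier work on
*Phoneutria nigriventer* cysteine-rich toxins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TOKEN_CC",
    "TOKEN_CXC",
    "TOKEN_LOOP",
    "CysteinePattern",
    "CysteineFramework",
    "FrameworkCatalog",
    "cysteine_positions",
    "tokenize_cysteines",
    "parse_motif",
    "render_motif",
    "assign_framework",
    "top_coverage_filter",
    "load_default_catalog",
]

TOKEN_CC = "CC"
TOKEN_CXC = "CXC"
TOKEN_LOOP = "C-C"

_VALID_TOKENS = frozenset({TOKEN_CC, TOKEN_CXC, TOKEN_LOOP})


@dataclass(frozen=True)
class CysteinePattern:
    """Ordered 1-based cysteine positions within a mature peptide."""

    sequence_id: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise ValueError(
                f"{self.sequence_id!r}: need at least 2 cysteines, "
                f"got {len(self.positions)}"
            )
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("cysteine positions must be strictly increasing")


@dataclass(frozen=True)
class CysteineFramework:
    """A tokenized cysteine spacing pattern.

    ``tokens`` has length ``n_cys - 1``; ``identifier`` is ``"n.k"`` with
    ``n == n_cys`` (empty string when unassigned).
    """

    tokens: tuple[str, ...]
    identifier: str = ""

    def __post_init__(self) -> None:
        bad = set(self.tokens) - _VALID_TOKENS
        if bad:
            raise ValueError(f"unknown spacing tokens: {sorted(bad)}")
        if self.identifier:
            n = int(self.identifier.split(".")[0])
            if n != self.n_cys:
                raise ValueError(
                    f"identifier {self.identifier!r} inconsistent with "
                    f"{self.n_cys} cysteines"
                )

    @property
    def n_cys(self) -> int:
        return len(self.tokens) + 1

    @property
    def motif(self) -> str:
        return render_motif(self.tokens)


def cysteine_positions(peptide: str) -> tuple[int, ...]:
    """1-based positions of every cysteine in *peptide*."""
    return tuple(i + 1 for i, aa in enumerate(peptide.upper()) if aa == "C")


def tokenize_cysteines(mature_peptide: str) -> CysteineFramework:
    """Tokenize the cysteine spacing of a mature peptide.

    Raises ``ValueError`` if the peptide has fewer than two cysteines.
    """
    pos = cysteine_positions(mature_peptide)
    if len(pos) < 2:
        raise ValueError(
            f"cannot tokenize: peptide has {len(pos)} cysteine(s), need >= 2"
        )
    tokens = []
    for a, b in zip(pos, pos[1:]):
        gap = b - a - 1
        if gap == 0:
            tokens.append(TOKEN_CC)
        elif gap == 1:
            tokens.append(TOKEN_CXC)
        else:
            tokens.append(TOKEN_LOOP)
    return CysteineFramework(tokens=tuple(tokens))


def render_motif(tokens: Sequence[str]) -> str:
    """Render spacing tokens to a numbered motif string (``C1-C2-C3C4...``)."""
    parts = ["C1"]
    for i, tok in enumerate(tokens, start=2):
        if tok == TOKEN_CC:
            sep = ""
        elif tok == TOKEN_CXC:
            sep = "X"
        elif tok == TOKEN_LOOP:
            sep = "-"
        else:
            raise ValueError(f"unknown token {tok!r}")
        parts.append(f"{sep}C{i}")
    return "".join(parts)


_MOTIF_RE = re.compile(r"C(\d+)([X\-]?)")


def parse_motif(motif: str) -> CysteineFramework:
    """Parse a motif string back to its token list (inverse of the renderer).

    The motif numbers cysteines ``C1..Cn`` in order, with separators ``""``
    (adjacent), ``"X"`` (one apart) or ``"-"`` (more than one apart).
    """
    motif = motif.strip()
    pieces = _MOTIF_RE.findall(motif)
    reassembled = "".join(f"C{n}{sep}" for n, sep in pieces)
    if not pieces or reassembled != motif:
        raise ValueError(f"malformed motif string: {motif!r}")
    numbers = [int(n) for n, _ in pieces]
    if numbers != list(range(1, len(numbers) + 1)):
        raise ValueError(f"motif must number cysteines C1..Cn in order: {motif!r}")
    if len(numbers) < 2:
        raise ValueError(f"motif needs at least 2 cysteines: {motif!r}")
    if pieces[-1][1]:
        raise ValueError(f"motif must not end with a separator: {motif!r}")
    tokens = []
    for _, sep in pieces[:-1]:
        if sep == "":
            tokens.append(TOKEN_CC)
        elif sep == "X":
            tokens.append(TOKEN_CXC)
        else:
            tokens.append(TOKEN_LOOP)
    return CysteineFramework(tokens=tuple(tokens))


@dataclass
class FrameworkCatalog:
    """Ordered catalog of named frameworks.

    Entries map identifier -> (tokens, numeral).  ``assign`` finds the entry
    whose token list matches a peptide exactly; novel patterns can be minted
    with the smallest unused variant index for their cysteine count.
    """

    _entries: dict[str, CysteineFramework] = field(default_factory=dict)
    _numerals: dict[str, str] = field(default_factory=dict)

    def add(self, identifier: str, motif: str, numeral: str = "") -> None:
        if identifier in self._entries:
            raise ValueError(f"duplicate framework identifier {identifier!r}")
        fw = parse_motif(motif)
        n = int(identifier.split(".")[0])
        if n != fw.n_cys:
            raise ValueError(
                f"identifier {identifier!r} inconsistent with motif {motif!r} "
                f"({fw.n_cys} cysteines)"
            )
        self._entries[identifier] = CysteineFramework(fw.tokens, identifier)
        if numeral:
            self._numerals[identifier] = numeral

    @property
    def identifiers(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, identifier: str) -> CysteineFramework:
        try:
            return self._entries[identifier]
        except KeyError:
            raise KeyError(f"unknown framework identifier {identifier!r}") from None

    def numeral(self, identifier: str) -> str:
        return self._numerals.get(identifier, "")

    def by_numeral(self, numeral: str) -> CysteineFramework:
        for ident, num in self._numerals.items():
            if num == numeral:
                return self._entries[ident]
        raise KeyError(f"no framework with numeral {numeral!r}")

    def match(self, tokens: Sequence[str]) -> str | None:
        """Identifier of the entry with exactly these tokens, or ``None``."""
        tokens = tuple(tokens)
        for ident, fw in self._entries.items():
            if fw.tokens == tokens:
                return ident
        return None

    def mint(self, tokens: Sequence[str]) -> str:
        """Register a novel token pattern under the smallest unused ``n.k``."""
        existing = self.match(tokens)
        if existing is not None:
            return existing
        n = len(tokens) + 1
        used = {
            int(ident.split(".")[1])
            for ident in self._entries
            if int(ident.split(".")[0]) == n
        }
        k = 0
        while k in used:
            k += 1
        ident = f"{n}.{k}"
        self._entries[ident] = CysteineFramework(tuple(tokens), ident)
        return ident


def load_default_catalog() -> FrameworkCatalog:
    """The packaged seven-class catalog (identifier, numeral, motif)."""
    cat = FrameworkCatalog()
    text = (
        resources.files("ickkit.data").joinpath("framework_catalog.tsv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    assert header == ["identifier", "numeral", "motif"]
    for line in lines[1:]:
        ident, numeral, motif = line.split("\t")
        cat.add(ident, motif, numeral)
    return cat


def assign_framework(
    mature_peptide: str,
    catalog: FrameworkCatalog,
    allow_new: bool = False,
) -> str:
    """Assign a framework identifier to a mature peptide.

    Returns the identifier of the catalog entry whose token list matches the
    peptide exactly.  If no entry matches: with ``allow_new`` a fresh ``n.k``
    is minted (and added to *catalog*); otherwise the empty string is
    returned, meaning *unassigned*.
    """
    fw = tokenize_cysteines(mature_peptide)
    ident = catalog.match(fw.tokens)
    if ident is not None:
        return ident
    if allow_new:
        return catalog.mint(fw.tokens)
    return ""


def top_coverage_filter(
    framework_counts: Mapping[str, int] | Iterable[tuple[str, int]],
    fraction: float = 0.8,
) -> list[str]:
    """Frameworks covering the top *fraction* of peptides.

    Frameworks are sorted by descending count (ties broken lexicographically
    on identifier) and the shortest prefix whose cumulative share reaches
    *fraction* is retained.  Used to keep only the dominant framework classes
    of the largest gene family before connectivity and selection analysis.
    """
    counts = dict(framework_counts)
    if not counts:
        raise ValueError("empty framework counts")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative framework count")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all framework counts are zero")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    retained: list[str] = []
    cum = 0
    for ident, count in ranked:
        if count == 0:
            break
        retained.append(ident)
        cum += count
        if cum / total >= fraction:
            break
    return retained
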