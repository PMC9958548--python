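"""Loop schema for the four structurally homologous inner-cysteine loops.

Every ICK framework class shares four loops bounded by eight structurally
homologous cysteines (two bounds per loop, with the right bound of loop 1
shared with loop 2 and the right bound of loop 3 shared with loop 4 — six
distinct ordinals in all).  Larger frameworks elaborate the core knot with
extra cysteines that fall either *inside* a loop (retained in place during
extraction) or outside the four loops (excluded, e.g. the trailing cysteine
pairs of the 12- and 14-cysteine classes).

The packaged schema covers the seven catalog classes.  A loop spec such as
``C5XC6-C7XC8`` reads: loop bounded by C5 and C8, with C6 and C7 as inner
cysteines; the separators record spacing but only the ordinals matter here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

__all__ = ["LoopDef", "LoopSchema", "load_default_schema", "parse_loop_spec"]

_ORD_RE = re.compile(r"C(\d+)")


@dataclass(frozen=True)
class LoopDef:
    """One loop: bounding cysteine ordinals and any inner cysteine ordinals."""

    left: int
    right: int
    inner: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.left < self.right:
            raise ValueError(f"loop bounds must increase: {self.left},{self.right}")
        if any(not self.left < i < self.right for i in self.inner):
            raise ValueError("inner ordinals must lie strictly between bounds")


def parse_loop_spec(spec: str) -> LoopDef:
    """Parse a loop spec like ``C2-C3XC4`` into a :class:`LoopDef`."""
    ordinals = [int(m) for m in _ORD_RE.findall(spec)]
    if len(ordinals) < 2 or ordinals != sorted(ordinals):
        raise ValueError(f"malformed loop spec {spec!r}")
    return LoopDef(left=ordinals[0], right=ordinals[-1], inner=tuple(ordinals[1:-1]))


@dataclass(frozen=True)
class LoopSchema:
    """Per-framework-class loop definitions (four loops per class)."""

    classes: dict[str, tuple[LoopDef, LoopDef, LoopDef, LoopDef]]

    def __post_init__(self) -> None:
        for ident, loops in self.classes.items():
            if len(loops) != 4:
                raise ValueError(f"class {ident!r}: need exactly 4 loops")
            bounds = [b for lp in loops for b in (lp.left, lp.right)]
            if bounds != sorted(bounds):
                raise ValueError(f"class {ident!r}: loop bounds must be ordered")
            if loops[0].left != 1:
                raise ValueError(f"class {ident!r}: loop 1 must start at C1")

    def __contains__(self, framework_id: str) -> bool:
        return framework_id in self.classes

    def loops(self, framework_id: str) -> tuple[LoopDef, LoopDef, LoopDef, LoopDef]:
        try:
            return self.classes[framework_id]
        except KeyError:
            raise KeyError(
                f"framework {framework_id!r} has no loop schema row"
            ) from None

    def bounding_ordinals(self, framework_id: str) -> tuple[int, ...]:
        """Distinct bounding cysteine ordinals of the four loops, sorted."""
        loops = self.loops(framework_id)
        return tuple(sorted({b for lp in loops for b in (lp.left, lp.right)}))

    def core_bridge_anchors(self, framework_id: str) -> tuple[int, int, int]:
        """Anchor ordinals of the three bridges homologous to every class.

        The six distinct bounding cysteines pair off as the core knot; the
        first three are the anchors whose partners the connectivity consensus
        is asked to decide.
        """
        bounds = self.bounding_ordinals(framework_id)
        return bounds[0], bounds[1], bounds[2]


def load_default_schema() -> LoopSchema:
    """The packaged four-loop alignment schema for the seven catalog classes."""
    text = resources.files("ickkit.data").joinpath("loop_schema.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    assert lines[0].split("\t") == ["class", "loop1", "loop2", "loop3", "loop4"]
    classes = {}
    for line in lines[1:]:
        ident, *specs = line.split("\t")
        classes[ident] = tuple(parse_loop_spec(s) for s in specs)
    return LoopSchema(classes=classes)
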