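"""Residue-region model for the myosin interacting-heads motif (IHM).

A :class:`ResidueRegion` is a named set of 1-based residue positions on one
sarcomere protein (beta-cardiac myosin heavy chain MYH7, or the light chains
MYL2/MYL3), tagged with the IHM interaction class it participates in
(priming, anchoring, stabilizing, scaffolding, regulating, motor-domain
functional site, mesa, light meromyosin) and the head context in which the
interaction occurs (blocked head, free head, the S2 tail, or either).

Region files are plain TSV: ``name  gene  class  context  residues`` with
residues in compact 1-based inclusive range syntax, e.g. ``169-170,403-411``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

PROTEIN_LENGTHS: Mapping[str, int] = {"MYH7": 1935, "MYL2": 166, "MYL3": 195}

INTERACTION_CLASSES = frozenset({
    "priming-f1", "priming-f2", "priming-g",
    "anchoring-h", "anchoring-i", "anchoring-j",
    "stabilizing-a", "stabilizing-d1", "stabilizing-d2", "stabilizing-e",
    "scaffolding-ELC", "scaffolding-RLC", "regulating-RLC-RLC",
    "MD-nucleotide", "MD-actin", "MD-converter", "MD-relay",
    "mesa", "LMM", "other",
})

#: classes that constitute the IHM interaction surface
IHM_CLASSES = frozenset(
    c for c in INTERACTION_CLASSES
    if c.split("-")[0] in {"priming", "anchoring", "stabilizing", "scaffolding"}
)

MD_CLASSES = frozenset({"MD-nucleotide", "MD-actin", "MD-converter", "MD-relay"})

HEAD_CONTEXTS = frozenset({"blocked", "free", "tail", "either"})


class RegionParseError(ValueError):
    """Raised for malformed region-definition rows."""


def parse_ranges(text: str, *, row: str = "?") -> set[int]:
    """Parse ``a-b,c,d-e`` 1-based inclusive range syntax into a position set."""
    positions: set[int] = set()
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token:
            a_s, b_s = token.split("-", 1)
            try:
                a, b = int(a_s), int(b_s)
            except ValueError as exc:
                raise RegionParseError(f"row {row}: bad range {token!r}") from exc
            if b < a:
                raise RegionParseError(f"row {row}: descending range {token!r}")
            positions.update(range(a, b + 1))
        else:
            try:
                positions.add(int(token))
            except ValueError as exc:
                raise RegionParseError(f"row {row}: bad position {token!r}") from exc
    return positions


def format_ranges(positions: Iterable[int]) -> str:
    """Canonical compact range string (sorted, merged) for a position set."""
    pos = sorted(set(positions))
    out: list[str] = []
    i = 0
    while i < len(pos):
        j = i
        while j + 1 < len(pos) and pos[j + 1] == pos[j] + 1:
            j += 1
        out.append(str(pos[i]) if i == j else f"{pos[i]}-{pos[j]}")
        i = j + 1
    return ",".join(out)


@dataclass
class ResidueRegion:
    """A named set of residue positions with interaction class and context."""

    name: str
    gene: str
    interaction_class: str
    head_context: str
    residues: set[int]

    def __post_init__(self) -> None:
        if self.gene not in PROTEIN_LENGTHS:
            raise RegionParseError(f"region {self.name}: unknown gene {self.gene!r}")
        if self.interaction_class not in INTERACTION_CLASSES:
            raise RegionParseError(
                f"region {self.name}: unknown class {self.interaction_class!r}")
        if self.head_context not in HEAD_CONTEXTS:
            raise RegionParseError(
                f"region {self.name}: unknown context {self.head_context!r}")
        if not self.residues:
            raise RegionParseError(f"region {self.name}: empty residue set")
        top = max(self.residues)
        if min(self.residues) < 1 or top > PROTEIN_LENGTHS[self.gene]:
            raise RegionParseError(
                f"region {self.name}: position {top} outside "
                f"{self.gene} (length {PROTEIN_LENGTHS[self.gene]})")

    @property
    def size(self) -> int:
        return len(self.residues)


@dataclass
class RegionSet:
    """A collection of regions over one or more genes."""

    regions: list[ResidueRegion] = field(default_factory=list)
    protein_lengths: Mapping[str, int] = field(default_factory=lambda: dict(PROTEIN_LENGTHS))

    def select(self, predicate: Callable[[ResidueRegion], bool]) -> list[ResidueRegion]:
        return [r for r in self.regions if predicate(r)]

    def union(self, predicate: Callable[[ResidueRegion], bool], gene: str = "MYH7") -> set[int]:
        out: set[int] = set()
        for r in self.regions:
            if r.gene == gene and predicate(r):
                out |= r.residues
        return out

    def union_size(self, predicate: Callable[[ResidueRegion], bool], gene: str = "MYH7") -> int:
        return len(self.union(predicate, gene))

    def regions_at(self, gene: str, position: int) -> list[ResidueRegion]:
        return [r for r in self.regions if r.gene == gene and position in r.residues]


def parse_regions(source: str | Path | io.TextIOBase) -> RegionSet:
    """Read a region-definition TSV.

    Duplicate positions within one row are collapsed; rows sharing the same
    name are merged by union (their gene/class/context must agree).
    """
    if isinstance(source, (str, Path)):
        fh: io.TextIOBase = open(source, "rt", encoding="utf-8")
        close = True
    else:
        fh, close = source, False
    merged: dict[str, ResidueRegion] = {}
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise RegionParseError(f"row {lineno}: expected 5 columns, got {len(parts)}")
            name, gene, iclass, context, ranges = (p.strip() for p in parts)
            residues = parse_ranges(ranges, row=str(lineno))
            region = ResidueRegion(name, gene, iclass, context, residues)
            if name in merged:
                prev = merged[name]
                if (prev.gene, prev.interaction_class, prev.head_context) != (
                        gene, iclass, context):
                    raise RegionParseError(
                        f"row {lineno}: region {name!r} redefined with different "
                        "gene/class/context")
                prev.residues |= residues
            else:
                merged[name] = region
    finally:
        if close:
            fh.close()
    return RegionSet(regions=list(merged.values()))


def write_regions(rs: RegionSet, dest: str | Path | io.TextIOBase) -> None:
    """Write a RegionSet as TSV with sorted canonical ranges."""
    if isinstance(dest, (str, Path)):
        fh: io.TextIOBase = open(dest, "wt", encoding="utf-8")
        close = True
    else:
        fh, close = dest, False
    try:
        fh.write("# name\tgene\tclass\tcontext\tresidues\n")
        for r in rs.regions:
            fh.write(f"{r.name}\t{r.gene}\t{r.interaction_class}\t"
                     f"{r.head_context}\t{format_ranges(r.residues)}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Named selectors over region sets.

@dataclass(frozen=True)
class Selector:
    """A predicate over regions: match by class, head context and/or name."""

    label: str
    classes: frozenset[str] | None = None
    contexts: frozenset[str] | None = None
    names: frozenset[str] | None = None

    def __call__(self, region: ResidueRegion) -> bool:
        by_class = self.classes is not None and region.interaction_class in self.classes
        by_name = self.names is not None and region.name in self.names
        if not (by_class or by_name):
            return False
        if self.contexts is not None and region.head_context not in self.contexts:
            return False
        return True


def _cls(label: str, *classes: str, contexts: Sequence[str] | None = None,
         names: Sequence[str] | None = None) -> Selector:
    return Selector(
        label,
        classes=frozenset(classes) if classes else None,
        contexts=frozenset(contexts) if contexts else None,
        names=frozenset(names) if names else None,
    )


SELECTORS: Mapping[str, Selector] = {
    "ihm_all": _cls("IHM Interactions (All)", *sorted(IHM_CLASSES)),
    "priming": _cls("Priming", "priming-f1", "priming-f2", "priming-g"),
    "anchoring": _cls("Anchoring", "anchoring-h", "anchoring-i", "anchoring-j"),
    "stabilizing": _cls("Stabilizing", "stabilizing-a", "stabilizing-d1",
                        "stabilizing-d2", "stabilizing-e"),
    "scaffolding": _cls("Scaffolding", "scaffolding-ELC", "scaffolding-RLC"),
    "md194": _cls("MD Functional", *sorted(MD_CLASSES)),
    "md210": _cls("MD Functional (extended)", *sorted(MD_CLASSES), names=["md210-extra"]),
    "nucleotide": _cls("Nucleotide binding", "MD-nucleotide"),
    "actin": _cls("Actin binding", "MD-actin"),
    "converter": _cls("Converter", "MD-converter"),
    "relay": _cls("Relay", "MD-relay"),
    "mesa": _cls("Mesa", "mesa"),
    "blocked": _cls("Blocked head", *sorted(IHM_CLASSES), contexts=["blocked"]),
    "free": _cls("Free head", *sorted(IHM_CLASSES), contexts=["free"]),
    "tail": _cls("Tail (S2)", *sorted(IHM_CLASSES), contexts=["tail"]),
    "lmm": _cls("LMM", "LMM"),
}
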