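"""Amino-acid substitution records and cohort variant tables.

Substitutions arrive in clinical shorthand: one-letter tokens (``R403W``),
slashed multi-allele tokens (``R403W/G/L/Q``, one record per alternate), or
HGVS protein notation (``p.Arg403Trp``).  A record carries the gene, the
pathogenicity class assigned by the reporting laboratory (PV = pathogenic,
LPV = likely pathogenic, or rare-unclassified), the cohort it was observed
in, and a multiplicity: the number of distinct nucleotide variants that
encode the same amino-acid substitution (two distinct DNA events can yield
one substitution, and burden denominators count events, not substitutions).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._aa import AA1, THREE_TO_ONE
from .regions import PROTEIN_LENGTHS, RegionSet

PCLASSES = ("PV", "LPV", "rare-unclassified")
COHORTS = ("HCM", "DCM", "control")


class VariantParseError(ValueError):
    """Raised for unparsable substitution tokens or malformed table rows."""


@dataclass(frozen=True)
class VariantRecord:
    gene: str
    ref_aa: str
    position: int
    alt_aa: str
    pclass: str
    cohort: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.ref_aa not in AA1 or self.alt_aa not in AA1:
            raise VariantParseError(
                f"{self.token}: ref/alt must be standard amino acids")
        if self.ref_aa == self.alt_aa:
            raise VariantParseError(f"{self.token}: synonymous (ref == alt)")
        if self.gene not in PROTEIN_LENGTHS:
            raise VariantParseError(f"{self.token}: unknown gene {self.gene!r}")
        if not 1 <= self.position <= PROTEIN_LENGTHS[self.gene]:
            raise VariantParseError(
                f"{self.token}: position outside {self.gene} "
                f"(length {PROTEIN_LENGTHS[self.gene]})")
        if self.multiplicity < 1:
            raise VariantParseError(f"{self.token}: multiplicity must be >= 1")
        if self.pclass not in PCLASSES:
            raise VariantParseError(f"{self.token}: unknown pclass {self.pclass!r}")
        if self.cohort not in COHORTS:
            raise VariantParseError(f"{self.token}: unknown cohort {self.cohort!r}")

    @property
    def token(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def substitution(self) -> tuple[str, int, str]:
        return (self.ref_aa, self.position, self.alt_aa)


_ONE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_HGVS_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def expand_token(token: str) -> list[tuple[str, int, str]]:
    """Expand one substitution token into (ref, pos, alt) triples.

    Slashed tokens (``R403W/G/L/Q``, spaces tolerated) share ref and
    position.  Stop-gain (X/*/Ter) and frameshift notation are rejected:
    only missense substitutions are modelled.
    """
    token = token.strip()
    if "fs" in token or "*" in token:
        raise VariantParseError(f"non-missense token {token!r}")
    parts = [p.strip() for p in token.split("/")]
    head = parts[0]
    m = _HGVS_RE.match(head)
    if m:
        ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
        if ref3 == "Ter" or alt3 == "Ter":
            raise VariantParseError(f"non-missense token {token!r}")
        try:
            triples = [(THREE_TO_ONE[ref3], pos, THREE_TO_ONE[alt3])]
        except KeyError as exc:
            raise VariantParseError(f"unknown residue name in {token!r}") from exc
        if len(parts) > 1:
            raise VariantParseError(f"slashed HGVS not supported: {token!r}")
        return triples
    m = _ONE_RE.match(head)
    if not m:
        raise VariantParseError(f"unparsable substitution token {token!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    alts = [alt]
    for extra in parts[1:]:
        if len(extra) != 1:
            raise VariantParseError(f"bad alternate allele {extra!r} in {token!r}")
        alts.append(extra)
    for a in [ref] + alts:
        if a == "X":
            raise VariantParseError(f"non-missense token {token!r}")
        if a not in AA1:
            raise VariantParseError(f"{a!r} is not a standard amino acid ({token!r})")
    return [(ref, pos, a) for a in alts]


def parse_substitutions(rows: Iterable[tuple[str, str, str, str]] |
                        Iterable[dict]) -> list[VariantRecord]:
    """Parse (gene, token, pclass, cohort[, multiplicity]) rows into records."""
    records: list[VariantRecord] = []
    for row in rows:
        if isinstance(row, dict):
            gene, token = row["gene"], row["substitution"]
            pclass, cohort = row["pclass"], row["cohort"]
            mult = int(row.get("multiplicity", 1))
        else:
            gene, token, pclass, cohort = row[:4]
            mult = int(row[4]) if len(row) > 4 else 1
        for ref, pos, alt in expand_token(token):
            records.append(VariantRecord(gene, ref, pos, alt, pclass, cohort, mult))
    return records


def load_variant_table(source: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a variant TSV (gene, substitution, pclass, cohort, multiplicity, ...).

    Returns the raw table; extra columns (fixture annotations such as
    ``regions``, ``md``, ``mesa``, ``dq``) are preserved.  Multiplicity
    defaults to 1 when the column is absent.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str).fillna("")
    required = {"gene", "substitution", "pclass", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise VariantParseError(f"variant table missing columns: {sorted(missing)}")
    if "multiplicity" not in df.columns:
        df["multiplicity"] = "1"
    df["multiplicity"] = df["multiplicity"].replace("", "1").astype(int)
    return df


def records_from_table(df: pd.DataFrame) -> list[VariantRecord]:
    return parse_substitutions(df.to_dict("records"))


def serialize_records(records: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene": [r.gene for r in records],
        "substitution": [r.token for r in records],
        "pclass": [r.pclass for r in records],
        "cohort": [r.cohort for r in records],
        "multiplicity": [r.multiplicity for r in records],
    })


def tally(records: Sequence[VariantRecord]) -> tuple[int, int, int]:
    """(variant events, distinct substitutions, distinct positions).

    Events are multiplicity-weighted: a substitution encoded by two distinct
    nucleotide variants counts twice in the first component only.
    """
    n_variants = sum(r.multiplicity for r in records)
    n_subs = len({r.substitution for r in records})
    n_pos = len({(r.gene, r.position) for r in records})
    return (n_variants, n_subs, n_pos)


# ---------------------------------------------------------------------------
# Annotation against a RegionSet.

@dataclass(frozen=True)
class Hit:
    region_name: str
    interaction_class: str
    head_context: str


@dataclass(frozen=True)
class AnnotatedVariant:
    record: VariantRecord
    hits: tuple[Hit, ...] = field(default=())

    def matches(self, selector) -> bool:
        """True if any hit's region satisfies the selector predicate fields."""
        for h in self.hits:
            by_class = selector.classes is not None and h.interaction_class in selector.classes
            by_name = selector.names is not None and h.region_name in selector.names
            if not (by_class or by_name):
                continue
            if selector.contexts is not None and h.head_context not in selector.contexts:
                continue
            return True
        return False


def annotate(records: Sequence[VariantRecord], rs: RegionSet) -> list[AnnotatedVariant]:
    """Attach every region membership of each record's position.

    A pure function of (position, RegionSet); records outside the protein
    length are rejected at record construction, so this cannot fail for
    well-formed records.
    """
    out = []
    for rec in records:
        hits = tuple(
            Hit(r.name, r.interaction_class, r.head_context)
            for r in rs.regions_at(rec.gene, rec.position)
        )
        out.append(AnnotatedVariant(rec, hits))
    return out
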