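"""Charge-change (Δq) annotation and exhaustive SNV enumeration over a CDS.

Δq of a missense substitution is the integer side-chain charge of the
variant residue minus that of the wild-type residue under a chosen scale.
The expected proportion of charge-changing missense events under a uniform
single-nucleotide mutation model is obtained by enumerating, for every codon
of a coding sequence, all nine single-base substitutions and classifying
each against the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Data.CodonTable import standard_dna_table

from ._aa import PAPER_SCALE, ChargeScale
from .variants import VariantRecord

CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

BASES = "ACGT"


class CdsError(ValueError):
    """Raised for coding sequences the enumerator cannot accept."""


def delta_q(v: VariantRecord, scale: ChargeScale = PAPER_SCALE) -> int:
    """Charge change of a missense substitution: q(alt) - q(ref)."""
    return scale.charge(v.alt_aa) - scale.charge(v.ref_aa)


def charge_change_fraction(records: Sequence[VariantRecord],
                           scale: ChargeScale = PAPER_SCALE) -> tuple[int, int, float]:
    """(k changed, n, k/n) over multiplicity-weighted records."""
    if not records:
        raise ValueError("charge_change_fraction needs at least one record")
    n = sum(r.multiplicity for r in records)
    k = sum(r.multiplicity for r in records if delta_q(r, scale) != 0)
    return (k, n, k / n)


@dataclass(frozen=True)
class SnvCensus:
    """Counts of all single-nucleotide substitution events over a CDS."""

    n_codons: int
    n_synonymous: int
    n_missense: int
    n_nonsense: int
    missense_negative: int  # dq < 0
    missense_neutral: int   # dq = 0
    missense_positive: int  # dq > 0

    @property
    def n_events(self) -> int:
        return 9 * self.n_codons

    @property
    def missense_by_sign(self) -> tuple[int, int, int]:
        return (self.missense_negative, self.missense_neutral, self.missense_positive)


def enumerate_snvs(cds: str, scale: ChargeScale = PAPER_SCALE,
                   on_internal_stop: str = "error") -> SnvCensus:
    """Classify all 9 x n_codons single-base substitution events of a CDS.

    The terminal stop codon, if present, is stripped before enumeration.
    Each event is synonymous, nonsense (stop gained), or missense; missense
    events additionally record the sign of the charge change.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise CdsError(f"CDS length {len(cds)} not divisible by 3")
    bad = set(cds) - set(BASES)
    if bad:
        raise CdsError(f"ambiguous or invalid bases in CDS: {sorted(bad)}")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and CODON_TO_AA[codons[-1]] == "*":
        codons = codons[:-1]
    if not codons:
        raise CdsError("empty CDS after stripping terminal stop")
    internal_stops = [i for i, c in enumerate(codons) if CODON_TO_AA[c] == "*"]
    if internal_stops:
        msg = f"internal stop codon(s) at codon index {internal_stops}"
        if on_internal_stop == "error":
            raise CdsError(msg)
        if on_internal_stop != "warn":
            raise ValueError("on_internal_stop must be 'error' or 'warn'")
        import warnings
        warnings.warn(msg, stacklevel=2)

    syn = mis = non = 0
    neg = neu = pos = 0
    for codon in codons:
        ref_aa = CODON_TO_AA[codon]
        for i in range(3):
            for b in BASES:
                if b == codon[i]:
                    continue
                alt = codon[:i] + b + codon[i + 1:]
                alt_aa = CODON_TO_AA[alt]
                if alt_aa == "*":
                    non += 1
                elif alt_aa == ref_aa:
                    syn += 1
                elif ref_aa == "*":
                    # only reachable with on_internal_stop="warn": a stop that
                    # mutates to a sense codon is neither missense nor nonsense;
                    # count it as synonymous-class (no protein change modelled)
                    syn += 1
                else:
                    mis += 1
                    dq = scale.charge(alt_aa) - scale.charge(ref_aa)
                    if dq < 0:
                        neg += 1
                    elif dq > 0:
                        pos += 1
                    else:
                        neu += 1
    return SnvCensus(len(codons), syn, mis, non, neg, neu, pos)


def expected_charge_change(census: SnvCensus) -> float:
    """Fraction of missense events with Δq != 0."""
    if census.n_missense == 0:
        return 0.0
    return (census.missense_negative + census.missense_positive) / census.n_missense
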