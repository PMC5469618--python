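"""Amino-acid code tables and side-chain charge scales.

The charge scale used throughout the analysis assigns integer side-chain
charges R=+2, K=+1, H=+1, D=E=-1 (all other residues 0).  It is the unique
integer scale consistent with every per-substitution charge change printed
in the cardiomyopathy variant tables this package transcribes (for example
R->K = -1 and G->R = +2 force R=+2, and Y->H = +1 forces H=+1).  A
conventional physiological scale (R=K=+1, H=0, D=E=-1) is provided as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

AA1 = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


@dataclass(frozen=True)
class ChargeScale:
    """Integer side-chain charges for the 20 standard amino acids.

    Residues missing from ``charges`` carry charge 0.
    """

    name: str
    charges: MappingProxyType

    def charge(self, aa: str) -> int:
        if aa not in AA1:
            raise ValueError(f"not a standard amino acid: {aa!r}")
        return self.charges.get(aa, 0)


PAPER_SCALE = ChargeScale(
    "paper", MappingProxyType({"R": 2, "K": 1, "H": 1, "D": -1, "E": -1})
)
STANDARD_SCALE = ChargeScale(
    "standard", MappingProxyType({"R": 1, "K": 1, "D": -1, "E": -1})
)

SCALES = {s.name: s for s in (PAPER_SCALE, STANDARD_SCALE)}
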