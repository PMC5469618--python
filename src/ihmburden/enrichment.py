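"""Regional variant enrichment against a uniform null.

For a cohort of n missense variants on a protein of length L, and a region
comprising m residues, the expected fraction of variants falling in the
region under a uniform placement null is p0 = m/L.  Observed counts k are
compared with an exact binomial test; the rate ratio (k/n)/p0 measures fold
enrichment.  Rows of an enrichment table are not disjoint: a variant whose
position participates in several interactions counts once in every row it
matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import binomtest

from .regions import PROTEIN_LENGTHS, RegionSet, Selector, SELECTORS
from .variants import AnnotatedVariant


def binom_test(k: int, n: int, p0: float, sided: str = "two") -> float:
    """Exact binomial p-value.

    Two-sided uses the minimum-likelihood convention: the sum of P(X=i) over
    all outcomes i with P(X=i) <= P(X=k)(1+1e-7).
    """
    if not (0 <= k <= n) or n < 0:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"invalid null probability p0={p0}")
    alternative = {"two": "two-sided", "greater": "greater"}.get(sided)
    if alternative is None:
        raise ValueError(f"sided must be 'two' or 'greater', got {sided!r}")
    return binomtest(k, n, p0, alternative=alternative).pvalue


def round_sig(x: float, sig: int = 3) -> float:
    """Round to `sig` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


@dataclass(frozen=True)
class EnrichmentResult:
    """One row of a regional enrichment table."""

    site_label: str
    n_obs: int
    n_total: int
    region_aa: int
    protein_aa: int
    p_value: float

    @property
    def rate(self) -> float:
        return self.n_obs / self.n_total

    @property
    def expected_rate(self) -> float:
        return self.region_aa / self.protein_aa

    @property
    def rate_ratio(self) -> float:
        return self.rate / self.expected_rate

    @property
    def printed_ratio(self) -> float:
        """Rate ratio as published: ratio of the rounded rate (3 decimals)
        to the rounded expected rate (3 significant figures), re-rounded to
        3 significant figures."""
        exp = round_sig(self.expected_rate, 3)
        return round_sig(round(self.rate, 3) / exp, 3) if exp else float("nan")


def enrich(annotated: Sequence[AnnotatedVariant], rs: RegionSet,
           selector: Selector, gene: str = "MYH7", sided: str = "two",
           label: str | None = None) -> EnrichmentResult:
    """Enrichment of a cohort's variants in the residues a selector picks out.

    Counts are multiplicity-weighted (nucleotide events, not distinct
    substitutions).  The null expectation is region size / protein length.
    """
    cohort = [a for a in annotated if a.record.gene == gene]
    if not cohort:
        raise ValueError("empty cohort: no variants for gene " + gene)
    region_aa = rs.union_size(selector, gene=gene)
    if region_aa == 0:
        raise ValueError(f"selector {selector.label!r} matches no {gene} residues")
    protein_aa = rs.protein_lengths.get(gene, PROTEIN_LENGTHS[gene])
    n_total = sum(a.record.multiplicity for a in cohort)
    n_obs = sum(a.record.multiplicity for a in cohort if a.matches(selector))
    p = binom_test(n_obs, n_total, region_aa / protein_aa, sided=sided)
    return EnrichmentResult(label or selector.label, n_obs, n_total,
                            region_aa, protein_aa, p)


#: row order of the published HCM and DCM summary tables
HCM_TABLE_SELECTORS = ("ihm_all", "priming", "anchoring", "stabilizing",
                       "scaffolding", "md194")
DCM_TABLE_SELECTORS = ("ihm_all", "priming", "anchoring", "stabilizing",
                       "scaffolding", "md210")
CONTEXT_SELECTORS = ("blocked", "free", "tail")


def enrichment_table(annotated: Sequence[AnnotatedVariant], rs: RegionSet,
                     selectors: Sequence[str | Selector] = HCM_TABLE_SELECTORS,
                     gene: str = "MYH7", sided: str = "two") -> list[EnrichmentResult]:
    """One enrichment row per selector, in the given (deterministic) order."""
    rows = []
    for sel in selectors:
        selector = SELECTORS[sel] if isinstance(sel, str) else sel
        rows.append(enrich(annotated, rs, selector, gene=gene, sided=sided))
    return rows


def format_table(rows: Sequence[EnrichmentResult],
                 bonferroni: bool = False) -> str:
    """TSV mirroring the published column order and rounding.

    Rates print to 3 decimals, expected rates to 4 decimals (3 significant
    figures), rate ratios to 3 significant figures, p-values to 3
    significant figures in scientific notation when small.
    """
    header = ["Specified site", "Variants within site", "Rate",
              "Amino acids within site", "Expected rate", "Rate ratio", "P-value"]
    if bonferroni:
        header.append("P-value (Bonferroni)")
    lines = ["\t".join(header)]
    m = len(rows)
    for r in rows:
        p = round_sig(r.p_value, 3)
        p_str = f"{p:.3g}" if p >= 1e-3 else f"{p:.2e}"
        cells = [r.site_label, str(r.n_obs), f"{r.rate:.3f}", str(r.region_aa),
                 f"{round_sig(r.expected_rate, 3):.4f}", f"{r.printed_ratio:g}",
                 p_str]
        if bonferroni:
            pb = min(1.0, r.p_value * m)
            cells.append(f"{round_sig(pb, 3):.3g}" if pb >= 1e-3 else f"{pb:.2e}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def results_as_dicts(rows: Sequence[EnrichmentResult]) -> list[Mapping]:
    return [{
        "site": r.site_label, "n_obs": r.n_obs, "n_total": r.n_total,
        "rate": r.rate, "region_aa": r.region_aa, "protein_aa": r.protein_aa,
        "expected_rate": r.expected_rate, "rate_ratio": r.rate_ratio,
        "printed_ratio": r.printed_ratio, "p_value": r.p_value,
    } for r in rows]
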