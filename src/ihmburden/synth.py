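"""Synthetic-data generators and the packaged region-fixture builder.

Two jobs live here.

First, seeded generators that produce inputs with the statistical structure
the analysis assumes — variant positions placed uniformly or with a known
fold-enrichment over a region, case/control cohorts with a known odds
ratio, random coding sequences, and noisy scattering profiles — so every
stage of the pipeline can be exercised and its estimators validated by
parameter recovery without external data.

Second, :func:`build_fixture_regions`: the packaged interaction-region
fixture is not available as a residue-level supplement, so it is
reconstructed by constraint satisfaction.  Every variant position carries
the region memberships its table row prints; filler residues (never
overlapping any tabulated variant position of any cohort, taken in
ascending order) pad each region so that all published region sizes hold
simultaneously: the per-class unions (priming 113, anchoring 156,
stabilizing 189, scaffolding 120, overall 447 of 1935), the head-context
unions (blocked 362, free 171, tail 69), the motor-domain sets
(39+60+68+27 = 194, extended 210), and the mesa (277, of which 126 overlap
IHM interaction residues).  ``FILL_PLAN`` records the unique filler
allocation solving these constraints; the builder verifies every printed
size and raises if the plan and the variant tables ever disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._aa import AA1
from .case_control import CohortCounts
from .regions import (IHM_CLASSES, PROTEIN_LENGTHS, RegionSet, ResidueRegion,
                      SELECTORS)
from .saxs import ScatteringProfile
from .variants import VariantRecord

# rng sub-stream salts: one per generator so adding a generator never
# perturbs the draws of another
_SALT_VARIANTS, _SALT_COHORTS, _SALT_CDS, _SALT_PROFILE = 1, 2, 3, 4


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), salt])


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the simulated study conditions.

    Defaults mirror the cardiomyopathy study design: a 1935-residue protein,
    135 cohort variants, 6112 cases vs 33364 reference subjects with a 1.4%
    reference carrier rate.
    """

    seed: int = 0
    protein_length: int = 1935
    region: frozenset[int] = frozenset()
    n_variants: int = 135
    enrichment_factor: float = 1.0
    n_cases: int = 6112
    n_controls: int = 33364
    control_rate: float = 449 / 33364
    true_or: float = 1.0
    ds_true: float = 0.8
    profile_points: int = 500
    profile_rel_sigma: float = 0.02


def gen_variants(spec: SimSpec) -> list[VariantRecord]:
    """Draw variant positions with a specified fold-enrichment over a region.

    The in-region probability is enrichment_factor * |region| / L, so the
    expected rate ratio measured by the enrichment statistic equals the
    factor exactly; positions are uniform within region and complement.
    """
    region = sorted(spec.region)
    if not region:
        raise ValueError("simulation region must be non-empty")
    if not set(region) <= set(range(1, spec.protein_length + 1)):
        raise ValueError("region positions outside the protein")
    p_in = spec.enrichment_factor * len(region) / spec.protein_length
    if not 0.0 < p_in < 1.0:
        raise ValueError(
            f"enrichment factor {spec.enrichment_factor} implies in-region "
            f"probability {p_in:.3f} outside (0, 1)")
    outside = sorted(set(range(1, spec.protein_length + 1)) - set(region))
    rng = _rng(spec.seed, _SALT_VARIANTS)
    records = []
    for _ in range(spec.n_variants):
        pool = region if rng.random() < p_in else outside
        pos = int(pool[rng.integers(len(pool))])
        ref, alt = rng.choice(list(AA1), size=2, replace=False)
        records.append(VariantRecord("MYH7", str(ref), pos, str(alt),
                                     "rare-unclassified", "HCM"))
    return records


def gen_cohorts(spec: SimSpec, site_label: str = "simulated") -> CohortCounts:
    """Simulate carrier counts with a specified true carrier odds ratio."""
    p0 = spec.control_rate
    if not 0.0 < p0 < 1.0:
        raise ValueError("control carrier probability must lie in (0, 1)")
    odds1 = spec.true_or * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    if p1 >= 1.0:
        raise ValueError("implied case carrier probability >= 1")
    rng = _rng(spec.seed, _SALT_COHORTS)
    carriers_cases = int(rng.binomial(spec.n_cases, p1))
    carriers_controls = int(rng.binomial(spec.n_controls, p0))
    return CohortCounts(site_label, carriers_cases, spec.n_cases,
                        carriers_controls, spec.n_controls)


_SENSE_CODONS = sorted(
    c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
)


def gen_cds(n_codons: int, seed: int = 0) -> str:
    """Uniform random sense codons; no internal or terminal stop."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = _rng(seed, _SALT_CDS)
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def gen_profile(spec: SimSpec) -> tuple[ScatteringProfile, ScatteringProfile]:
    """(model, experiment) pair: Iexp = I + N(0, sigma), sigma = rel_sigma * I.

    The noiseless model is a Guinier-like decay over q in [0.01, 0.5] 1/A,
    a shape adequate for exercising the chi statistic.
    """
    rng = _rng(spec.seed, _SALT_PROFILE)
    q = np.linspace(0.01, 0.5, spec.profile_points)
    intensity = 1000.0 * np.exp(-(q * 45.0) ** 2 / 3.0) + 5.0
    sigma = spec.profile_rel_sigma * intensity
    i_exp = intensity + rng.normal(0.0, sigma)
    model = ScatteringProfile(q, intensity)
    exp = ScatteringProfile(q, i_exp, sigma)
    return model, exp


# ---------------------------------------------------------------------------
# Region fixture reconstruction.

#: cell name -> (gene, interaction class, head context)
CELLS: Mapping[str, tuple[str, str, str]] = {
    "g-head":             ("MYH7", "priming-g", "blocked"),
    "f2-head":            ("MYH7", "priming-f2", "blocked"),
    "g-tail":             ("MYH7", "priming-g", "tail"),
    "f1-tail":            ("MYH7", "priming-f1", "tail"),
    "f2-tail":            ("MYH7", "priming-f2", "tail"),
    "h-blocked":          ("MYH7", "anchoring-h", "blocked"),
    "i-blocked":          ("MYH7", "anchoring-i", "blocked"),
    "j-blocked":          ("MYH7", "anchoring-j", "blocked"),
    "d1-blocked":         ("MYH7", "stabilizing-d1", "blocked"),
    "d1-free":            ("MYH7", "stabilizing-d1", "free"),
    "d2-free":            ("MYH7", "stabilizing-d2", "free"),
    "e-blocked":          ("MYH7", "stabilizing-e", "blocked"),
    "a-tail":             ("MYH7", "stabilizing-a", "tail"),
    "scELC-conv-blocked": ("MYH7", "scaffolding-ELC", "blocked"),
    "scELC-conv-free":    ("MYH7", "scaffolding-ELC", "free"),
    "scELC-neck-blocked": ("MYH7", "scaffolding-ELC", "blocked"),
    "scELC-neck-free":    ("MYH7", "scaffolding-ELC", "free"),
    "scRLC-blocked":      ("MYH7", "scaffolding-RLC", "blocked"),
    "scRLC-free":         ("MYH7", "scaffolding-RLC", "free"),
    "md-nucleotide":      ("MYH7", "MD-nucleotide", "either"),
    "md-actin":           ("MYH7", "MD-actin", "either"),
    "md-converter":       ("MYH7", "MD-converter", "either"),
    "md-relay":           ("MYH7", "MD-relay", "either"),
    "md210-extra":        ("MYH7", "other", "either"),
    "mesa":               ("MYH7", "mesa", "either"),
    "lmm":                ("MYH7", "LMM", "either"),
    "elc-anchoring-i":    ("MYL3", "anchoring-i", "blocked"),
    "elc-stab-e":         ("MYL3", "stabilizing-e", "free"),
    "elc-scaff-blocked":  ("MYL3", "scaffolding-ELC", "blocked"),
    "elc-scaff-free":     ("MYL3", "scaffolding-ELC", "free"),
    "rlc-regulating":     ("MYL2", "regulating-RLC-RLC", "either"),
    "rlc-scaff":          ("MYL2", "scaffolding-RLC", "either"),
}

#: filler residues added to each cell (tuples share the same positions);
#: the unique solution of the published size constraints (see module doc)
FILL_PLAN: Sequence[tuple[tuple[str, ...], int]] = (
    (("g-head",), 20),
    (("f2-head",), 40),
    (("g-tail",), 15),
    (("f2-tail",), 20),
    (("h-blocked",), 5),
    (("i-blocked",), 10),
    (("j-blocked",), 54),
    (("j-blocked", "d2-free", "scELC-conv-blocked"), 33),
    (("j-blocked", "d2-free"), 37),
    (("d1-blocked",), 49),
    (("d1-free",), 4),
    (("d2-free",), 4),
    (("e-blocked",), 8),
    (("a-tail",), 20),
    (("scELC-conv-blocked",), 4),
    (("scELC-neck-blocked", "scELC-neck-free"), 45),
    (("scRLC-blocked", "scRLC-free"), 18),
    (("md-nucleotide",), 32),
    (("md-actin",), 47),
    (("md-converter",), 56),
    (("md-relay",), 24),
    (("md210-extra",), 16),
    (("mesa",), 135),
)

#: the mesa additionally absorbs the first N filler residues placed in IHM
#: cells, giving the published 126-residue mesa/IHM overlap
MESA_SHARED_IHM_FILLERS = 99

#: first residue of the light meromyosin rod segment in the fixture
LMM_START = 1161

#: published union sizes the finished fixture must reproduce (selector -> aa)
PRINTED_SIZES: Mapping[str, int] = {
    "ihm_all": 447, "priming": 113, "anchoring": 156, "stabilizing": 189,
    "scaffolding": 120, "md194": 194, "md210": 210, "mesa": 277,
    "blocked": 362, "free": 171, "tail": 69,
    "nucleotide": 39, "actin": 60, "converter": 68, "relay": 27,
}


class FixtureError(ValueError):
    """The variant tables and the fill plan are mutually inconsistent."""


def _variant_cells(tables: Iterable[pd.DataFrame]) -> tuple[dict[str, set[int]], set[int]]:
    """Collect per-cell variant positions and all occupied MYH7 positions."""
    cells: dict[str, set[int]] = {name: set() for name in CELLS}
    occupied: set[int] = set()
    from .variants import expand_token
    for df in tables:
        for row in df.itertuples():
            triples = expand_token(row.substitution)
            pos = triples[0][1]
            if row.gene == "MYH7":
                occupied.add(pos)
            names: list[str] = []
            if getattr(row, "regions", ""):
                names += [n for n in str(row.regions).split(";") if n]
            if getattr(row, "md", ""):
                names += ["md-" + n for n in str(row.md).split(";") if n]
            if str(getattr(row, "mesa", "0")) == "1":
                names.append("mesa")
            for name in names:
                if name not in cells:
                    raise FixtureError(
                        f"{row.gene} {row.substitution}: unknown region cell {name!r}")
                gene = CELLS[name][0]
                if gene != row.gene:
                    raise FixtureError(
                        f"{row.gene} {row.substitution}: cell {name!r} belongs to {gene}")
                cells[name].add(pos)
    return cells, occupied


def build_fixture_regions(tables: Iterable[pd.DataFrame]) -> RegionSet:
    """Reconstruct the packaged RegionSet from annotated variant tables.

    Deterministic: filler residues are the lowest available positions (those
    untouched by any tabulated variant of any cohort), consumed in the fixed
    ``FILL_PLAN`` order.  Raises :class:`FixtureError` if any published
    union size fails to hold for the finished set.
    """
    cells, occupied = _variant_cells(tables)

    free_iter = (p for p in range(1, PROTEIN_LENGTHS["MYH7"] + 1)
                 if p not in occupied)

    mesa_shared: list[int] = []
    for names, count in FILL_PLAN:
        taken = [next(free_iter) for _ in range(count)]
        for name in names:
            cells[name].update(taken)
        is_ihm = any(CELLS[n][1] in IHM_CLASSES for n in names)
        if is_ihm and len(mesa_shared) < MESA_SHARED_IHM_FILLERS:
            room = MESA_SHARED_IHM_FILLERS - len(mesa_shared)
            mesa_shared.extend(taken[:room])
    if len(mesa_shared) != MESA_SHARED_IHM_FILLERS:
        raise FixtureError("not enough IHM filler residues to share with the mesa")
    cells["mesa"].update(mesa_shared)

    cells["lmm"].update(range(LMM_START, PROTEIN_LENGTHS["MYH7"] + 1))

    regions = []
    for name, positions in cells.items():
        if not positions:
            continue
        gene, iclass, context = CELLS[name]
        regions.append(ResidueRegion(name, gene, iclass, context, set(positions)))
    rs = RegionSet(regions=regions)

    for key, expected in PRINTED_SIZES.items():
        got = rs.union_size(SELECTORS[key], gene="MYH7")
        if got != expected:
            raise FixtureError(
                f"fixture union {key!r} has {got} residues, published size is "
                f"{expected}; the fill plan and variant tables conflict")
    mesa_ihm = rs.union(SELECTORS["mesa"]) & rs.union(SELECTORS["ihm_all"])
    if len(mesa_ihm) != 126:
        raise FixtureError(
            f"mesa/IHM overlap is {len(mesa_ihm)} residues, expected 126")
    return rs
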