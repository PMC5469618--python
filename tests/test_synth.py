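"""Generator determinism, distributional properties, fixture reconstruction."""

import math

import numpy as np
import pytest

from ihmburden import fixtures
from ihmburden.regions import SELECTORS, format_ranges
from ihmburden.synth import (FixtureError, SimSpec, build_fixture_regions,
                             gen_cds, gen_cohorts, gen_profile, gen_variants)


REGION = frozenset(range(100, 547))  # 447 residues, mirrors the IHM union size


class TestDeterminism:
    def test_same_seed_same_variants(self):
        spec = SimSpec(seed=42, region=REGION, n_variants=50)
        assert gen_variants(spec) == gen_variants(spec)

    def test_different_seeds_differ(self):
        a = gen_variants(SimSpec(seed=1, region=REGION, n_variants=50))
        b = gen_variants(SimSpec(seed=2, region=REGION, n_variants=50))
        assert a != b

    def test_substreams_are_independent(self):
        # the cohort stream must not perturb the variant stream for one seed
        spec1 = SimSpec(seed=9, region=REGION, true_or=1.0)
        spec2 = SimSpec(seed=9, region=REGION, true_or=12.0)
        assert gen_variants(spec1) == gen_variants(spec2)
        assert gen_cds(30, seed=9) == gen_cds(30, seed=9)

    def test_profile_reproducible(self):
        m1, e1 = gen_profile(SimSpec(seed=5))
        m2, e2 = gen_profile(SimSpec(seed=5))
        np.testing.assert_array_equal(e1.I, e2.I)
        np.testing.assert_array_equal(m1.I, m2.I)


class TestGenVariants:
    def test_uniform_null_matches_region_share(self):
        spec = SimSpec(seed=0, region=REGION, n_variants=10000,
                       enrichment_factor=1.0)
        recs = gen_variants(spec)
        share = len(REGION) / 1935
        in_region = sum(r.position in REGION for r in recs) / len(recs)
        se = math.sqrt(share * (1 - share) / len(recs))
        assert abs(in_region - share) < 3 * se

    def test_enrichment_factor_scales_in_region_mass(self):
        spec = SimSpec(seed=1, region=REGION, n_variants=10000,
                       enrichment_factor=3.0)
        recs = gen_variants(spec)
        target = 3.0 * len(REGION) / 1935
        in_region = sum(r.position in REGION for r in recs) / len(recs)
        se = math.sqrt(target * (1 - target) / len(recs))
        assert abs(in_region - target) < 3 * se

    def test_records_are_wellformed_missense(self):
        for r in gen_variants(SimSpec(seed=3, region=REGION, n_variants=100)):
            assert r.ref_aa != r.alt_aa
            assert 1 <= r.position <= 1935

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            gen_variants(SimSpec(seed=0, region=frozenset()))

    def test_infeasible_factor_rejected(self):
        with pytest.raises(ValueError):
            gen_variants(SimSpec(seed=0, region=REGION, enrichment_factor=10.0))


class TestGenCohorts:
    def test_counts_within_bounds(self):
        c = gen_cohorts(SimSpec(seed=4, true_or=5.0))
        assert 0 <= c.carriers_cases <= c.n_cases
        assert 0 <= c.carriers_controls <= c.n_controls

    def test_degenerate_control_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_cohorts(SimSpec(seed=0, control_rate=0.0))
        with pytest.raises(ValueError):
            gen_cohorts(SimSpec(seed=0, control_rate=1.0))


class TestGenCds:
    def test_no_stops_and_event_count(self):
        from ihmburden.charge import enumerate_snvs
        cds = gen_cds(1935, seed=0)
        census = enumerate_snvs(cds)
        assert census.n_events == 17415
        assert census.n_codons == 1935

    def test_single_codon(self):
        from ihmburden.charge import enumerate_snvs
        assert enumerate_snvs(gen_cds(1, seed=1)).n_events == 9

    def test_bad_codon_count_rejected(self):
        with pytest.raises(ValueError):
            gen_cds(0)


class TestFixtureBuilder:
    def test_builder_reproduces_packaged_region_file(self, regions):
        """The packaged regions.tsv is exactly what the deterministic
        constraint-satisfying builder produces from the variant tables."""
        rebuilt = build_fixture_regions([
            fixtures.load_hcm_pv_table(), fixtures.load_hcm_lpv_table(),
            fixtures.load_dcm_table()])
        packaged = {r.name: r for r in regions.regions}
        fresh = {r.name: r for r in rebuilt.regions}
        assert packaged.keys() == fresh.keys()
        for name in packaged:
            assert format_ranges(packaged[name].residues) == \
                format_ranges(fresh[name].residues), name

    def test_builder_validates_published_sizes(self, regions):
        # spot check two key unions straight off the builder's output
        rebuilt = build_fixture_regions([
            fixtures.load_hcm_pv_table(), fixtures.load_hcm_lpv_table(),
            fixtures.load_dcm_table()])
        assert rebuilt.union_size(SELECTORS["ihm_all"]) == 447
        assert rebuilt.union_size(SELECTORS["mesa"]) == 277

    def test_inconsistent_tables_raise(self):
        # drop the LPV table: stabilizing/priming unions can no longer pad
        # to the published sizes without colliding with the constraints
        with pytest.raises(FixtureError):
            build_fixture_regions([fixtures.load_hcm_pv_table()])
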