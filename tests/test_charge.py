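"""Charge-change computation and exhaustive SNV enumeration."""

import itertools
from types import MappingProxyType

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from ihmburden._aa import AA1, PAPER_SCALE, STANDARD_SCALE, ChargeScale
from ihmburden.charge import (CdsError, SnvCensus, charge_change_fraction,
                              delta_q, enumerate_snvs, expected_charge_change)
from ihmburden.regions import SELECTORS
from ihmburden.variants import expand_token, parse_substitutions, records_from_table


def _rec(token):
    (r,) = parse_substitutions([("MYH7", token, "PV", "HCM")])
    return r


class TestDeltaQ:
    @pytest.mark.parametrize("token,dq", [
        ("E170K", 2), ("R169K", -1), ("M515T", 0), ("R403W", -2),
        ("Y115H", 1), ("D906G", 1), ("K766Q", -1),
    ])
    def test_known_substitutions_on_inferred_scale(self, token, dq):
        assert delta_q(_rec(token), PAPER_SCALE) == dq

    def test_standard_scale_differs_for_arginine_and_histidine(self):
        assert delta_q(_rec("R403W"), STANDARD_SCALE) == -1
        assert delta_q(_rec("Y115H"), STANDARD_SCALE) == 0

    def test_every_printed_dq_reproduced(self, hcm_tables, dcm_table):
        """Regression pinning the inferred charge scale: all table Δq values
        (including slashed multi-values) match exactly."""
        mismatches = []
        for df in (*hcm_tables, dcm_table):
            recs = iter(records_from_table(df))
            for row in df.itertuples():
                for _ in expand_token(row.substitution):
                    rec = next(recs)
                    want = int(str(row.dq).replace("+", ""))
                    if delta_q(rec, PAPER_SCALE) != want:
                        mismatches.append(rec.token)
        assert mismatches == []

    @settings(max_examples=100, derandomize=True)
    @given(st.sampled_from(AA1), st.sampled_from(AA1), st.integers(-3, 3))
    def test_antisymmetry_and_translation_invariance(self, x, y, c):
        if x == y:
            return
        fwd, rev = _rec(f"{x}100{y}"), _rec(f"{y}100{x}")
        assert delta_q(fwd, PAPER_SCALE) == -delta_q(rev, PAPER_SCALE)
        shifted = ChargeScale("shifted", MappingProxyType(
            {aa: PAPER_SCALE.charge(aa) + c for aa in AA1}))
        assert delta_q(fwd, shifted) == delta_q(fwd, PAPER_SCALE)


class TestChargeFraction:
    def test_ihm_hitting_hcm_pvs(self, hcm_pv_annotated):
        ihm = [a.record for a in hcm_pv_annotated if a.matches(SELECTORS["ihm_all"])]
        k, n, frac = charge_change_fraction(ihm)
        assert (k, n) == (22, 31)
        assert round(100 * frac) == 71

    def test_ihm_hitting_dcm_variants(self, dcm_annotated):
        ihm = [a.record for a in dcm_annotated if a.matches(SELECTORS["ihm_all"])]
        k, n, frac = charge_change_fraction(ihm)
        assert (k, n) == (5, 7)
        assert round(100 * frac) == 71

    def test_neutral_swaps_count_zero(self):
        recs = [_rec("A10V"), _rec("V20A")]
        assert charge_change_fraction(recs)[:2] == (0, 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            charge_change_fraction([])


def oracle_census(cds, scale=PAPER_SCALE):
    """Independent brute force: mutate each base, re-translate the whole CDS,
    and compare protein sequences."""
    ref_prot = str(Seq(cds).translate())
    if ref_prot.endswith("*"):
        cds = cds[:-3]
        ref_prot = ref_prot[:-1]
    syn = mis = non = 0
    neg = neu = pos = 0
    for i in range(len(cds)):
        for b in "ACGT":
            if b == cds[i]:
                continue
            mut_prot = str(Seq(cds[:i] + b + cds[i + 1:]).translate())
            diffs = [j for j in range(len(ref_prot)) if mut_prot[j] != ref_prot[j]]
            if not diffs:
                syn += 1
            elif mut_prot[diffs[0]] == "*":
                non += 1
            else:
                mis += 1
                dq = scale.charge(mut_prot[diffs[0]]) - scale.charge(ref_prot[diffs[0]])
                neg += dq < 0
                neu += dq == 0
                pos += dq > 0
    return (len(cds) // 3, syn, mis, non, neg, neu, pos)


class TestEnumerateSnvs:
    def test_single_lysine_codon_by_hand(self):
        c = enumerate_snvs("AAA")
        assert (c.n_events, c.n_synonymous, c.n_nonsense, c.n_missense) == (9, 1, 1, 7)
        # every missense neighbour of AAA (K, q=+1) changes the charge
        assert c.missense_neutral == 0

    def test_single_tryptophan_codon_by_hand(self):
        c = enumerate_snvs("TGG")
        assert (c.n_synonymous, c.n_nonsense, c.n_missense) == (0, 2, 7)

    def test_terminal_stop_stripped(self):
        assert enumerate_snvs("AAATAA").n_events == 9

    def test_full_length_protein_event_count(self):
        from ihmburden.synth import gen_cds
        assert enumerate_snvs(gen_cds(1935, seed=7)).n_events == 17415

    @pytest.mark.parametrize("cds,err", [
        ("AAAA", CdsError), ("AAN", CdsError), ("AAATAAAAA", CdsError),
    ])
    def test_bad_cds_rejected(self, cds, err):
        with pytest.raises(err):
            enumerate_snvs(cds)

    def test_internal_stop_warn_mode(self):
        with pytest.warns(UserWarning):
            enumerate_snvs("AAATAAAAA", on_internal_stop="warn")

    def test_matches_bruteforce_oracle_on_random_cds(self):
        from ihmburden.synth import gen_cds
        for seed in range(12):
            cds = gen_cds(5 + seed * 7, seed=seed)
            c = enumerate_snvs(cds)
            assert oracle_census(cds) == (
                c.n_codons, c.n_synonymous, c.n_missense, c.n_nonsense,
                c.missense_negative, c.missense_neutral, c.missense_positive)


class TestExpectedChargeChange:
    def test_published_sign_split_gives_49_percent(self):
        census = SnvCensus(1935, n_synonymous=0, n_missense=12850, n_nonsense=0,
                           missense_negative=2681, missense_neutral=6565,
                           missense_positive=3604)
        assert expected_charge_change(census) == pytest.approx(6285 / 12850)
        assert round(100 * expected_charge_change(census)) == 49

    def test_all_neutral_census(self):
        census = SnvCensus(1, 0, 7, 2, 0, 7, 0)
        assert expected_charge_change(census) == 0.0
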