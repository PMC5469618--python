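"""Region parsing, unions, selectors and fixture internal consistency."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from ihmburden.regions import (RegionParseError, RegionSet, ResidueRegion,
                               SELECTORS, Selector, format_ranges,
                               parse_ranges, parse_regions, write_regions)
from ihmburden.variants import expand_token


def _rs(text: str) -> RegionSet:
    return parse_regions(io.StringIO(text))


class TestParsing:
    def test_range_syntax_counts_each_position_once(self):
        rs = _rs("d1\tMYH7\tstabilizing-d1\tfree\t169-170,403-411\n")
        assert rs.regions[0].size == 11

    def test_rows_with_same_name_merge_by_union(self):
        rs = _rs("X\tMYH7\tother\teither\t1-10\nX\tMYH7\tother\teither\t5-15\n")
        assert len(rs.regions) == 1
        assert rs.regions[0].size == 15

    @pytest.mark.parametrize("row", [
        "bad\tMYH7\tother\teither\t10-5",          # descending range
        "bad\tMYH7\tnot-a-class\teither\t1-5",     # unknown class
        "bad\tMYH7\tother\tsideways\t1-5",         # unknown context
        "bad\tMYH7\tother\teither\t1900-1940",     # beyond protein length
        "bad\tNOPE\tother\teither\t1-5",           # unknown gene
        "bad\tMYH7\tother\teither\t",              # empty residues
    ])
    def test_malformed_rows_are_rejected_with_row_identity(self, row):
        with pytest.raises(RegionParseError):
            _rs(row + "\n")

    def test_comments_and_blank_lines_skipped(self):
        rs = _rs("# header\n\nX\tMYH7\tmesa\teither\t5,7\n")
        assert rs.regions[0].residues == {5, 7}

    def test_write_then_reparse_is_identity(self, regions, tmp_path):
        out = tmp_path / "roundtrip.tsv"
        write_regions(regions, out)
        again = parse_regions(out)
        orig = {r.name: r for r in regions.regions}
        back = {r.name: r for r in again.regions}
        assert orig.keys() == back.keys()
        for name in orig:
            assert orig[name].residues == back[name].residues
            assert orig[name].interaction_class == back[name].interaction_class
            assert orig[name].head_context == back[name].head_context


class TestUnionSize:
    def test_hand_union_of_overlapping_regions(self):
        rs = _rs("p\tMYH7\tpriming-g\tblocked\t1-5\n"
                 "s\tMYH7\tstabilizing-a\ttail\t4-8\n")
        sel = Selector("ps", classes=frozenset({"priming-g", "stabilizing-a"}))
        assert rs.union_size(sel) == 8

    def test_empty_selection_is_zero(self, regions):
        sel = Selector("none", classes=frozenset({"regulating-RLC-RLC"}))
        assert regions.union_size(sel, gene="MYH7") == 0

    @pytest.mark.parametrize("key,size", [
        ("ihm_all", 447), ("priming", 113), ("anchoring", 156),
        ("stabilizing", 189), ("scaffolding", 120), ("md194", 194),
        ("md210", 210), ("mesa", 277), ("blocked", 362), ("free", 171),
        ("tail", 69), ("nucleotide", 39), ("actin", 60), ("converter", 68),
        ("relay", 27),
    ])
    def test_packaged_fixture_reproduces_published_sizes(self, regions, key, size):
        assert regions.union_size(SELECTORS[key], gene="MYH7") == size


@st.composite
def region_lists(draw):
    n = draw(st.integers(1, 6))
    out = []
    for i in range(n):
        residues = draw(st.sets(st.integers(1, 200), min_size=1, max_size=40))
        out.append(ResidueRegion(f"r{i}", "MYH7", "other", "either", residues))
    return out


class TestUnionProperties:
    @settings(max_examples=50, derandomize=True)
    @given(region_lists())
    def test_union_monotone_and_subadditive(self, regs):
        sel = Selector("all", classes=frozenset({"other"}))
        sizes = []
        for i in range(1, len(regs) + 1):
            sizes.append(RegionSet(regions=regs[:i]).union_size(sel))
        assert sizes == sorted(sizes)  # monotone under adding regions
        total = sum(len(r.residues) for r in regs)
        assert sizes[-1] <= total      # subadditive

    @settings(max_examples=50, derandomize=True)
    @given(region_lists())
    def test_format_parse_ranges_roundtrip(self, regs):
        for r in regs:
            assert parse_ranges(format_ranges(r.residues)) == r.residues


class TestFixtureConsistency:
    def test_every_annotation_matches_region_membership(
            self, regions, hcm_tables, dcm_table):
        """Each fixture variant lies inside exactly the regions its row
        names (interaction cells + MD cells + mesa), and outside all
        others — including md210 padding, which must avoid variants."""
        for df in (*hcm_tables, dcm_table):
            for row in df.itertuples():
                pos = expand_token(row.substitution)[0][1]
                expected = set()
                if row.regions:
                    expected |= {n for n in row.regions.split(";") if n}
                if row.md:
                    expected |= {"md-" + n for n in row.md.split(";") if n}
                if str(row.mesa) == "1":
                    expected.add("mesa")
                actual = {r.name for r in regions.regions_at(row.gene, pos)}
                assert actual == expected, (
                    f"{row.gene} {row.substitution}: regions {actual} != "
                    f"annotations {expected}")

    def test_lmm_variants_never_hit_ihm_regions(self, regions, hcm_tables):
        ihm = regions.union(SELECTORS["ihm_all"])
        for df in hcm_tables:
            for row in df.itertuples():
                if "lmm" in str(row.regions):
                    pos = expand_token(row.substitution)[0][1]
                    assert pos not in ihm
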