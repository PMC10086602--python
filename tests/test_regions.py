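"""Element parsing, region merging and region summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import psimap as pm
from conftest import components_oracle, make_region, union_oracle


def intervals_strategy(max_len=100_000):
    interval = st.tuples(st.integers(0, max_len - 2), st.integers(1, 5_000)).map(
        lambda t: (t[0], min(t[0] + t[1], max_len)))
    return st.lists(interval, min_size=0, max_size=60)


def elements_from(intervals, chrom="chr1", type_code=1):
    return [pm.PSIElement(f"e{i}", type_code, chrom, s, e)
            for i, (s, e) in enumerate(intervals)]


class TestReadPsiBed:
    def test_parses_bed3_rows(self, genome, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t100\t200\nchr2\t0\t50\n")
        elements = pm.read_psi_bed(path, 1, genome)
        assert [(e.chrom, e.start, e.end, e.type_code) for e in elements] == [
            ("chr1", 100, 200, 1), ("chr2", 0, 50, 1)]
        assert elements[0].type_name == "HAR"

    def test_inverted_interval_rejected(self, genome, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t200\t100\n")
        with pytest.raises(pm.ValidationError, match="start"):
            pm.read_psi_bed(path, 1, genome)

    def test_malformed_row_names_line(self, genome, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t100\t200\nchr1\t100\n")
        with pytest.raises(pm.ParseError, match="line 2"):
            pm.read_psi_bed(path, 1, genome)

    def test_unknown_chromosome_rejected(self, genome, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr9\t100\t200\n")
        with pytest.raises(pm.ValidationError, match="chr9"):
            pm.read_psi_bed(path, 1, genome)

    def test_out_of_bounds_end_rejected(self, genome, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr2\t100\t600000\n")
        with pytest.raises(pm.ValidationError, match="exceeds"):
            pm.read_psi_bed(path, 1, genome)


class TestMerge:
    def test_overlapping_pair_merges(self):
        regions = pm.merge_into_regions(elements_from([(100, 200), (150, 250)]))
        assert len(regions) == 1
        r = regions[0]
        assert (r.chrom, r.start, r.end) == ("chr1", 100, 250)
        assert r.multi_element

    def test_abutting_intervals_stay_separate(self):
        regions = pm.merge_into_regions(elements_from([(100, 200), (200, 300)]))
        assert [(r.start, r.end) for r in regions] == [(100, 200), (200, 300)]

    def test_empty_input_gives_empty_output(self):
        assert pm.merge_into_regions([]) == []

    def test_identical_duplicates_merge_to_multi_element_region(self):
        els = [pm.PSIElement("a", 1, "chr1", 10, 20),
               pm.PSIElement("b", 6, "chr1", 10, 20)]
        regions = pm.merge_into_regions(els)
        assert len(regions) == 1
        assert regions[0].element_ids == {"a", "b"}
        assert regions[0].type_set == {1, 6}
        assert not regions[0].regulatory  # hsInsert in the mix

    def test_matches_base_array_oracle_500_on_1mb(self):
        rng = np.random.default_rng(42)
        starts = rng.integers(0, 1_000_000 - 5_000, size=500)
        lengths = rng.integers(1, 5_000, size=500)
        intervals = [(int(s), int(s + l)) for s, l in zip(starts, lengths)]
        regions = pm.merge_into_regions(elements_from(intervals))
        assert [(r.start, r.end) for r in regions] == components_oracle(intervals)
        # covered bases agree with the base-array union
        assert sum(r.length for r in regions) == \
            sum(e - s for s, e in union_oracle(intervals, 1_000_000))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(intervals_strategy())
    def test_merge_properties(self, intervals):
        elements = elements_from(intervals)
        regions = pm.merge_into_regions(elements)
        # equals the brute-force connected-components oracle
        assert [(r.start, r.end) for r in regions] == components_oracle(intervals)
        # covered bases equal the base-array union oracle
        assert sum(r.length for r in regions) == \
            sum(e - s for s, e in union_oracle(intervals, 100_000))
        # idempotence: re-merging the regions changes nothing
        again = pm.merge_into_regions(
            [pm.PSIElement(r.region_id, 1, r.chrom, r.start, r.end) for r in regions])
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in regions]
        # total region length <= total element length, equality iff no overlap
        total_el = sum(e - s for s, e in intervals)
        total_reg = sum(r.length for r in regions)
        assert total_reg <= total_el
        # every element is contained in exactly one region
        by_id = {e.element_id: e for e in elements}
        seen = set()
        for r in regions:
            for eid in r.element_ids:
                e = by_id[eid]
                assert r.start <= e.start and e.end <= r.end
                seen.add(eid)
        assert seen == set(by_id)
        # sum over regions of (members - 1) = n_elements - n_regions
        assert sum(len(r.element_ids) - 1 for r in regions) == len(elements) - len(regions)


class TestSummary:
    def test_single_region_coverage(self):
        genome = pm.GenomeTable((("chr1", 1_000),))
        s = pm.summarize_regions([make_region("r1", "chr1", 0, 100)], genome)
        assert s.genome_coverage == pytest.approx(0.10)
        assert s.total_bp == 100 and s.n_regions == 1

    def test_mean_reported_both_ways(self):
        # 3 regions totalling 50 bp -> mean 16.7 / truncated 16
        genome = pm.GenomeTable((("chr1", 1_000),))
        regions = [make_region("a", "chr1", 0, 10), make_region("b", "chr1", 20, 40),
                   make_region("c", "chr1", 50, 70)]
        s = pm.summarize_regions(regions, genome)
        assert (s.mean_bp, s.mean_bp_truncated) == (16.7, 16)

    def test_missing_chromosome_errors(self):
        genome = pm.GenomeTable((("chr1", 1_000),))
        with pytest.raises(pm.ValidationError):
            pm.summarize_regions([make_region("r", "chrZ", 0, 10)], genome)

    def test_per_chrom_sums_to_total(self):
        rng = np.random.default_rng(3)
        genome = pm.GenomeTable((("chr1", 100_000), ("chr2", 100_000)))
        els = []
        for chrom in ("chr1", "chr2"):
            for i, s in enumerate(rng.integers(0, 99_000, size=50)):
                els.append(pm.PSIElement(f"{chrom}_{i}", 1, chrom, int(s), int(s) + 500))
        regions = pm.merge_into_regions(els)
        s = pm.summarize_regions(regions, genome)
        assert sum(bp for _, _, bp, _ in s.per_chrom) == s.total_bp
        assert sum(n for _, n, _, _ in s.per_chrom) == s.n_regions


class TestChromosomeDistribution:
    def _regions(self, counts):
        out = []
        for chrom, n in counts.items():
            out.extend(make_region(f"{chrom}_{i}", chrom, i * 10, i * 10 + 5)
                       for i in range(n))
        return out

    def test_proportional_counts_give_zero_statistic(self):
        genome = pm.GenomeTable((("chr1", 100), ("chr2", 100)))
        res = pm.chisq_chromosome_distribution(
            self._regions({"chr1": 10, "chr2": 10}), genome)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # E = (10, 10); O = (5, 15): sum (O-E)^2/E = 25/10 + 25/10 = 5.0
        genome = pm.GenomeTable((("chr1", 100), ("chr2", 100)))
        res = pm.chisq_chromosome_distribution(
            self._regions({"chr1": 5, "chr2": 15}), genome)
        assert res.statistic == pytest.approx(5.0)
        assert res.df == 1
        assert res.p == pytest.approx(sps.chi2.sf(5.0, 1), rel=1e-12)
        assert res.p == pytest.approx(0.0253, abs=5e-4)

    def test_invariant_to_chromosome_order(self):
        regions = self._regions({"chr1": 7, "chr2": 21, "chr3": 2})
        g1 = pm.GenomeTable((("chr1", 100), ("chr2", 300), ("chr3", 50)))
        g2 = pm.GenomeTable((("chr3", 50), ("chr1", 100), ("chr2", 300)))
        r1 = pm.chisq_chromosome_distribution(regions, g1)
        r2 = pm.chisq_chromosome_distribution(regions, g2)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_display_floor_only_affects_display(self):
        genome = pm.GenomeTable((("chr1", 1_000), ("chr2", 1_000)))
        res = pm.chisq_chromosome_distribution(
            self._regions({"chr1": 500, "chr2": 1}), genome)
        assert res.p < 2.2e-16  # raw p retained
        assert res.p_display == "< 2.2e-16"
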