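"""Variant-to-region mapping, pleiotropy counting and type-level counts."""

import numpy as np
import pytest
from intervaltree import IntervalTree

import psimap as pm
from conftest import make_record, make_region


class TestMapVariants:
    def test_interior_position_maps(self):
        regions = [make_region("r1", "chr1", 100, 200)]
        mapped = pm.map_variants([make_record("chr1", 150)], regions)
        assert len(mapped) == 1 and mapped[0].region_id == "r1"

    def test_left_boundary_convention(self):
        # 1-based pos 100 is 0-based offset 99, outside [100, 200)
        regions = [make_region("r1", "chr1", 100, 200)]
        assert pm.map_variants([make_record("chr1", 100)], regions) == []
        assert len(pm.map_variants([make_record("chr1", 101)], regions)) == 1

    def test_right_boundary_convention(self):
        # offset 199 inside, offset 200 outside the half-open end
        regions = [make_region("r1", "chr1", 100, 200)]
        assert len(pm.map_variants([make_record("chr1", 200)], regions)) == 1
        assert pm.map_variants([make_record("chr1", 201)], regions) == []

    def test_inherits_full_type_set(self):
        regions = [make_region("r1", "chr1", 0, 50, type_codes=(1, 6))]
        mapped = pm.map_variants([make_record("chr1", 10)], regions)
        assert mapped[0].type_set == {1, 6}

    def test_overlapping_regions_rejected(self):
        regions = [make_region("r1", "chr1", 0, 100), make_region("r2", "chr1", 50, 150)]
        with pytest.raises(pm.ValidationError, match="overlap"):
            pm.map_variants([make_record("chr1", 10)], regions)

    def test_matches_interval_tree_oracle_on_random_data(self):
        rng = np.random.default_rng(9)
        starts = np.sort(rng.choice(np.arange(0, 2_000_000, 400), 800, replace=False))
        regions = [make_region(f"r{i}", "chr1", int(s), int(s) + int(rng.integers(1, 380)))
                   for i, s in enumerate(starts)]
        tree = IntervalTree()
        for r in regions:
            tree[r.start:r.end] = r.region_id
        records = [make_record("chr1", int(p))
                   for p in rng.integers(1, 2_000_001, size=10_000)]
        mapped = {mv.record.pos: mv.region_id
                  for mv in pm.map_variants(records, regions)}
        oracle = {}
        for rec in records:
            hits = tree[rec.pos - 1]
            assert len(hits) <= 1
            if hits:
                oracle[rec.pos] = next(iter(hits)).data
        assert mapped == oracle

    def test_stable_under_region_order_permutation(self):
        rng = np.random.default_rng(5)
        regions = [make_region(f"r{i}", "chr1", i * 100, i * 100 + 60) for i in range(30)]
        records = [make_record("chr1", int(p)) for p in rng.integers(1, 3_100, size=300)]
        a = [(m.identity, m.region_id) for m in pm.map_variants(records, regions)]
        shuffled = list(regions)
        rng.shuffle(shuffled)
        b = [(m.identity, m.region_id) for m in pm.map_variants(records, shuffled)]
        assert a == b

    def test_round_trip_position_inside_region(self, default_bundle):
        out, config, _ = default_bundle
        rc = pm.RunConfig.from_bundle(out, out / "rt")
        genome = pm.GenomeTable.from_chrom_sizes(rc.chrom_sizes)
        elements = []
        for code in sorted(rc.psi_beds):
            elements.extend(pm.read_psi_bed(rc.psi_beds[code], code, genome))
        regions = pm.merge_into_regions(elements)
        by_id = {r.region_id: r for r in regions}
        records = []
        for spec, path in pm.read_trait_manifest(rc.trait_manifest):
            records.extend(pm.filter_significant(pm.read_gwas_table(path, spec), spec))
        for mv in pm.map_variants(records, regions):
            r = by_id[mv.region_id]
            assert r.start <= mv.record.pos - 1 < r.end


class TestPleiotropy:
    def test_two_trait_variant_counts_once(self):
        region = make_region("r1", "chr1", 0, 1000)
        mapped = pm.map_variants(
            [make_record("chr1", 10, trait_id="a", variant_id="rs1"),
             make_record("chr1", 10, trait_id="b", variant_id="rs1"),
             make_record("chr1", 20, trait_id="a", variant_id="rs2")], [region])
        assert pm.count_pleiotropic(mapped) == (2, 1)

    def test_all_unique_gives_zero(self):
        region = make_region("r1", "chr1", 0, 1000)
        mapped = pm.map_variants(
            [make_record("chr1", p, trait_id=f"t{p}") for p in (10, 20, 30)], [region])
        assert pm.count_pleiotropic(mapped) == (3, 0)

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(17)
        region = make_region("r1", "chr1", 0, 100_000)
        records = [make_record("chr1", int(rng.integers(1, 300)), trait_id=f"t{t}")
                   for t in range(6) for _ in range(120)]
        mapped = pm.map_variants(records, [region])
        n_distinct, n_pleio = pm.count_pleiotropic(mapped)
        groups = {}
        for mv in mapped:
            groups.setdefault(mv.identity, set()).add(mv.record.trait_id)
        assert n_distinct == len(groups)
        assert n_pleio == sum(1 for ts in groups.values() if len(ts) >= 2)
        assert n_pleio <= n_distinct


class TestTypeLevelCounts:
    traits = [pm.TraitSpec("dz", "disease", "pvalue"),
              pm.TraitSpec("qt", "quantitative", "pvalue")]

    def test_single_type_single_event(self):
        regions = [make_region("r1", "chr1", 0, 100, type_codes=(9,))]
        mapped = pm.map_variants([make_record("chr1", 10, trait_id="dz")], regions)
        table = pm.type_level_counts(mapped, self.traits)
        assert table.loc[9, "disease"] == 1
        assert int(table.to_numpy().sum()) == 1

    def test_multi_type_region_increments_every_type(self):
        regions = [make_region("r1", "chr1", 0, 100, type_codes=(1, 6))]
        mapped = pm.map_variants([make_record("chr1", 10, trait_id="dz")], regions)
        table = pm.type_level_counts(mapped, self.traits)
        assert table.loc[1, "disease"] == 1 and table.loc[6, "disease"] == 1

    def test_exclude_mode_drops_multi_type(self):
        regions = [make_region("r1", "chr1", 0, 100, type_codes=(1, 6))]
        mapped = pm.map_variants([make_record("chr1", 10, trait_id="dz")], regions)
        table = pm.type_level_counts(mapped, self.traits, multi_type="exclude")
        assert int(table.to_numpy().sum()) == 0

    def test_column_sums_equal_event_recount(self):
        rng = np.random.default_rng(23)
        regions = [make_region(f"r{i}", "chr1", i * 200, i * 200 + 150,
                               type_codes=tuple(rng.choice(range(1, 10),
                                                           rng.integers(1, 3),
                                                           replace=False)))
                   for i in range(40)]
        records = [make_record("chr1", int(p), trait_id=rng.choice(["dz", "qt"]))
                   for p in rng.integers(1, 8_000, size=500)]
        mapped = pm.map_variants(records, regions)
        table = pm.type_level_counts(mapped, self.traits)
        expected = sum(len(mv.type_set) for mv in mapped)
        assert int(table.to_numpy().sum()) == expected
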