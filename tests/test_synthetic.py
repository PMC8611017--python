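"""Generator invariants: tree shapes, lineage consistency, copy-number
evolution rules and the closed-form read-count model."""

import numpy as np
import pandas as pd
import pytest

from mrevo.errors import InvalidConfigError, InvalidInputError
from mrevo.synthetic import (GroundTruth, SimulationConfig, clade,
                             expected_snv_vaf, make_segments,
                             simulate_ccf_matrix, simulate_clone_tree,
                             simulate_cn_evolution, simulate_cohort,
                             simulate_reads, write_cohort)


class TestCloneTree:
    def test_single_clone_is_root_only(self):
        assert list(simulate_clone_tree(1, 0)) == [-1]

    def test_two_clones_forced_topology(self):
        assert list(simulate_clone_tree(2, 99)) == [-1, 0]

    def test_deterministic_under_seed(self):
        a = simulate_clone_tree(5, 7)
        b = simulate_clone_tree(5, 7)
        assert np.array_equal(a, b)

    def test_rejects_empty_tree(self):
        with pytest.raises(InvalidConfigError):
            simulate_clone_tree(0, 0)

    def test_linear_and_branched_shapes_both_occur(self):
        shapes = set()
        for seed in range(40):
            parent = simulate_clone_tree(4, seed)
            n_children_root = int(np.sum(parent == 0))
            shapes.add("branched" if n_children_root > 1 else "linear")
        assert shapes == {"linear", "branched"}


class TestCcfMatrix:
    def test_single_clone_row_of_ones(self):
        ccf = simulate_ccf_matrix(np.array([-1]), 3, 0)
        assert np.allclose(ccf, 1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_lineage_consistency_and_sibling_sum(self, seed):
        parent = simulate_clone_tree(6, seed)
        ccf = simulate_ccf_matrix(parent, 4, seed)
        for k, p in enumerate(parent):
            if p >= 0:
                assert np.all(ccf[k] <= ccf[p] + 1e-9)
        for p in range(6):
            kids = [k for k in range(6) if parent[k] == p]
            if kids:
                assert np.all(ccf[kids].sum(axis=0) <= ccf[p] + 1e-9)

    def test_fixed_design_replayed_exactly(self):
        parent = np.array([-1, 0, 1])
        planted = np.array([[1.0], [0.6], [0.2]])
        out = simulate_ccf_matrix(parent, 1, 0, fixed=planted)
        assert np.array_equal(out, planted)

    def test_fixed_design_rejects_lineage_violation(self):
        parent = np.array([-1, 0, 1])
        bad = np.array([[1.0], [0.2], [0.6]])
        with pytest.raises(InvalidInputError):
            simulate_ccf_matrix(parent, 1, 0, fixed=bad)

    def test_min_gap_honoured(self):
        parent = simulate_clone_tree(4, 3)
        ccf = simulate_ccf_matrix(parent, 3, 3, min_gap=0.15)
        gaps = np.abs(ccf[:, None, :] - ccf[None, :, :]).max(axis=2)
        iu = np.triu_indices(4, 1)
        assert gaps[iu].min() >= 0.15


class TestCnEvolution:
    def _config(self, **kw):
        base = dict(n_clones=5, n_segments=44, seed=0)
        base.update(kw)
        return SimulationConfig(**base)

    def test_zero_msai_probability_gives_empty_truth(self):
        parent = simulate_clone_tree(5, 1)
        _, msai, _, _, _ = simulate_cn_evolution(
            parent, self._config(msai_probability=0.0), 1)
        assert msai == set()

    def test_whole_chromosome_fraction_one_types_all_whole(self):
        parent = simulate_clone_tree(5, 2)
        cfg = self._config(whole_chromosome_event_fraction=1.0,
                           cn_event_rate=2.0, msai_probability=0.0)
        _, _, chrom_type, _, events = simulate_cn_evolution(parent, cfg, 2)
        assert len(events) > 0
        assert all(t in ("none", "whole") for t in chrom_type.values())

    def test_planted_msai_mirrors_haplotypes(self):
        # branched tree, no background events: the mirrored gain must show
        # opposite-haplotype imbalance in the two disjoint clades
        found = 0
        for seed in range(30):
            parent = np.array([-1, 0, 0])
            cfg = self._config(n_clones=3, cn_event_rate=0.0,
                               msai_probability=0.3, seed=seed)
            profiles, msai, _, _, _ = simulate_cn_evolution(parent, cfg, seed)
            for s in msai:
                found += 1
                d1 = profiles[1, s, 0] - profiles[1, s, 1]
                d2 = profiles[2, s, 0] - profiles[2, s, 1]
                assert d1 * d2 < 0, "clades must favour opposite haplotypes"
        assert found > 0

    @pytest.mark.parametrize("seed", range(6))
    def test_loss_irreversibility(self, seed):
        parent = simulate_clone_tree(6, seed)
        cfg = self._config(n_clones=6, cn_event_rate=4.0)
        profiles, _, _, _, _ = simulate_cn_evolution(parent, cfg, seed)
        for k, p in enumerate(parent):
            if p >= 0:
                lost = profiles[p] == 0
                assert np.all(profiles[k][lost] == 0)

    def test_deterministic(self):
        parent = simulate_clone_tree(5, 3)
        a = simulate_cn_evolution(parent, self._config(), 3)
        b = simulate_cn_evolution(parent, self._config(), 3)
        assert np.array_equal(a[0], b[0])
        assert a[1] == b[1]


class TestSegments:
    def test_tiling_covers_each_chromosome_without_overlap(self):
        segs = make_segments(44)
        for chrom, grp in segs.groupby("chrom"):
            g = grp.sort_values("start")
            assert g["start"].iloc[0] == 0
            assert np.array_equal(g["end"].to_numpy()[:-1],
                                  g["start"].to_numpy()[1:])

    def test_fewer_segments_than_chromosomes(self):
        segs = make_segments(5)
        assert len(segs) == 5


class TestReadModel:
    def test_vaf_mean_matches_closed_form_within_3_se(self):
        # clonal het SNVs on a diploid genome at purity 0.6: E[VAF] = 0.30
        cfg = SimulationConfig(n_samples=2, n_clones=1, n_trunk_snvs=60,
                               purity_range=(0.6, 0.6), cn_event_rate=0.0,
                               msai_probability=0.0, seed=5)
        truth, tables = simulate_cohort(cfg)
        alt = tables.variants["alt_count"].sum()
        depth = tables.variants["depth"].sum()
        assert depth > 1e4
        se = np.sqrt(0.3 * 0.7 / depth)
        assert abs(alt / depth - 0.30) < 3 * se

    def test_purity_one_diploid_limit_is_half(self):
        cfg = SimulationConfig(n_samples=1, n_clones=1, n_trunk_snvs=5,
                               purity_range=(1.0, 1.0), cn_event_rate=0.0,
                               msai_probability=0.0, seed=6)
        truth, _ = simulate_cohort(cfg)
        for i in range(len(truth.snvs)):
            assert expected_snv_vaf(truth, truth.snvs.iloc[i], 0) == pytest.approx(0.5)

    def test_balanced_segment_baf_near_half(self):
        cfg = SimulationConfig(n_samples=1, n_clones=1, cn_event_rate=0.0,
                               msai_probability=0.0,
                               n_het_snps_per_segment=30, seed=7)
        _, tables = simulate_cohort(cfg)
        baf = tables.snp_baf["b_count"].sum() / tables.snp_baf["depth"].sum()
        assert abs(baf - 0.5) < 0.01

    def test_normals_carry_only_technical_noise(self):
        cfg = SimulationConfig(seed=8)
        _, tables = simulate_cohort(cfg)
        rate = tables.panel["alt_count"].sum() / tables.panel["depth"].sum()
        assert rate < 0.01


class TestWriteCohort:
    def test_round_trip_and_byte_identical_rerun(self, tmp_path):
        from mrevo.pipeline import load_cohort

        cfg = SimulationConfig(n_samples=2, n_clones=3, seed=11)
        truth, tables = simulate_cohort(cfg)
        write_cohort(truth, tables, tmp_path / "a", cfg)
        write_cohort(truth, tables, tmp_path / "b", cfg)
        for name in ("variants.tsv", "segments.seg", "snp_baf.tsv",
                     "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
        cohort = load_cohort(tmp_path / "a")
        pd.testing.assert_frame_equal(
            cohort.variants.sort_index(axis=1),
            tables.variants.sort_index(axis=1), check_dtype=False)
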