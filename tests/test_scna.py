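"""Event classification rules, cytoband aggregation, clonality
stratification and chromosome typing."""

import numpy as np
import pandas as pd
import pytest

from mrevo.errors import ValidationError
from mrevo.phasing import PhasedSegments
from mrevo.scna import (aggregate_cytobands, classify_chromosomes,
                        classify_cn, classify_segment_events,
                        cytoband_clonality, load_published_cohort,
                        make_uniform_cytobands, segment_clonality,
                        stratify_scna_clonality, summarize_cohort)


class TestEventClasses:
    @pytest.mark.parametrize("total,mn,baseline,expected", [
        (2, 1, 2, "neutral"),
        (0, 0, 2, "deep_loss"),
        (1, 0, 2, "loh"),
        (2, 0, 2, "loh"),          # copy-neutral LOH
        (3, 0, 2, "gain"),         # gained with one haplotype lost
        (3, 1, 2, "gain"),
        (4, 2, 2, "gain"),
        (5, 1, 2, "amplification"),
        (17, 1, 2, "amplification"),   # MYCN-like high-level amplification
        (4, 2, 4, "neutral"),      # tetraploid baseline
        (4, 0, 4, "loh"),
        (9, 4, 4, "amplification"),
    ])
    def test_rule_table(self, total, mn, baseline, expected):
        assert classify_cn(total, mn, baseline) == expected


def phased_fixture(cn_by_sample, seg_len=10, chrom_per_seg=None):
    """Minimal PhasedSegments with explicit (cnA, cnB) per sample."""
    samples = sorted(cn_by_sample)
    n_seg = len(next(iter(cn_by_sample.values())))
    if chrom_per_seg is None:
        chrom_per_seg = ["chr1"] * n_seg
    starts = []
    offsets = {}
    rows = []
    for i, c in enumerate(chrom_per_seg):
        off = offsets.get(c, 0)
        rows.append((c, off, off + seg_len))
        offsets[c] = off + seg_len
    segments = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    cn_a = np.array([[cn_by_sample[s][i][0] for s in samples]
                     for i in range(n_seg)])
    cn_b = np.array([[cn_by_sample[s][i][1] for s in samples]
                     for i in range(n_seg)])
    return PhasedSegments(
        segments=segments, samples=samples,
        cn_major=np.maximum(cn_a, cn_b), cn_minor=np.minimum(cn_a, cn_b),
        purity={s: 0.7 for s in samples}, ploidy={s: 2.0 for s in samples},
        cn_a=cn_a, cn_b=cn_b, phased=np.ones(n_seg, dtype=bool),
        ref_sample=np.zeros(n_seg, dtype=int),
        baf_a=np.full((n_seg, len(samples)), 0.5),
        p_value=np.ones((n_seg, len(samples))),
        direction=np.full((n_seg, len(samples)), "", dtype=object),
        n_snps=np.full(n_seg, 20))


class TestClonality:
    def test_identical_alterations_everywhere_all_clonal(self):
        ph = phased_fixture({"a": [(2, 1), (1, 0)], "b": [(2, 1), (1, 0)]})
        events = classify_segment_events(ph)
        row = stratify_scna_clonality(events)
        assert row["n_clonal_segments"] == 2
        assert row["n_subclonal_segments"] == 0

    def test_event_in_one_of_five_samples_is_subclonal(self):
        cn = {f"s{i}": [(1, 1)] for i in range(5)}
        cn["s0"] = [(2, 1)]
        events = classify_segment_events(phased_fixture(cn))
        seg = segment_clonality(events)
        assert seg.loc[0, "clonality"] == "subclonal"

    def test_different_gain_levels_still_one_clonal_gain(self):
        # a 3-copy and a 4-copy gain are the same event class
        ph = phased_fixture({"a": [(2, 1)], "b": [(2, 2)]})
        seg = segment_clonality(classify_segment_events(ph))
        assert seg.loc[0, "clonality"] == "clonal"

    def test_length_conservation(self):
        ph = phased_fixture({"a": [(2, 1), (1, 1), (1, 0)],
                             "b": [(1, 1), (1, 1), (1, 0)]})
        row = stratify_scna_clonality(classify_segment_events(ph))
        seg = segment_clonality(classify_segment_events(ph))
        unaffected = 100.0 * seg.loc[seg["clonality"] == "unaffected",
                                     "length"].sum() / seg["length"].sum()
        total = row["pct_genome_clonal"] + row["pct_genome_subclonal"] + unaffected
        assert total == pytest.approx(100.0, abs=0.1)

    def test_sample_order_invariance(self):
        cn = {"a": [(2, 1), (1, 1)], "b": [(1, 1), (1, 0)],
              "c": [(2, 1), (1, 0)]}
        e1 = classify_segment_events(phased_fixture(cn))
        e2 = classify_segment_events(phased_fixture(dict(reversed(cn.items()))))
        pd.testing.assert_frame_equal(
            segment_clonality(e1), segment_clonality(e2))


class TestPublishedCohort:
    def test_cohort_medians_reproduce_printed_values(self):
        summary = summarize_cohort(load_published_cohort())
        assert summary["median_clonal_segments"] == 132
        assert summary["median_subclonal_segments"] == 57
        assert summary["median_union_pct"] == pytest.approx(34.0, abs=0.5)
        assert summary["mean_union_pct"] == pytest.approx(42.0, abs=1.0)


class TestCytobands:
    def test_full_coverage_flags_band(self):
        ph = phased_fixture({"a": [(2, 1)]}, seg_len=10)
        events = classify_segment_events(ph)
        bands = pd.DataFrame([("chr1", 0, 10, "1p1")],
                             columns=["chrom", "start", "end", "band"])
        out = aggregate_cytobands(events, bands)
        assert list(out["band"]) == ["1p1"]

    def test_ten_percent_coverage_not_flagged(self):
        ph = phased_fixture({"a": [(2, 1), (1, 1)]}, seg_len=10)
        events = classify_segment_events(ph)
        bands = pd.DataFrame([("chr1", 0, 100, "1p1")],
                             columns=["chrom", "start", "end", "band"])
        assert aggregate_cytobands(events, bands).empty

    def test_unknown_chromosome_is_a_validation_error(self):
        ph = phased_fixture({"a": [(2, 1)]})
        events = classify_segment_events(ph)
        bands = pd.DataFrame([("chr9", 0, 10, "9p1")],
                             columns=["chrom", "start", "end", "band"])
        with pytest.raises(ValidationError):
            aggregate_cytobands(events, bands)

    def test_clonal_band_across_all_samples(self):
        # a 17q-style gain present in every sample aggregates as clonal
        ph = phased_fixture({"a": [(2, 1)], "b": [(2, 1)], "c": [(2, 1)]})
        events = classify_segment_events(ph)
        bands = make_uniform_cytobands(bands_per_chrom=1)
        bands = bands[bands["chrom"] == "chr1"].copy()
        bands[["start", "end"]] = [[0, 10]]
        band_events = aggregate_cytobands(events, bands)
        clonality = cytoband_clonality(band_events, ph.samples)
        assert (clonality["clonality"] == "clonal").all()


class TestChromosomeClasses:
    def test_no_events_unchanged(self):
        ph = phased_fixture({"a": [(1, 1), (1, 1)]})
        _, fractions = classify_chromosomes(classify_segment_events(ph))
        assert fractions["fraction_unchanged"] == 1.0

    def test_full_chromosome_gain_is_whole(self):
        ph = phased_fixture({"a": [(2, 1), (2, 1)]})
        table, _ = classify_chromosomes(classify_segment_events(ph))
        assert table.set_index("chrom").loc["chr1", "class"] == "whole_chromosome"

    def test_partial_gain_is_segmental(self):
        ph = phased_fixture({"a": [(2, 1), (1, 1)]})
        table, _ = classify_chromosomes(classify_segment_events(ph))
        assert table.set_index("chrom").loc["chr1", "class"] == "segmental"

    def test_whole_chromosome_cohort_has_zero_segmental(self):
        from mrevo.synthetic import (SimulationConfig, simulate_clone_tree,
                                     simulate_cn_evolution)

        parent = simulate_clone_tree(4, 3)
        cfg = SimulationConfig(n_clones=4, cn_event_rate=2.0,
                               whole_chromosome_event_fraction=1.0,
                               msai_probability=0.0, seed=3)
        profiles, _, _, segments, events = simulate_cn_evolution(parent, cfg, 3)
        assert len(events) > 0
        cn = {f"s{k}": [tuple(profiles[k, i]) for i in range(len(segments))]
              for k in range(4)}
        ph = phased_fixture(cn, chrom_per_seg=list(segments["chrom"]))
        _, fractions = classify_chromosomes(classify_segment_events(ph))
        assert fractions["fraction_segmental"] == 0.0
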