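"""Coverage quantification, normalization, and readthrough calling."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtchimera.annotation_io import AnnotationSet, GeneModel
from rtchimera.detect import (
    CoverageTrack,
    call_readthrough,
    calls_to_dataframe,
    candidate_set,
    count_interval,
    downstream_fold_change,
    pool_tracks,
    rpkm,
    rpm,
)
from rtchimera.simulate import SimConfig, simulate_readthrough_dataset


def make_track(sample_id, plus, minus, lib):
    return CoverageTrack(sample_id, lib,
                         {c: np.asarray(v, float) for c, v in plus.items()},
                         {c: np.asarray(v, float) for c, v in minus.items()})


class TestCountInterval:
    def test_uniform_depth_sums_per_base(self):
        t = make_track("s", {"chr1": [2.0] * 100}, {"chr1": [0.0] * 100}, 1)
        assert count_interval(t, "chr1", 0, 50, "+") == 100.0

    def test_opposite_strand_is_zero(self):
        t = make_track("s", {"chr1": [2.0] * 100}, {"chr1": [0.0] * 100}, 1)
        assert count_interval(t, "chr1", 0, 50, "-") == 0.0

    def test_depth_vector_sum(self):
        t = make_track("s", {"chr1": [1.0, 2.0, 3.0]}, {"chr1": [0.0] * 3}, 1)
        assert count_interval(t, "chr1", 0, 3, "+") == 6.0  # brute-force 1+2+3

    def test_zero_length_interval(self):
        t = make_track("s", {"chr1": [1.0] * 10}, {"chr1": [0.0] * 10}, 1)
        assert count_interval(t, "chr1", 5, 5, "+") == 0.0

    def test_unknown_chromosome_errors(self):
        t = make_track("s", {"chr1": [1.0]}, {"chr1": [0.0]}, 1)
        with pytest.raises(KeyError):
            count_interval(t, "chrX", 0, 1, "+")


class TestNormalization:
    @pytest.mark.parametrize(
        "count,lib,expected",
        [(10, 1_000_000, 10.0), (0, 5, 0.0), (30, 2_000_000, 15.0)],
    )
    def test_rpm(self, count, lib, expected):
        assert rpm(count, lib) == expected

    def test_rpkm_worked_example(self):
        assert rpkm(200, 10_000_000, 2000) == 10.0

    def test_rpm_invalid_library(self):
        with pytest.raises(ValueError):
            rpm(1, 0)

    @given(
        count=st.floats(0, 1e6),
        lib=st.integers(1, 10**9),
        length=st.integers(1, 10**6),
    )
    @settings(max_examples=50, derandomize=True)
    def test_rpkm_is_rpm_scaled_by_length(self, count, lib, length):
        assert rpkm(count, lib, length) == pytest.approx(
            rpm(count, lib) * 1000 / length
        )


class TestFoldChange:
    def test_simple_ratio(self):
        assert downstream_fold_change(15.0, 10.0) == 1.5

    def test_silent_wildtype_gives_infinity(self):
        assert downstream_fold_change(5.0, 0.0) == math.inf

    def test_both_zero_is_undefined(self):
        assert math.isnan(downstream_fold_change(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            downstream_fold_change(-1.0, 1.0)

    @given(a=st.floats(0.001, 1e6), b=st.floats(0.001, 1e6))
    @settings(max_examples=50, derandomize=True)
    def test_swapping_samples_gives_reciprocal(self, a, b):
        assert downstream_fold_change(a, b) == pytest.approx(
            1.0 / downstream_fold_change(b, a)
        )


def two_gene_setup(window_depth_wt=2.0, window_depth_mut=10.0, body_depth=5.0):
    """One + strand gene of 1000 bp with a 500 bp downstream window."""
    ann = AnnotationSet([GeneModel("g1", "chr1", 0, 1000, "+")],
                        chrom_lengths={"chr1": 2000})
    wt_plus = np.zeros(2000)
    mut_plus = np.zeros(2000)
    wt_plus[0:1000] = body_depth
    mut_plus[0:1000] = body_depth
    wt_plus[1000:1500] = window_depth_wt
    mut_plus[1000:1500] = window_depth_mut
    lib = 1_000_000
    wt = make_track("wt", {"chr1": wt_plus}, {"chr1": np.zeros(2000)}, lib)
    mut = make_track("mut", {"chr1": mut_plus}, {"chr1": np.zeros(2000)}, lib)
    return ann, wt, mut


class TestCallReadthrough:
    def test_expressed_gene_with_fivefold_window_is_candidate(self):
        ann, wt, mut = two_gene_setup()
        (call,) = call_readthrough(ann, wt, mut)
        assert call.fold_change == pytest.approx(5.0)
        assert call.expressed_pass and call.min_reads_pass
        assert call.candidate

    def test_de_exclusion_blocks_candidate(self):
        ann, wt, mut = two_gene_setup()
        (call,) = call_readthrough(ann, wt, mut, de_exclusion={"g1"})
        assert call.de_excluded and not call.candidate

    def test_low_expression_blocks_candidate(self):
        ann, wt, mut = two_gene_setup(body_depth=0.0)
        (call,) = call_readthrough(ann, wt, mut)
        assert not call.expressed_pass and not call.candidate

    def test_min_mut_window_reads_guards_infinite_fc(self):
        ann, wt, mut = two_gene_setup(window_depth_wt=0.0, window_depth_mut=0.01)
        (call,) = call_readthrough(ann, wt, mut)
        assert call.fold_change == math.inf
        assert not call.min_reads_pass and not call.candidate

    def test_internal_de_fallback_excludes_shifted_body(self):
        ann = AnnotationSet([GeneModel("g1", "chr1", 0, 1000, "+")],
                            chrom_lengths={"chr1": 2000})
        wt_plus = np.zeros(2000)
        mut_plus = np.zeros(2000)
        wt_plus[0:1000] = 5.0
        mut_plus[0:1000] = 25.0  # body itself is 5x up: not a readthrough call
        wt_plus[1000:1500] = 2.0
        mut_plus[1000:1500] = 10.0
        wt = make_track("wt", {"chr1": wt_plus}, {"chr1": np.zeros(2000)}, 10**6)
        mut = make_track("mut", {"chr1": mut_plus}, {"chr1": np.zeros(2000)}, 10**6)
        (call,) = call_readthrough(ann, wt, mut, de_exclusion=None)
        assert call.de_excluded and not call.candidate

    def test_scale_invariance_of_rpm_rpkm_fc(self):
        ann, wt, mut = two_gene_setup()
        (base,) = call_readthrough(ann, wt, mut)
        wt2 = make_track("wt2", {"chr1": wt.plus["chr1"] * 2},
                         {"chr1": wt.minus["chr1"] * 2}, wt.library_size * 2)
        mut2 = make_track("mut2", {"chr1": mut.plus["chr1"] * 2},
                          {"chr1": mut.minus["chr1"] * 2}, mut.library_size * 2)
        (doubled,) = call_readthrough(ann, wt2, mut2)
        assert doubled.rpm_wt == pytest.approx(base.rpm_wt)
        assert doubled.gene_rpkm_mut == pytest.approx(base.gene_rpkm_mut)
        assert doubled.fold_change == pytest.approx(base.fold_change)

    def test_candidate_flag_rederivable_from_stored_fields(self):
        ds = simulate_readthrough_dataset(SimConfig(seed=5, n_gene_pairs=30))
        calls = call_readthrough(ds.annotation, ds.wt, ds.mut)
        for c in calls:
            fc_pass = (not math.isnan(c.fold_change)) and c.fold_change >= 2.0
            rederived = (fc_pass and c.expressed_pass and not c.de_excluded
                         and c.min_reads_pass)
            assert c.candidate == rederived

    def test_replicate_pooling_sums_counts_and_libraries(self):
        ann, wt, mut = two_gene_setup()
        pooled = pool_tracks([wt, wt])
        assert pooled.library_size == 2 * wt.library_size
        assert count_interval(pooled, "chr1", 0, 1000, "+") == pytest.approx(
            2 * count_interval(wt, "chr1", 0, 1000, "+")
        )
        # pooled replicates give the same calls as a single track (scale invariance)
        (single,) = call_readthrough(ann, wt, mut)
        (rep,) = call_readthrough(ann, [wt, wt], [mut, mut])
        assert rep.fold_change == pytest.approx(single.fold_change)
        assert rep.candidate == single.candidate


class TestPlantedRecovery:
    def test_noise_free_candidates_equal_planted_set(self):
        ds = simulate_readthrough_dataset(SimConfig(seed=1, noise="none"))
        calls = call_readthrough(ds.annotation, ds.wt, ds.mut)
        assert candidate_set(calls) == ds.planted_gene1_ids()

    def test_no_signal_when_ratio_is_one(self):
        ds = simulate_readthrough_dataset(
            SimConfig(seed=2, noise="none", readthrough_ratio=1.0)
        )
        calls = call_readthrough(ds.annotation, ds.wt, ds.mut)
        assert candidate_set(calls) == set()

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_poisson_noise_sensitivity_and_precision(self, seed):
        ds = simulate_readthrough_dataset(SimConfig(seed=seed, noise="poisson"))
        calls = call_readthrough(ds.annotation, ds.wt, ds.mut)
        called = candidate_set(calls)
        planted = ds.planted_gene1_ids()
        tp = len(called & planted)
        assert tp / len(planted) >= 0.9
        assert tp / max(1, len(called)) >= 0.9


class TestDataFrameOutput:
    def test_calls_table_has_one_row_per_gene(self, toy_annotation):
        n = 10_000
        zeros = {"chr1": np.zeros(n), "chr2": np.zeros(900)}
        ones = {"chr1": np.ones(n), "chr2": np.ones(900)}
        wt = make_track("wt", ones, zeros, 10**6)
        mut = make_track("mut", ones, zeros, 10**6)
        calls = call_readthrough(toy_annotation, wt, mut)
        df = calls_to_dataframe(calls)
        assert list(df["gene_id"]) == toy_annotation.gene_ids()
        assert set(df.columns) >= {"fold_change", "candidate", "rpm_wt", "rpm_mut"}
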