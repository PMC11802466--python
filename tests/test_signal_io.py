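import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histoswarm.signal_io import (DatasetSplit, GeneAnnotation,
                                  bin_index, bin_label, bin_signal,
                                  binarize_expression, split_genes)


def make_track(start, end, values_per_base):
    """One interval per base: the most general (and slowest) track form."""
    return np.array([[b, b + 1, v] for b, v in
                     zip(range(start, end), values_per_base)], dtype=float)


class TestBinSignal:
    def test_default_window_yields_200_bins(self):
        ann = GeneAnnotation("g1", "chr1", 100_000, "+")
        track = np.array([[0, 300_000, 1.0]])
        assert bin_signal(track, ann).shape == (200,)

    def test_constant_track_gives_constant_bins(self):
        ann = GeneAnnotation("g1", "chr1", 50_000, "+")
        bins = bin_signal(np.array([[0, 100_000, 2.0]]), ann)
        assert np.allclose(bins, 2.0)

    def test_per_bin_means_match_brute_force_base_loop(self):
        # track value = base offset index over a 10 kb window
        tss, flank, width = 20_000, 5_000, 50
        ann = GeneAnnotation("g1", "chr1", tss, "+")
        offsets = np.arange(2 * flank, dtype=float)
        track = make_track(tss - flank, tss + flank, offsets)
        bins = bin_signal(track, ann, flank, width)
        expected = np.array([
            np.mean([offsets[i] for i in range(b * width, (b + 1) * width)])
            for b in range(2 * flank // width)
        ])
        assert np.allclose(bins, expected)

    def test_binning_is_mean_preserving(self, rng):
        tss, flank, width = 30_000, 1_000, 50
        vals = rng.integers(0, 9, size=2 * flank).astype(float)
        track = make_track(tss - flank, tss + flank, vals)
        bins = bin_signal(track, GeneAnnotation("g", "c", tss, "+"), flank, width)
        assert bins.sum() * width == pytest.approx(vals.sum())

    def test_minus_strand_mirrors_plus_strand(self, rng):
        tss, flank = 10_000, 500
        vals = rng.gamma(2, 1, size=2 * flank)
        track_fwd = make_track(tss - flank, tss + flank, vals)
        track_rev = make_track(tss - flank, tss + flank, vals[::-1])
        plus = bin_signal(track_fwd, GeneAnnotation("g", "c", tss, "+"), flank, 50)
        minus = bin_signal(track_rev, GeneAnnotation("g", "c", tss, "-"), flank, 50)
        assert np.allclose(plus, minus)

    def test_window_past_chromosome_start_pads_zero_with_warning(self):
        ann = GeneAnnotation("g1", "chr1", 1_000, "+")
        with pytest.warns(UserWarning, match="past the chromosome start"):
            bins = bin_signal(np.array([[0, 20_000, 1.0]]), ann)
        # first 4000 bp of the window are off-chromosome -> 80 zero bins
        assert np.allclose(bins[:80], 0.0)
        assert np.allclose(bins[80:], 1.0)

    def test_negative_signal_rejected(self):
        ann = GeneAnnotation("g1", "chr1", 10_000, "+")
        with pytest.raises(ValueError, match="negative"):
            bin_signal(np.array([[0, 20_000, -1.0]]), ann)

    def test_flank_must_divide_into_bins(self):
        ann = GeneAnnotation("g1", "chr1", 10_000, "+")
        with pytest.raises(ValueError, match="divisible"):
            bin_signal(np.array([[0, 20_000, 1.0]]), ann, flank_bp=5_001)


class TestBinarizeExpression:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3, 4], [0, 0, 1, 1]),
        ([0, 0, 5, 9], [0, 0, 1, 1]),
    ])
    def test_median_split(self, values, expected):
        assert binarize_expression(values).tolist() == expected

    def test_median_ties_promoted_in_stable_order(self):
        labels = binarize_expression([3, 3, 3, 7])
        assert labels.sum() == 2
        assert labels.tolist() == [1, 0, 0, 1]

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            binarize_expression([5.0, 5.0, 5.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=60))
    def test_classes_balanced_within_one(self, values):
        if np.ptp(values) == 0:
            return
        labels = binarize_expression(values)
        assert abs(len(values) - 2 * labels.sum()) <= 1


class TestSplitGenes:
    def test_reference_cohort_sizes(self):
        ids = [f"g{i}" for i in range(18_421)]
        sp = split_genes(ids, n_train=6_600, seed=0)
        assert (len(sp.train_ids), len(sp.valid_ids), len(sp.test_ids)) == (6600, 5911, 5910)

    @pytest.mark.parametrize("n,n_train,sizes", [
        (10, 6, (6, 2, 2)),
        (11, 6, (6, 3, 2)),  # larger remainder half goes to validation
    ])
    def test_small_splits(self, n, n_train, sizes):
        sp = split_genes([f"g{i}" for i in range(n)], n_train=n_train, seed=1)
        assert (len(sp.train_ids), len(sp.valid_ids), len(sp.test_ids)) == sizes

    def test_partition_is_disjoint_and_complete(self):
        ids = [f"g{i}" for i in range(101)]
        sp = split_genes(ids, n_train=50, seed=3)
        union = set(sp.train_ids) | set(sp.valid_ids) | set(sp.test_ids)
        assert union == set(ids)

    def test_same_seed_is_bit_identical_different_seed_is_not(self):
        ids = [f"g{i}" for i in range(200)]
        a = split_genes(ids, n_train=100, seed=9)
        b = split_genes(ids, n_train=100, seed=9)
        c = split_genes(ids, n_train=100, seed=10)
        assert a.train_ids == b.train_ids and a.valid_ids == b.valid_ids
        assert a.train_ids != c.train_ids

    def test_odd_n_train_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            split_genes([f"g{i}" for i in range(10)], n_train=5, seed=0)

    def test_split_roundtrip_tsv(self, tmp_path):
        sp = split_genes([f"g{i}" for i in range(20)], n_train=10, seed=4)
        path = tmp_path / "split.tsv"
        sp.to_tsv(path)
        back = DatasetSplit.from_tsv(path)
        assert back.seed == 4
        assert set(back.train_ids) == set(sp.train_ids)
        assert set(back.test_ids) == set(sp.test_ids)


class TestBinLabels:
    def test_no_bin_zero_and_endpoints(self):
        assert bin_label(0) == -100
        assert bin_label(99) == -1
        assert bin_label(100) == 1
        assert bin_label(199) == 100
        assert all(bin_label(i) != 0 for i in range(200))

    def test_label_index_roundtrip(self):
        for i in range(200):
            assert bin_index(bin_label(i)) == i
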