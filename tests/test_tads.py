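"""Insulation, boundary calling, matching, bootstrap overlap, change modes."""

import numpy as np
import pytest

from tadmut.genome import BinnedGenome
from tadmut.hic import kr_balance, mask_low_coverage_bins
from tadmut.simulate import SimParams, simulate_contact_map, simulate_truth
from tadmut.tads import (
    BoundarySet,
    boundaries_to_tads,
    boundary_overlap_pvalue,
    call_boundaries,
    classify_tad_changes,
    insulation_track,
    match_boundaries,
    short_long_ratio,
    tad_signal_track,
)

from conftest import make_balanced_map


def two_block_matrix(n=5, split=3, within=10.0, across=1.0):
    m = np.full((n, n), across)
    m[:split, :split] = within
    m[split:, split:] = within
    return m


class TestInsulation:
    def test_window_one_reads_single_cell(self):
        m = two_block_matrix()
        track = insulation_track(make_balanced_map(m), window_bins=1)
        raw = track.raw["chrT"]
        # raw[i] = M[i-1, i+1]
        assert raw[1] == m[0, 2]
        assert raw[3] == m[2, 4]

    def test_two_block_matrix_derived_values(self):
        # blocks {0,1,2} and {3,4}: crossing cell at bin 1 is within-block
        # (10), at bin 3 across (1); the minimum sits between the blocks
        track = insulation_track(make_balanced_map(two_block_matrix()), window_bins=1)
        raw = track.raw["chrT"]
        assert raw[1] == 10.0 and raw[3] == 1.0
        assert np.nanargmin(raw) in (2, 3)

    def test_uniform_matrix_normalized_zero(self):
        track = insulation_track(make_balanced_map(np.ones((9, 9))), window_bins=2)
        norm = track.normalized["chrT"]
        defined = ~np.isnan(norm)
        assert defined.sum() == 9 - 4
        np.testing.assert_allclose(norm[defined], 0.0, atol=1e-12)

    def test_window_exceeding_flank_cap_rejected(self, balanced_small):
        with pytest.raises(ValueError, match="2000000"):
            insulation_track(balanced_small, window_bins=41)

    def test_window_larger_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="larger than chromosome"):
            insulation_track(make_balanced_map(np.ones((5, 5))), window_bins=3)


class TestTadSignal:
    def test_uniform_matrix_signal_zero(self):
        sig = tad_signal_track(make_balanced_map(np.ones((10, 10))), window_bp=100_000)
        inner = sig["chrT"][2:-2]
        np.testing.assert_allclose(inner, 0.0, atol=1e-9)

    def test_window_cap_rejected(self):
        with pytest.raises(ValueError):
            tad_signal_track(make_balanced_map(np.ones((10, 10))), window_bp=2_500_000)

    def test_doubled_window_sum_gives_log2_one(self):
        # bin 5's near-diagonal sum doubled relative to the others
        n = 11
        m = np.ones((n, n))
        m[5, :] *= 2.0
        m[:, 5] *= 2.0
        sig = tad_signal_track(make_balanced_map(m), window_bp=0)  # w=0: diagonal only
        # diagonal entry at 5 is 4, others 1; mean = (10*1+4)/11
        expected = np.log2(4.0 / ((10 + 4) / 11))
        assert sig["chrT"][5] == pytest.approx(expected)


class TestCallBoundaries:
    def test_two_block_planted_matrix_single_boundary(self):
        m = two_block_matrix(n=13, split=7, within=10.0, across=1.0)
        track = insulation_track(make_balanced_map(m), window_bins=2)
        bset = call_boundaries(track, delta_bins=2, strength_min=0.1)
        bins = bset.bins["chrT"]
        assert len(bins) == 1
        assert abs(int(bins[0]) - 7) <= 1

    def test_monotone_track_empty(self):
        # monotone decreasing insulation: no + to - crossing of the delta
        n = 15
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        m = 1.0 + (i + j) * 0.5
        m = (m + m.T) / 2
        track = insulation_track(make_balanced_map(m), window_bins=2)
        bset = call_boundaries(track, delta_bins=2, strength_min=0.0)
        assert len(bset.bins["chrT"]) == 0

    def test_weak_dip_below_strength_excluded(self):
        m = two_block_matrix(n=13, split=7, within=1.08, across=1.0)
        track = insulation_track(make_balanced_map(m), window_bins=2)
        strong = call_boundaries(track, delta_bins=2, strength_min=0.5)
        weak = call_boundaries(track, delta_bins=2, strength_min=0.0)
        assert len(strong.bins["chrT"]) == 0
        assert len(weak.bins["chrT"]) == 1

    def test_translation_equivariance(self):
        n, split = 21, 8
        base = two_block_matrix(n=n, split=split)
        shifted = two_block_matrix(n=n, split=split + 4)
        t1 = insulation_track(make_balanced_map(base), window_bins=2)
        t2 = insulation_track(make_balanced_map(shifted), window_bins=2)
        b1 = call_boundaries(t1, 2, 0.1).bins["chrT"]
        b2 = call_boundaries(t2, 2, 0.1).bins["chrT"]
        np.testing.assert_array_equal(b1 + 4, b2)

    def test_recovery_on_simulated_map(self, genome_recovery=None):
        genome = BinnedGenome(("chr1",), (30_000_000,), 50_000)
        f1s = []
        for seed in range(3):
            p = SimParams(seed=seed, tau=3.0, alpha=1.0, L=100.0, kappa=0.0)
            truth = simulate_truth(genome, p)
            cm = simulate_contact_map(genome, truth, p)
            bal, _ = kr_balance(mask_low_coverage_bins(cm))
            track = insulation_track(bal, 10)
            called = call_boundaries(track).bins["chr1"]
            tb = truth.boundaries["chr1"]
            tp = sum(np.abs(tb - b).min() <= 1 for b in called)
            prec = tp / len(called) if len(called) else 0.0
            rec = sum(np.abs(called - b).min() <= 1 for b in tb) / len(tb)
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert np.mean(f1s) >= 0.8


class TestBoundariesToTads:
    def test_midpoint_convention(self):
        g = BinnedGenome(("chr1",), (2_000_000,), 50_000)
        bset = BoundarySet(g, {"chr1": np.array([10, 20])})
        tads = boundaries_to_tads(bset)
        np.testing.assert_allclose(tads.intervals["chr1"], [[525_000.0, 1_025_000.0]])

    def test_single_boundary_warns_empty(self):
        g = BinnedGenome(("chr1",), (2_000_000,), 50_000)
        bset = BoundarySet(g, {"chr1": np.array([10])})
        with pytest.warns(UserWarning, match="fewer than 2"):
            tads = boundaries_to_tads(bset)
        assert tads.n_tads() == 0

    def test_three_boundaries_two_tiling_tads(self):
        g = BinnedGenome(("chr1",), (5_000_000,), 50_000)
        tads = boundaries_to_tads(BoundarySet(g, {"chr1": np.array([5, 40, 70])}))
        iv = tads.intervals["chr1"]
        assert iv.shape == (2, 2)
        assert iv[0, 1] == iv[1, 0]  # tiling, non-overlapping


class TestMatchBoundaries:
    def test_identical_sets_all_common(self):
        g = BinnedGenome(("chr1",), (10_000_000,), 50_000)
        a = BoundarySet(g, {"chr1": np.array([10, 30, 60])})
        b = BoundarySet(g, {"chr1": np.array([10, 30, 60])})
        common, stats = match_boundaries([a, b], tol_bins=2)
        assert stats["n_common"] == 3
        assert stats["median_spacing_bp"] == pytest.approx(25 * 50_000)

    @pytest.mark.parametrize("offset,expected", [(2, 3), (3, 0)])
    def test_tolerance_boundary(self, offset, expected):
        g = BinnedGenome(("chr1",), (10_000_000,), 50_000)
        a = BoundarySet(g, {"chr1": np.array([10, 50, 100])})
        b = BoundarySet(g, {"chr1": np.array([10 + offset, 50 + offset, 100 + offset])})
        _, stats = match_boundaries([a, b], tol_bins=2)
        assert stats["n_common"] == expected

    def test_mutual_symmetry_on_random_sets(self):
        g = BinnedGenome(("chr1",), (50_000_000,), 50_000)
        rng = np.random.default_rng(4)
        a = BoundarySet(g, {"chr1": np.sort(rng.choice(999, 40, replace=False)) + 1})
        b = BoundarySet(g, {"chr1": np.sort(rng.choice(999, 40, replace=False)) + 1})
        ab, _ = match_boundaries([a, b], tol_bins=2)
        ba, _ = match_boundaries([b, a], tol_bins=2)
        # every common a-boundary has a matching common b-boundary and back
        for x in ab.bins["chr1"]:
            assert np.abs(ba.bins["chr1"] - x).min() <= 2
        for x in ba.bins["chr1"]:
            assert np.abs(ab.bins["chr1"] - x).min() <= 2


class TestOverlapPvalue:
    def test_identical_dense_sets_minimal_p(self):
        g = BinnedGenome(("chr1",), (50_000_000,), 50_000)
        bins = np.arange(25, 1000, 50)
        a = BoundarySet(g, {"chr1": bins})
        b = BoundarySet(g, {"chr1": bins.copy()})
        observed, p = boundary_overlap_pvalue(a, b, tol_bins=0, n_boot=999, seed=0)
        assert observed == len(bins)
        assert p == pytest.approx(1 / 1000)

    def test_single_boundary_matches_enumeration(self):
        # 10-bin chromosome, tol 0: null hit probability is exactly 1/10
        g = BinnedGenome(("chr1",), (500_000,), 50_000)
        a = BoundarySet(g, {"chr1": np.array([4])})
        b = BoundarySet(g, {"chr1": np.array([4])})
        observed, p = boundary_overlap_pvalue(a, b, tol_bins=0, n_boot=10_000, seed=1)
        assert observed == 1
        exact = (1 + 10_000 * 0.1) / (10_000 + 1)
        assert p == pytest.approx(exact, abs=0.02)

    def test_p_bounds(self):
        g = BinnedGenome(("chr1",), (5_000_000,), 50_000)
        a = BoundarySet(g, {"chr1": np.array([10])})
        b = BoundarySet(g, {"chr1": np.array([90])})
        _, p = boundary_overlap_pvalue(a, b, tol_bins=0, n_boot=99, seed=2)
        assert 1 / 100 <= p <= 1.0

    def test_empty_set_rejected(self):
        g = BinnedGenome(("chr1",), (5_000_000,), 50_000)
        a = BoundarySet(g, {"chr1": np.array([10])})
        b = BoundarySet(g, {"chr1": np.array([], dtype=int)})
        with pytest.raises(ValueError, match="empty"):
            boundary_overlap_pvalue(a, b)


class TestChangeModes:
    def _sets(self, q, r, size=10_000_000):
        g = BinnedGenome(("chr1",), (size,), 50_000)
        return (
            BoundarySet(g, {"chr1": np.array(q)}),
            BoundarySet(g, {"chr1": np.array(r)}),
        )

    def test_identical_sets_all_conserved(self):
        q, r = self._sets([10, 20, 30], [10, 20, 30])
        records, fractions = classify_tad_changes(q, r, 2, 6)
        assert all(rec.mode == "conserved" for rec in records)
        assert all(v == 0.0 for v in fractions.values())

    def test_subdividing_boundary_is_gain(self):
        q, r = self._sets([10, 20, 30], [10, 30])
        records, _ = classify_tad_changes(q, r, tol_bins=2, shift_max_bins=6)
        by_bin = {rec.query_bin: rec for rec in records if rec.query_bin is not None}
        assert by_bin[20].mode == "gain"
        assert by_bin[20].is_de_novo_like

    def test_shifted_offset_two(self):
        q, r = self._sets([10, 22, 30], [10, 20, 30])
        records, _ = classify_tad_changes(q, r, tol_bins=1, shift_max_bins=4)
        by_bin = {rec.query_bin: rec for rec in records if rec.query_bin is not None}
        assert by_bin[22].mode == "shifted"
        assert by_bin[22].offset_bins == 2

    def test_loss_of_reference_boundary(self):
        q, r = self._sets([10, 30], [10, 20, 30])
        records, fractions = classify_tad_changes(q, r, 2, 6)
        losses = [rec for rec in records if rec.mode == "loss"]
        assert len(losses) == 1 and losses[0].ref_bin == 20
        assert fractions["loss"] == 1.0

    def test_mode_partition_and_fraction_sum(self):
        g = BinnedGenome(("chr1",), (60_000_000,), 50_000)
        rng = np.random.default_rng(9)
        q = BoundarySet(g, {"chr1": np.sort(rng.choice(1100, 60, replace=False)) + 1})
        r = BoundarySet(g, {"chr1": np.sort(rng.choice(1100, 60, replace=False)) + 1})
        records, fractions = classify_tad_changes(q, r, 2, 6)
        changed = [rec for rec in records if rec.mode != "conserved"]
        assert all(rec.mode in ("de_novo", "gain", "shifted", "loss") for rec in changed)
        if changed:
            assert sum(fractions.values()) == pytest.approx(1.0)


class TestShortLongRatio:
    def test_balanced_lengths(self):
        g = BinnedGenome(("chr1",), (10_000_000,), 50_000)
        tads = boundaries_to_tads(BoundarySet(g, {"chr1": np.array([0, 20, 80])}))
        # lengths 1 Mb and 3 Mb, cutoff 2 Mb
        assert short_long_ratio(tads, 2_000_000) == 1.0

    def test_all_short_flagged_infinite(self):
        g = BinnedGenome(("chr1",), (10_000_000,), 50_000)
        tads = boundaries_to_tads(BoundarySet(g, {"chr1": np.array([0, 10, 20])}))
        with pytest.warns(UserWarning, match="infinite"):
            assert short_long_ratio(tads) == np.inf

    def test_empty_rejected(self):
        g = BinnedGenome(("chr1",), (10_000_000,), 50_000)
        with pytest.warns(UserWarning):
            tads = boundaries_to_tads(BoundarySet(g, {"chr1": np.array([5])}))
        with pytest.raises(ValueError):
            short_long_ratio(tads)
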