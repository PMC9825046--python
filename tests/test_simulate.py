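"""Generator contracts: determinism, planted structure, and rate recovery."""

import numpy as np
import pandas as pd
import pytest

from tadmut.genome import BinnedGenome
from tadmut.simulate import (
    SimParams,
    simulate_cnv_segments,
    simulate_contact_map,
    simulate_expression,
    simulate_mutations,
    simulate_svs,
    simulate_truth,
    truth_from_json,
    truth_to_json,
)
from tadmut.cnvsv import extract_breakpoints, breakpoint_boundary_distances
from tadmut.tads import BoundarySet


@pytest.fixture(scope="module")
def genome():
    return BinnedGenome(("chr1", "chr2"), (10_000_000, 10_000_000), 50_000)


class TestTruth:
    def test_same_seed_identical(self, genome):
        p = SimParams(seed=3)
        a, b = simulate_truth(genome, p), simulate_truth(genome, p)
        for chrom in genome.chrom_names:
            np.testing.assert_array_equal(a.boundaries[chrom], b.boundaries[chrom])
            np.testing.assert_array_equal(
                a.compartment_labels[chrom], b.compartment_labels[chrom]
            )
        pd.testing.assert_frame_equal(a.genes, b.genes)
        assert a.hotspot_tads == b.hotspot_tads

    def test_boundary_bins_in_valid_range(self, genome):
        t = simulate_truth(genome, SimParams(seed=1))
        for chrom in genome.chrom_names:
            b = t.boundaries[chrom]
            assert b.min() >= 1 and b.max() <= genome.n_bins(chrom) - 1
            assert np.all(np.diff(b) > 0)

    def test_spacing_median_near_541kb(self):
        # pool spacings from a long chromosome: ~1000 draws
        g = BinnedGenome(("chrL",), (600_000_000,), 50_000)
        p = SimParams(seed=5)
        t = simulate_truth(g, p)
        spac = np.diff(t.boundaries["chrL"]) * g.bin_size
        assert len(spac) > 800
        assert abs(np.median(spac) - 541_000) / 541_000 < 0.05

    def test_chromosome_shorter_than_bin_rejected(self):
        with pytest.raises(ValueError, match="shorter than one bin"):
            BinnedGenome(("c",), (10_000,), 50_000)

    def test_compartment_labels_cover_all_bins(self, genome):
        t = simulate_truth(genome, SimParams(seed=2))
        for chrom in genome.chrom_names:
            lab = t.compartment_labels[chrom]
            assert len(lab) == genome.n_bins(chrom)
            assert set(np.unique(lab)) <= {-1, 1}

    def test_json_round_trip(self, genome, tmp_path):
        t = simulate_truth(genome, SimParams(seed=4))
        truth_to_json(t, tmp_path / "t.json")
        back = truth_from_json(tmp_path / "t.json")
        for chrom in genome.chrom_names:
            np.testing.assert_array_equal(back.boundaries[chrom], t.boundaries[chrom])
        assert back.hotspot_tads == t.hotspot_tads


class TestContactMap:
    def test_diagonal_expectation_tau1_kappa0(self, genome):
        p = SimParams(seed=1, tau=1.0, kappa=0.0, L=400.0)
        t = simulate_truth(genome, p)
        cm = simulate_contact_map(genome, t, p)
        diag = np.diag(cm.matrices["chr1"])
        # Poisson(L) mean within 3 standard errors
        assert abs(diag.mean() - 400.0) <= 3 * np.sqrt(400.0 / diag.size)

    def test_symmetry_and_nonnegative_integers(self, cmap_small):
        for chrom, m in cmap_small.matrices.items():
            np.testing.assert_array_equal(m, m.T)
            assert (m >= 0).all()
            np.testing.assert_array_equal(m, np.round(m))

    def test_within_tad_enrichment_ratio(self, genome):
        p = SimParams(seed=9, tau=3.0, kappa=0.0, L=200.0)
        t = simulate_truth(genome, p)
        cm = simulate_contact_map(genome, t, p)
        m = cm.matrices["chr1"]
        dom = t.domain_id("chr1")
        n = m.shape[0]
        d = 3
        i = np.arange(n - d)
        same = dom[i] == dom[i + d]
        within = m[i[same], i[same] + d].mean()
        across = m[i[~same], i[~same] + d].mean()
        assert within / across == pytest.approx(3.0, rel=0.15)

    def test_distance_decay_mean(self, genome):
        p = SimParams(seed=2, tau=1.0, kappa=0.0, L=100.0, alpha=1.0)
        t = simulate_truth(genome, p)
        cm = simulate_contact_map(genome, t, p)
        m = cm.matrices["chr1"]
        n = m.shape[0]
        for d in (0, 2, 10):
            band = m[np.arange(n - d), np.arange(d, n)]
            expected = 100.0 * (1 + d) ** -1.0
            se = np.sqrt(expected / band.size)
            assert abs(band.mean() - expected) <= 3 * se

    def test_determinism(self, genome):
        p = SimParams(seed=6)
        t = simulate_truth(genome, p)
        a = simulate_contact_map(genome, t, p)
        b = simulate_contact_map(genome, t, p)
        np.testing.assert_array_equal(a.matrices["chr1"], b.matrices["chr1"])


class TestMutations:
    def test_hotspots_exceed_comut_threshold(self, genome):
        p = SimParams(seed=3, m_hot=12)
        t = simulate_truth(genome, p)
        muts = simulate_mutations(t, p)
        ivals = t.tad_intervals()
        passing = muts[muts["filter"] == "PASS"]
        for chrom, ti in t.hotspot_tads:
            s, e = ivals[chrom][ti]
            genes = t.genes[t.genes["chrom"] == chrom]
            mid = (genes["start"] + genes["end"]) // 2
            inside = set(genes["name"][(mid >= s) & (mid < e)])
            mutated_inside = set(passing["gene"]) & inside
            assert len(mutated_inside) >= 12

    def test_no_hotspots_no_background_empty(self, genome):
        p = SimParams(seed=3, p_bg=0.0, n_hotspots=0, decoy_frac=0.0)
        t = simulate_truth(genome, p)
        muts = simulate_mutations(t, p)
        assert muts.empty

    def test_background_rate_binomial(self):
        g = BinnedGenome(("chr1",), (50_000_000,), 50_000)
        p = SimParams(seed=8, p_bg=0.05, n_hotspots=0, decoy_frac=0.0)
        t = simulate_truth(g, p)
        muts = simulate_mutations(t, p)
        n = len(t.genes)
        k = muts["gene"].nunique()
        mean, sd = n * 0.05, np.sqrt(n * 0.05 * 0.95)
        assert abs(k - mean) <= 4 * sd

    def test_determinism(self, genome):
        p = SimParams(seed=12)
        t = simulate_truth(genome, p)
        a = simulate_mutations(t, p)
        t2 = simulate_truth(genome, p)
        b = simulate_mutations(t2, p)
        pd.testing.assert_frame_equal(a, b)


class TestCNV:
    def test_statuses_from_allowed_set(self, genome):
        p = SimParams(seed=4)
        t = simulate_truth(genome, p)
        segs = simulate_cnv_segments(t, p)
        assert set(segs["cn"]) <= {0, 1, 2, 3, 4, 5}
        assert set(segs.loc[segs["cn"] != 2, "cn"]) <= {0, 1, 3, 4, 5}

    def test_pure_near_mode_exponential_mean(self, genome):
        p = SimParams(seed=5, pi_near=1.0, lambda_near=40_000.0, n_cnv_events=400)
        t = simulate_truth(genome, p)
        simulate_cnv_segments(t, p)
        bp = t.cnv_breakpoints
        bset = BoundarySet(genome, {c: b.copy() for c, b in t.boundaries.items()})
        d = breakpoint_boundary_distances(bp, bset)
        # clipping at chromosome edges and nearest-boundary reassignment only
        # shrink distances; mean stays near lambda
        assert d.mean() == pytest.approx(40_000.0, rel=0.15)

    def test_pi_near_monotone_mean_distance(self, genome):
        means = []
        for pi in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(4):
                p = SimParams(seed=seed, pi_near=pi, lambda_near=40_000.0, n_cnv_events=150)
                t = simulate_truth(genome, p)
                simulate_cnv_segments(t, p)
                bset = BoundarySet(genome, {c: b.copy() for c, b in t.boundaries.items()})
                vals.append(breakpoint_boundary_distances(t.cnv_breakpoints, bset).mean())
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_planted_breakpoints_recovered_exactly(self, genome):
        p = SimParams(seed=6)
        t = simulate_truth(genome, p)
        segs = simulate_cnv_segments(t, p)
        bps = extract_breakpoints(segs)
        planted = t.cnv_breakpoints.sort_values(["chrom", "pos"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            bps[["chrom", "pos"]], planted[["chrom", "pos"]], check_dtype=False
        )


class TestSV:
    def test_single_class_probabilities(self, genome):
        probs = {c: 0.0 for c in SimParams().sv_class_probs}
        probs["deletion"] = 1.0
        p = SimParams(seed=2, sv_class_probs=probs, n_svs=30)
        t = simulate_truth(genome, p)
        svs = simulate_svs(t, p)
        assert (svs["sv_class"] == "deletion").all()

    def test_within_placement_inside_one_tad(self, genome):
        p = SimParams(seed=3, n_svs=120)
        t = simulate_truth(genome, p)
        svs = simulate_svs(t, p)
        ivals = t.tad_intervals()
        within = svs[svs["placement_truth"] == "within"]
        assert len(within) > 10
        for _, r in within.iterrows():
            s, e = r["start1"], r["start2"]
            tad = ivals[r["chrom1"]]
            assert np.any((tad[:, 0] <= s) & (e <= tad[:, 1]))

    def test_short_fraction_matches_lognormal(self, genome):
        p = SimParams(seed=4, n_svs=300)
        t = simulate_truth(genome, p)
        svs = simulate_svs(t, p)
        intra = svs[svs["chrom1"] == svs["chrom2"]]
        lengths = (intra["start2"] - intra["start1"]).abs()
        frac_short = (lengths < 2_000_000).mean()
        # placement resampling truncates the extreme tail upward, so the
        # short fraction can only exceed the unconstrained log-normal value
        from scipy import stats

        p_expected = stats.norm.cdf(
            (np.log(2_000_000) - p.sv_len_mu) / p.sv_len_sigma
        )
        assert frac_short >= p_expected - 0.05

    def test_determinism(self, genome):
        p = SimParams(seed=5)
        t = simulate_truth(genome, p)
        a, b = simulate_svs(t, p), simulate_svs(t, p)
        pd.testing.assert_frame_equal(a, b)


class TestExpression:
    def test_switch_region_shift_recovered(self, genome):
        p = SimParams(seed=6, mu_de=1.0, sigma_expr=0.1)
        t = simulate_truth(genome, p)
        expr = simulate_expression(t, t.switch_regions, p)
        ab = expr[expr["switch"] == "A->B"]
        if len(ab) >= 5:
            assert ab["log2fc"].mean() == pytest.approx(-1.0, abs=0.2)
        ba = expr[expr["switch"] == "B->A"]
        if len(ba) >= 5:
            assert ba["log2fc"].mean() == pytest.approx(1.0, abs=0.2)

    def test_mu_zero_centers_switch_genes(self, genome):
        p = SimParams(seed=7, mu_de=0.0, sigma_expr=0.3)
        t = simulate_truth(genome, p)
        expr = simulate_expression(t, t.switch_regions, p)
        sw = expr[expr["switch"] != "none"]
        if len(sw) >= 10:
            assert abs(sw["log2fc"].mean()) < 0.3

    def test_non_switch_gene_status_consistent_with_cutoff(self, genome):
        p = SimParams(seed=8)
        t = simulate_truth(genome, p)
        expr = simulate_expression(t, t.switch_regions, p)
        ns = expr[expr["status"] == "ns"]
        assert (ns["log2fc"].abs() < p.lfc_cutoff).all()
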