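"""Global-alpha estimation, windowed ancestry calls, MAA, region calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from merinoscan.genotype_io import AlleleFrequencyPanel
from merinoscan.local_ancestry import (MAATrack, compute_maa, estimate_alpha,
                                       maa_signal_regions,
                                       nearest_rank_quantile, window_ancestry)
from merinoscan.synthetic_data import (AncestralPanelSpec,
                                       simulate_admixed_cohort,
                                       simulate_ancestral_panels)

from conftest import make_dataset, make_map


def fixed_difference_panel(L=40):
    snp_map = make_map(np.arange(1, L + 1) * 50_000)
    return snp_map, AlleleFrequencyPanel(snp_map, np.ones(L), np.zeros(L))


class TestEstimateAlpha:
    def test_fully_informative_panel(self):
        snp_map, panel = fixed_difference_panel()
        ds = make_dataset(np.full((1, 40), 2.0), snp_map=snp_map)
        alphas, mean = estimate_alpha(ds, panel)
        assert mean == pytest.approx(1.0, abs=1e-4)

    def test_panel_swap_symmetry(self, rng):
        L = 200
        snp_map = make_map(np.arange(1, L + 1) * 50_000)
        fa, fb = rng.uniform(0.1, 0.9, L), rng.uniform(0.1, 0.9, L)
        panel = AlleleFrequencyPanel(snp_map, fa, fb)
        d = rng.integers(0, 3, size=(4, L)).astype(float)
        ds = make_dataset(d, snp_map=snp_map)
        a1, _ = estimate_alpha(ds, panel)
        a2, _ = estimate_alpha(ds, panel.swapped())
        np.testing.assert_allclose(a1, 1.0 - a2, atol=1e-4)

    def test_recovery_on_simulated_cohort(self):
        spec = AncestralPanelSpec(n_snps_per_chrom=2500, n_chromosomes=2,
                                  spacing_bp=50_000, fst=0.1)
        panel, _ = simulate_ancestral_panels(spec, 21)
        ds, truth = simulate_admixed_cohort(panel, n=40, alpha=0.8, seed=22)
        _, mean = estimate_alpha(ds, panel)
        assert abs(mean - truth.alpha_true.mean()) < 0.02

    def test_snp_mismatch_rejected(self):
        snp_map, panel = fixed_difference_panel(10)
        ds = make_dataset(np.zeros((1, 9)))
        with pytest.raises(ValueError):
            estimate_alpha(ds, panel)


class TestWindowAncestry:
    def test_pure_merino_called_everywhere(self):
        snp_map, panel = fixed_difference_panel(100)
        ds = make_dataset(np.full((3, 100), 2.0), snp_map=snp_map)
        dos = window_ancestry(ds, panel, alpha=0.5, window_snps=10)
        assert (dos == 2.0).all()

    def test_uninformative_panel_returns_prior_mode(self):
        L = 100
        snp_map = make_map(np.arange(1, L + 1) * 50_000)
        panel = AlleleFrequencyPanel(snp_map, np.full(L, 0.4), np.full(L, 0.4))
        ds = make_dataset(np.ones((2, L)), snp_map=snp_map)
        # alpha=0.9: prior mode of Binom(2, 0.9) is 2 Merino copies
        dos = window_ancestry(ds, panel, alpha=0.9, window_snps=10)
        assert (dos == 2.0).all()
        # alpha=0.1: prior mode is 0
        dos = window_ancestry(ds, panel, alpha=0.1, window_snps=10)
        assert (dos == 0.0).all()

    def test_recovery_accuracy_on_simulation(self):
        spec = AncestralPanelSpec(n_snps_per_chrom=2500, n_chromosomes=2,
                                  spacing_bp=50_000, fst=0.2)
        panel, _ = simulate_ancestral_panels(spec, 31)
        ds, truth = simulate_admixed_cohort(panel, n=30, alpha=0.5, g=7,
                                            seed=32)
        dos = window_ancestry(ds, panel, alpha=0.5)
        accuracy = (dos == truth.merino_dosage).mean()
        assert accuracy >= 0.90

    def test_oversized_window_truncated_not_fatal(self):
        snp_map, panel = fixed_difference_panel(8)
        ds = make_dataset(np.full((1, 8), 2.0), snp_map=snp_map)
        dos = window_ancestry(ds, panel, alpha=0.5, window_snps=50)
        assert (dos == 2.0).all()


class TestComputeMaa:
    def test_all_merino_and_permutation_invariance(self, rng):
        snp_map = make_map(np.arange(1, 21) * 1000)
        track = compute_maa(np.full((5, 20), 2.0), snp_map)
        assert (track.maa == 1.0).all()
        d = rng.integers(0, 3, size=(10, 20)).astype(float)
        t1 = compute_maa(d, snp_map)
        t2 = compute_maa(d[rng.permutation(10)], snp_map)
        np.testing.assert_allclose(t1.maa, t2.maa)
        assert t1.genomewide_mean == pytest.approx(t1.maa.mean())

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            compute_maa(np.empty((0, 5)), make_map(np.arange(1, 6) * 1000))

    def test_genomewide_mean_recovers_alpha(self):
        spec = AncestralPanelSpec(n_snps_per_chrom=2500, n_chromosomes=2,
                                  spacing_bp=50_000, fst=0.2)
        panel, snp_map = simulate_ancestral_panels(spec, 41)
        ds, truth = simulate_admixed_cohort(panel, n=50, alpha=0.8, seed=42)
        alphas, alpha_mean = estimate_alpha(ds, panel)
        dos = window_ancestry(ds, panel, alpha_mean)
        track = compute_maa(dos, snp_map)
        assert abs(track.genomewide_mean - 0.8) < 0.03
        # genome-wide MAA tracks the mean of per-sample alpha estimates
        assert abs(track.genomewide_mean - alphas.mean()) < 0.01


def brute_force_regions(snp_map, maa, top_frac, merge_gap_bp):
    """Independent application of the dual criterion + merge, SNP by SNP."""
    mean = maa.mean()
    k = max(1, int(np.ceil((1 - top_frac) * len(maa))))
    thr = np.sort(maa)[k - 1]
    sig = [i for i in range(len(maa)) if maa[i] > mean and maa[i] >= thr]
    groups = []
    for i in sig:
        if (groups and snp_map.chromosome[i] == snp_map.chromosome[groups[-1][-1]]
                and snp_map.position_bp[i] - snp_map.position_bp[groups[-1][-1]]
                <= merge_gap_bp):
            groups[-1].append(i)
        else:
            groups.append([i])
    return [(int(snp_map.chromosome[g[0]]), int(snp_map.position_bp[g[0]]),
             int(snp_map.position_bp[g[-1]]), float(max(maa[j] for j in g)),
             len(g)) for g in groups]


class TestMaaSignalRegions:
    def test_constant_track_yields_nothing(self):
        snp_map = make_map(np.arange(1, 101) * 1000)
        track = MAATrack(snp_map, np.full(100, 0.7), 0.7)
        assert maa_signal_regions(track) == []

    def test_contiguous_peak_becomes_single_region(self):
        snp_map = make_map(np.arange(1, 1001) * 50_000)
        maa = np.full(1000, 0.50)
        maa[400:410] = 0.95
        track = MAATrack(snp_map, maa, float(maa.mean()))
        regions = maa_signal_regions(track, top_frac=0.05)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (401 * 50_000, 410 * 50_000)
        assert r.score == pytest.approx(0.95) and r.n_snps == 10

    def test_reported_interval_matches_boundary_snp_ids(self):
        # a maximal run of top-ranked SNPs reports its first/last SNP and MAA,
        # mirroring the published per-breed table layout
        positions = np.concatenate([np.arange(1, 91) * 200_000,
                                    [48_474_658, 50_000_000, 71_582_708]])
        order = np.argsort(positions)
        ids = np.array([f"bg{i}" for i in range(90)]
                       + ["rs426738329", "mid", "rs414015395"], dtype=object)
        from merinoscan.genotype_io import SnpMap
        snp_map = SnpMap(ids[order], np.ones(93, dtype=int), positions[order])
        maa = np.where(np.isin(snp_map.snp_id, ["rs426738329", "mid",
                                                "rs414015395"]), 0.88, 0.5)
        track = MAATrack(snp_map, maa, float(maa.mean()))
        regions = maa_signal_regions(track, top_frac=0.05,
                                     merge_gap_bp=30_000_000)
        assert len(regions) == 1
        r = regions[0]
        assert r.start_snp_id == "rs426738329" and r.start_bp == 48_474_658
        assert r.end_snp_id == "rs414015395" and r.end_bp == 71_582_708
        assert r.score == pytest.approx(0.88)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.02, 0.3))
    def test_matches_brute_force_oracle(self, seed, top_frac):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(20, 200))
        pos = np.cumsum(rng.integers(10_000, 2_000_000, L))
        chrom = np.sort(rng.integers(1, 4, L))
        snp_map = make_map(pos, chrom)
        maa = np.round(rng.random(L), 3)
        track = MAATrack(snp_map, maa, float(maa.mean()))
        gap = int(rng.integers(50_000, 5_000_000))
        got = [(r.chromosome, r.start_bp, r.end_bp, r.score, r.n_snps)
               for r in maa_signal_regions(track, top_frac, gap)]
        assert got == brute_force_regions(snp_map, maa, top_frac, gap)

    def test_every_boundary_snp_is_significant(self, rng):
        L = 500
        snp_map = make_map(np.arange(1, L + 1) * 100_000)
        maa = rng.beta(8, 2, L)
        track = MAATrack(snp_map, maa, float(maa.mean()))
        regions = maa_signal_regions(track, 0.05, 1_000_000)
        thr = nearest_rank_quantile(maa, 0.95)
        covered = np.zeros(L, bool)
        for r in regions:
            for snp in (r.start_snp_id, r.end_snp_id):
                i = int(np.flatnonzero(snp_map.snp_id == snp)[0])
                assert maa[i] > track.genomewide_mean and maa[i] >= thr
            covered |= ((snp_map.position_bp >= r.start_bp)
                        & (snp_map.position_bp <= r.end_bp))
        sig = (maa > track.genomewide_mean) & (maa >= thr)
        assert not np.any(sig & ~covered)

    def test_bad_top_frac_rejected(self):
        track = MAATrack(make_map([1000]), np.array([0.5]), 0.5)
        with pytest.raises(ValueError):
            maa_signal_regions(track, top_frac=1.5)
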