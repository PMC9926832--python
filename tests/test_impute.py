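"""Copying-model HMM: grid binning, forward-backward against exhaustive
path enumeration, EM monotonicity and parameter recovery, INFO scores and
window stitching."""

import numpy as np
import pytest
from oracles import diploid_path_enumeration

from ulcgwas.impute import (
    AncestralHaps,
    GenotypePosterior,
    HmmParams,
    Sites,
    SiteInfo,
    WindowResult,
    build_grid,
    em_fit,
    genotype_posteriors,
    info_score,
    plan_windows,
    stitch_windows,
)
from ulcgwas.synthetic_cohort import ReadPileup


def _pileup(rows, n_samples, n_sites):
    """rows: (sample, site, base, error)"""
    if rows:
        s, m, b, e = map(np.array, zip(*rows))
    else:
        s = m = b = e = np.array([])
    return ReadPileup(
        s.astype(np.int32), m.astype(np.int32),
        b.astype(np.uint8), e.astype(float), n_samples, n_sites,
    )


def _sites(positions, ref=0, alt=1):
    n = len(positions)
    return Sites("1", np.asarray(positions, dtype=np.int64),
                 np.full(n, ref, dtype=np.uint8), np.full(n, alt, dtype=np.uint8))


class TestBuildGrid:
    def test_boundary(self):
        params = HmmParams(grid_size=10_000)
        g = build_grid(np.array([1, 10_001]), params)
        assert list(g) == [0, 1]

    def test_single_grid_when_span_small(self):
        params = HmmParams(grid_size=10**9)
        g = build_grid(np.array([5, 500, 50_000]), params)
        assert len(np.unique(g)) == 1

    def test_monotone_assignment(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 10**6), 500, replace=False))
        g = build_grid(pos, HmmParams(grid_size=7000))
        assert np.all(np.diff(g) >= 0)
        assert len(g) == 500

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            build_grid(np.array([10, 5]), HmmParams())


def _enumeration_setup(theta, pi, params, rows, positions):
    """Shared bridge between module objects and the enumeration oracle."""
    sites = _sites(positions)
    grid = build_grid(sites.positions, params)
    used = np.unique(grid)
    site_grid = np.searchsorted(used, grid)
    centers = 1 + (used + 0.5) * params.grid_size
    rho = 1 - np.exp(-params.n_gen * params.recomb_rate_bp * np.diff(centers))
    reads_by_grid = [[] for _ in used]
    for s, m, b, e in rows:
        la = 1 - e if b == 1 else e / 3
        lr = 1 - e if b == 0 else e / 3
        reads_by_grid[site_grid[m]].append((m, la, lr))
    return sites, site_grid, rho, reads_by_grid


class TestForwardBackwardOracle:
    def test_one_sample_two_sites_matches_enumeration(self):
        params = HmmParams(K=2, grid_size=10_000, n_gen=2000, recomb_rate_bp=1e-8)
        theta = np.array([[0.9, 0.2], [0.1, 0.8]])
        pi = np.array([0.6, 0.4])
        rows = [(0, 0, 1, 0.01), (0, 1, 0, 0.02), (0, 1, 1, 0.01)]
        positions = [100, 25_000]
        sites, site_grid, rho, rbg = _enumeration_setup(theta, pi, params, rows, positions)
        post_o, _, gp_o = diploid_path_enumeration(theta, pi, rho, rbg, site_grid)

        pile = _pileup(rows, 1, 2)
        haps = AncestralHaps(theta, pi)
        from ulcgwas.impute import _HmmData

        data = _HmmData(pile, sites, params)
        P, _ = data.forward_backward(haps)
        assert np.allclose(P[:, 0], post_o, atol=1e-9)
        post, _ = genotype_posteriors(pile, sites, haps, data.trans, params)
        assert np.allclose(post.gp[0], gp_o, atol=1e-9)

    def test_three_samples_four_sites_posteriors_match_enumeration(self):
        rng = np.random.default_rng(5)
        params = HmmParams(K=2, grid_size=5_000, n_gen=500, recomb_rate_bp=1e-7)
        theta = rng.uniform(0.05, 0.95, (2, 4))
        pi = np.array([0.5, 0.5])
        positions = [10, 6_000, 13_000, 18_500]
        pile_rows = []
        for s in range(3):
            for _ in range(rng.integers(1, 5)):
                m = int(rng.integers(0, 4))
                pile_rows.append((s, m, int(rng.integers(0, 2)), float(rng.uniform(0.005, 0.05))))
        pile = _pileup(pile_rows, 3, 4)
        sites = _sites(positions)
        haps = AncestralHaps(theta, pi)
        from ulcgwas.impute import _HmmData

        data = _HmmData(pile, sites, params)
        post, _ = genotype_posteriors(pile, sites, haps, data.trans, params)
        for s in range(3):
            rows_s = [r for r in pile_rows if r[0] == s]
            _, site_grid, rho, rbg = _enumeration_setup(theta, pi, params, rows_s, positions)
            _, _, gp_o = diploid_path_enumeration(theta, pi, rho, rbg, site_grid)
            assert np.allclose(post.gp[s], gp_o, atol=1e-9)


class TestGenotypePosteriors:
    def test_no_reads_k1_gives_hardy_weinberg_prior(self):
        theta = np.array([[0.3, 0.7]])
        haps = AncestralHaps(theta, np.array([1.0]))
        params = HmmParams(K=1)
        pile = _pileup([(0, 0, 1, 0.01)], 2, 2)  # sample 1 has no reads
        sites = _sites([100, 200])
        from ulcgwas.impute import _HmmData

        data = _HmmData(pile, sites, params)
        post, _ = genotype_posteriors(pile, sites, haps, data.trans, params)
        for m, th in enumerate([0.3, 0.7]):
            expect = [(1 - th) ** 2, 2 * th * (1 - th), th**2]
            assert np.allclose(post.gp[1, m], expect, atol=1e-12)

    def test_overwhelming_alt_evidence(self):
        rows = [(0, 0, 1, 1e-4)] * 30
        pile = _pileup(rows, 1, 1)
        sites = _sites([100])
        haps = AncestralHaps(np.array([[0.5]]), np.array([1.0]))
        params = HmmParams(K=1)
        from ulcgwas.impute import _HmmData

        data = _HmmData(pile, sites, params)
        post, _ = genotype_posteriors(pile, sites, haps, data.trans, params)
        assert post.gp[0, 0, 2] > 0.999

    def test_posterior_normalization(self, small_panel, small_cohort, small_pileup, fast_params):
        sites = Sites(
            small_panel.chrom, small_panel.positions, small_panel.ref, small_panel.alt
        )
        haps, trans, _ = em_fit(small_pileup, sites, fast_params)
        post, si = genotype_posteriors(small_pileup, sites, haps, trans, fast_params)
        assert np.allclose(post.gp.sum(axis=2), 1.0, atol=1e-9)
        dosage = post.dosage
        assert dosage.min() >= 0 and dosage.max() <= 2


class TestEmFit:
    def test_loglik_nondecreasing(self, small_panel, small_pileup):
        sites = Sites(
            small_panel.chrom, small_panel.positions, small_panel.ref, small_panel.alt
        )
        params = HmmParams(K=4, n_em_iters=12, recomb_rate_bp=1e-9, seed=1)
        _, _, trace = em_fit(small_pileup, sites, params)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) >= -1e-6 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_determinism(self, small_panel, small_pileup, fast_params):
        sites = Sites(
            small_panel.chrom, small_panel.positions, small_panel.ref, small_panel.alt
        )
        h1, _, t1 = em_fit(small_pileup, sites, fast_params)
        h2, _, t2 = em_fit(small_pileup, sites, fast_params)
        assert np.array_equal(t1, t2)
        assert np.allclose(h1.theta, h2.theta)

    def test_recovers_two_well_separated_haplotypes(self):
        """1x coverage, 500 samples, two complementary haplotypes."""
        from ulcgwas.synthetic_cohort import (
            default_error_profile, generate_panel, sample_cohort, simulate_pileups,
        )

        panel = generate_panel(100, 40, 200_000, 0.0, seed=8, n_founders=2)
        truth = np.unique(panel.alleles, axis=0).astype(float)
        assert len(truth) == 2
        cohort = sample_cohort(panel, 500, seed=9)
        profile = {k: 0.002 for k in default_error_profile()}
        pile = simulate_pileups(cohort, panel, 1.0, profile, seed=10)
        sites = Sites("1", panel.positions, panel.ref, panel.alt)
        params = HmmParams(K=2, n_em_iters=25, recomb_rate_bp=1e-10, seed=2)
        haps, _, _ = em_fit(pile, sites, params)
        direct = max(
            np.abs(haps.theta - truth).max(axis=1).min(),
            np.abs(haps.theta[::-1] - truth).max(axis=1).min(),
        )
        swap = min(
            np.abs(haps.theta - truth).max(),
            np.abs(haps.theta[::-1] - truth).max(),
        )
        assert min(direct, swap) < 0.1

    def test_no_reads_returns_prior_model_with_warning(self):
        pile = _pileup([], 3, 5)
        sites = _sites([10, 20, 30, 40, 50])
        with pytest.warns(UserWarning):
            haps, trans, trace = em_fit(
                pile, sites, HmmParams(K=2), af_init=np.full(5, 0.3)
            )
        assert haps.theta.shape == (2, 5)
        assert len(trace) == 0


class TestInfoScore:
    def test_point_masses_give_one(self):
        gp = np.zeros((10, 3))
        gp[:5, 0] = 1.0
        gp[5:, 2] = 1.0
        est, info = info_score(gp)
        assert info == 1.0 and est == pytest.approx(0.5)

    def test_hardy_weinberg_prior_gives_zero(self):
        th = 0.3
        gp = np.tile([(1 - th) ** 2, 2 * th * (1 - th), th**2], (50, 1))
        est, info = info_score(gp)
        assert est == pytest.approx(th)
        assert info == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_defined_as_one(self):
        gp = np.tile([1.0, 0.0, 0.0], (5, 1))
        est, info = info_score(gp)
        assert est == 0.0 and info == 1.0

    def test_matches_hand_evaluated_formula(self):
        gp = np.array(
            [
                [0.7, 0.2, 0.1],
                [0.1, 0.8, 0.1],
                [0.05, 0.15, 0.8],
                [1.0, 0.0, 0.0],
                [0.25, 0.5, 0.25],
            ]
        )
        e = gp[:, 1] + 2 * gp[:, 2]
        f = gp[:, 1] + 4 * gp[:, 2]
        th = e.sum() / 10
        expect = 1 - (f - e**2).sum() / (10 * th * (1 - th))
        est, info = info_score(gp)
        assert info == pytest.approx(expect, abs=1e-12)


class TestWindows:
    def _wr(self, start, end, site_idx, value, n_samples=2):
        m = len(site_idx)
        gp = np.zeros((n_samples, m, 3))
        gp[:, :, 0] = 1 - value
        gp[:, :, 1] = value
        return WindowResult(start, end, np.asarray(site_idx),
                            gp, np.full(m, value), np.full(m, value))

    def test_single_window_identity(self):
        positions = np.array([100, 200, 300])
        w = self._wr(1, 1000, [0, 1, 2], 0.25)
        post, si = stitch_windows([w], positions)
        assert np.allclose(post.gp, w.gp)

    def test_equidistant_site_taken_from_left(self):
        positions = np.array([1500])
        left = self._wr(0, 2000, [0], 0.1)     # center 1000
        right = self._wr(1000, 3000, [0], 0.9)  # center 2000; tie at 1500
        post, _ = stitch_windows([left, right], positions)
        assert post.gp[0, 0, 1] == pytest.approx(0.1)

    def test_three_windows_cover_union_once(self):
        rng = np.random.default_rng(4)
        positions = np.sort(rng.choice(np.arange(1, 12_000_000), 300, replace=False))
        wins = []
        spans = [(1, 5_000_000), (4_500_000, 9_500_000), (9_000_000, 12_000_001)]
        for start, end in spans:
            idx = np.flatnonzero((positions >= start) & (positions < end))
            wins.append(self._wr(start, end, idx, rng.uniform(0.1, 0.9)))
        post, si = stitch_windows(wins, positions)
        assert post.gp.shape[1] == 300
        assert np.all(np.isfinite(si.est_af))

    def test_gap_between_windows_raises(self):
        positions = np.array([100, 5000])
        a = self._wr(1, 1000, [0], 0.2)
        b = self._wr(4000, 6000, [1], 0.3)
        with pytest.raises(ValueError):
            stitch_windows([a, b], positions)

    def test_plan_windows_tiles_with_overlap(self):
        params = HmmParams(window_size=5_000_000, window_overlap=500_000)
        plan = plan_windows(1, 12_000_000, params)
        assert plan[0][0] == 1
        assert all(b - a == 5_000_000 for a, b in plan)
        assert all(
            n_start < p_end for (_, p_end), (n_start, _) in zip(plan, plan[1:])
        )
        assert plan[-1][1] >= 12_000_000
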