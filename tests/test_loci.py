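"""LD clumping into independent/lead/candidate SNPs and merged risk loci,
checked against brute-force oracles on toy LD structures."""

import numpy as np
import pytest
from oracles import greedy_clump_oracle

from ulcgwas.loci import (
    candidate_snps,
    define_loci,
    find_independent,
    find_leads,
    ld_matrix,
    map_genes_positional,
)


def _toy_blocks(seed=0, n=300, n_blocks=5, snps_per_block=6):
    """Block-diagonal-ish LD from correlated binomial dosages."""
    rng = np.random.default_rng(seed)
    m = n_blocks * snps_per_block
    D = np.empty((n, m))
    for b in range(n_blocks):
        core = rng.binomial(2, 0.3, n).astype(float)
        for j in range(snps_per_block):
            noise = rng.binomial(2, 0.3, n).astype(float)
            w = rng.uniform(0.2, 1.0)
            D[:, b * snps_per_block + j] = w * core + (1 - w) * noise
    positions = np.arange(1, m + 1) * 10_000
    pvals = rng.uniform(0, 1, m) ** 4  # heavy-ish tail
    return D, positions, pvals


class TestLdMatrix:
    def test_properties(self):
        D, _, _ = _toy_blocks()
        r2 = ld_matrix(D)
        assert np.allclose(r2, r2.T)
        assert np.allclose(np.diag(r2), 1.0)
        assert r2.min() >= 0 and r2.max() <= 1

    def test_zero_variance_column(self):
        D = np.column_stack([np.ones(50), np.arange(50, dtype=float)])
        r2 = ld_matrix(D)
        assert r2[0, 1] == 0.0 and r2[0, 0] == 1.0


class TestFindIndependent:
    def test_no_significant_snps(self):
        D, pos, pvals = _toy_blocks()
        r2 = ld_matrix(D)
        assert find_independent(np.full(len(pos), 0.5), pos, r2, 1e-8) == []

    def test_high_ld_pair_keeps_smaller_p(self):
        r2 = np.array([[1.0, 0.9], [0.9, 1.0]])
        pvals = np.array([1e-10, 1e-9])
        out = find_independent(pvals, np.array([100, 200]), r2, 1e-8)
        assert out == [0]

    def test_matches_bruteforce_on_toy_blocks(self):
        D, pos, pvals = _toy_blocks(seed=5)
        r2 = ld_matrix(D)
        got = find_independent(pvals, pos, r2, 0.05, r2_indep=0.6)
        assert got == greedy_clump_oracle(pvals, pos, r2, 0.05, 0.6)

    def test_relaxing_r2_never_shrinks_selection(self):
        D, pos, pvals = _toy_blocks(seed=6)
        r2 = ld_matrix(D)
        sizes = [
            len(find_independent(pvals, pos, r2, 0.05, r2_indep=x))
            for x in (0.2, 0.4, 0.6, 0.8)
        ]
        assert sizes == sorted(sizes)


class TestFindLeads:
    def test_single_independent_is_lead(self):
        r2 = np.eye(1)
        assert find_leads([0], np.array([1e-9]), np.array([10]), r2) == [0]

    def test_moderate_ld_pair_gives_one_lead(self):
        r2 = np.array([[1.0, 0.3], [0.3, 1.0]])
        pvals = np.array([1e-9, 1e-10])
        out = find_leads([0, 1], pvals, np.array([10, 20]), r2, r2_lead=0.1)
        assert out == [1]

    def test_matches_bruteforce(self):
        D, pos, pvals = _toy_blocks(seed=7)
        r2 = ld_matrix(D)
        ind = find_independent(pvals, pos, r2, 0.05, 0.6)
        got = find_leads(ind, pvals, pos, r2, 0.1)
        sig = np.full(len(pvals), 1.0)
        sig[ind] = pvals[ind]
        assert got == greedy_clump_oracle(sig, pos, r2, 0.05, 0.1)


class TestCandidateSnps:
    def test_isolated_independent(self):
        r2 = np.eye(3)
        pvals = np.array([1e-9, 0.5, 0.9])
        assert candidate_snps([0], pvals, r2) == [0]

    def test_linked_but_nonnominal_excluded(self):
        r2 = np.array([[1.0, 0.7], [0.7, 1.0]])
        pvals = np.array([1e-9, 0.2])
        assert candidate_snps([0], pvals, r2) == [0]

    def test_matches_set_comprehension(self):
        D, pos, pvals = _toy_blocks(seed=8)
        r2 = ld_matrix(D)
        ind = find_independent(pvals, pos, r2, 0.05, 0.6)
        got = candidate_snps(ind, pvals, r2, 0.6, 0.05)
        expect = sorted(
            set(ind)
            | {
                j
                for j in range(len(pvals))
                if pvals[j] < 0.05 and any(r2[j, i] >= 0.6 for i in ind)
            }
        )
        assert got == expect


class TestDefineLoci:
    def test_single_lead_span(self):
        pos = np.array([100_000, 110_000, 140_000])
        pvals = np.array([1e-10, 1e-3, 1e-4])
        loci = define_loci([0], [0, 1, 2], [0], pvals, pos)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100_000, 140_000)
        assert loci[0].lead_snp == 0

    def test_nearby_leads_merge(self):
        pos = np.array([100_000, 200_000])
        pvals = np.array([1e-10, 1e-9])
        loci = define_loci([0, 1], [0, 1], [0, 1], pvals, pos, merge_dist=250_000)
        assert len(loci) == 1
        assert loci[0].lead_snp == 0

    def test_distant_leads_stay_separate(self):
        pos = np.array([100_000, 600_000])
        pvals = np.array([1e-10, 1e-9])
        loci = define_loci([0, 1], [0, 1], [0, 1], pvals, pos, merge_dist=250_000)
        assert len(loci) == 2

    def test_fixed_point_independent_of_lead_order(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 40, replace=False))
        pvals = rng.uniform(0, 1e-6, 40)
        leads = list(rng.choice(40, 5, replace=False))
        cands = sorted(set(leads) | set(rng.choice(40, 20, replace=False)))
        ref = define_loci(leads, cands, leads, pvals, pos)
        for _ in range(5):
            rng.shuffle(leads)
            alt = define_loci(leads, cands, sorted(leads), pvals, pos)
            assert [(l.start, l.end, l.lead_snp) for l in alt] == [
                (l.start, l.end, l.lead_snp) for l in ref
            ]

    def test_every_candidate_in_exactly_one_locus(self):
        D, pos, pvals = _toy_blocks(seed=10)
        r2 = ld_matrix(D)
        ind = find_independent(pvals, pos, r2, 0.05, 0.6)
        if not ind:
            pytest.skip("no significant SNPs in this draw")
        leads = find_leads(ind, pvals, pos, r2, 0.1)
        cands = candidate_snps(ind, pvals, r2, 0.6, 0.05)
        loci = define_loci(leads, cands, ind, pvals, pos)
        seen = [c for l in loci for c in l.candidate_snps]
        assert sorted(seen) == sorted(set(seen)) == sorted(cands)

    def test_larger_merge_distance_never_adds_loci(self):
        D, pos, pvals = _toy_blocks(seed=11)
        r2 = ld_matrix(D)
        ind = find_independent(pvals, pos, r2, 0.05, 0.6)
        leads = find_leads(ind, pvals, pos, r2, 0.1)
        cands = candidate_snps(ind, pvals, r2, 0.6, 0.05)
        counts = [
            len(define_loci(leads, cands, ind, pvals, pos, merge_dist=d))
            for d in (10_000, 100_000, 500_000, 2_000_000)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMapGenes:
    def _locus(self, cands, pos):
        from ulcgwas.loci import RiskLocus

        return RiskLocus("1", int(pos[cands].min()), int(pos[cands].max()),
                         cands[0], 1e-9, cands, cands)

    def test_snp_inside_gene_body(self):
        pos = np.array([5_000])
        locus = self._locus([0], pos)
        genes = [("1", 4_000, 6_000, "GENE1")]
        assert map_genes_positional([locus], genes, pos)[0] == {"GENE1"}

    def test_boundary_at_10kb(self):
        pos = np.array([30_001, 30_000])
        genes = [("1", 0, 20_000, "NEAR")]  # 1-based span 1..20000
        # 30_001 is 10_001 bp away -> excluded; 30_000 is exactly 10_000 -> kept
        far = self._locus([0], pos)
        near = self._locus([1], pos)
        assert map_genes_positional([far], genes, pos)[0] == set()
        assert map_genes_positional([near], genes, pos)[0] == {"NEAR"}

    def test_matches_bruteforce_distance_scan(self):
        rng = np.random.default_rng(12)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), 50, replace=False))
        genes = []
        for gi in range(20):
            s = int(rng.integers(0, 1_900_000))
            genes.append(("1", s, s + int(rng.integers(1_000, 50_000)), f"G{gi}"))
        locus = self._locus(list(range(50)), pos)
        got = map_genes_positional([locus], genes, pos, max_dist=10_000)[0]
        expect = set()
        for chrom, s, e, name in genes:
            lo, hi = s + 1, e
            for p in pos:
                d = lo - p if p < lo else (p - hi if p > hi else 0)
                if d <= 10_000:
                    expect.add(name)
        assert got == expect

    def test_malformed_gene_interval_raises(self):
        pos = np.array([100])
        locus = self._locus([0], pos)
        with pytest.raises(ValueError):
            map_genes_positional([locus], [("1", 50, 50, "BAD")], pos)
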