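"""Independent oracles: brute-force / enumeration / exact-arithmetic
implementations used to validate the package's fast paths. These stay
deliberately naive and share no code with the implementation."""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def grid_search_af(bases, errors, ref_base, alt_base, step=1e-5):
    """Dense grid scan of the pooled-read log-likelihood over f in [0, 1]."""
    bases = np.asarray(bases)
    errors = np.asarray(errors, dtype=float)
    pa = np.where(bases == alt_base, 1 - errors, errors / 3)
    pr = np.where(bases == ref_base, 1 - errors, errors / 3)
    fs = np.arange(0.0, 1.0 + step, step)
    ll = np.log(fs[:, None] * pa + (1 - fs[:, None]) * pr).sum(axis=1)
    return float(fs[np.argmax(ll)])


def hwe_exact_fraction(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational HWE conditional test via integer factorials."""
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)

    def prob(h):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        num = (
            math.factorial(n)
            * math.factorial(n_rare)
            * math.factorial(2 * n - n_rare)
            * 2**h
        )
        den = (
            math.factorial(rare_hom)
            * math.factorial(h)
            * math.factorial(common_hom)
            * math.factorial(2 * n)
        )
        return Fraction(num, den)

    hets = range(n_rare % 2, n_rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_het]
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= p_obs)))


def point_in_intervals(chrom, pos_1based, intervals):
    """O(n*m) scan: does a 1-based position fall in any 0-based half-open
    interval on its chromosome?"""
    p = pos_1based - 1
    return any(c == chrom and s <= p < e for c, s, e in intervals)


def _emission_pair(read_la, read_lr, theta_k1, theta_k2):
    """Per-read diploid emission: mean of the two haplotypes' allele mixes."""
    b1 = theta_k1 * read_la + (1 - theta_k1) * read_lr
    b2 = theta_k2 * read_la + (1 - theta_k2) * read_lr
    return 0.5 * (b1 + b2)


def diploid_path_enumeration(theta, pi, rho, reads_by_grid, site_grid):
    """Exhaustively enumerate ordered diploid haplotype paths for 1 sample.

    theta: (K, M); pi: (K,); rho: (G-1,) per-chromosome switch probability
    with a uniform jump destination; reads_by_grid: list per grid of
    (site m, L_alt, L_ref) tuples; site_grid: site index -> grid.

    Returns (state posterior per grid (G, K, K), total likelihood,
    genotype posterior per site (M, 3)) where the allele pair at a site is
    drawn from the copied haplotypes' theta and conditioned on the site's
    reads (each read a uniform mixture over the two chromosomes).
    """
    K, M = theta.shape
    G = len(reads_by_grid)

    def trans(a, b, r):
        return (1 - r) * (1.0 if a == b else 0.0) + r / K

    paths = list(itertools.product(itertools.product(range(K), repeat=2), repeat=G))
    post = np.zeros((G, K, K))
    total = 0.0
    path_probs = []
    for path in paths:
        p = pi[path[0][0]] * pi[path[0][1]]
        for g in range(1, G):
            (a1, b1), (a2, b2) = path[g - 1], path[g]
            p *= trans(a1, a2, rho[g - 1]) * trans(b1, b2, rho[g - 1])
        for g, (k1, k2) in enumerate(path):
            for m, la, lr in reads_by_grid[g]:
                p *= _emission_pair(la, lr, theta[k1, m], theta[k2, m])
        path_probs.append(p)
        total += p
        for g, (k1, k2) in enumerate(path):
            post[g, k1, k2] += p
    post /= total

    gp = np.zeros((M, 3))
    reads_by_site = {}
    for g, reads in enumerate(reads_by_grid):
        for m, la, lr in reads:
            reads_by_site.setdefault(m, []).append((la, lr))
    for m in range(M):
        g = site_grid[m]
        acc = np.zeros(3)
        for k1 in range(K):
            for k2 in range(K):
                w = post[g, k1, k2]
                if w == 0:
                    continue
                for a1 in (0, 1):
                    for a2 in (0, 1):
                        pp = (theta[k1, m] if a1 else 1 - theta[k1, m]) * (
                            theta[k2, m] if a2 else 1 - theta[k2, m]
                        )
                        for la, lr in reads_by_site.get(m, []):
                            l1 = la if a1 else lr
                            l2 = la if a2 else lr
                            pp *= 0.5 * (l1 + l2)
                        acc[a1 + a2] += w * pp
        gp[m] = acc / acc.sum()
    return post, total, gp


def greedy_clump_oracle(pvals, positions, r2, threshold, r2_max):
    """Literal restatement of greedy ascending-p clumping."""
    sig = [j for j in range(len(pvals)) if pvals[j] <= threshold]
    sig.sort(key=lambda j: (pvals[j], positions[j]))
    out = []
    for j in sig:
        if all(r2[j, k] < r2_max for k in out):
            out.append(j)
    return out
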