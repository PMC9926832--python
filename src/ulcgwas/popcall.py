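"""Population SNV discovery from pooled ultra-low-coverage reads.

Individual samples at ~0.04x depth carry almost no per-sample information,
but pooling all reads at a site across the cohort supports a maximum-
likelihood estimate of the population alt-allele frequency and a
likelihood-ratio test of polymorphism. The likelihood treats every read as
an independent draw from a two-allele mixture:

    L(f) = prod_r [ f * P(b_r | alt) + (1 - f) * P(b_r | ref) ]

with P(b | a) = 1 - e_r if b == a else e_r / 3 (uniform substitution to the
three other bases). The log-likelihood is concave in f, so a golden-section
search on [0, 1] finds the MLE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .synthetic_cohort import BASES, ReadPileup

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0

PASS = "PASS"
NOT_SIGNIFICANT = "NOT_SIGNIFICANT"
MULTIALLELIC = "MULTIALLELIC"
REGION_FILTERED = "REGION_FILTERED"

#: Phred-derived error probabilities are floored/capped to this domain
ERROR_FLOOR = 1e-4
ERROR_CAP = 0.75


@dataclass
class AFEstimate:
    site_index: int
    f_hat: float
    loglik_fhat: float
    loglik_null: float
    n_reads: int


@dataclass
class SiteCall:
    chrom: str
    pos: int                # 1-based
    ref_base: str
    alt_base: str
    f_hat: float
    lrt_stat: float
    p_value: float
    status: str


@dataclass
class ExclusionRegions:
    """Sorted, merged half-open 0-based intervals per chromosome."""

    intervals: dict[str, np.ndarray]  # chrom -> (n, 2) array of [start, end)

    @staticmethod
    def from_list(raw: Sequence[tuple[str, int, int]]) -> "ExclusionRegions":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in raw:
            if end <= start or start < 0:
                raise ValueError(f"malformed interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        merged = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.array(out, dtype=np.int64)
        return ExclusionRegions(merged)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        ivs = self.intervals.get(str(chrom))
        if ivs is None or not len(ivs):
            return False
        p = pos_1based - 1
        i = np.searchsorted(ivs[:, 0], p, side="right") - 1
        return i >= 0 and p < ivs[i, 1]


def error_prob_from_phred(q) -> np.ndarray:
    """e = 10^(-Q/10), floored at 1e-4 and capped at 0.75."""
    e = np.power(10.0, -np.asarray(q, dtype=float) / 10.0)
    return np.clip(e, ERROR_FLOOR, ERROR_CAP)


def _golden_max(fun, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Golden-section maximization of a unimodal function on [lo, hi]."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = fun(c), fun(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = fun(d)
    return 0.5 * (a + b)


def _read_likelihoods(
    bases: np.ndarray, errors: np.ndarray, allele_base: int
) -> np.ndarray:
    """P(observed base | true allele) per read."""
    return np.where(bases == allele_base, 1.0 - errors, errors / 3.0)


def estimate_af(
    bases: np.ndarray,
    errors: np.ndarray,
    ref_base: int,
    alt_base: int,
    site_index: int = -1,
    tol: float = 1e-6,
) -> AFEstimate:
    """MLE of the pooled alt-allele frequency from reads at one site."""
    bases = np.asarray(bases)
    errors = np.asarray(errors, dtype=float)
    if len(errors) and (errors.min() <= 0 or errors.max() > ERROR_CAP):
        raise ValueError("error probabilities must lie in (0, 0.75]")
    if len(bases) == 0:
        return AFEstimate(site_index, 0.0, 0.0, 0.0, 0)
    pa = _read_likelihoods(bases, errors, alt_base)
    pr = _read_likelihoods(bases, errors, ref_base)

    def loglik(f: float) -> float:
        return float(np.log(f * pa + (1.0 - f) * pr).sum())

    f_hat = _golden_max(loglik, 0.0, 1.0, tol)
    ll_null = loglik(0.0)
    ll_hat = loglik(f_hat)
    if ll_null >= ll_hat:  # maximum on the f=0 boundary
        f_hat, ll_hat = 0.0, ll_null
    return AFEstimate(site_index, f_hat, ll_hat, ll_null, len(bases))


def lrt_call(
    est: AFEstimate,
    chrom: str,
    pos: int,
    ref_base: int,
    alt_base: int,
    alpha: float = 1e-6,
) -> SiteCall:
    """Likelihood-ratio test of f > 0 against f = 0, chi-square(1) null.

    The chi-square(1) reference (rather than the boundary mixture
    0.5*chi2_0 + 0.5*chi2_1) is deliberately conservative.
    """
    lam = max(0.0, 2.0 * (est.loglik_fhat - est.loglik_null))
    p = float(chi2.sf(lam, df=1))
    status = PASS if p <= alpha else NOT_SIGNIFICANT
    return SiteCall(
        chrom=str(chrom),
        pos=int(pos),
        ref_base=BASES[ref_base],
        alt_base=BASES[alt_base],
        f_hat=est.f_hat,
        lrt_stat=lam,
        p_value=p,
        status=status,
    )


def determine_alt(
    bases: np.ndarray,
    errors: np.ndarray,
    ref_base: int,
    alpha: float = 1e-6,
) -> tuple[int, bool, AFEstimate]:
    """Pick the alt allele and flag multi-allelic sites.

    The candidate alt is the non-ref base whose two-allele model attains the
    highest maximized likelihood (ties broken lexicographically A<C<G<T);
    the site is multi-allelic when a second non-ref base also passes the
    per-allele LRT at ``alpha``.
    """
    bases = np.asarray(bases)
    if len(bases) == 0:
        raise ValueError("determine_alt requires at least one read")
    candidates = sorted(set(int(b) for b in bases) - {int(ref_base)})
    if not candidates:  # all reads ref; pick the smallest non-ref base
        cand = min(b for b in range(4) if b != ref_base)
        est = estimate_af(bases, errors, ref_base, cand)
        return cand, False, est

    ests = [estimate_af(bases, errors, ref_base, c) for c in candidates]
    # highest maximized likelihood wins; base code is the deterministic tie-break
    order = sorted(range(len(candidates)), key=lambda i: (-ests[i].loglik_fhat, candidates[i]))
    best = order[0]
    multi = False
    crit = chi2.isf(alpha, df=1)
    for i in order[1:]:
        lam = 2.0 * (ests[i].loglik_fhat - ests[i].loglik_null)
        if lam >= crit:
            multi = True
            break
    return candidates[best], multi, ests[best]


def call_sites(
    pileup: ReadPileup,
    chrom: str,
    positions: np.ndarray,
    ref: np.ndarray,
    alpha: float = 1e-6,
) -> list[SiteCall]:
    """Run alt determination + AF estimation + LRT over every site."""
    order = np.argsort(pileup.site_idx, kind="stable")
    s_sites = pileup.site_idx[order]
    s_bases = pileup.base[order]
    s_errs = pileup.error_prob[order]
    bounds = np.searchsorted(s_sites, np.arange(pileup.n_sites + 1))

    calls: list[SiteCall] = []
    for m in range(pileup.n_sites):
        lo, hi = bounds[m], bounds[m + 1]
        b, e = s_bases[lo:hi], s_errs[lo:hi]
        if hi == lo:
            alt = min(x for x in range(4) if x != int(ref[m]))
            est = AFEstimate(m, 0.0, 0.0, 0.0, 0)
            call = lrt_call(est, chrom, positions[m], int(ref[m]), alt, alpha)
        else:
            alt, multi, est = determine_alt(b, e, int(ref[m]), alpha)
            est = replace(est, site_index=m)
            call = lrt_call(est, chrom, positions[m], int(ref[m]), alt, alpha)
            if multi and call.status == PASS:
                call.status = MULTIALLELIC
        calls.append(call)
    return calls


def apply_region_filters(
    calls: Sequence[SiteCall], regions: ExclusionRegions
) -> list[SiteCall]:
    """Mark calls inside exclusion intervals as REGION_FILTERED (order kept)."""
    out = []
    for c in calls:
        if regions.contains(c.chrom, c.pos):
            out.append(replace(c, status=REGION_FILTERED))
        else:
            out.append(replace(c))
    return out
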