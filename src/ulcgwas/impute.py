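"""Genotype imputation with a diploid ancestral-haplotype copying HMM.

Each sample's two chromosomes are modelled as mosaics of K latent ancestral
haplotypes (a Li & Stephens copying model). Sites are binned into physical
grids; the hidden state — the ordered pair of ancestral haplotypes being
copied — is shared by all sites in a grid and switches between adjacent
grids with probability rho = 1 - exp(-nGen * r * d) per chromosome, where d
is the physical distance and r a per-bp recombination rate. Ancestral
haplotype k carries an alt-allele dosage theta[k, m] in [0, 1] at site m;
a read b at site m emits

    P(b | state (k1, k2)) = 1/2 B(b; theta[k1, m]) + 1/2 B(b; theta[k2, m])
    B(b; t) = t * P(b | alt) + (1 - t) * P(b | ref)

Parameters (theta, initial distribution pi) are fitted by EM with exact
forward-backward E-steps over the ordered K x K diploid state space, so the
total log-likelihood is nondecreasing across iterations. The ancestry
switch destination is uniform over the K haplotypes, which keeps the
transition kernel parameter-free and the M-step closed-form.

Genotype posteriors marginalize the allele pair at each site over the state
posterior and the site's own reads; per-site certainty is summarized by the
IMPUTE2-style INFO score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthetic_cohort import ReadPileup


@dataclass
class Sites:
    """Ordered bi-allelic site table shared by imputation and downstream QC."""

    chrom: str
    positions: np.ndarray  # 1-based, strictly increasing
    ref: np.ndarray        # base codes 0..3
    alt: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def subset(self, idx: np.ndarray) -> "Sites":
        return Sites(self.chrom, self.positions[idx], self.ref[idx], self.alt[idx])


@dataclass
class HmmParams:
    K: int = 20                    # ancestral haplotype count
    n_gen: float = 2000.0          # generations since founding
    grid_size: int = 10_000        # bp per grid window
    window_size: int = 5_000_000   # bp per imputation window
    window_overlap: int = 500_000  # bp overlap between adjacent windows
    n_em_iters: int = 30
    recomb_rate_bp: float = 1e-8   # per-bp rate feeding the switch probability
    tol: float = 1e-6              # relative log-likelihood change to stop EM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.grid_size < 1:
            raise ValueError("K and grid_size must be >= 1")
        if self.window_overlap >= self.window_size:
            raise ValueError("window_overlap must be smaller than window_size")


@dataclass
class AncestralHaps:
    theta: np.ndarray  # (K, n_sites) alt-allele dosage of each ancestral hap
    pi: np.ndarray     # (K,) initial state distribution

    def __post_init__(self) -> None:
        if np.any(self.theta < 0) or np.any(self.theta > 1):
            raise ValueError("theta entries must lie in [0, 1]")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")


@dataclass
class TransitionModel:
    rho: np.ndarray           # (n_grids - 1,) per-chromosome switch probability
    grid_centers: np.ndarray  # physical center of each used grid
    n_gen: float
    recomb_rate_bp: float


@dataclass
class GenotypePosterior:
    """Per sample x site posterior over alt-allele count, plus dosages."""

    gp: np.ndarray  # (n_samples, n_sites, 3)

    @property
    def dosage(self) -> np.ndarray:
        return self.gp[:, :, 1] + 2.0 * self.gp[:, :, 2]

    @property
    def hard_calls(self) -> np.ndarray:
        # argmax takes the lowest genotype on ties
        return np.argmax(self.gp, axis=2).astype(np.int8)


@dataclass
class SiteInfo:
    est_af: np.ndarray     # theta-hat = mean dosage / 2
    info_score: np.ndarray


def build_grid(
    positions: np.ndarray, params: HmmParams, window_start: int = 1
) -> np.ndarray:
    """Grid index floor((pos - window_start) / grid_size) per site."""
    positions = np.asarray(positions)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    return ((positions - window_start) // params.grid_size).astype(np.int64)


def _apply_transition(F: np.ndarray, rho: float, K: int) -> np.ndarray:
    """One HMM step: each chromosome keeps its haplotype w.p. 1-rho, else
    jumps to a uniformly drawn one. Applied as two rank-1 updates."""
    if rho == 0.0:
        return F
    F = (1.0 - rho) * F + (rho / K) * F.sum(axis=1, keepdims=True)
    F = (1.0 - rho) * F + (rho / K) * F.sum(axis=2, keepdims=True)
    return F


class _HmmData:
    """Static read groupings per grid, shared by EM and the posterior pass."""

    def __init__(
        self,
        pileup: ReadPileup,
        sites: Sites,
        params: HmmParams,
        window_start: int = 1,
    ):
        self.S = pileup.n_samples
        self.M = sites.n_sites
        self.K = params.K
        grid_raw = build_grid(sites.positions, params, window_start)
        used, site_grid = np.unique(grid_raw, return_inverse=True)
        self.site_grid = site_grid            # site -> dense grid rank
        self.G = len(used)
        centers = window_start + (used + 0.5) * params.grid_size
        d = np.diff(centers).astype(float)
        rho = 1.0 - np.exp(-params.n_gen * params.recomb_rate_bp * d)
        self.trans = TransitionModel(rho, centers, params.n_gen, params.recomb_rate_bp)

        # per-read emission ingredients
        m = pileup.site_idx
        self.read_site = m.astype(np.int64)
        self.read_sample = pileup.sample_idx.astype(np.int64)
        e = pileup.error_prob
        self.read_La = np.where(pileup.base == sites.alt[m], 1.0 - e, e / 3.0)
        self.read_Lr = np.where(pileup.base == sites.ref[m], 1.0 - e, e / 3.0)
        self.read_grid = site_grid[m]

        order = np.argsort(self.read_grid, kind="stable")
        self._order = order
        g_sorted = self.read_grid[order]
        self.grid_bounds = np.searchsorted(g_sorted, np.arange(self.G + 1))
        # per grid: read rows (into ordered arrays), unique samples + inverse
        self.groups = []
        for g in range(self.G):
            lo, hi = self.grid_bounds[g], self.grid_bounds[g + 1]
            rows = order[lo:hi]
            if len(rows):
                uids, inv = np.unique(self.read_sample[rows], return_inverse=True)
            else:
                uids, inv = np.empty(0, np.int64), np.empty(0, np.int64)
            self.groups.append((rows, uids, inv))

    # -- emissions -----------------------------------------------------------
    def read_hap_liks(self, theta: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """a[r, k] = B(b_r; theta[k, m_r]) for the given read rows."""
        th = theta[:, self.read_site[rows]].T  # (R, K)
        return th * self.read_La[rows, None] + (1.0 - th) * self.read_Lr[rows, None]

    def grid_emission(self, theta: np.ndarray, g: int):
        """(unique sample ids, per-sample K x K emission matrices) for grid g."""
        rows, uids, inv = self.groups[g]
        if not len(rows):
            return uids, None
        a = self.read_hap_liks(theta, rows)  # (R, K)
        mats = 0.5 * (a[:, :, None] + a[:, None, :])
        E = np.ones((len(uids), self.K, self.K))
        np.multiply.at(E, inv, mats)
        return uids, E

    # -- forward-backward ----------------------------------------------------
    def forward_backward(self, haps: AncestralHaps):
        """Posterior P(state | reads) per grid and the total log-likelihood.

        Returns (P, loglik) with P of shape (G, S, K, K), each sample slice
        normalized to sum 1.
        """
        S, K, G = self.S, self.K, self.G
        theta, pi = haps.theta, haps.pi
        rho = self.trans.rho
        emis = [self.grid_emission(theta, g) for g in range(G)]

        P = np.empty((G, S, K, K))
        F = np.broadcast_to(np.outer(pi, pi), (S, K, K)).copy()
        loglik = 0.0
        for g in range(G):
            if g > 0:
                F = _apply_transition(F, float(rho[g - 1]), K)
            uids, E = emis[g]
            if E is not None:
                F[uids] *= E
            c = F.sum(axis=(1, 2))
            F /= c[:, None, None]
            loglik += float(np.log(c).sum())
            P[g] = F

        B = np.ones((S, K, K))
        for g in range(G - 2, -1, -1):
            W = B.copy()
            uids, E = emis[g + 1]
            if E is not None:
                W[uids] *= E
            B = _apply_transition(W, float(rho[g]), K)
            B /= B.sum(axis=(1, 2))[:, None, None]
            P[g] *= B
            P[g] /= P[g].sum(axis=(1, 2))[:, None, None]
        return P, loglik


def initial_theta(
    af: np.ndarray, K: int, rng: np.random.Generator, concentration: float = 30.0
) -> np.ndarray:
    """Beta-perturbed start around per-site allele frequencies."""
    af = np.clip(np.asarray(af, dtype=float), 0.01, 0.99)
    a = af * concentration
    b = (1.0 - af) * concentration
    return np.clip(rng.beta(a, b, size=(K, len(af))), 1e-4, 1.0 - 1e-4)


def em_fit(
    pileup: ReadPileup,
    sites: Sites,
    params: HmmParams,
    af_init: np.ndarray | None = None,
    window_start: int = 1,
) -> tuple[AncestralHaps, TransitionModel, np.ndarray]:
    """Fit ancestral haplotype dosages by EM; log-likelihood is nondecreasing."""
    if pileup.n_samples < 2:
        raise ValueError("EM fitting needs at least 2 samples")
    data = _HmmData(pileup, sites, params, window_start)
    rng = np.random.default_rng(params.seed)
    if af_init is None:
        af_init = _pooled_af(pileup, sites)
    haps = AncestralHaps(initial_theta(af_init, params.K, rng), np.full(params.K, 1.0 / params.K))

    if pileup.n_reads == 0:
        warnings.warn("no reads: returning the prior-only model", stacklevel=2)
        return haps, data.trans, np.array([])

    trace = []
    for _ in range(params.n_em_iters):
        P, loglik = data.forward_backward(haps)
        trace.append(loglik)
        haps = _m_step(data, haps, P)
        if len(trace) > 1:
            denom = max(abs(trace[-2]), 1.0)
            if (trace[-1] - trace[-2]) / denom < params.tol:
                break
    return haps, data.trans, np.asarray(trace)


def _pooled_af(pileup: ReadPileup, sites: Sites) -> np.ndarray:
    """Quick pooled MLE of per-site allele frequencies (EM starting point)."""
    from .popcall import estimate_af

    order = np.argsort(pileup.site_idx, kind="stable")
    bounds = np.searchsorted(pileup.site_idx[order], np.arange(sites.n_sites + 1))
    af = np.empty(sites.n_sites)
    for m in range(sites.n_sites):
        rows = order[bounds[m] : bounds[m + 1]]
        est = estimate_af(
            pileup.base[rows], pileup.error_prob[rows], int(sites.ref[m]), int(sites.alt[m])
        )
        af[m] = est.f_hat
    return af


def _m_step(data: _HmmData, haps: AncestralHaps, P: np.ndarray) -> AncestralHaps:
    K, M = data.K, data.M
    theta = haps.theta
    alt_acc = np.zeros((M, K))
    tot_acc = np.zeros((M, K))
    for g in range(data.G):
        rows, uids, inv = data.groups[g]
        if not len(rows):
            continue
        a = data.read_hap_liks(theta, rows)          # (R, K)
        Pr = P[g][data.read_sample[rows]]            # (R, K, K)
        denom = a[:, :, None] + a[:, None, :]
        D = ((Pr + Pr.transpose(0, 2, 1)) / denom).sum(axis=2)  # (R, K)
        W = a * D                                    # read->hap responsibility
        th = theta[:, data.read_site[rows]].T
        q = th * data.read_La[rows, None] / a        # P(alt | hap k, read)
        np.add.at(alt_acc, data.read_site[rows], W * q)
        np.add.at(tot_acc, data.read_site[rows], W)

    new_theta = theta.copy()
    seen = tot_acc.T > 1e-12
    new_theta[seen] = (alt_acc.T[seen]) / (tot_acc.T[seen])
    # box-constrained M-step: the per-parameter objective is concave, so
    # clipping is the exact constrained maximizer and EM stays monotone;
    # keeping theta off {0,1} stops degenerate priors from vetoing reads
    np.clip(new_theta, 1e-4, 1.0 - 1e-4, out=new_theta)

    P0 = P[0]
    pi = (P0.sum(axis=2) + P0.sum(axis=1)).sum(axis=0)
    pi = pi / pi.sum()
    return AncestralHaps(new_theta, pi)


def genotype_posteriors(
    pileup: ReadPileup,
    sites: Sites,
    haps: AncestralHaps,
    trans: TransitionModel,
    params: HmmParams,
    window_start: int = 1,
) -> tuple[GenotypePosterior, SiteInfo]:
    """Posterior genotype triples, dosages, estimated AFs and INFO scores.

    The allele pair at a site is drawn per chromosome from the copied
    haplotype's theta and conditioned on the site's own reads (each read
    sampling one chromosome uniformly).
    """
    data = _HmmData(pileup, sites, params, window_start)
    if haps.theta.shape != (params.K, sites.n_sites):
        raise KeyError("model does not cover the requested site set")
    P, _ = data.forward_backward(haps)
    S, M, K = data.S, data.M, data.K

    pA1 = np.empty((S, M))
    pA2 = np.empty((S, M))
    p11 = np.empty((S, M))
    for g in range(data.G):
        cols = np.flatnonzero(data.site_grid == g)
        thb = haps.theta[:, cols]                    # (K, m)
        Pg = P[g]
        row = Pg.sum(axis=2)                         # (S, K)
        col = Pg.sum(axis=1)
        pA1[:, cols] = row @ thb
        pA2[:, cols] = col @ thb
        p11[:, cols] = np.einsum("skl,km,lm->sm", Pg, thb, thb, optimize=True)

    gp = np.empty((S, M, 3))
    gp[:, :, 2] = p11
    gp[:, :, 1] = pA1 + pA2 - 2.0 * p11
    gp[:, :, 0] = 1.0 - pA1 - pA2 + p11

    # exact correction at sample x site cells that carry reads
    if pileup.n_reads:
        key = data.read_site * S + data.read_sample
        order = np.argsort(key, kind="stable")
        ukey, starts = np.unique(key[order], return_index=True)
        t00 = data.read_Lr[order]
        t11 = data.read_La[order]
        t01 = 0.5 * (t00 + t11)
        T00 = np.multiply.reduceat(t00, starts)
        T01 = np.multiply.reduceat(t01, starts)
        T11 = np.multiply.reduceat(t11, starts)
        ms = ukey // S
        ss = ukey % S
        q11 = p11[ss, ms]
        qa1 = pA1[ss, ms]
        qa2 = pA2[ss, ms]
        u00 = (1.0 - qa1 - qa2 + q11) * T00
        u01 = (qa2 - q11 + qa1 - q11) * T01
        u11 = q11 * T11
        Z = u00 + u01 + u11
        gp[ss, ms, 0] = u00 / Z
        gp[ss, ms, 1] = u01 / Z
        gp[ss, ms, 2] = u11 / Z

    np.clip(gp, 0.0, None, out=gp)
    gp /= gp.sum(axis=2, keepdims=True)
    post = GenotypePosterior(gp)

    est_af = np.empty(M)
    info = np.empty(M)
    for m2 in range(M):
        est_af[m2], info[m2] = info_score(gp[:, m2, :])
    return post, SiteInfo(est_af, info)


def info_score(gp_site: np.ndarray) -> tuple[float, float]:
    """IMPUTE2-style INFO score at one site across N samples.

    With e_i = p1 + 2 p2 and f_i = p1 + 4 p2, theta-hat = sum e_i / 2N:
    info = 1 - sum(f_i - e_i^2) / (2 N theta (1 - theta)), defined as 1 at
    theta in {0, 1} and clamped to [0, 1].
    """
    gp_site = np.asarray(gp_site, dtype=float)
    if gp_site.ndim != 2 or gp_site.shape[0] < 1:
        raise ValueError("need (N, 3) posterior triples")
    e = gp_site[:, 1] + 2.0 * gp_site[:, 2]
    f = gp_site[:, 1] + 4.0 * gp_site[:, 2]
    n = len(e)
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return float(np.clip(theta, 0.0, 1.0)), 1.0
    info = 1.0 - (f - e**2).sum() / (2.0 * n * theta * (1.0 - theta))
    return float(theta), float(np.clip(info, 0.0, 1.0))


# ---------------------------------------------------------------------------
# windows


@dataclass
class WindowResult:
    start: int                 # window span, 1-based inclusive start
    end: int                   # exclusive end
    site_idx: np.ndarray       # global site indices covered by this window
    gp: np.ndarray             # (S, m_w, 3)
    est_af: np.ndarray
    info: np.ndarray
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


def plan_windows(span_start: int, span_end: int, params: HmmParams) -> list[tuple[int, int]]:
    """Tile [span_start, span_end) with windows of the configured size/overlap."""
    step = params.window_size - params.window_overlap
    out = []
    s = span_start
    while True:
        out.append((s, s + params.window_size))
        if s + params.window_size >= span_end:
            break
        s += step
    return out


def stitch_windows(
    windows: Sequence[WindowResult], positions: np.ndarray
) -> tuple[GenotypePosterior, SiteInfo]:
    """Merge overlapping per-window posteriors into one genome-wide set.

    In overlap zones a site is taken from the window whose center is nearer,
    ties going to the left (earlier-starting) window. Windows must jointly
    cover every site exactly once after this selection.
    """
    windows = sorted(windows, key=lambda w: (w.start, w.end))
    for a, b in zip(windows, windows[1:]):
        if b.start > a.end:
            raise ValueError("gap between imputation windows")
    M = len(positions)
    S = windows[0].gp.shape[0]
    best = np.full(M, -1, dtype=np.int64)
    best_dist = np.full(M, np.inf)
    for wi, w in enumerate(windows):
        d = np.abs(positions[w.site_idx] - w.center)
        take = d < best_dist[w.site_idx]  # strict: ties stay with the left window
        gsel = w.site_idx[take]
        best[gsel] = wi
        best_dist[gsel] = d[take]
    if np.any(best < 0):
        raise ValueError("stitched windows do not cover every site")

    gp = np.empty((S, M, 3))
    est_af = np.empty(M)
    info = np.empty(M)
    for wi, w in enumerate(windows):
        local = np.flatnonzero(best[w.site_idx] == wi)
        gsel = w.site_idx[local]
        gp[:, gsel, :] = w.gp[:, local, :]
        est_af[gsel] = w.est_af[local]
        info[gsel] = w.info[local]
    return GenotypePosterior(gp), SiteInfo(est_af, info)


@dataclass
class WindowFit:
    """A fitted copying model for one imputation window."""

    start: int
    end: int
    site_idx: np.ndarray
    haps: AncestralHaps
    trans: TransitionModel
    loglik_trace: np.ndarray


def fit_region(
    pileup: ReadPileup,
    sites: Sites,
    params: HmmParams,
    af_init: np.ndarray | None = None,
) -> list[WindowFit]:
    """EM-fit the copying model in overlapping windows across a region."""
    pos = sites.positions
    plan = plan_windows(int(pos.min()), int(pos.max()) + 1, params)
    fits = []
    for start, end in plan:
        sel = np.flatnonzero((pos >= start) & (pos < end))
        if not len(sel):
            continue
        wsites = sites.subset(sel)
        wpile = pileup.subset_sites(sel)
        wa = af_init[sel] if af_init is not None else None
        haps, trans, trace = em_fit(wpile, wsites, params, af_init=wa, window_start=start)
        fits.append(WindowFit(start, end, sel, haps, trans, trace))
    return fits


def posteriors_from_fits(
    pileup: ReadPileup,
    sites: Sites,
    params: HmmParams,
    fits: Sequence[WindowFit],
) -> tuple[GenotypePosterior, SiteInfo]:
    """Genotype posteriors for any pileup under already-fitted window models."""
    results = []
    for fit in fits:
        wsites = sites.subset(fit.site_idx)
        wpile = pileup.subset_sites(fit.site_idx)
        post, si = genotype_posteriors(
            wpile, wsites, fit.haps, fit.trans, params, window_start=fit.start
        )
        results.append(
            WindowResult(
                fit.start, fit.end, fit.site_idx, post.gp, si.est_af,
                si.info_score, fit.loglik_trace,
            )
        )
    return stitch_windows(results, sites.positions)


def impute_region(
    pileup: ReadPileup,
    sites: Sites,
    params: HmmParams,
    af_init: np.ndarray | None = None,
) -> tuple[GenotypePosterior, SiteInfo, list[WindowFit]]:
    """Impute a whole region: per-window EM fits stitched across overlaps."""
    fits = fit_region(pileup, sites, params, af_init)
    post, si = posteriors_from_fits(pileup, sites, params, fits)
    return post, si, fits
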