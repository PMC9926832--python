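"""Synthetic cohorts for ultra-low-coverage WGS experiments.

This module generates every input the rest of the pipeline needs: a
haplotype panel with tunable linkage disequilibrium, a diploid cohort with
sibling families and batch labels (whole-genome-amplification kit x
sequencing platform), sparse read pileups at a requested mean coverage,
and a z-scored quantitative phenotype with clinical covariates.

The panel generator is a founder-mosaic copying process, not a coalescent:
founder haplotypes are drawn site-wise from an allele-frequency spectrum
and every panel haplotype copies one founder at a time, switching founders
with a per-bp probability. This gives LD that decays with distance, exact
ground truth, and trivial reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

BASES = "ACGT"

#: the three whole-genome-amplification kits used to prepare biopsies
WGA_KITS = ("MDA", "dop-PCR", "PicoPlex")
#: the four sequencing platforms
PLATFORMS = ("BGI-Seq500", "MiSeq", "IonProton", "IonTorrent")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class HaplotypePanel:
    """Binary allele matrix over ordered sites with a recombination map."""

    chrom: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    ref: np.ndarray        # base codes 0..3 (ACGT)
    alt: np.ndarray
    alleles: np.ndarray    # (n_haplotypes, n_sites) in {0, 1}
    recomb_rate: float     # per-bp founder-switch probability used in generation
    region_length: int
    n_founders: int = 0

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def validate(self) -> None:
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("site positions must be strictly increasing")
        if np.any(self.ref == self.alt):
            raise ValueError("every site needs ref != alt")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele matrix entries must be 0/1")

    def allele_frequencies(self) -> np.ndarray:
        return self.alleles.mean(axis=0)


@dataclass
class CohortTruth:
    """Ground-truth diploid cohort sampled from a panel."""

    hap1: np.ndarray       # (n_samples, n_sites) alleles of the paternal copy
    hap2: np.ndarray       # maternal copy
    family_id: np.ndarray  # (n_samples,) int
    wga: np.ndarray        # (n_samples,) index into WGA_KITS
    platform: np.ndarray   # (n_samples,) index into PLATFORMS

    @property
    def n_samples(self) -> int:
        return self.hap1.shape[0]

    @property
    def n_sites(self) -> int:
        return self.hap1.shape[1]

    @property
    def genotypes(self) -> np.ndarray:
        """Alt-allele count per sample x site, in {0, 1, 2}."""
        return (self.hap1 + self.hap2).astype(np.int8)

    @property
    def true_af(self) -> np.ndarray:
        return (self.hap1.sum(axis=0) + self.hap2.sum(axis=0)) / (2 * self.n_samples)

    def batch_key(self, i: int) -> tuple[str, str]:
        return (WGA_KITS[self.wga[i]], PLATFORMS[self.platform[i]])


@dataclass
class ReadPileup:
    """Sparse per-sample, per-site read observations.

    Stored as flat parallel arrays; this is the only evidence visible to the
    calling and imputation stages.
    """

    sample_idx: np.ndarray  # int32
    site_idx: np.ndarray    # int32
    base: np.ndarray        # uint8 code 0..3
    error_prob: np.ndarray  # float64 in (0, 0.75]
    n_samples: int
    n_sites: int

    def __post_init__(self) -> None:
        if len(self.error_prob) and (
            self.error_prob.min() <= 0 or self.error_prob.max() > 0.75
        ):
            raise ValueError("error_prob must lie in (0, 0.75]")
        if len(self.site_idx) and (
            self.site_idx.min() < 0 or self.site_idx.max() >= self.n_sites
        ):
            raise ValueError("site index out of range")

    @property
    def n_reads(self) -> int:
        return len(self.base)

    def reads_at_site(self, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(bases, error_probs, sample indices) of all reads at site ``m``."""
        sel = self.site_idx == m
        return self.base[sel], self.error_prob[sel], self.sample_idx[sel]

    def subset_sites(self, keep: np.ndarray) -> "ReadPileup":
        """Restrict to a sorted array of site indices, renumbering 0..len-1."""
        keep = np.asarray(keep, dtype=np.int64)
        lookup = np.full(self.n_sites, -1, dtype=np.int64)
        lookup[keep] = np.arange(len(keep))
        new = lookup[self.site_idx]
        sel = new >= 0
        return ReadPileup(
            self.sample_idx[sel],
            new[sel].astype(np.int32),
            self.base[sel],
            self.error_prob[sel],
            self.n_samples,
            len(keep),
        )

    @staticmethod
    def concatenate(parts: Sequence["ReadPileup"]) -> "ReadPileup":
        n_sites = parts[0].n_sites
        if any(p.n_sites != n_sites for p in parts):
            raise ValueError("pileups must share a site set")
        offsets = np.cumsum([0] + [p.n_samples for p in parts])
        return ReadPileup(
            np.concatenate(
                [p.sample_idx + off for p, off in zip(parts, offsets)]
            ).astype(np.int32),
            np.concatenate([p.site_idx for p in parts]).astype(np.int32),
            np.concatenate([p.base for p in parts]),
            np.concatenate([p.error_prob for p in parts]),
            int(offsets[-1]),
            n_sites,
        )


@dataclass
class PhenotypeModel:
    """Additive genetic + covariate + batch + noise model for a z-scored trait."""

    causal_sites: np.ndarray                 # site indices
    betas: np.ndarray                        # per-causal effect, z-scale
    covariate_effects: np.ndarray = field(
        default_factory=lambda: np.zeros(8)
    )                                        # one per clinical covariate
    wga_effects: np.ndarray = field(default_factory=lambda: np.zeros(3))
    platform_effects: np.ndarray = field(default_factory=lambda: np.zeros(4))
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        # zero is allowed for noiseless limiting cases
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# allele-frequency spectra

AfSpectrum = Callable[[np.random.Generator, int], np.ndarray]


def resolve_af_spectrum(spec) -> AfSpectrum:
    """Turn a spectrum spec into a sampler ``f(rng, n) -> frequencies``.

    Accepts a callable, ``("uniform", lo, hi)``, ``("beta", a, b)`` or None
    (uniform on [0.05, 0.95], a common-variant spectrum suitable for
    MAF >= 0.01 pipelines).
    """
    if spec is None:
        return lambda rng, n: rng.uniform(0.05, 0.95, n)
    if callable(spec):
        return spec
    kind, *args = spec
    if kind == "uniform":
        lo, hi = args
        return lambda rng, n: rng.uniform(lo, hi, n)
    if kind == "beta":
        a, b = args
        return lambda rng, n: np.clip(rng.beta(a, b, n), 1e-3, 1 - 1e-3)
    raise ValueError(f"unknown af_spectrum {spec!r}")


# ---------------------------------------------------------------------------
# operations


def generate_panel(
    n_hap: int,
    n_sites: int,
    region_length: int,
    recomb_rate: float,
    af_spectrum=None,
    seed: int = 0,
    n_founders: int = 8,
    chrom: str = "1",
    n_blocks: int = 1,
) -> HaplotypePanel:
    """Generate a haplotype panel by founder-mosaic copying.

    Founders are drawn site-wise from ``af_spectrum``; each panel haplotype
    copies a founder, switching to a uniformly drawn founder with per-bp
    probability ``recomb_rate`` (so LD decays with physical distance).

    ``n_blocks`` > 1 adds deterministic recombination hotspots that split
    the region into equal-length blocks: every haplotype re-draws its
    founder at each block boundary, so LD is strong within blocks and
    absent between them. This emulates the haplotype-block structure a
    small region of a real genome would show while keeping the population's
    genome-wide rank well above the number of blocks' founders.
    """
    if n_hap < 2 or n_sites < 1 or region_length < n_sites:
        raise ValueError("need n_hap >= 2, n_sites >= 1, region >= n_sites bp")
    if recomb_rate < 0:
        raise ValueError("recomb_rate must be >= 0")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(np.arange(1, region_length + 1), size=n_sites, replace=False)
    ).astype(np.int64)
    af = resolve_af_spectrum(af_spectrum)(rng, n_sites)
    founders = (rng.random((n_founders, n_sites)) < af).astype(np.uint8)

    fid = rng.integers(0, n_founders, n_hap)
    alleles = np.empty((n_hap, n_sites), dtype=np.uint8)
    alleles[:, 0] = founders[fid, 0]
    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-recomb_rate * gaps)
    if n_blocks > 1:
        block_len = region_length / n_blocks
        block_id = ((positions - 1) // block_len).astype(np.int64)
        p_switch = np.where(np.diff(block_id) > 0, 1.0, p_switch)
    for m in range(1, n_sites):
        sw = rng.random(n_hap) < p_switch[m - 1]
        if sw.any():
            fid = np.where(sw, rng.integers(0, n_founders, n_hap), fid)
        alleles[:, m] = founders[fid, m]

    ref = rng.integers(0, 4, n_sites).astype(np.uint8)
    alt = (ref + rng.integers(1, 4, n_sites)).astype(np.uint8) % 4
    panel = HaplotypePanel(
        chrom=chrom,
        positions=positions,
        ref=ref,
        alt=alt,
        alleles=alleles,
        recomb_rate=recomb_rate,
        region_length=region_length,
        n_founders=n_founders,
    )
    panel.validate()
    return panel


def sample_cohort(
    panel: HaplotypePanel,
    n_samples: int,
    sibs_per_family: int = 1,
    seed: int = 0,
    batch_proportions: tuple[np.ndarray, np.ndarray] | None = None,
) -> CohortTruth:
    """Sample a sibling-structured diploid cohort from a panel.

    Each family draws two parental haplotype pairs from the panel; every sib
    inherits one whole haplotype from each parent (no meiotic recombination
    within the simulated region). The last family may be smaller when
    ``n_samples`` is not a multiple of ``sibs_per_family``.
    """
    if n_samples < 1 or sibs_per_family < 1:
        raise ValueError("n_samples and sibs_per_family must be >= 1")
    rng = np.random.default_rng(seed)
    n_fam = -(-n_samples // sibs_per_family)
    # four parental haplotype indices per family
    parents = rng.integers(0, panel.n_haplotypes, (n_fam, 4))
    family_id = np.repeat(np.arange(n_fam), sibs_per_family)[:n_samples]
    pat = parents[family_id, rng.integers(0, 2, n_samples)]
    mat = parents[family_id, 2 + rng.integers(0, 2, n_samples)]
    hap1 = panel.alleles[pat]
    hap2 = panel.alleles[mat]

    if batch_proportions is None:
        p_wga = np.full(3, 1 / 3)
        p_plat = np.full(4, 1 / 4)
    else:
        p_wga, p_plat = batch_proportions
    wga = rng.choice(3, n_samples, p=p_wga).astype(np.int8)
    platform = rng.choice(4, n_samples, p=p_plat).astype(np.int8)
    return CohortTruth(hap1, hap2, family_id, wga, platform)


def default_error_profile(base_error: float = 0.002) -> dict[tuple[str, str], float]:
    """Per-batch substitution error probabilities.

    One value per (WGA kit, platform) combination; deterministic spread in
    [base_error, ~5*base_error] so batches are distinguishable.
    """
    profile = {}
    for i, kit in enumerate(WGA_KITS):
        for j, plat in enumerate(PLATFORMS):
            profile[(kit, plat)] = base_error * (1.0 + 0.4 * i + 0.25 * j)
    return profile


def simulate_pileups(
    cohort: CohortTruth,
    panel: HaplotypePanel,
    coverage: float,
    error_profile: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> ReadPileup:
    """Simulate sparse read pileups at a mean per-site depth.

    Per sample per site the read count is Poisson(coverage); each read copies
    one of the sample's two true alleles uniformly and is substituted to a
    uniformly chosen other base with the batch's error probability.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if error_profile is None:
        error_profile = default_error_profile()
    rng = np.random.default_rng(seed)
    S, M = cohort.n_samples, cohort.n_sites

    e_sample = np.empty(S)
    for i in range(S):
        key = cohort.batch_key(i)
        if key not in error_profile:
            raise KeyError(f"batch {key} missing from error_profile")
        e = float(error_profile[key])
        if not (0 < e <= 0.75):
            raise ValueError("error probabilities must lie in (0, 0.75]")
        e_sample[i] = e

    counts = rng.poisson(coverage, (S, M))
    s_idx, m_idx = np.nonzero(counts)
    reps = counts[s_idx, m_idx]
    s_idx = np.repeat(s_idx, reps).astype(np.int32)
    m_idx = np.repeat(m_idx, reps).astype(np.int32)
    n_reads = len(s_idx)

    from_hap2 = rng.integers(0, 2, n_reads, dtype=np.int8)
    allele = np.where(
        from_hap2 == 1, cohort.hap2[s_idx, m_idx], cohort.hap1[s_idx, m_idx]
    )
    base = np.where(allele == 1, panel.alt[m_idx], panel.ref[m_idx]).astype(np.uint8)
    err = e_sample[s_idx]
    flip = rng.random(n_reads) < err
    base = np.where(
        flip, (base + rng.integers(1, 4, n_reads)) % 4, base
    ).astype(np.uint8)
    return ReadPileup(s_idx, m_idx, base, err, S, M)


def make_clinical_covariates(n_samples: int, seed: int = 0) -> np.ndarray:
    """Stand-in clinical records: 6 continuous Gaussians + 2 binary indicators."""
    rng = np.random.default_rng(seed)
    cont = rng.normal(size=(n_samples, 6))
    binary = (rng.random((n_samples, 2)) < (0.5, 0.1)).astype(float)
    return np.hstack([cont, binary])


def simulate_phenotype(
    cohort: CohortTruth,
    model: PhenotypeModel,
    clinical_covariates: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a quantitative phenotype and z-score it.

    y = sum_j beta_j g_j + covariate terms + batch shifts + N(0, noise_sd),
    standardized to mean 0, SD 1 (ddof=1).
    """
    causal = np.asarray(model.causal_sites, dtype=np.int64)
    if len(causal) and (causal.min() < 0 or causal.max() >= cohort.n_sites):
        raise ValueError("causal site index out of range")
    X = np.asarray(clinical_covariates, dtype=float)
    if X.shape[0] != cohort.n_samples:
        raise ValueError("covariate row count must equal n_samples")
    rng = np.random.default_rng(seed)
    g = cohort.genotypes[:, causal].astype(float)
    y = g @ np.asarray(model.betas, dtype=float)
    y = y + X @ np.asarray(model.covariate_effects, dtype=float)
    y = y + np.asarray(model.wga_effects)[cohort.wga]
    y = y + np.asarray(model.platform_effects)[cohort.platform]
    y = y + rng.normal(0.0, model.noise_sd, cohort.n_samples)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("phenotype is constant; cannot standardize")
    return (y - y.mean()) / sd
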