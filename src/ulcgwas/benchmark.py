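"""Coverage x sample-size benchmarking of imputation accuracy.

Replays the benchmarking experiment on synthetic truth: a cohort of size s
is simulated at its own ultra-low coverage, one truth sample with known
genotypes is injected at coverage c, the pooled calling + imputation chain
runs on the combined pileups, and genotype/allele accuracy is measured on
the truth sample only. A linear model acc ~ coverage + sample size + 1
summarizes the grid, mirroring the published accuracy regression

    acc = 2.227 c + 8.937e-6 s + 0.494   (c >= 0.01, s >= 4000)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import popcall
from .impute import (
    GenotypePosterior,
    HmmParams,
    Sites,
    fit_region,
    posteriors_from_fits,
)
from .qc_filters import AccuracyReport, accuracy_vs_truth
from .synthetic_cohort import (
    HaplotypePanel,
    ReadPileup,
    default_error_profile,
    sample_cohort,
    simulate_pileups,
)


@dataclass
class GridPoint:
    coverage: float
    sample_size: int
    genotype_accuracy: float
    allele_accuracy: float
    n_sites_evaluated: int


@dataclass
class AccuracyModelFit:
    coef_coverage: float
    coef_samplesize: float
    intercept: float
    r2: float
    c_min: float
    s_min: float

    def predict(self, c: float, s: float) -> float:
        return self.coef_coverage * c + self.coef_samplesize * s + self.intercept


@dataclass
class BenchmarkRun:
    """Full artifacts of one grid point, for reuse by filter sweeps."""

    point: GridPoint
    sites_kept: np.ndarray       # panel site indices that entered imputation
    posterior_gp: np.ndarray     # (s+1, m, 3); last row is the truth sample
    info: np.ndarray
    est_af: np.ndarray
    truth_genotypes: np.ndarray  # (1, m)
    cohort_genotypes: np.ndarray  # (s, m)


def _child_seed(seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(seed)] + [int(t) for t in tags])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CohortModel:
    """A population callset + fitted copying model for one cohort size.

    Mirrors the published benchmark design, where one cohort is imputed and
    only the truth sample's coverage varies: fitting once per size removes
    cohort-to-cohort variance from the coverage axis.
    """

    cohort_genotypes: np.ndarray
    sites_kept: np.ndarray
    sites: Sites
    fits: list
    params: HmmParams
    cohort_pileup: ReadPileup


def prepare_cohort_model(
    panel: HaplotypePanel,
    size: int,
    seed: int,
    cohort_coverage: float = 0.04,
    sibs_per_family: int = 3,
    params: HmmParams | None = None,
    alpha: float = 1e-6,
    maf_min: float = 0.01,
    base_error: float = 0.002,
) -> CohortModel:
    """Simulate a cohort, call population SNVs and fit the copying model.

    The truth sample is not part of the cohort, so its reads never enter
    the population AF estimation or the EM fit (no self-information
    leakage into the callset or the model).
    """
    if size < 2:
        raise ValueError("sample size must be >= 2")
    if params is None:
        params = HmmParams()
    profile = default_error_profile(base_error)
    cohort = sample_cohort(panel, size, sibs_per_family, seed=_child_seed(seed, 1))
    cohort_pile = simulate_pileups(
        cohort, panel, cohort_coverage, profile, seed=_child_seed(seed, 3)
    )
    calls = popcall.call_sites(
        cohort_pile, panel.chrom, panel.positions, panel.ref, alpha=alpha
    )
    kept = np.array(
        [
            i
            for i, c in enumerate(calls)
            if c.status == popcall.PASS and min(c.f_hat, 1 - c.f_hat) >= maf_min
        ],
        dtype=np.int64,
    )
    if len(kept) == 0:
        raise RuntimeError("population calling kept no sites")
    sites = Sites(
        panel.chrom, panel.positions[kept], panel.ref[kept], panel.alt[kept]
    )
    f_hat = np.array([calls[i].f_hat for i in kept])
    sub = cohort_pile.subset_sites(kept)
    fits = fit_region(sub, sites, params, af_init=f_hat)
    return CohortModel(
        cohort_genotypes=cohort.genotypes[:, kept],
        sites_kept=kept,
        sites=sites,
        fits=fits,
        params=params,
        cohort_pileup=sub,
    )


def _score_truth_pileup(
    model: CohortModel,
    truth,
    truth_pile: ReadPileup,
    coverage: float,
) -> BenchmarkRun:
    combined = ReadPileup.concatenate([model.cohort_pileup, truth_pile])
    post, si = posteriors_from_fits(combined, model.sites, model.params, model.fits)

    size = model.cohort_genotypes.shape[0]
    truth_g = truth.genotypes[:, model.sites_kept]
    rep = accuracy_vs_truth(
        GenotypePosterior(post.gp[[size], :, :]), truth_g,
        np.arange(len(model.sites_kept)),
    )
    point = GridPoint(
        coverage=float(coverage),
        sample_size=int(size),
        genotype_accuracy=rep.genotype_accuracy,
        allele_accuracy=rep.allele_accuracy,
        n_sites_evaluated=rep.n_sites_evaluated,
    )
    return BenchmarkRun(
        point=point,
        sites_kept=model.sites_kept,
        posterior_gp=post.gp,
        info=si.info_score,
        est_af=si.est_af,
        truth_genotypes=truth_g,
        cohort_genotypes=model.cohort_genotypes,
    )


def impute_truth_sample(
    model: CohortModel,
    panel: HaplotypePanel,
    coverage: float,
    seed: int,
    base_error: float = 0.002,
) -> BenchmarkRun:
    """Impute one truth sample at the requested coverage under a fitted model."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    profile = default_error_profile(base_error)
    truth = sample_cohort(panel, 1, 1, seed=_child_seed(seed, 2))
    truth_pile = simulate_pileups(
        truth, panel, coverage, profile, seed=_child_seed(seed, 4)
    ).subset_sites(model.sites_kept)
    return _score_truth_pileup(model, truth, truth_pile, coverage)


def run_benchmark_point(
    panel: HaplotypePanel,
    coverage: float,
    size: int,
    seed: int,
    **kwargs,
) -> BenchmarkRun:
    """One (coverage, size) combination end to end."""
    base_error = kwargs.get("base_error", 0.002)
    model = prepare_cohort_model(panel, size, seed, **kwargs)
    return impute_truth_sample(model, panel, coverage, seed, base_error=base_error)


def run_grid(
    panel: HaplotypePanel,
    coverages: list[float],
    sizes: list[int],
    seed: int = 0,
    **kwargs,
) -> list[GridPoint]:
    """Accuracy grid over all (coverage, size) combinations; seed-deterministic.

    One cohort and model fit per size. The truth individual is shared
    across the whole grid, sequenced once at the highest coverage, and
    lower coverages are nested Poisson thinnings of that one read set —
    mirroring benchmark designs that subsample one truth sample's raw
    reads, so the information content is monotone along the coverage axis.
    """
    if any(c <= 0 for c in coverages):
        raise ValueError("coverages must be positive")
    if any(s < 2 for s in sizes):
        raise ValueError("sizes must be >= 2")
    base_error = kwargs.get("base_error", 0.002)
    profile = default_error_profile(base_error)
    c_max = max(coverages)
    truth = sample_cohort(panel, 1, 1, seed=_child_seed(seed, 2))
    truth_full = simulate_pileups(
        truth, panel, c_max, profile, seed=_child_seed(seed, 4)
    )
    thin_rng = np.random.default_rng(_child_seed(seed, 8))
    marks = thin_rng.random(truth_full.n_reads)

    out = []
    for si_, s in enumerate(sizes):
        model = prepare_cohort_model(panel, s, _child_seed(seed, 100 + si_), **kwargs)
        for c in coverages:
            keep = marks < c / c_max
            thinned = ReadPileup(
                truth_full.sample_idx[keep],
                truth_full.site_idx[keep],
                truth_full.base[keep],
                truth_full.error_prob[keep],
                1,
                truth_full.n_sites,
            ).subset_sites(model.sites_kept)
            run = _score_truth_pileup(model, truth, thinned, c)
            out.append(run.point)
    return out


def fit_accuracy_model(
    grid: list[GridPoint], c_min: float = 0.01, s_min: float = 4000.0
) -> AccuracyModelFit:
    """OLS of genotype accuracy on (coverage, sample size, 1), in-domain only."""
    pts = [g for g in grid if g.coverage >= c_min and g.sample_size >= s_min]
    if len(pts) < 3:
        raise ValueError("need at least 3 in-domain grid points")
    A = np.array([[g.coverage, g.sample_size, 1.0] for g in pts])
    y = np.array([g.genotype_accuracy for g in pts])
    if np.linalg.matrix_rank(A) < 3:
        raise np.linalg.LinAlgError("collinear benchmark design")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ coef
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return AccuracyModelFit(
        coef_coverage=float(coef[0]),
        coef_samplesize=float(coef[1]),
        intercept=float(coef[2]),
        r2=r2,
        c_min=c_min,
        s_min=s_min,
    )


def predict_accuracy(fit: AccuracyModelFit, c: float, s: float) -> float:
    """Linear accuracy prediction, clamped to [0, 1]; warns out of domain."""
    if c < fit.c_min or s < fit.s_min:
        warnings.warn(
            f"({c}, {s}) outside the fitted domain "
            f"(c >= {fit.c_min}, s >= {fit.s_min})",
            stacklevel=2,
        )
    return float(np.clip(fit.predict(c, s), 0.0, 1.0))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests
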