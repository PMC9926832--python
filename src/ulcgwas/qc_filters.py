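"""Site-level quality metrics and accuracy-vs-truth reporting.

Imputed sites are screened by the four conditions used for the GWAS input:
membership in a known-variant catalog, MAF >= 0.01, INFO score >= 0.4 and
Hardy-Weinberg exact-test p-value > 1e-6. Accuracy against a truth sample
is reported both as hard-call genotype concordance and as the relaxed
allele accuracy (agreement on presence of the non-reference allele only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .impute import GenotypePosterior, info_score


@dataclass
class SiteQcRecord:
    site: int
    info_score: float
    hwe_p: float
    maf: float
    known_flag: bool


@dataclass
class AccuracyReport:
    n_sites_evaluated: int
    genotype_accuracy: float
    allele_accuracy: float


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele totals and sums the probabilities of
    all heterozygote counts (same parity) whose probability does not exceed
    that of the observed configuration.
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if min(counts) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_rare = min(2 * counts[0] + counts[1], 2 * counts[2] + counts[1])
    het_obs = counts[1]

    hets = np.arange(het_obs % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    # log P(het = h | n, n_rare) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == het_obs][0]
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-12)].sum()))


def site_qc(
    gp_site: np.ndarray, known_flag: bool = True, site: int = -1
) -> SiteQcRecord:
    """QC metrics at one site from its posterior triples.

    Hard calls are argmax posteriors (ties to the lower genotype), HWE is
    the exact test on hard-call counts, and the MAF comes from mean dosage
    (smoother than hard calls at ultra-low coverage).
    """
    gp_site = np.asarray(gp_site, dtype=float)
    if gp_site.ndim != 2 or gp_site.shape[0] < 1:
        raise ValueError("need (N, 3) posterior triples")
    hard = np.argmax(gp_site, axis=1)
    n0, n1, n2 = np.bincount(hard, minlength=3)
    theta, info = info_score(gp_site)
    return SiteQcRecord(
        site=site,
        info_score=info,
        hwe_p=hwe_exact_test(n0, n1, n2),
        maf=float(min(theta, 1.0 - theta)),
        known_flag=bool(known_flag),
    )


def qc_table(
    post: GenotypePosterior, known_flags: np.ndarray | None = None
) -> list[SiteQcRecord]:
    """Per-site QC records for a whole posterior matrix."""
    M = post.gp.shape[1]
    if known_flags is None:
        known_flags = np.ones(M, dtype=bool)
    return [site_qc(post.gp[:, m, :], known_flags[m], site=m) for m in range(M)]


def apply_filters(
    records: Sequence[SiteQcRecord],
    info_min: float = 0.4,
    hwe_min: float = 1e-6,
    maf_min: float = 0.01,
    require_known: bool = False,
) -> np.ndarray:
    """Indices of surviving sites: INFO >= info_min, HWE p > hwe_min,
    MAF >= maf_min and (if required) known-catalog membership."""
    keep = [
        r.site
        for r in records
        if r.info_score >= info_min
        and r.hwe_p > hwe_min
        and r.maf >= maf_min
        and (r.known_flag or not require_known)
    ]
    return np.asarray(keep, dtype=np.int64)


def accuracy_vs_truth(
    post: GenotypePosterior,
    truth_genotypes: np.ndarray,
    eval_sites: np.ndarray,
) -> AccuracyReport:
    """Genotype and allele accuracy of hard calls against truth genotypes.

    Genotype accuracy requires the exact alt-allele count; allele accuracy
    only that the presence of a non-reference allele agrees. Both share the
    same denominator.
    """
    eval_sites = np.asarray(eval_sites, dtype=np.int64)
    if len(eval_sites) == 0:
        raise ValueError("empty evaluation site set")
    calls = post.hard_calls[:, eval_sites]
    truth = np.asarray(truth_genotypes)[:, eval_sites]
    n = calls.size
    gt_acc = float((calls == truth).sum() / n)
    allele_acc = float(((calls > 0) == (truth > 0)).sum() / n)
    return AccuracyReport(
        n_sites_evaluated=len(eval_sites),
        genotype_accuracy=gt_acc,
        allele_accuracy=allele_acc,
    )
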