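"""Score-test GWAS of a quantitative trait on imputed genotype dosages.

The null linear model y = X beta (intercept + top principal components +
clinical covariates) is fitted once by least squares; each site is then
screened with the score statistic

    U = e' r / sigma^2,   V = (e'e - e'X(X'X)^-1 X'e) / sigma^2,
    chi2 = U^2 / V ~ chi-square(1)

where e is the posterior-mean dosage vector, r the null residuals and
sigma^2 the null residual variance. A site is tested only when at least
``min_high`` samples carry a high-confidence genotype (max posterior >=
``high_cutoff``), mirroring the minHigh rule of score-test GWAS on
genotype probabilities. Effect sizes come from ordinary least squares of
the phenotype on [X, dosage]; inflation is summarized by median-based
genomic control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

SPAN_DEGENERATE = "SPAN_DEGENERATE"
CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))  # 0.45494


@dataclass
class ScoreTestResult:
    site: int
    score_u: float
    variance_v: float
    chi2: float
    p_value: float
    n_high: int
    tested_flag: bool
    flag: str = ""


@dataclass
class EffectEstimate:
    site: int
    beta: float
    se: float


@dataclass
class GcReport:
    lambda_gc: float
    mean_chi2: float


@dataclass
class NullModel:
    X: np.ndarray
    Q: np.ndarray        # orthonormal basis of the column space of X
    residuals: np.ndarray
    sigma2: float
    df: int


def standardize_phenotype(y: np.ndarray) -> np.ndarray:
    """z-score (mean 0, SD 1 with denominator N-1), order preserving."""
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must have at least 2 distinct values")
    return (y - y.mean()) / y.std(ddof=1)


def compute_pcs(
    dosages: np.ndarray, n_pcs: int = 8, maf_min: float = 0.05
) -> np.ndarray:
    """Principal-component sample scores from a dosage matrix.

    Sites with MAF >= maf_min are centered by 2*theta-hat and scaled by
    sqrt(2*theta-hat*(1-theta-hat)); scores are the top right-singular
    directions' projections, ordered by variance, each PC sign-fixed so its
    largest-magnitude site loading is positive.
    """
    D = np.asarray(dosages, dtype=float)
    if D.shape[0] < n_pcs + 1:
        raise ValueError("need more samples than requested PCs")
    eaf = D.mean(axis=0) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)
    keep = maf >= maf_min
    if not keep.any():
        raise ValueError("no site passes the MAF threshold")
    eaf = eaf[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (D[:, keep] - 2.0 * eaf) / np.sqrt(2.0 * eaf * (1.0 - eaf))
    if not np.isfinite(Z).all() or np.allclose(Z, 0):
        raise ValueError("degenerate (zero-variance) dosage matrix")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    scores = U[:, :n_pcs] * s[:n_pcs]
    for j in range(n_pcs):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def build_covariates(
    n_samples: int,
    pcs: np.ndarray | None = None,
    clinical: np.ndarray | None = None,
) -> np.ndarray:
    """Covariate matrix [intercept | PCs | clinical records]."""
    cols = [np.ones((n_samples, 1))]
    if pcs is not None:
        cols.append(np.asarray(pcs, dtype=float))
    if clinical is not None:
        cols.append(np.asarray(clinical, dtype=float))
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    return X


def fit_null(y: np.ndarray, X: np.ndarray) -> NullModel:
    """Least-squares fit of the covariate-only model, done once per scan."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    Q, _ = np.linalg.qr(X)
    r = y - Q @ (Q.T @ y)
    df = len(y) - X.shape[1]
    return NullModel(X=X, Q=Q, residuals=r, sigma2=float(r @ r / df), df=df)


def score_scan(
    dosages: np.ndarray,
    null: NullModel,
    gp: np.ndarray | None = None,
    min_high: int = 15,
    high_cutoff: float = 0.9,
    site_ids: np.ndarray | None = None,
) -> list[ScoreTestResult]:
    """Score test at every site of a (samples x sites) dosage matrix."""
    D = np.asarray(dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    M = D.shape[1]
    if site_ids is None:
        site_ids = np.arange(M)
    U = (D.T @ null.residuals) / null.sigma2
    QtD = null.Q.T @ D
    V = ((D * D).sum(axis=0) - (QtD * QtD).sum(axis=0)) / null.sigma2
    if gp is not None:
        n_high = (np.asarray(gp).max(axis=2) >= high_cutoff).sum(axis=0)
    else:
        n_high = np.full(M, D.shape[0])

    out = []
    for j in range(M):
        degenerate = V[j] <= 1e-10
        stat = 0.0 if degenerate else float(U[j] ** 2 / V[j])
        p = 1.0 if degenerate else float(chi2.sf(stat, df=1))
        tested = (not degenerate) and n_high[j] >= min_high
        out.append(
            ScoreTestResult(
                site=int(site_ids[j]),
                score_u=float(U[j]),
                variance_v=float(V[j]),
                chi2=stat,
                p_value=p,
                n_high=int(n_high[j]),
                tested_flag=bool(tested),
                flag=SPAN_DEGENERATE if degenerate else "",
            )
        )
    return out


def score_test(
    dosage: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    gp_site: np.ndarray | None = None,
    min_high: int = 15,
    high_cutoff: float = 0.9,
) -> ScoreTestResult:
    """Single-site convenience wrapper around :func:`score_scan`."""
    null = fit_null(y, X)
    gp = gp_site[:, None, :] if gp_site is not None else None
    return score_scan(dosage, null, gp, min_high, high_cutoff)[0]


def effect_size(dosage: np.ndarray, y: np.ndarray, X: np.ndarray) -> EffectEstimate:
    """Per-alt-allele effect: the dosage coefficient of OLS of y on [X, dosage].

    Computed by Frisch-Waugh residualization; the standard error uses the
    usual unbiased variance estimator of the full model.
    """
    e = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    null = fit_null(y, X)
    et = e - null.Q @ (null.Q.T @ e)
    denom = float(et @ et)
    if denom <= 1e-12:
        raise np.linalg.LinAlgError("dosage lies in the covariate span")
    beta = float(et @ y) / denom
    r_full = null.residuals - beta * et
    df = len(y) - X.shape[1] - 1
    sigma2 = float(r_full @ r_full) / df
    return EffectEstimate(site=-1, beta=beta, se=float(np.sqrt(sigma2 / denom)))


def genomic_control(chi2_stats: np.ndarray) -> GcReport:
    """Median-based genomic-control inflation factor and mean chi-square."""
    x = np.asarray(chi2_stats, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("need at least one finite statistic")
    return GcReport(
        lambda_gc=float(np.median(x) / CHI2_1_MEDIAN),
        mean_chi2=float(x.mean()),
    )


def qq_data(p_values: np.ndarray) -> np.ndarray:
    """Expected vs observed -log10 p pairs for a QQ plot, smallest p last."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.maximum(p, 1e-300))
    return np.column_stack([expected[::-1], observed[::-1]])
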