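"""Association of region methylation with quantitative traits.

Region β values are variance-stabilized to M-values, M = log2(β/(1−β))
(with eps-clipping so the transform stays finite at β ∈ {0, 1}), and each
(region, trait) pair is tested with ordinary least squares

    y = intercept + PC1 + PC2 + Meth

where PC1/PC2 are the leading principal components of the standardized
genotype dosage matrix, absorbing population structure.  The p-value is the
two-sided t-test on the Meth coefficient (residual df = n − 4 with two
PCs).  With R tested regions, p < 0.05/R is *significant* and
0.05/R <= p < 1/R *suggestive* (Bonferroni tiers).

Internally the OLS fit is computed by residualizing y and M on the
covariates (Frisch–Waugh), which vectorizes over regions; the result is
identical to a full OLS fit and cross-checked against statsmodels in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "AssociationResult",
    "beta_to_m",
    "m_to_beta",
    "genotype_pca",
    "associate",
    "association_frame",
]


@dataclass(frozen=True)
class AssociationResult:
    region: str
    trait: str
    effect: float  # phenotype units per M unit
    se: float
    t_stat: float
    p: float
    n: int
    tier: str  # "significant" | "suggestive" | "none"


def beta_to_m(beta, eps: float = 1e-6):
    """M = log2(β'/(1−β')) with β clipped into [eps, 1−eps].

    Accepts scalars or arrays; NaN propagates.  Raises when any finite β
    lies outside [0, 1].
    """
    arr = np.asarray(beta, dtype=float)
    finite = ~np.isnan(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, eps, 1 - eps)
    m = np.log2(clipped / (1 - clipped))
    return float(m) if np.isscalar(beta) else m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (without the clipping)."""
    arr = np.asarray(m, dtype=float)
    beta = 2.0**arr / (1 + 2.0**arr)
    return float(beta) if np.isscalar(m) else beta


def genotype_pca(genotypes: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Leading principal components of the standardized dosage matrix.

    ``genotypes``: samples × SNPs dosage (0/1/2) frame.  Monomorphic SNPs
    are dropped; remaining columns are mean-centered and scaled to unit
    variance.  Components are ordered by decreasing explained variance and
    sign-fixed so each component's largest-magnitude SNP loading is
    positive.  Returns samples × PCs scores.
    """
    if genotypes.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if n_components > genotypes.shape[0]:
        raise ValueError("more components requested than samples")
    x = genotypes.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    poly = sd > 0
    x = x[:, poly]
    if x.shape[1] == 0:
        raise ValueError("all SNPs monomorphic")
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    for k in range(n_components):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1
    return pd.DataFrame(
        scores,
        index=genotypes.index,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )


def _ols_slope_test(y: np.ndarray, x: np.ndarray, covariates: np.ndarray):
    """Effect, SE, t, p for the x coefficient in OLS y ~ 1 + covariates + x.

    Implemented by projecting out [1, covariates] from both y and x
    (Frisch–Waugh–Lovell); df = n − n_covariates − 2.
    """
    n = y.size
    z = np.column_stack([np.ones(n), covariates]) if covariates.size else np.ones((n, 1))
    df = n - z.shape[1] - 1
    if df <= 0:
        return math.nan, math.nan, math.nan, math.nan, df
    q, _ = np.linalg.qr(z)
    y_res = y - q @ (q.T @ y)
    x_res = x - q @ (q.T @ x)
    sxx = float(x_res @ x_res)
    if sxx <= 1e-12 * max(1.0, float(x @ x)):
        return math.nan, math.nan, math.nan, math.nan, df  # constant predictor
    slope = float(x_res @ y_res) / sxx
    resid = y_res - slope * x_res
    sigma2 = float(resid @ resid) / df
    se = math.sqrt(sigma2 / sxx)
    if se == 0:
        return slope, 0.0, math.inf, 0.0, df
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return slope, se, t, float(p), df


def associate(
    m_matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha_significant: float = 0.05,
    alpha_suggestive: float = 1.0,
) -> list[AssociationResult]:
    """OLS association of every region's M-value with every trait.

    ``m_matrix``: regions × samples M-values; ``phenotypes``: samples ×
    traits; ``covariates``: samples × k (e.g. PC1/PC2).  Samples with a
    missing y or M are dropped listwise per test.  Tiers use R = number of
    regions tested: significant below ``alpha_significant``/R, suggestive
    below ``alpha_suggestive``/R.  Constant-M regions are reported with NaN
    statistics (untestable), never raised.
    """
    samples = list(m_matrix.columns)
    if list(phenotypes.index) != samples:
        phenotypes = phenotypes.loc[samples]
    if covariates is not None and list(covariates.index) != samples:
        covariates = covariates.loc[samples]
    n_regions = m_matrix.shape[0]
    if n_regions == 0:
        raise ValueError("no regions to test")
    thr_sig = alpha_significant / n_regions
    thr_sug = alpha_suggestive / n_regions

    cov_arr = (
        covariates.to_numpy(dtype=float)
        if covariates is not None
        else np.empty((len(samples), 0))
    )
    results: list[AssociationResult] = []
    for trait in phenotypes.columns:
        y_full = phenotypes[trait].to_numpy(dtype=float)
        for region in m_matrix.index:
            x_full = m_matrix.loc[region].to_numpy(dtype=float)
            keep = ~(np.isnan(y_full) | np.isnan(x_full))
            if cov_arr.shape[1]:
                keep &= ~np.isnan(cov_arr).any(axis=1)
            y, x, z = y_full[keep], x_full[keep], cov_arr[keep]
            slope, se, t, p, df = _ols_slope_test(y, x, z)
            if math.isnan(p):
                tier = "none"
            elif p < thr_sig:
                tier = "significant"
            elif p < thr_sug:
                tier = "suggestive"
            else:
                tier = "none"
            results.append(
                AssociationResult(region, trait, slope, se, t, p, int(keep.sum()), tier)
            )
    return results


def association_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
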