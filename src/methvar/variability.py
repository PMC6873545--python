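"""Classification of regions by inter-individual methylation variability.

Two complementary tests drive the classification:

* **SD variance test.**  The cohort-wide reference σ₀ is the median, over
  regions, of the sample standard deviation of β values.  For a region with
  n non-missing samples and sample SD s, X = (n−1)·s²/σ₀² is referred to a
  χ² distribution with n−1 degrees of freedom.  The test is one-sided in
  the direction of the observed deviation: upper tail when s > σ₀ (variable),
  lower tail when s <= σ₀ (conserved).
* **CpG-observation chi-square test.**  Every sequenced CpG call in the
  region is treated as an individual methylated/unmethylated observation;
  the per-sample aggregated counts form a k×2 contingency table tested for
  homogeneity with Pearson's chi-square (df = k−1, no continuity
  correction; zero-total samples drop out of k).

With R tested regions and family-wise level ``alpha_hvmr`` (default 0.01),
per-test thresholds are Bonferroni-corrected to ``alpha/R``:

* HVMR   — both tests significant and SD above the median;
* hypo-CMR  — SD test significant below the median, mean β <= 0.2;
* hyper-CMR — SD test significant below the median, mean β >= 0.8;
* VMR    — the lenient tier: CpG-count test significant at
  ``alpha_vmr``/R (default 1e-4/R) and β observed in every sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mhb import MHB
from .region_methylation import RegionMethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VariabilityResult",
    "median_sd",
    "sd_variance_test",
    "cpg_count_chisq",
    "bonferroni_threshold",
    "classify",
]


@dataclass(frozen=True)
class VariabilityResult:
    """Per-region variability statistics and class label."""

    region: str
    n_obs: int
    mean_beta: float
    sd_beta: float
    sigma0: float
    p_sd: float
    sd_direction: str  # "above" | "below"
    p_cpg: float
    label: str  # "HVMR" | "hypoCMR" | "hyperCMR" | "none"
    is_vmr: bool


def median_sd(matrix: RegionMethylationMatrix | pd.DataFrame) -> float:
    """Median over regions of the sample SD (ddof=1) of non-missing β values."""
    beta = matrix.beta if isinstance(matrix, RegionMethylationMatrix) else matrix
    sds = beta.std(axis=1, ddof=1, skipna=True)
    sds = sds[beta.notna().sum(axis=1) >= 2]
    if sds.empty:
        raise ValueError("no region with >= 2 non-missing samples")
    return float(sds.median())


def sd_variance_test(betas: Sequence[float], sigma0: float) -> tuple[float, str]:
    """One-sided chi-square test of a region's SD against the cohort median σ₀.

    Returns (p, direction) where direction is "above" when s > σ₀ (upper
    tail) and "below" otherwise (lower tail).
    """
    values = np.asarray(betas, dtype=float)
    values = values[~np.isnan(values)]
    n = values.size
    if n < 2:
        raise ValueError("need >= 2 non-missing values")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    s = values.std(ddof=1)
    x = (n - 1) * s * s / (sigma0 * sigma0)
    if s > sigma0:
        return float(stats.chi2.sf(x, df=n - 1)), "above"
    return float(stats.chi2.cdf(x, df=n - 1)), "below"


def cpg_count_chisq(table: pd.DataFrame | np.ndarray) -> float:
    """Pearson chi-square homogeneity p for a k×2 (sample × M/U) count table.

    Zero-total samples are excluded from k; no continuity correction.  A
    warning is logged when any expected cell is below 5.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("expected a k×2 count table")
    counts = counts[counts.sum(axis=1) > 0]
    k = counts.shape[0]
    if k < 2:
        raise ValueError("need >= 2 samples with non-zero totals")
    if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0:
        return 1.0  # all observations identical: no heterogeneity
    stat, p, _, expected = stats.chi2_contingency(counts, correction=False)
    if np.any(expected < 5):
        logger.warning("chi-square homogeneity test has expected cells < 5")
    return float(p)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def classify(
    matrix: RegionMethylationMatrix,
    region_counts: Mapping[str, pd.DataFrame],
    alpha_hvmr: float = 0.01,
    alpha_vmr: float = 1e-4,
    hypo_mean: float = 0.2,
    hyper_mean: float = 0.8,
    two_sided: bool = False,
) -> list[VariabilityResult]:
    """Label every region as HVMR / hypoCMR / hyperCMR / none and flag VMRs.

    ``region_counts`` maps region name to its k×2 aggregated count table.
    Thresholds are Bonferroni-corrected by R, the number of regions in the
    (already NA-filtered) matrix.  ``two_sided=True`` doubles the one-sided
    variance-test p (capped at 1).
    """
    names = list(matrix.beta.index)
    n_regions = len(names)
    if n_regions == 0:
        raise ValueError("no regions to classify")
    sigma0 = median_sd(matrix)
    thr_hvmr = bonferroni_threshold(alpha_hvmr, n_regions)
    thr_vmr = bonferroni_threshold(alpha_vmr, n_regions)

    results: list[VariabilityResult] = []
    for name in names:
        row = matrix.beta.loc[name]
        values = row.to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        n_obs = observed.size
        mean_b = float(observed.mean()) if n_obs else math.nan
        sd_b = float(observed.std(ddof=1)) if n_obs >= 2 else math.nan
        if n_obs >= 2:
            p_sd, direction = sd_variance_test(observed, sigma0)
            if two_sided:
                p_sd = min(1.0, 2.0 * p_sd)
        else:
            p_sd, direction = math.nan, "below"
        try:
            p_cpg = cpg_count_chisq(region_counts[name])
        except (KeyError, ValueError):
            p_cpg = math.nan

        label = "none"
        if n_obs >= 2 and p_sd <= thr_hvmr:
            if direction == "above":
                if not math.isnan(p_cpg) and p_cpg <= thr_hvmr:
                    label = "HVMR"
            elif mean_b <= hypo_mean:
                label = "hypoCMR"
            elif mean_b >= hyper_mean:
                label = "hyperCMR"
        fully_observed = n_obs == matrix.beta.shape[1]
        is_vmr = bool(
            fully_observed and not math.isnan(p_cpg) and p_cpg <= thr_vmr
        )
        results.append(
            VariabilityResult(
                name, n_obs, mean_b, sd_b, sigma0, p_sd, direction, p_cpg,
                label, is_vmr,
            )
        )
    return results


def results_to_frame(results: Sequence[VariabilityResult]) -> pd.DataFrame:
    """Tabulate classification results (one row per region)."""
    return pd.DataFrame(
        {
            "region": [r.region for r in results],
            "n_obs": [r.n_obs for r in results],
            "mean_beta": [r.mean_beta for r in results],
            "sd_beta": [r.sd_beta for r in results],
            "sigma0": [r.sigma0 for r in results],
            "p_sd": [r.p_sd for r in results],
            "sd_direction": [r.sd_direction for r in results],
            "p_cpg": [r.p_cpg for r in results],
            "label": [r.label for r in results],
            "is_vmr": [r.is_vmr for r in results],
        }
    ).set_index("region")
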