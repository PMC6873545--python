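"""cis-meQTL mapping: SNPs near a region tested against its M-value.

For every candidate region, SNPs within ``window`` (default 1 Mb) of the
region boundary on the same chromosome are tested by additive-dosage OLS of
the region's M-value on the dosage (optionally with covariates).  SNPs are
pre-filtered on genotype-class counts: monomorphic SNPs are dropped, as are
SNPs showing exactly two genotype classes where the rarer class has fewer
than ``min_class`` (default 3) individuals.  Benjamini–Hochberg adjustment
is applied jointly over all tested (region, SNP) pairs; q <= ``fdr``
(default 0.2) is called significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .association import _ols_slope_test
from .io_formats import GenomicInterval

__all__ = [
    "MeQTLResult",
    "select_cis_snps",
    "filter_genotype_classes",
    "meqtl_scan",
    "meqtl_frame",
]


@dataclass(frozen=True)
class MeQTLResult:
    region: str
    snp: str
    distance: int  # signed, SNP − region midpoint (bp)
    effect: float  # M units per allele
    se: float
    p: float
    q: float
    significant: bool


def select_cis_snps(
    region: GenomicInterval,
    snp_positions: pd.DataFrame,
    window: int = 1_000_000,
) -> list[str]:
    """SNP ids within ``window`` bp of the region's boundaries (inclusive).

    ``snp_positions``: frame indexed by SNP id with columns ``chrom`` and
    ``pos``.  Distance is measured from the nearest region boundary; SNPs
    inside [start, end) have distance 0.
    """
    same = snp_positions[snp_positions["chrom"] == region.chrom]
    pos = same["pos"].to_numpy()
    dist = np.maximum.reduce(
        [region.start - pos, pos - (region.end - 1), np.zeros_like(pos)]
    )
    return list(same.index[dist <= window])


def filter_genotype_classes(
    dosages: Sequence[float] | np.ndarray, min_class: int = 3
) -> tuple[bool, str]:
    """Keep/drop decision for one SNP's dosage vector, with the reason.

    Drops monomorphic SNPs and SNPs with exactly two observed genotype
    classes whose rarer class has fewer than ``min_class`` individuals.
    Missing dosages (NaN) are ignored for class counting.
    """
    arr = np.asarray(dosages, dtype=float)
    arr = arr[~np.isnan(arr)]
    classes, counts = np.unique(arr, return_counts=True)
    if classes.size <= 1:
        return False, "monomorphic"
    if classes.size == 2 and counts.min() < min_class:
        return False, f"two genotype classes, rarer has {counts.min()} < {min_class}"
    return True, "ok"


def meqtl_scan(
    m_matrix: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    genotypes: pd.DataFrame,
    snp_positions: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    fdr: float = 0.2,
    min_class: int = 3,
    min_samples: int = 5,
) -> list[MeQTLResult]:
    """Additive-dosage OLS scan of cis SNPs against region M-values.

    ``m_matrix``: regions × samples M-values (index must carry the names of
    ``regions``); ``genotypes``: samples × SNPs dosage frame;
    ``snp_positions``: SNP id -> chrom/pos.  BH adjustment is global over
    all tested pairs; pairs with fewer than ``min_samples`` complete
    observations are skipped.
    """
    samples = list(m_matrix.columns)
    genotypes = genotypes.loc[samples]
    if covariates is not None:
        covariates = covariates.loc[samples]
    cov_arr = (
        covariates.to_numpy(dtype=float)
        if covariates is not None
        else np.empty((len(samples), 0))
    )

    keep_snp: dict[str, bool] = {}
    rows: list[tuple[str, str, int, float, float, float]] = []
    for region in regions:
        if region.name not in m_matrix.index:
            raise KeyError(f"region {region.name!r} missing from M matrix")
        m_full = m_matrix.loc[region.name].to_numpy(dtype=float)
        midpoint = (region.start + region.end) // 2
        for snp in select_cis_snps(region, snp_positions, window):
            dose_full = genotypes[snp].to_numpy(dtype=float)
            if snp not in keep_snp:
                keep_snp[snp] = filter_genotype_classes(dose_full, min_class)[0]
            if not keep_snp[snp]:
                continue
            keep = ~(np.isnan(m_full) | np.isnan(dose_full))
            if cov_arr.shape[1]:
                keep &= ~np.isnan(cov_arr).any(axis=1)
            if keep.sum() < min_samples:
                continue
            slope, se, _, p, _ = _ols_slope_test(
                m_full[keep], dose_full[keep], cov_arr[keep]
            )
            if math.isnan(p):
                continue
            dist = int(snp_positions.loc[snp, "pos"]) - midpoint
            rows.append((region.name, snp, dist, slope, se, p))

    if not rows:
        raise ValueError("no testable (region, SNP) pairs")
    pvals = np.array([r[5] for r in rows])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        MeQTLResult(name, snp, dist, eff, se, p, float(q), bool(q <= fdr))
        for (name, snp, dist, eff, se, p), q in zip(rows, qvals)
    ]


def meqtl_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
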