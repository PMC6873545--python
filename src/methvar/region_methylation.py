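"""Per-region weighted methylation levels and the region × sample β matrix.

The weighted methylation level of a region in one sample is
β = Σ m_i / Σ t_i over its member CpGs (methylated reads over total reads),
so every read, not every CpG, carries equal weight.  A region-sample cell is
missing ("NA") when the coverage rule fails: by default when the *mean*
per-CpG coverage Σ t_i / n_cpg is below ``min_cov`` (default 5); with
``per_cpg=True`` every member CpG must individually reach ``min_cov``.

Regions with more than ``max_na`` missing samples are dropped before any
variability analysis; ``max_na=None`` scales the published 13-of-28 rule to
the cohort: ceil(0.46 · n_samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mhb import MHB

__all__ = [
    "RegionMethylationMatrix",
    "weighted_methylation",
    "build_beta_matrix",
    "filter_na",
    "region_counts_per_sample",
]

#: fraction of the cohort allowed to be missing per region (13/28 rounded up)
DEFAULT_MAX_NA_FRACTION = 13 / 28


@dataclass
class RegionMethylationMatrix:
    """Regions × samples β values (NaN = missing) with mean per-CpG coverage."""

    regions: list[MHB]
    beta: pd.DataFrame  # index: region names, columns: sample ids
    coverage: pd.DataFrame  # same shape; mean reads per CpG

    def __post_init__(self) -> None:
        if self.beta.shape != self.coverage.shape:
            raise ValueError("beta and coverage shapes differ")
        if len(self.regions) != self.beta.shape[0]:
            raise ValueError("region list must align with beta rows")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    def region_by_name(self, name: str) -> MHB:
        for region in self.regions:
            if region.interval.name == name:
                return region
        raise KeyError(name)


def weighted_methylation(
    methylated: Sequence[int],
    total: Sequence[int],
    min_cov: float = 5,
    per_cpg: bool = False,
) -> float:
    """β = Σm/Σt over member CpGs, or NaN when the coverage rule fails.

    ``per_cpg=False`` (default) requires mean per-CpG coverage >= min_cov;
    ``per_cpg=True`` requires every CpG's own coverage to reach min_cov.
    """
    m = np.asarray(methylated, dtype=float)
    t = np.asarray(total, dtype=float)
    if m.shape != t.shape or m.ndim != 1 or m.size == 0:
        raise ValueError("methylated/total must be equal-length non-empty vectors")
    if np.any(m > t):
        raise ValueError("methylated count exceeds total count")
    if np.any(m < 0) or np.any(t < 0):
        raise ValueError("negative counts")
    covered = np.min(t) >= min_cov if per_cpg else t.mean() >= min_cov
    if not covered:
        return math.nan
    return float(m.sum() / t.sum()) if t.sum() > 0 else math.nan


def build_beta_matrix(
    regions: Sequence[MHB],
    counts: Mapping[str, pd.DataFrame],
    min_cov: float = 5,
    per_cpg: bool = False,
) -> RegionMethylationMatrix:
    """Assemble the region × sample β matrix from per-CpG count tables.

    ``counts`` maps sample id to a table indexed by (chrom, pos) with columns
    ``methylated`` and ``total``.  A region referencing a CpG absent from a
    sample's table contributes zero coverage at that site (the site was
    simply not sequenced in that sample).
    """
    samples = list(counts)
    names = []
    for region in regions:
        if region.interval.name is None:
            raise ValueError("regions must be named before matrix assembly")
        names.append(region.interval.name)
    if len(set(names)) != len(names):
        raise ValueError("duplicate region names")

    beta = np.full((len(regions), len(samples)), np.nan)
    cov = np.zeros((len(regions), len(samples)))
    for j, sample in enumerate(samples):
        table = counts[sample]
        for i, region in enumerate(regions):
            chrom = region.interval.chrom
            m_vec, t_vec = [], []
            for pos in region.cpg_sites:
                key = (chrom, pos)
                if key in table.index:
                    row = table.loc[key]
                    m_vec.append(int(row["methylated"]))
                    t_vec.append(int(row["total"]))
                else:
                    m_vec.append(0)
                    t_vec.append(0)
            cov[i, j] = float(np.mean(t_vec))
            beta[i, j] = weighted_methylation(m_vec, t_vec, min_cov, per_cpg)
    return RegionMethylationMatrix(
        list(regions),
        pd.DataFrame(beta, index=names, columns=samples),
        pd.DataFrame(cov, index=names, columns=samples),
    )


def filter_na(
    matrix: RegionMethylationMatrix, max_na: int | None = None
) -> tuple[RegionMethylationMatrix, dict]:
    """Drop regions whose missing-sample count exceeds ``max_na``.

    ``max_na=None`` uses ceil(0.46 · n_samples), the published 13-of-28 rule
    scaled to the cohort.  Returns the filtered matrix and a summary dict
    with kept/dropped counts.
    """
    n_samples = matrix.beta.shape[1]
    if max_na is None:
        max_na = math.ceil(DEFAULT_MAX_NA_FRACTION * n_samples)
    na_counts = matrix.beta.isna().sum(axis=1)
    keep = na_counts <= max_na
    kept_regions = [r for r, k in zip(matrix.regions, keep) if k]
    filtered = RegionMethylationMatrix(
        kept_regions, matrix.beta.loc[keep], matrix.coverage.loc[keep]
    )
    return filtered, {
        "max_na": max_na,
        "kept": int(keep.sum()),
        "dropped": int((~keep).sum()),
    }


def region_counts_per_sample(
    regions: Sequence[MHB], counts: Mapping[str, pd.DataFrame]
) -> dict[str, pd.DataFrame]:
    """Aggregate (methylated, unmethylated) read counts per region per sample.

    Returns region name -> DataFrame indexed by sample with columns
    ``methylated`` / ``unmethylated`` — the k×2 tables consumed by the
    CpG-observation chi-square test.
    """
    samples = list(counts)
    out: dict[str, pd.DataFrame] = {}
    for region in regions:
        rows = np.zeros((len(samples), 2), dtype=int)
        chrom = region.interval.chrom
        for j, sample in enumerate(samples):
            table = counts[sample]
            for pos in region.cpg_sites:
                key = (chrom, pos)
                if key in table.index:
                    row = table.loc[key]
                    rows[j, 0] += int(row["methylated"])
                    rows[j, 1] += int(row["total"]) - int(row["methylated"])
        out[region.interval.name] = pd.DataFrame(
            rows, index=samples, columns=["methylated", "unmethylated"]
        )
    return out
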