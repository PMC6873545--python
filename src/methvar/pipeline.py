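"""End-to-end orchestration of the methylation-variability analysis.

Chains the individual stages — segment partitioning, MHB calling, β-matrix
assembly, NA filtering, variability classification, β→M transformation,
trait association and cis-meQTL scanning — with the published defaults at
every step.  Each stage remains independently callable from its own module;
this module only wires them together for the CLI and for scripted runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .association import AssociationResult, associate, beta_to_m, genotype_pca
from .io_formats import ReadHaplotype
from .meqtl import MeQTLResult, meqtl_scan
from .mhb import MHB, Segment, build_segments, call_mhbs_genome, pooled_coverage
from .region_methylation import (
    RegionMethylationMatrix,
    build_beta_matrix,
    filter_na,
    region_counts_per_sample,
)
from .variability import VariabilityResult, classify

__all__ = ["PipelineResult", "run_mhb_stage", "run_classification_stage", "run_pipeline"]


@dataclass
class PipelineResult:
    segments: list[Segment]
    mhbs: list[MHB]
    matrix: RegionMethylationMatrix
    na_summary: dict
    classification: list[VariabilityResult]
    associations: list[AssociationResult] = field(default_factory=list)
    meqtls: list[MeQTLResult] = field(default_factory=list)

    @property
    def vmr_names(self) -> list[str]:
        return [r.region for r in self.classification if r.is_vmr]

    def labelled(self, label: str) -> list[str]:
        return [r.region for r in self.classification if r.label == label]


def run_mhb_stage(
    reads: Sequence[ReadHaplotype],
    counts: Mapping[str, pd.DataFrame],
    min_coverage: int = 10,
    min_size: int = 80,
    r2_threshold: float = 0.5,
    min_cpgs: int = 3,
    min_pair_reads: int = 4,
) -> tuple[list[Segment], list[MHB]]:
    segments = build_segments(pooled_coverage(counts), min_coverage, min_size)
    mhbs = call_mhbs_genome(segments, reads, r2_threshold, min_cpgs, min_pair_reads)
    return segments, mhbs


def run_classification_stage(
    mhbs: Sequence[MHB],
    counts: Mapping[str, pd.DataFrame],
    min_cov: float = 5,
    max_na: int | None = None,
    alpha_hvmr: float = 0.01,
    alpha_vmr: float = 1e-4,
) -> tuple[RegionMethylationMatrix, dict, list[VariabilityResult]]:
    matrix = build_beta_matrix(mhbs, counts, min_cov)
    filtered, summary = filter_na(matrix, max_na)
    region_counts = region_counts_per_sample(filtered.regions, counts)
    results = classify(filtered, region_counts, alpha_hvmr, alpha_vmr)
    return filtered, summary, results


def run_pipeline(
    reads: Sequence[ReadHaplotype],
    counts: Mapping[str, pd.DataFrame],
    genotypes: pd.DataFrame | None = None,
    snp_positions: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
    n_pcs: int = 2,
    meqtl_window: int = 1_000_000,
    meqtl_fdr: float = 0.2,
    **stage_kwargs,
) -> PipelineResult:
    """Full analysis from read haplotypes to associations and cis-meQTLs.

    Association and meQTL stages run only when genotypes / phenotypes /
    SNP positions are supplied and at least one VMR survives filtering.
    """
    mhb_keys = {
        k: stage_kwargs[k]
        for k in ("min_coverage", "min_size", "r2_threshold", "min_cpgs",
                  "min_pair_reads")
        if k in stage_kwargs
    }
    cls_keys = {
        k: stage_kwargs[k]
        for k in ("min_cov", "max_na", "alpha_hvmr", "alpha_vmr")
        if k in stage_kwargs
    }
    segments, mhbs = run_mhb_stage(reads, counts, **mhb_keys)
    matrix, summary, results = run_classification_stage(mhbs, counts, **cls_keys)
    out = PipelineResult(segments, mhbs, matrix, summary, results)

    vmrs = out.vmr_names
    if not vmrs or phenotypes is None and genotypes is None:
        return out
    m_matrix = pd.DataFrame(
        beta_to_m(matrix.beta.loc[vmrs].to_numpy()),
        index=vmrs,
        columns=matrix.beta.columns,
    )
    covariates = genotype_pca(genotypes, n_pcs) if genotypes is not None else None
    if phenotypes is not None:
        out.associations = associate(m_matrix, phenotypes, covariates)
    if genotypes is not None and snp_positions is not None:
        regions = [matrix.region_by_name(v).interval for v in vmrs]
        try:
            out.meqtls = meqtl_scan(
                m_matrix, regions, genotypes, snp_positions,
                covariates=covariates, window=meqtl_window, fdr=meqtl_fdr,
            )
        except ValueError:
            out.meqtls = []
    return out
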