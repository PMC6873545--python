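"""Methylation haplotype block (MHB) detection.

The genome is first partitioned into "sequenceable and mappable" segments:
maximal runs of consecutive CpG sites whose read coverage, pooled over all
samples, reaches ``min_coverage`` (default 10), kept when the genomic span
reaches ``min_size`` (default 80 bp).  Within each segment, linkage
disequilibrium of methylation states is computed for each *adjacent* pair of
CpG sites from the reads covering both sites (pooled across samples,
weighted by record multiplicity):

    r² = (p_AB − p_A·p_B)² / (p_A(1−p_A) · p_B(1−p_B))

where p_A, p_B are the frequencies of the methylated state at each site and
p_AB the frequency of joint methylation.  A block extends greedily left to
right while the next adjacent pair has a *defined* r² at or above the
threshold (default 0.5); runs of at least ``min_cpgs`` (default 3) CpGs are
emitted as MHBs.  An undefined r² — a site monomorphic among the
co-covering reads, or fewer than ``min_pair_reads`` reads covering the pair
— breaks the block: absence of evidence of coupling is not treated as
coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GenomicInterval, ReadHaplotype

__all__ = [
    "Segment",
    "MHB",
    "ReadPool",
    "pooled_coverage",
    "build_segments",
    "pairwise_r2",
    "call_mhbs",
    "call_mhbs_genome",
]


def pooled_coverage(counts) -> dict[str, dict[int, int]]:
    """Pool per-CpG total read counts over samples.

    ``counts``: sample -> table indexed by (chrom, pos) with a ``total``
    column.  Returns chrom -> {pos -> pooled count}, the input of
    :func:`build_segments`.
    """
    pooled: dict[str, dict[int, int]] = {}
    for table in counts.values():
        for (chrom, pos), total in table["total"].items():
            chrom_map = pooled.setdefault(chrom, {})
            chrom_map[pos] = chrom_map.get(pos, 0) + int(total)
    return pooled


@dataclass(frozen=True)
class Segment:
    """A mappable-genome segment: consecutive well-covered CpG sites."""

    interval: GenomicInterval
    cpg_sites: tuple[int, ...]
    combined_coverage: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.cpg_sites) != len(self.combined_coverage):
            raise ValueError("coverage vector must align with sites")


@dataclass(frozen=True)
class MHB:
    """A methylation haplotype block (>= min_cpgs CpGs, all adjacent r² >= cut)."""

    interval: GenomicInterval
    cpg_sites: tuple[int, ...]
    min_adjacent_r2: float

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_sites)


def build_segments(
    pooled_coverage: Mapping[str, Mapping[int, int]],
    min_coverage: int = 10,
    min_size: int = 80,
) -> list[Segment]:
    """Partition CpG sites into maximal well-covered runs.

    Parameters
    ----------
    pooled_coverage
        chrom -> {position -> read count pooled over samples}.
    min_coverage
        Minimum pooled coverage per site (sites below it break a run).
    min_size
        Minimum genomic span (last site + 1 − first site) of a kept run.
    """
    if not pooled_coverage or all(len(v) == 0 for v in pooled_coverage.values()):
        raise ValueError("empty count table")
    segments: list[Segment] = []
    for chrom in sorted(pooled_coverage):
        site_cov = pooled_coverage[chrom]
        positions = sorted(site_cov)
        run: list[int] = []
        for pos in positions + [None]:  # sentinel flushes the last run
            if pos is not None and site_cov[pos] >= min_coverage:
                run.append(pos)
                continue
            if run:
                span_end = run[-1] + 1
                if span_end - run[0] >= min_size:
                    segments.append(
                        Segment(
                            GenomicInterval(chrom, run[0], span_end),
                            tuple(run),
                            tuple(site_cov[p] for p in run),
                        )
                    )
                run = []
    return segments


class ReadPool:
    """Index of read haplotypes by chromosome for fast pair lookups.

    Reads from all samples are pooled; multiplicity-k records contribute k
    reads.  Per chromosome the pool stores, for every read, its position
    tuple and state string, so extracting the sub-reads covering a given
    site pair is a dictionary lookup plus a scan of reads indexed at the
    left site.
    """

    def __init__(self, reads: Iterable[ReadHaplotype]):
        # chrom -> pos -> list of (states, pos_index_map, multiplicity)
        self._by_site: dict[str, dict[int, list[tuple[ReadHaplotype, int]]]] = {}
        for read in reads:
            chrom_index = self._by_site.setdefault(read.chrom, {})
            for i, pos in enumerate(read.cpg_positions):
                chrom_index.setdefault(pos, []).append((read, i))

    def pair_counts(
        self, chrom: str, site_a: int, site_b: int
    ) -> tuple[int, int, int, int]:
        """Weighted 2x2 tallies (n_MM, n_MU, n_UM, n_UU) over reads covering both."""
        counts = [0, 0, 0, 0]
        for read, i in self._by_site.get(chrom, {}).get(site_a, ()):
            try:
                j = read.cpg_positions.index(site_b)
            except ValueError:
                continue
            a_m = read.states[i] == "M"
            b_m = read.states[j] == "M"
            counts[(not a_m) * 2 + (not b_m)] += read.multiplicity
        return tuple(counts)  # type: ignore[return-value]


def _r2_from_counts(
    n_mm: int, n_mu: int, n_um: int, n_uu: int, min_pair_reads: int
) -> float | None:
    n = n_mm + n_mu + n_um + n_uu
    if n < min_pair_reads:
        return None
    p_a = (n_mm + n_mu) / n
    p_b = (n_mm + n_um) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None  # monomorphic site: LD undefined
    p_ab = n_mm / n
    d = p_ab - p_a * p_b
    return (d * d) / (p_a * (1 - p_a) * p_b * (1 - p_b))


def pairwise_r2(
    reads: Iterable[ReadHaplotype] | ReadPool,
    chrom: str,
    site_a: int,
    site_b: int,
    min_pair_reads: int = 4,
) -> float | None:
    """LD r² of methylation at two CpG sites, or None when undefined.

    Only reads covering *both* sites contribute, pooled over samples and
    weighted by multiplicity.  Undefined when fewer than ``min_pair_reads``
    reads co-cover the pair or either site is monomorphic among them.
    """
    pool = reads if isinstance(reads, ReadPool) else ReadPool(reads)
    return _r2_from_counts(*pool.pair_counts(chrom, site_a, site_b), min_pair_reads)


def call_mhbs(
    segment: Segment,
    reads: Iterable[ReadHaplotype] | ReadPool,
    r2_threshold: float = 0.5,
    min_cpgs: int = 3,
    min_pair_reads: int = 4,
) -> list[MHB]:
    """Greedy left-to-right block caller within one segment.

    A block extends while the next adjacent CpG pair has defined r² >=
    ``r2_threshold``; maximal runs with >= ``min_cpgs`` sites are emitted,
    carrying the minimum adjacent r² observed inside the block.
    """
    pool = reads if isinstance(reads, ReadPool) else ReadPool(reads)
    sites = segment.cpg_sites
    chrom = segment.interval.chrom
    blocks: list[MHB] = []
    run_start = 0
    run_r2: list[float] = []

    def flush(end_index: int) -> None:
        if end_index - run_start + 1 >= min_cpgs:
            members = sites[run_start : end_index + 1]
            blocks.append(
                MHB(
                    GenomicInterval(
                        chrom, members[0], members[-1] + 1, name=None
                    ),
                    tuple(members),
                    min(run_r2),
                )
            )

    for k in range(len(sites) - 1):
        r2 = pairwise_r2(pool, chrom, sites[k], sites[k + 1], min_pair_reads)
        if r2 is not None and r2 >= r2_threshold:
            run_r2.append(r2)
        else:
            flush(k)
            run_start = k + 1
            run_r2 = []
    if len(sites) > 0:
        flush(len(sites) - 1)
    return blocks


def call_mhbs_genome(
    segments: Sequence[Segment],
    reads: Iterable[ReadHaplotype],
    r2_threshold: float = 0.5,
    min_cpgs: int = 3,
    min_pair_reads: int = 4,
    name_prefix: str = "MHB",
) -> list[MHB]:
    """Call blocks over every segment; blocks are named ``<prefix>_<k>``."""
    pool = ReadPool(reads)
    out: list[MHB] = []
    for seg in segments:
        out.extend(call_mhbs(seg, pool, r2_threshold, min_cpgs, min_pair_reads))
    out.sort(key=lambda b: b.interval)
    named = []
    for k, blk in enumerate(out, start=1):
        iv = blk.interval
        named.append(
            MHB(
                GenomicInterval(iv.chrom, iv.start, iv.end, f"{name_prefix}_{k}"),
                blk.cpg_sites,
                blk.min_adjacent_r2,
            )
        )
    return named
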