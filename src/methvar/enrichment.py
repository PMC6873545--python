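"""Region-overlap enrichment statistics.

Three tests, mirroring standard practice in regulatory genomics:

* **Permutation test.**  Each query interval is relocated uniformly at
  random within the mappable background segments (length preserved; the
  destination segment is chosen with probability proportional to its
  placeable width).  The statistic is the number of query intervals
  overlapping at least one feature interval (region counting, not base
  pairs).  The empirical p uses the +1 correction,
  p = (1 + #{perm >= observed}) / (n_perm + 1), so it is never exactly 0.
* **Fisher overlap test.**  2×2 table of universe regions (in/out of the
  query × with/without the feature label), two-sided exact p.
* **Hypergeometric trait enrichment.**  Candidate-gene sets per trait
  against a query gene set, upper-tail hypergeometric p with BH adjustment
  across traits; traits with <= ``min_genes`` candidates are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicInterval

__all__ = [
    "EnrichmentResult",
    "permutation_enrichment",
    "count_overlapping",
    "fisher_overlap",
    "hypergeom_trait_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    query: str
    feature: str
    observed: int
    perm_mean: float
    z: float
    p_empirical: float
    enrichment_factor: float
    n_perm: int
    alternative: str


def _merged_arrays(intervals: Iterable[GenomicInterval]):
    """chrom -> (starts, ends) of merged, sorted intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        merged = [list(pairs[0])]
        for s, e in pairs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def _overlaps_any(merged, chrom: str, starts: np.ndarray, ends: np.ndarray):
    """Vectorized: does [start, end) hit any merged feature on chrom?"""
    if chrom not in merged:
        return np.zeros(starts.shape, dtype=bool)
    f_starts, f_ends = merged[chrom]
    j = np.searchsorted(f_starts, ends, side="left") - 1
    hit = j >= 0
    hit[hit] = f_ends[j[hit]] > starts[hit]
    return hit


def count_overlapping(
    query: Sequence[GenomicInterval], features: Iterable[GenomicInterval]
) -> int:
    """Number of query intervals overlapping >= 1 feature interval."""
    merged = _merged_arrays(features)
    total = 0
    for iv in query:
        if _overlaps_any(
            merged, iv.chrom, np.array([iv.start]), np.array([iv.end])
        )[0]:
            total += 1
    return total


def permutation_enrichment(
    query: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    alternative: str = "greater",
    query_name: str = "query",
    feature_name: str = "features",
) -> EnrichmentResult:
    """Permutation test of query/feature overlap against the background.

    Each permutation relocates every query interval independently and
    uniformly within the pooled background segments, preserving its length;
    the destination segment is drawn proportional to placeable width
    (segment length − interval length + 1).  ``alternative`` "greater"
    tests enrichment, "less" depletion.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if not query:
        raise ValueError("empty query set")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    merged_features = _merged_arrays(features)

    observed = 0
    for iv in query:
        if _overlaps_any(
            merged_features, iv.chrom, np.array([iv.start]), np.array([iv.end])
        )[0]:
            observed += 1

    seg_chroms = [s.chrom for s in background]
    seg_starts = np.array([s.start for s in background])
    seg_lens = np.array([len(s) for s in background])

    # linearize the background so placements and clipped features share one axis
    seg_offsets = np.concatenate([[0], np.cumsum(seg_lens)])[:-1]
    linear_features: list[tuple[int, int]] = []
    for i, seg in enumerate(background):
        if seg.chrom not in merged_features:
            continue
        f_starts, f_ends = merged_features[seg.chrom]
        lo = np.maximum(f_starts, seg.start)
        hi = np.minimum(f_ends, seg.end)
        for s, e in zip(lo, hi):
            if s < e:
                linear_features.append(
                    (int(s - seg.start + seg_offsets[i]), int(e - seg.start + seg_offsets[i]))
                )
    if linear_features:
        lf = np.array(sorted(linear_features))
        lf_starts, lf_ends = lf[:, 0], np.maximum.accumulate(lf[:, 1])
    else:
        lf_starts = lf_ends = np.array([], dtype=int)

    perm_counts = np.zeros(n_perm, dtype=int)
    for iv in query:
        length = len(iv)
        widths = np.maximum(seg_lens - length + 1, 0)
        total_width = widths.sum()
        if total_width == 0:
            raise ValueError(
                f"query interval of length {length} does not fit in any background segment"
            )
        cum = np.cumsum(widths)
        u = rng.integers(0, total_width, size=n_perm)
        seg_idx = np.searchsorted(cum, u, side="right")
        offset = u - np.concatenate([[0], cum])[seg_idx]
        lin_start = seg_offsets[seg_idx] + offset
        lin_end = lin_start + length
        if lf_starts.size:
            j = np.searchsorted(lf_starts, lin_end, side="left") - 1
            hit = j >= 0
            hit[hit] = lf_ends[j[hit]] > lin_start[hit]
        else:
            hit = np.zeros(n_perm, dtype=bool)
        perm_counts += hit

    perm_mean = float(perm_counts.mean())
    perm_sd = float(perm_counts.std(ddof=1)) if n_perm > 1 else math.nan
    z = (observed - perm_mean) / perm_sd if perm_sd and perm_sd > 0 else math.nan
    if alternative == "greater":
        extreme = int(np.sum(perm_counts >= observed))
    else:
        extreme = int(np.sum(perm_counts <= observed))
    p_emp = (1 + extreme) / (n_perm + 1)
    factor = observed / perm_mean if perm_mean > 0 else math.inf
    return EnrichmentResult(
        query_name, feature_name, observed, perm_mean, z, p_emp, factor,
        n_perm, alternative,
    )


def fisher_overlap(
    query_names: Iterable[str],
    feature_labels: Mapping[str, bool],
    universe_names: Iterable[str],
) -> dict:
    """Two-sided Fisher's exact test on query membership × feature label.

    ``feature_labels`` must cover every universe region.  Returns the 2×2
    table, odds ratio (ad/bc; 0.5 continuity applied and flagged when any
    cell is zero) and exact p.
    """
    universe = list(universe_names)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_names)
    if not query <= set(universe):
        raise ValueError("query must be a subset of the universe")
    a = b = c = d = 0
    for name in universe:
        feat = bool(feature_labels[name])
        if name in query:
            a, b = a + feat, b + (not feat)
        else:
            c, d = c + feat, d + (not feat)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    continuity = 0 in (a, b, c, d)
    if continuity:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        odds = (aa * dd) / (bb * cc)
    else:
        odds = (a * d) / (b * c)
    return {
        "table": [[a, b], [c, d]],
        "odds_ratio": float(odds),
        "p": float(p),
        "continuity_corrected": continuity,
    }


def hypergeom_trait_enrichment(
    trait_sets: Mapping[str, Iterable[str]],
    query_genes: Iterable[str],
    universe_genes: Iterable[str],
    min_genes: int = 5,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of the query in each trait set.

    Traits with <= ``min_genes`` candidate genes are skipped (strictly more
    than ``min_genes`` required).  p = P(X >= overlap) with population =
    universe, successes = trait set, draws = query; BH-adjusted across the
    tested traits.  Returns a frame indexed by trait.
    """
    universe = set(universe_genes)
    query = set(query_genes) & universe
    if not set(query_genes) <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for trait, genes in trait_sets.items():
        trait_genes = set(genes) & universe
        if len(trait_genes) <= min_genes:
            continue
        overlap = len(trait_genes & query)
        p = float(
            stats.hypergeom.sf(
                overlap - 1, len(universe), len(trait_genes), len(query)
            )
        )
        rows.append((trait, len(trait_genes), overlap, p))
    if not rows:
        return pd.DataFrame(
            columns=["n_candidates", "overlap", "p", "q"]
        ).rename_axis("trait")
    df = pd.DataFrame(rows, columns=["trait", "n_candidates", "overlap", "p"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.set_index("trait")
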