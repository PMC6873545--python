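"""Segment partitioning and LD-based block calling."""

from __future__ import annotations

import numpy as np
import pytest

from methvar import (
    GenomicInterval,
    ReadHaplotype,
    ReadPool,
    build_segments,
    call_mhbs,
    pairwise_r2,
)
from methvar.mhb import Segment


def reads_from_patterns(patterns, positions=(100, 110), chrom="chr1", sample="S"):
    """Build reads from {pattern: count} over the given sites."""
    return [
        ReadHaplotype(chrom, tuple(positions), pat, sample, count)
        for pat, count in patterns.items()
    ]


class TestBuildSegments:
    def test_span_boundary_exactly_min_size_is_kept(self):
        cov = {"chr1": {0: 12, 40: 12, 79: 12}}
        (seg,) = build_segments(cov, min_coverage=10, min_size=80)
        assert seg.interval.start == 0 and seg.interval.end == 80
        assert seg.cpg_sites == (0, 40, 79)

    def test_low_coverage_site_splits_run(self):
        positions = list(range(0, 500, 20))
        cov = {"chr1": {p: 15 for p in positions}}
        cov["chr1"][240] = 9  # below threshold: breaks the run
        segments = build_segments(cov, min_coverage=10, min_size=80)
        assert len(segments) == 2
        assert all(240 not in seg.cpg_sites for seg in segments)

    def test_short_runs_dropped(self):
        cov = {"chr1": {0: 12, 30: 12}}  # span 31 < 80
        assert build_segments(cov, min_coverage=10, min_size=80) == []

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            build_segments({})

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        positions = np.sort(rng.choice(10_000, size=400, replace=False))
        coverage = rng.integers(0, 30, size=400)
        cov = {"chr1": dict(zip(map(int, positions), map(int, coverage)))}
        segments = build_segments(cov, min_coverage=10, min_size=80)

        # oracle: enumerate maximal runs directly
        expected = []
        run = []
        for pos, c in zip(positions, coverage):
            if c >= 10:
                run.append(int(pos))
            else:
                if run and run[-1] + 1 - run[0] >= 80:
                    expected.append(tuple(run))
                run = []
        if run and run[-1] + 1 - run[0] >= 80:
            expected.append(tuple(run))
        assert [seg.cpg_sites for seg in segments] == expected


class TestPairwiseR2:
    def test_perfect_coupling(self):
        reads = reads_from_patterns({"MM": 5, "UU": 5})
        assert pairwise_r2(reads, "chr1", 100, 110) == pytest.approx(1.0)

    def test_independence(self):
        reads = reads_from_patterns({"MM": 1, "MU": 1, "UM": 1, "UU": 1})
        assert pairwise_r2(reads, "chr1", 100, 110) == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_frequency_formula(self):
        # {MM x6, MU x2, UM x1, UU x3}: p_A=8/12, p_B=7/12, p_AB=6/12
        reads = reads_from_patterns({"MM": 6, "MU": 2, "UM": 1, "UU": 3})
        p_a, p_b, p_ab = 8 / 12, 7 / 12, 6 / 12
        expected = (p_ab - p_a * p_b) ** 2 / (p_a * (1 - p_a) * p_b * (1 - p_b))
        assert pairwise_r2(reads, "chr1", 100, 110) == pytest.approx(expected, abs=1e-15)

    def test_monomorphic_site_undefined(self):
        reads = reads_from_patterns({"MM": 6, "MU": 6})
        assert pairwise_r2(reads, "chr1", 100, 110) is None

    def test_insufficient_co_coverage_undefined(self):
        reads = reads_from_patterns({"MM": 2, "UU": 1})
        assert pairwise_r2(reads, "chr1", 100, 110, min_pair_reads=4) is None
        assert pairwise_r2(reads, "chr1", 100, 110, min_pair_reads=3) == pytest.approx(1.0)

    def test_uncovered_pair_undefined_not_error(self):
        reads = reads_from_patterns({"MM": 5})
        assert pairwise_r2(reads, "chr1", 100, 999) is None

    def test_equals_squared_pearson_and_invariances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            a = rng.integers(0, 2, size=n)
            b = rng.integers(0, 2, size=n)
            if a.std() == 0 or b.std() == 0:
                continue
            reads = [
                ReadHaplotype("chr1", (100, 110), f"{'MU'[1-x]}{'MU'[1-y]}", "S", 1)
                for x, y in zip(a, b)
            ]
            r2 = pairwise_r2(reads, "chr1", 100, 110, min_pair_reads=2)
            oracle = np.corrcoef(a, b)[0, 1] ** 2
            assert r2 == pytest.approx(oracle, abs=1e-12)
            # symmetry in the two sites
            swapped = [
                ReadHaplotype("chr1", (100, 110), rec.states[::-1], "S", 1)
                for rec in reads
            ]
            assert pairwise_r2(swapped, "chr1", 100, 110, min_pair_reads=2) == pytest.approx(r2, abs=1e-12)
            # global M<->U relabelling leaves r² unchanged
            flipped = [
                ReadHaplotype(
                    "chr1", (100, 110),
                    rec.states.translate(str.maketrans("MU", "UM")), "S", 1,
                )
                for rec in reads
            ]
            assert pairwise_r2(flipped, "chr1", 100, 110, min_pair_reads=2) == pytest.approx(r2, abs=1e-12)

    def test_multiplicity_expansion_invariance(self):
        collapsed = reads_from_patterns({"MM": 6, "MU": 2, "UM": 1, "UU": 3})
        expanded = [
            ReadHaplotype("chr1", (100, 110), rec.states, "S", 1)
            for rec in collapsed
            for _ in range(rec.multiplicity)
        ]
        assert pairwise_r2(collapsed, "chr1", 100, 110) == pytest.approx(
            pairwise_r2(expanded, "chr1", 100, 110), abs=1e-15
        )
        # read order is irrelevant
        assert pairwise_r2(expanded[::-1], "chr1", 100, 110) == pytest.approx(
            pairwise_r2(expanded, "chr1", 100, 110), abs=1e-15
        )


def _segment(sites):
    return Segment(
        GenomicInterval("chr1", sites[0], sites[-1] + 1),
        tuple(sites),
        tuple(999 for _ in sites),
    )


def _coupled_reads(sites, pair_r, rng, n=400):
    """Reads whose every adjacent pair has population r² ≈ pair_r[i]²."""
    reads = []
    for _ in range(n):
        states = [rng.random() < 0.5]
        for r in pair_r:
            keep = rng.random() < (1 + r) / 2  # correlation r between adjacent sites
            states.append(states[-1] if keep else not states[-1])
        reads.append(
            ReadHaplotype(
                "chr1", tuple(sites), "".join("M" if s else "U" for s in states), "S", 1
            )
        )
    return reads


class TestCallMhbs:
    def test_fully_coupled_segment_gives_one_block(self):
        sites = [0, 10, 20, 30, 40]
        reads = reads_from_patterns(
            {"MMMMM": 20, "UUUUU": 20}, positions=sites
        )
        (block,) = call_mhbs(_segment(sites), reads)
        assert block.cpg_sites == tuple(sites)
        assert block.min_adjacent_r2 == pytest.approx(1.0)
        assert block.interval.end == sites[-1] + 1

    def test_weak_pair_breaks_block_and_short_fragment_dropped(self):
        # adjacent r² pattern (high, low, high, high) over 5 sites:
        # left fragment of 2 CpGs is discarded, right fragment of 3 kept
        sites = [0, 10, 20, 30, 40]
        rng = np.random.default_rng(0)
        reads = _coupled_reads(sites, [0.95, 0.1, 0.95, 0.95], rng, n=2000)
        blocks = call_mhbs(_segment(sites), reads)
        assert len(blocks) == 1
        assert blocks[0].cpg_sites == (20, 30, 40)

    def test_undefined_pair_breaks_block(self):
        # middle site covered by no read together with its right neighbour
        sites = [0, 10, 20, 30, 40]
        left = reads_from_patterns({"MMM": 10, "UUU": 10}, positions=sites[:3])
        right = reads_from_patterns({"MM": 10, "UU": 10}, positions=sites[3:])
        blocks = call_mhbs(_segment(sites), left + right)
        assert len(blocks) == 1  # only the left trio reaches min_cpgs
        assert blocks[0].cpg_sites == (0, 10, 20)

    def test_raising_threshold_never_adds_cpgs(self):
        sites = list(range(0, 120, 10))
        rng = np.random.default_rng(5)
        reads = _coupled_reads(sites, rng.uniform(0.3, 1.0, size=len(sites) - 1), rng)
        pool = ReadPool(reads)
        total_cpgs = []
        for thr in (0.3, 0.5, 0.7, 0.9):
            blocks = call_mhbs(_segment(sites), pool, r2_threshold=thr)
            total_cpgs.append(sum(b.n_cpg for b in blocks))
        assert total_cpgs == sorted(total_cpgs, reverse=True)

    def test_planted_blocks_recovered_and_gaps_clean(self, block_fixture_dataset):
        from methvar.pipeline import run_mhb_stage
        from methvar.synthetic import block_recovery

        ds = block_fixture_dataset
        _, mhbs = run_mhb_stage(ds.reads, ds.counts)
        stats = block_recovery(ds.truth, mhbs)
        assert stats["n_planted"] == 20
        assert stats["recovered"] >= 18
        assert stats["false_calls"] == 0
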