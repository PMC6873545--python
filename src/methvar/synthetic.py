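"""Synthetic WGBS read-haplotype, genotype and phenotype generator.

The generator emulates the data regime of a sperm-methylome cohort study:
~28 samples, read-level methylation haplotypes over a dense CpG map, pooled
coverage well above the 10× segment rule, planted correlated-CpG blocks,
three inter-individual variance classes, cis-SNP effects on region
methylation and trait effects of region methylation with one
population-structure confounding axis.

**Read model.**  Within a planted block, each read draws a latent
all-methylated / all-unmethylated state with probability π_s (the sample's
latent level); each CpG copies the latent state with probability
``coupling`` and is otherwise an independent Bernoulli(π_s) draw; every
emitted call is then flipped with probability ``per_cpg_error``.  This
mixture-of-monomorphic-haplotypes model produces tunable adjacent-CpG r²
(the quantity the block caller consumes); at coupling 1 and zero error
every read is monomorphic, at coupling 0 within-sample LD vanishes.  Gap
CpGs between planted blocks get an independent per-site, per-sample latent
level, so pooled LD across samples also vanishes there (no Simpson-effect
coupling).

**Variance classes.**  Per-sample latent levels π_s are Beta draws:
hypo-CMR ~ Beta(10, 90) (mean 0.10, SD 0.03), hyper-CMR its mirror
Beta(90, 10), HVMR an equal mixture of Beta(8, 2) and Beta(2, 8) (bimodal,
SD ≈ 0.32), neutral ~ Beta(8, 8) (mean 0.5, SD ≈ 0.12).  These defaults
put the conserved classes' SD well below, and the HVMR SD well above, the
cohort-median SD at the default coverage.

**Randomness.**  One root seed feeds a ``numpy`` ``SeedSequence``; child
streams are spawned in a fixed order (CpG map, block layout/levels,
genotypes, reads, phenotypes) so stages can be re-run independently and
identical configs give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    ReadHaplotype,
    write_bed,
    write_config,
    write_haplotype_file,
    write_matrix_tsv,
)

__all__ = [
    "SimulationConfig",
    "PlantedBlock",
    "TruthTable",
    "SyntheticDataset",
    "CLASS_LEVEL_DEFAULTS",
    "simulate_cpg_map",
    "simulate_sample_levels",
    "simulate_reads",
    "simulate_genotypes",
    "simulate_genotypes_and_phenotypes",
    "simulate_dataset",
    "write_dataset",
]

CLASS_LABELS = ("HVMR", "hypoCMR", "hyperCMR", "neutral")

#: Hyperparameters for the per-sample latent level of each variance class.
#: "mixture": components of (weight, a, b) Beta draws per sample.
#: "symmetric": one Beta(k, k) per region with k ~ Uniform(k_range), giving a
#: continuum of inter-individual SDs around the cohort median — the bulk of
#: unremarkable regions real cohorts show.
CLASS_LEVEL_DEFAULTS: dict[str, dict] = {
    "hypoCMR": {"kind": "mixture", "components": ((1.0, 10.0, 90.0),)},
    "hyperCMR": {"kind": "mixture", "components": ((1.0, 90.0, 10.0),)},
    "HVMR": {"kind": "mixture", "components": ((0.5, 8.0, 2.0), (0.5, 2.0, 8.0))},
    "neutral": {"kind": "symmetric", "k_range": (2.0, 12.0)},
}

#: CpG run length of the uncoupled gaps separating planted blocks.
GAP_N_CPGS = (3, 6)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 28
    n_chromosomes: int = 1
    chrom_length: int = 120_000
    cpg_spacing_mean: float = 25.0
    n_blocks_per_class: Mapping[str, int] = field(
        default_factory=lambda: {
            "HVMR": 20, "hypoCMR": 20, "hyperCMR": 20, "neutral": 60
        }
    )
    block_n_cpgs: tuple[int, int] = (4, 8)
    coupling: float = 0.95
    per_cpg_error: float = 0.005  # bisulfite non-conversion / miscall rate
    mean_coverage: float = 20.0
    read_span_cpgs: int = 2  # CpGs per sequenced fragment
    n_snps: int = 60  # ~ cis SNPs per region at the default window
    maf_range: tuple[float, float] = (0.1, 0.5)
    meqtl_effect: float = 1.0  # logit-scale shift per alternate allele
    n_meqtl: int = 5
    n_traits: int = 5
    n_trait_pairs: int = 3
    trait_effect: float = 0.5  # phenotype units per M-value unit
    trait_noise_sd: float = 1.0
    confound_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coupling", "per_cpg_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_samples", "n_chromosomes", "chrom_length", "n_snps",
                     "n_traits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cpg_spacing_mean < 2:
            raise ValueError("cpg_spacing_mean must be >= 2 bp")
        if self.block_n_cpgs[0] < 3:
            raise ValueError("planted blocks need >= 3 CpGs")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        unknown = set(self.n_blocks_per_class) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")


@dataclass(frozen=True)
class PlantedBlock:
    name: str
    interval: GenomicInterval
    label: str
    cpg_positions: tuple[int, ...]
    pi: np.ndarray  # per-sample latent level, length n_samples


@dataclass
class TruthTable:
    """Ground truth for every planted feature of one synthetic cohort."""

    blocks: list[PlantedBlock]
    gap_intervals: list[GenomicInterval]
    meqtl_pairs: list[tuple[str, str, float]]  # (region, snp, gamma)
    trait_pairs: list[tuple[str, str, float]]  # (region, trait, effect)

    def blocks_by_label(self, label: str) -> list[PlantedBlock]:
        return [b for b in self.blocks if b.label == label]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    truth: TruthTable
    cpg_map: dict[str, np.ndarray]
    reads: list[ReadHaplotype]
    counts: dict[str, pd.DataFrame]  # sample -> (chrom,pos)-indexed m/t table
    genotypes: pd.DataFrame  # samples × SNPs dosage
    snp_positions: pd.DataFrame  # SNP id -> chrom, pos
    phenotypes: pd.DataFrame  # samples × traits

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes.index)


# ---------------------------------------------------------------------------
# stage 1: CpG site map


def simulate_cpg_map(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Geometric-gap CpG site positions per chromosome.

    Inter-site gaps are iid Geometric with mean ``cpg_spacing_mean``
    (support >= 1); positions are strictly increasing and truncated at the
    chromosome length.  May legitimately be empty when the mean spacing
    far exceeds the chromosome length.
    """
    if config.chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    rng = rng or np.random.default_rng(_streams(config.seed)["cpg_map"])
    out: dict[str, np.ndarray] = {}
    p = 1.0 / config.cpg_spacing_mean
    for c in range(config.n_chromosomes):
        n_draw = max(int(2 * config.chrom_length * p) + 16, 16)
        gaps = rng.geometric(p, size=n_draw)
        positions = np.cumsum(gaps) - 1  # first site may sit at 0
        positions = positions[positions < config.chrom_length]
        while positions.size and positions[-1] + 1 < config.chrom_length:
            extra = rng.geometric(p, size=n_draw)
            more = positions[-1] + np.cumsum(extra)
            positions = np.concatenate([positions, more[more < config.chrom_length]])
            if more[-1] >= config.chrom_length:
                break
        out[f"chr{c + 1}"] = positions.astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# stage 2: latent per-sample levels


def simulate_sample_levels(
    class_label: str,
    n_samples: int,
    rng: np.random.Generator,
    params: Mapping[str, tuple] | None = None,
) -> np.ndarray:
    """Per-sample latent methylation levels π_s for one planted region."""
    table = params or CLASS_LEVEL_DEFAULTS
    if class_label not in table:
        raise ValueError(f"unknown class label {class_label!r}")
    spec = table[class_label]
    if spec["kind"] == "symmetric":
        lo, hi = spec["k_range"]
        k = rng.uniform(lo, hi)
        return rng.beta(k, k, size=n_samples)
    components = spec["components"]
    weights = np.array([w for w, _, _ in components])
    choice = rng.choice(len(components), size=n_samples, p=weights / weights.sum())
    a = np.array([components[c][1] for c in choice])
    b = np.array([components[c][2] for c in choice])
    return rng.beta(a, b)


# ---------------------------------------------------------------------------
# stage 3: reads


def simulate_reads(
    chrom: str,
    positions: Sequence[int],
    pi,
    sample_id: str,
    mean_coverage: float,
    coupling: float,
    per_cpg_error: float,
    rng: np.random.Generator,
    read_span_cpgs: int | None = None,
) -> tuple[list[ReadHaplotype], np.ndarray]:
    """Reads for one sample over one CpG run, plus exact per-CpG tallies.

    ``pi`` is either a scalar latent level (planted block: one latent state
    per read) or a per-site vector (gap run: sites independent).  Each read
    is a fragment covering ``read_span_cpgs`` consecutive sites (``None`` =
    the whole run): fragments start at every eligible site with a Poisson
    count tuned so interior sites see ~``mean_coverage`` reads (edge sites
    see proportionally fewer starts, as in real sequencing).  Returns
    (reads, counts) where counts is an (n_sites, 2) array of
    (methylated, total) equal to the read tallies exactly.
    """
    positions = tuple(int(p) for p in positions)
    n_sites = len(positions)
    if n_sites == 0:
        raise ValueError("need >= 1 CpG site")
    pi_vec = np.broadcast_to(np.asarray(pi, dtype=float), (n_sites,)).astype(float)
    span = n_sites if read_span_cpgs is None else max(1, min(read_span_cpgs, n_sites))
    n_starts = n_sites - span + 1
    lam = mean_coverage if n_starts == 1 else mean_coverage / span

    counts = np.zeros((n_sites, 2), dtype=np.int64)
    reads: list[ReadHaplotype] = []
    for i in range(n_starts):
        k = int(rng.poisson(lam))
        if k == 0:
            continue
        sub_pi = pi_vec[i : i + span]
        latent = rng.random(k) < float(sub_pi.mean())
        copy_latent = rng.random((k, span)) < coupling
        independent = rng.random((k, span)) < sub_pi
        states = np.where(copy_latent, latent[:, None], independent)
        if per_cpg_error > 0:
            states ^= rng.random((k, span)) < per_cpg_error
        counts[i : i + span, 0] += states.sum(axis=0)
        counts[i : i + span, 1] += k
        patterns, multiplicity = np.unique(states, axis=0, return_counts=True)
        sub_pos = positions[i : i + span]
        for pattern, mult in zip(patterns, multiplicity):
            reads.append(
                ReadHaplotype(
                    chrom,
                    sub_pos,
                    "".join("M" if s else "U" for s in pattern),
                    sample_id,
                    int(mult),
                )
            )
    return reads, counts


# ---------------------------------------------------------------------------
# stage 4: genotypes, meQTL effects, phenotypes


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """SNP dosages, SNP positions and the latent structure axis.

    Dosages are Binomial(2, MAF).  The structure axis u_s = ±1 splits the
    cohort in half; for half of the SNPs the per-sample allele frequency is
    tilted by ±0.15·confound_strength along u, so a genotype PCA recovers
    the axis on its first component.
    """
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    snp_ids = [f"snp_{j + 1:04d}" for j in range(config.n_snps)]
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=config.n_snps)
    u = np.where(np.arange(config.n_samples) < config.n_samples // 2, -1.0, 1.0)
    tilt_mask = rng.random(config.n_snps) < 0.5
    tilt = 0.15 * config.confound_strength
    freq = np.clip(
        maf[None, :] + np.where(tilt_mask[None, :], tilt * u[:, None], 0.0),
        0.01,
        0.99,
    )
    dosage = rng.binomial(2, freq)
    chroms = rng.integers(1, config.n_chromosomes + 1, size=config.n_snps)
    pos = rng.integers(0, config.chrom_length, size=config.n_snps)
    snp_positions = pd.DataFrame(
        {"chrom": [f"chr{c}" for c in chroms], "pos": pos}, index=snp_ids
    ).rename_axis("snp")
    genotypes = pd.DataFrame(dosage, index=samples, columns=snp_ids).rename_axis(
        "sample"
    )
    return genotypes, snp_positions, u


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_genotypes_and_phenotypes(
    config: SimulationConfig,
    truth: TruthTable,
    rng_geno: np.random.Generator,
    rng_pheno: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw genotypes, plant cis effects into truth π, and draw phenotypes.

    meQTL pairs shift logit(π_s) by γ·dosage_s *before* read simulation
    (the caller must therefore invoke this between level and read stages).
    Phenotypes are y = b·M(region) + confound·u + N(0, noise²) with one
    planted region per associated trait; M(region) is the logit2 of the
    latent level.  Raises when a planted pair references an unknown region.
    """
    genotypes, snp_positions, u = simulate_genotypes(config, rng_geno)
    blocks_by_name = {b.name: b for b in truth.blocks}

    for region, snp, gamma in truth.meqtl_pairs:
        if region not in blocks_by_name:
            raise ValueError(f"meQTL pair references unplanted region {region!r}")
        if gamma == 0:
            continue
        block = blocks_by_name[region]
        block.pi[:] = rng_geno.beta(12.0, 12.0, size=block.pi.size)
        dose = genotypes[snp].to_numpy(dtype=float)
        block.pi[:] = _expit(_logit(block.pi) + gamma * dose)

    samples = list(genotypes.index)
    traits = [f"trait_{t + 1}" for t in range(config.n_traits)]
    y = rng_pheno.normal(0.0, config.trait_noise_sd, size=(len(samples), len(traits)))
    y += config.confound_strength * u[:, None]
    for region, trait, effect in truth.trait_pairs:
        if region not in blocks_by_name:
            raise ValueError(f"trait pair references unplanted region {region!r}")
        if trait not in traits:
            raise ValueError(f"trait pair references unknown trait {trait!r}")
        m_vals = np.log2(np.clip(blocks_by_name[region].pi, 1e-6, 1 - 1e-6))
        m_vals -= np.log2(1 - np.clip(blocks_by_name[region].pi, 1e-6, 1 - 1e-6))
        y[:, traits.index(trait)] += effect * m_vals
    phenotypes = pd.DataFrame(y, index=samples, columns=traits).rename_axis("sample")
    return genotypes, snp_positions, phenotypes


# ---------------------------------------------------------------------------
# full pipeline


def _streams(seed: int) -> dict[str, np.random.SeedSequence]:
    names = ("cpg_map", "layout", "genotypes", "reads", "phenotypes")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return dict(zip(names, children))


def _layout_blocks(
    config: SimulationConfig,
    cpg_map: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[list[PlantedBlock], list[tuple[str, tuple[int, ...], np.ndarray]]]:
    """Assign disjoint CpG runs to planted blocks (shuffled classes) and gaps.

    Returns (blocks, gap_units) where each gap unit carries per-site,
    per-sample latent levels.  Layout walks each chromosome alternating
    gap run, block, gap run, …; raises when the CpG map cannot host all
    requested blocks.
    """
    labels: list[str] = []
    for label in CLASS_LABELS:
        labels.extend([label] * int(config.n_blocks_per_class.get(label, 0)))
    rng.shuffle(labels)

    blocks: list[PlantedBlock] = []
    gap_units: list[tuple[str, tuple[int, ...], np.ndarray]] = []
    label_iter = iter(labels)
    pending = next(label_iter, None)
    block_id = 0
    for chrom in sorted(cpg_map):
        sites = cpg_map[chrom]
        cursor = 0
        while pending is not None and cursor < sites.size:
            gap_len = int(rng.integers(GAP_N_CPGS[0], GAP_N_CPGS[1] + 1))
            gap_sites = sites[cursor : cursor + gap_len]
            if gap_sites.size:
                gap_pi = rng.beta(2.0, 2.0, size=(gap_sites.size, config.n_samples))
                gap_units.append((chrom, tuple(int(p) for p in gap_sites), gap_pi))
            cursor += gap_len
            n_cpg = int(rng.integers(config.block_n_cpgs[0], config.block_n_cpgs[1] + 1))
            if cursor + n_cpg > sites.size:
                break
            member = sites[cursor : cursor + n_cpg]
            cursor += n_cpg
            block_id += 1
            name = f"block_{block_id:04d}"
            pi = simulate_sample_levels(pending, config.n_samples, rng)
            blocks.append(
                PlantedBlock(
                    name,
                    GenomicInterval(chrom, int(member[0]), int(member[-1]) + 1, name),
                    pending,
                    tuple(int(p) for p in member),
                    pi,
                )
            )
            pending = next(label_iter, None)
        # trailing gap so the last block has uncoupled flanks
        if cursor < sites.size:
            gap_len = int(rng.integers(GAP_N_CPGS[0], GAP_N_CPGS[1] + 1))
            gap_sites = sites[cursor : cursor + gap_len]
            gap_pi = rng.beta(2.0, 2.0, size=(gap_sites.size, config.n_samples))
            gap_units.append((chrom, tuple(int(p) for p in gap_sites), gap_pi))
    if pending is not None:
        raise ValueError(
            "CpG map too small for the requested blocks; increase chrom_length "
            "or lower n_blocks_per_class"
        )
    return blocks, gap_units


def _plant_pairs(
    config: SimulationConfig,
    blocks: Sequence[PlantedBlock],
    snp_positions: pd.DataFrame,
) -> tuple[list, list]:
    """Choose (region, SNP, γ) and (region, trait, b) planted pairs.

    meQTL effects go on neutral blocks (mid-range latent levels make the
    logit shift most visible), nearest same-chromosome SNP to the block
    midpoint; trait effects on HVMR blocks (the variable tier entering
    association).
    """
    meqtl_pairs = []
    neutral = [b for b in blocks if b.label == "neutral"]
    hvmr = [b for b in blocks if b.label == "HVMR"]
    hosts = (neutral + hvmr)[: config.n_meqtl]
    for block in hosts:
        same = snp_positions[snp_positions["chrom"] == block.interval.chrom]
        if same.empty:
            continue
        mid = (block.interval.start + block.interval.end) // 2
        snp = (same["pos"] - mid).abs().idxmin()
        meqtl_pairs.append((block.name, snp, config.meqtl_effect))

    trait_pairs = []
    trait_hosts = [b for b in hvmr if b.name not in {m[0] for m in meqtl_pairs}]
    for t, block in enumerate(trait_hosts[: min(config.n_trait_pairs, config.n_traits)]):
        trait_pairs.append((block.name, f"trait_{t + 1}", config.trait_effect))
    return meqtl_pairs, trait_pairs


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one fully self-consistent synthetic cohort."""
    streams = _streams(config.seed)
    rng_map = np.random.default_rng(streams["cpg_map"])
    rng_layout = np.random.default_rng(streams["layout"])
    rng_geno = np.random.default_rng(streams["genotypes"])
    rng_reads = np.random.default_rng(streams["reads"])
    rng_pheno = np.random.default_rng(streams["phenotypes"])

    cpg_map = simulate_cpg_map(config, rng_map)
    blocks, gap_units = _layout_blocks(config, cpg_map, rng_layout)

    # genotypes must exist before reads so cis effects can shift π
    genotypes, snp_positions, _u = simulate_genotypes(config, rng_geno)
    meqtl_pairs, trait_pairs = _plant_pairs(config, blocks, snp_positions)
    truth = TruthTable(
        blocks,
        [GenomicInterval(c, p[0], p[-1] + 1) for c, p, _ in gap_units if len(p) >= 2],
        meqtl_pairs,
        trait_pairs,
    )
    blocks_by_name = {b.name: b for b in blocks}
    # meQTL host regions: genotype is the dominant variance source, so the
    # residual (non-genetic) latent spread is tightened before the shift
    for region, snp, gamma in meqtl_pairs:
        if gamma != 0:
            block = blocks_by_name[region]
            block.pi[:] = rng_layout.beta(12.0, 12.0, size=block.pi.size)
            dose = genotypes[snp].to_numpy(dtype=float)
            block.pi[:] = _expit(_logit(block.pi) + gamma * dose)

    samples = list(genotypes.index)
    all_reads: list[ReadHaplotype] = []
    count_rows: dict[str, list] = {s: [] for s in samples}
    # planted blocks carry the configured within-read coupling; gap runs are
    # fully uncoupled (independent latent level per site) so no LD arises there
    units: list[tuple[str, tuple[int, ...], object, float]] = [
        (b.interval.chrom, b.cpg_positions, b.pi, config.coupling) for b in blocks
    ] + [(chrom, pos, pi, 0.0) for chrom, pos, pi in gap_units]
    units.sort(key=lambda u: (u[0], u[1][0]))
    for chrom, positions, pi, coupling in units:
        per_site = np.asarray(pi)
        for s_idx, sample in enumerate(samples):
            pi_s = per_site[:, s_idx] if per_site.ndim == 2 else float(per_site[s_idx])
            reads, counts = simulate_reads(
                chrom, positions, pi_s, sample,
                config.mean_coverage, coupling, config.per_cpg_error,
                rng_reads, config.read_span_cpgs,
            )
            all_reads.extend(reads)
            for pos, (m, t) in zip(positions, counts):
                count_rows[sample].append((chrom, pos, int(m), int(t)))

    counts = {}
    for sample in samples:
        df = pd.DataFrame(
            count_rows[sample], columns=["chrom", "pos", "methylated", "total"]
        ).set_index(["chrom", "pos"])
        counts[sample] = df.sort_index()

    # phenotypes come last: they read the final (possibly shifted) π
    traits = [f"trait_{t + 1}" for t in range(config.n_traits)]
    y = rng_pheno.normal(0.0, config.trait_noise_sd, size=(len(samples), len(traits)))
    y += config.confound_strength * _u[:, None]
    for region, trait, effect in trait_pairs:
        pi = np.clip(blocks_by_name[region].pi, 1e-6, 1 - 1e-6)
        y[:, traits.index(trait)] += effect * (np.log2(pi) - np.log2(1 - pi))
    phenotypes = pd.DataFrame(y, index=samples, columns=traits).rename_axis("sample")

    return SyntheticDataset(
        config, truth, cpg_map, all_reads, counts, genotypes, snp_positions,
        phenotypes,
    )


# ---------------------------------------------------------------------------
# truth evaluation


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Overlap length divided by the *longer* interval (0 when disjoint)."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    return max(ov, 0) / max(len(a), len(b))


def block_recovery(
    truth: TruthTable,
    called: Sequence,
    min_reciprocal: float = 0.8,
) -> dict:
    """Compare called blocks against the planted truth.

    ``called`` is a list of objects with an ``interval`` attribute.  A
    planted block is *recovered* when some called block matches it at
    reciprocal overlap >= ``min_reciprocal``; a called block is a *false
    call* when it overlaps no planted block at all (it lies in the
    uncoupled gaps).
    """
    truth_ivs = [b.interval for b in truth.blocks]
    called_ivs = [c.interval for c in called]
    recovered = sum(
        any(reciprocal_overlap(t, c) >= min_reciprocal for c in called_ivs)
        for t in truth_ivs
    )
    false_calls = sum(
        all(reciprocal_overlap(t, c) == 0.0 for t in truth_ivs) for c in called_ivs
    )
    return {
        "n_planted": len(truth_ivs),
        "n_called": len(called_ivs),
        "recovered": recovered,
        "false_calls": false_calls,
    }


def match_truth_labels(
    truth: TruthTable, classification, called_regions
) -> pd.DataFrame:
    """Best-overlap assignment of classifier labels to planted blocks.

    ``classification``: VariabilityResult list; ``called_regions``: the MHB
    list the classification refers to.  Returns a frame with one row per
    planted block (truth label, assigned label, overlap); blocks with no
    overlapping call get label "unrecovered".
    """
    by_name = {c.region: c for c in classification}
    rows = []
    for block in truth.blocks:
        best, best_ov = None, 0.0
        for region in called_regions:
            name = region.interval.name
            if name not in by_name:
                continue
            ov = reciprocal_overlap(block.interval, region.interval)
            if ov > best_ov:
                best, best_ov = by_name[name], ov
        rows.append(
            (
                block.name,
                block.label,
                best.label if best is not None else "unrecovered",
                best_ov,
            )
        )
    return pd.DataFrame(
        rows, columns=["block", "truth_label", "called_label", "overlap"]
    ).set_index("block")


# ---------------------------------------------------------------------------
# writers


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write every table of the dataset as headerless-stable TSV/BED files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_haplotype_file(ds.reads, outdir / "haplotypes.tsv")
    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    for sample, table in ds.counts.items():
        table.reset_index().to_csv(
            counts_dir / f"{sample}.tsv", sep="\t", index=False
        )
    write_matrix_tsv(ds.genotypes, outdir / "genotypes.tsv")
    write_matrix_tsv(ds.phenotypes, outdir / "phenotypes.tsv")
    ds.snp_positions.reset_index().to_csv(
        outdir / "snp_positions.tsv", sep="\t", index=False
    )
    write_bed(
        [b.interval for b in ds.truth.blocks],
        outdir / "truth_blocks.bed",
    )
    truth_rows = pd.DataFrame(
        {
            "name": [b.name for b in ds.truth.blocks],
            "chrom": [b.interval.chrom for b in ds.truth.blocks],
            "start": [b.interval.start for b in ds.truth.blocks],
            "end": [b.interval.end for b in ds.truth.blocks],
            "label": [b.label for b in ds.truth.blocks],
            "n_cpg": [len(b.cpg_positions) for b in ds.truth.blocks],
            "mean_pi": [float(np.mean(b.pi)) for b in ds.truth.blocks],
        }
    )
    truth_rows.to_csv(outdir / "truth_blocks.tsv", sep="\t", index=False)
    pd.DataFrame(
        ds.truth.meqtl_pairs, columns=["region", "snp", "gamma"]
    ).to_csv(outdir / "truth_meqtl.tsv", sep="\t", index=False)
    pd.DataFrame(
        ds.truth.trait_pairs, columns=["region", "trait", "effect"]
    ).to_csv(outdir / "truth_traits.tsv", sep="\t", index=False)
    cfg = {k: v for k, v in ds.config.__dict__.items() if k != "n_blocks_per_class"}
    for label, n in ds.config.n_blocks_per_class.items():
        cfg[f"n_blocks_{label}"] = n
    write_config(cfg, outdir / "config.txt")
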