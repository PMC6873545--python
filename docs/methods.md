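# Methods

This note documents the statistical procedures, the generative model behind
the synthetic cohorts, the defaults and the numerical choices. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from memory.

## 1. Segments and methylation haplotype blocks

**Segments.** CpG sites are partitioned into maximal runs whose pooled
(all-sample) read coverage is ≥ `min_coverage` (default 10); a run is kept
as a mappable segment when its genomic span (last site + 1 − first site)
is ≥ `min_size` (default 80 bp). A single under-covered site splits its
run. Segments are the unit inside which blocks are called and the
background for permutation enrichment.

**Pairwise r².** For two adjacent CpGs, only reads covering *both* sites
contribute, pooled over all samples and weighted by record multiplicity.
With methylated-state frequencies p_A, p_B and joint frequency p_AB,
r² = (p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B)). The value is *undefined*
(not zero) when fewer than `min_pair_reads` (default 4) reads co-cover the
pair or when either site is monomorphic among them. Undefined pairs
**break** blocks: absence of evidence of coupling is not evidence of
coupling. The statistic equals the squared Pearson correlation of the two
binary read-state vectors (property-tested to 1e-12).

**Caller.** A greedy left-to-right scan: a block extends while the next
adjacent pair has defined r² ≥ `r2_threshold` (default 0.5); maximal runs
with ≥ `min_cpgs` (default 3) CpGs are emitted, carrying their minimum
adjacent r². Blocks are therefore disjoint, within one segment, and span
[first CpG, last CpG + 1) in 0-based half-open coordinates. Greedy maximal
runs (rather than an optimised partition) are a deliberate, documented
choice; raising the threshold can only shrink the total CpG content of
called blocks (tested monotonicity).

## 2. Region methylation

β = Σmᵢ/Σtᵢ over a region's member CpGs — each *read*, not each CpG, has
equal weight. The coverage rule for a defined cell is mean per-CpG
coverage ≥ `min_cov` (default 5); a strict per-CpG variant (every site
individually ≥ min_cov) is available via `per_cpg=True`. The mean reading
was chosen as the default because fragment ends systematically
under-cover the first and last CpG of a region, and a per-site rule would
discard otherwise well-measured cells. Regions with more than `max_na`
missing samples are dropped; `max_na=None` scales the published 13-of-28
rule as ceil(0.46·n).

## 3. Variability classification

σ₀ is the median over regions of the sample SD (ddof = 1) of the defined
β values, computed once from the NA-filtered matrix. Per region with n
defined samples and SD s:

* **SD variance test**: X = (n−1)s²/σ₀² referred to χ²(n−1); upper-tail p
  when s > σ₀ ("above"), lower-tail when s ≤ σ₀ ("below"). The test is
  one-sided in the observed direction because the classification rules
  condition on direction separately; a two-sided option (doubled p) is
  exposed and is what the type-I calibration checks, since the
  direction-agnostic event {p ≤ α} has probability 2α for the one-sided
  construction. n is the region's defined-sample count, not the cohort
  size.
* **CpG-observation chi-square**: per-sample aggregated (methylated,
  unmethylated) read counts over the region form a k×2 table; Pearson
  chi-square with df = k−1, no continuity correction, zero-total samples
  excluded. No low-expected-count pooling is applied; a warning is logged
  when any expected cell is < 5. Aggregated read-level counts per sample
  are used as the "individual observations".

With R regions tested and family-wise levels `alpha_hvmr` (0.01) and
`alpha_vmr` (1e-4), per-test cuts are alpha/R. HVMR requires both tests
below the cut with direction "above"; hypo-/hyper-CMR require the SD test
below the cut with direction "below" and mean β ≤ 0.2 / ≥ 0.8 (the SD
test only — whether the conserved tiers also required the count test is
left as stated, SD-only). VMR status uses only the CpG-count test at the
lenient level plus complete observation across samples. At R = 29,542 the
cuts reproduce the printed 3.39e-7 and 3.39e-9.

## 4. Association and cis-meQTL

β is clipped into [1e-6, 1−1e-6] before M = log2(β/(1−β)) so boundary
values stay finite; the bound only matters for exactly-0/1 cells.
Genotype PCA standardises dosages (monomorphic SNPs dropped), takes the
top components of the sample covariance, and fixes signs by making each
component's largest-magnitude loading positive (deterministic output).
Two PCs are used by default.

OLS of y on [1, PC1, PC2, M] is computed by residualising y and M on the
covariate block (Frisch–Waugh), which vectorises across regions; the
slope, SE, t and two-sided p (df = n − 4 with two PCs) are identical to a
full OLS fit (cross-checked against statsmodels). Constant-M regions are
reported untestable (NaN), never raised. Tiers with R tested regions:
significant p < 0.05/R, suggestive p < 1/R (disjoint by construction).
No mixed-model relatedness correction is applied — structure is handled
by the PCs only — and phenotype reliabilities are not used as weights;
both are stated limitations.

cis-SNP selection is boundary-based: a SNP is cis when its distance to
the nearest edge of [start, end) is ≤ `window` (1 Mb, inclusive); the
signed distance reported uses the region midpoint for readability. SNP
pre-filter: monomorphic SNPs are dropped, as are SNPs with exactly two
observed genotype classes whose rarer class has < 3 individuals (three
observed classes are always kept). The scan is additive-dosage OLS with
optional covariates; BH adjustment is applied jointly over all tested
(region, SNP) pairs, and q ≤ 0.2 is significant.

## 5. Enrichment statistics

The permutation test relocates each query interval independently and
uniformly within the pooled background segments, preserving its length
(destination segment drawn proportional to placeable width,
len − L + 1). The statistic is the number of query intervals overlapping
≥ 1 feature (region counting, not base pairs). The empirical p uses the
+1 correction, p = (1 + #{perm ≥ obs})/(n_perm + 1), so the floor at
1000 permutations is 1/1001. Per-chromosome placement is *not* enforced
by default (segments are pooled genome-wide); the caller can restrict
placement by passing per-chromosome backgrounds. The Fisher test counts
regions (in/out of query × with/without feature) with a two-sided exact
p; the odds ratio is ad/bc, with 0.5 added to every cell (and flagged)
when any cell is zero. Trait enrichment is an upper-tail hypergeometric
per trait (candidate sets with ≤ 5 genes skipped), BH-adjusted across
the tested traits.

## 6. The synthetic cohort generator

The generator emulates a sperm-WGBS cohort: one latent methylation level
π_s per sample per planted region, short sequenced fragments carrying
coupled CpG states, per-CpG counts that tally the emitted reads exactly,
SNP dosages with one population-structure axis, and continuous traits.

**Read model.** Each fragment covers `read_span_cpgs` (default 2)
consecutive CpGs; fragment counts per start position are Poisson with a
rate tuned so interior sites see ~`mean_coverage` (default 20) reads
(edge sites see proportionally fewer, as in real data). Per fragment a
latent all-M/all-U state is drawn with probability π_s; each CpG copies
it with probability `coupling` (default 0.95) and is otherwise an
independent Bernoulli(π_s) draw; each emitted call flips with probability
`per_cpg_error` (default 0.005, a typical bisulfite
non-conversion/miscall rate). This mixture-of-monomorphic-haplotypes
model is what gives adjacent CpGs tunable r² — a per-CpG-independent
model cannot plant blocks at all. Gap runs between planted blocks draw
an independent latent level per *site* per sample, so both within-read
and pooled between-sample LD vanish there (pooling samples with shared
per-region levels would otherwise manufacture LD by a Simpson effect).
Fragments never span the boundary between two planted units, so boundary
pairs are undefined and blocks terminate there; with ≥ 10 co-covering
reads a defined near-zero r² in the gaps does the same job.

**Variance classes.** Latent levels per class: hypo-CMR ~ Beta(10, 90)
(mean 0.10, SD 0.03); hyper-CMR its mirror Beta(90, 10); HVMR an equal
mixture of Beta(8, 2) and Beta(2, 8) (bimodal, SD ≈ 0.32 — the
distributional form of real HVMRs is unknown, and the bimodal default is
an explicit modelling choice exposed through `CLASS_LEVEL_DEFAULTS`);
neutral regions draw one concentration k ~ Uniform(2, 12) per region and
then Beta(k, k) per sample, producing a continuum of inter-individual
SDs that straddles the cohort median. The default composition
(20/20/20/60 hypo/hyper/HVMR/neutral) makes the unremarkable bulk the
majority, as in real cohorts, which in turn places σ₀ inside the neutral
continuum rather than at a cluster boundary.

**Genotypes, meQTLs, traits.** Dosages are Binomial(2, MAF) with MAF ~
U(0.1, 0.5) over 60 SNPs (≈ the number of cis SNPs per region at the
1 Mb window). A ±1 structure axis u splits the cohort; half the SNPs'
frequencies are tilted by 0.15·`confound_strength` along u, so genotype
PCA recovers the axis. Planted cis effects shift logit(π_s) by
γ·dosage_s (γ = `meqtl_effect`, default 1.0) *before* read simulation;
host regions get a tight residual Beta(12, 12) latent first, emulating
meQTLs whose variance is genotype-dominated. Trait effects add
b·M(π_s) (b = `trait_effect`) plus `confound_strength`·u and Gaussian
noise (SD 1) to the phenotype; one region per associated trait.

**Randomness.** One root seed feeds `numpy.random.SeedSequence`; five
child streams are spawned in fixed order (CpG map, layout/levels,
genotypes, reads, phenotypes). Identical configs give byte-identical
output files (tested).

**What the generator does not emulate.** Alignment and conversion
chemistry, read-length heterogeneity, chromosome-scale coverage waves,
pedigree relatedness beyond one structure axis, heritability structure
of the phenotypes, and LD between SNPs. Passing tests therefore
demonstrate correctness of the *inference machinery* under a faithful
block/variance/effect structure, not performance on real sperm WGBS.

## 7. Problem sizes and calibration checks

The default cohort is 28 samples × 120 planted blocks (~1,000 CpGs,
~70,000 read records) — small enough to simulate in seconds while giving
each region ~40–70 fragments per sample. Fixtures used by the suite and
the acceptance script: 20-block genomes for caller recovery (reciprocal
overlap ≥ 0.8), the default cohort for the 60-block classification check,
5,000-region nulls for variance-test size, 250 × 20 null tests for
association uniformity (KS), 15 × 2 planted pairs at b/σ = 1.5 and n = 19
for sign recovery, 25 null and 10 effect replicates for meQTL FDR and
top-rank recovery, exhaustive small tables plus random margins ≤ 20 for
the Fisher oracle, and 120 runs × 1000 permutations for the z
calibration. Null-z calibration uses a feature set dense enough that the
overlap count is approximately symmetric; with very sparse features the
count is Poisson-skewed and the +3σ tail genuinely exceeds its Gaussian
bound — a property of the statistic, not a defect of the test.

## 8. Known limitations

* The one-sided-in-observed-direction variance test doubles the nominal
  direction-agnostic rejection rate; consumers filtering on direction
  (as the classifier does) get the nominal level.
* σ₀ is a cohort-level plug-in; no uncertainty in the median is
  propagated into the per-region χ² reference.
* BH control in the meQTL scan is over dependent tests (shared regions);
  BH remains valid under the positive dependence typical here but is not
  exact.
* The permutation test's uniform relocation ignores local covariates
  (GC, CpG density) that real enrichment analyses sometimes match on.
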