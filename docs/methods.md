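# Methods

## Overview

`sweepscan` implements a composite selection scan for multi-group SNP
panels: five established selection/diversity statistics per SNP or
25-SNP window, combined into a Decorrelated Composite of Multiple
Signals (DCMS), converted to q-values, parsed into candidate selection
regions with ranked genes and flagged missense variants, and masked
against copy-number-variable regions (CNVRs). A forward Wright–Fisher
simulator with planted sweeps provides synthetic study populations so
every stage is testable without external data.

## Statistics and their site domains

All coordinates are 1-based inclusive; missing values propagate as NaN
and are never zero-filled.

Two quality-control filter sets, applied in the fixed order
per-sample missingness (`mind`) → per-SNP missingness (`geno`) →
minor-allele frequency (`maf`), define two site domains, and each
statistic lives on the domain where it is informative:

* **Light / phased track** (`maf 1e-7, geno 0.1, mind 0.1`): Garud's
  H12 and H2/H1 (sliding windows of 25 SNPs, step 1, anchored at the
  central SNP) and Tajima's D on the same windows. Dense windows keep
  D defined inside sweep footprints, where segregating sites are
  scarce.
* **Strict / common-variant track** (`maf 0.05, geno 0.01, mind
  0.05`): Weir–Cockerham F_ST (focal group vs pooled remainder,
  negatives truncated to 0) and its 31-SNP running median. Rare
  variants carry almost no allele-frequency information; on an
  all-sites track they drown the F_ST running median.
* **π** is computed per site as 2·n_alt·n_ref/(n(n−1)) on sites
  polymorphic *within the focal group* (the per-group-file analogue of
  a minimal MAF filter) and smoothed with a 31-SNP running median over
  that domain. Sites monomorphic in the group would otherwise pile an
  enormous tie block at π = 0 that flattens the left-tail ranks.

The per-statistic tables are then joined by SNP id into one panel;
each statistic keeps its own ranking depth.

Numerical choices: windows never span chromosomes and chromosomes
with fewer SNPs than the window yield no windows; the running median
shrinks symmetrically at chromosome ends (width 1 at the first/last
SNP) and drops NaNs within each window; Tajima's D uses the minimum
called chromosome count across a window's sites for its constants and
is NaN for S = 0 or n < 4; F_ST is NaN when either side has < 2 called
diploids or the site is monomorphic overall.

## The composite

Empirical one-tailed p-values come from genome-wide ranking
(right-tailed for H2/H1, H12 and smoothed F_ST; left-tailed for
smoothed π and D); ties share the count of values at least as extreme,
so p ∈ [1/n, 1]. The 5×5 correlation matrix is a Minimum Covariance
Determinant estimate (FAST-MCD: 500 random elemental (p+1)-subsets,
two concentration steps each, the ten best candidates iterated to
convergence, h = ⌈α·n⌉ with α = 0.75) on complete-case rows sampled
without replacement (default cap 300,000; desk-scale studies use all
rows). Rows with any missing statistic are excluded from covariance
sampling and carry a missing DCMS.

DCMS_i = Σ_s log10((1−p_si)/p_si)/w_s with w_s = Σ_t |r_st| (diagonal
included). Only the boundary values p ≥ 1 (and p ≤ 0, unreachable for
rank p) are clipped, to n/(n+1) and 1/(n+1) of the statistic's own
ranking depth, keeping the log-odds finite.

DCMS values are fitted to a normal distribution by regressing the
ordered values on standard-normal plotting quantiles (i−½)/n with a
Huber M-estimator (intercept = μ, slope = σ); p_i = 1 − Φ((DCMS_i −
μ)/σ). q-values use Storey's method: π₀(λ) on the grid 0.05…0.95
(step 0.05) smoothed by a cubic polynomial — the closed-form analogue
of a heavily smoothed df-3 spline — evaluated at λ = 0.95 and clipped
to (0, 1], then the step-up q_i = min_{p_t ≥ p_i} π₀·n·p_t/rank(p_t).
Below 20 p-values Storey is unstable and the code falls back to
Benjamini–Hochberg with a warning.

## Regions, genes, missense candidates, CNVRs

A selection region is a maximal run, in SNP-index order within a
chromosome, of SNPs with q < 0.2 containing at least one SNP with
q < 0.01; a SNP at or above the boundary (or with missing q) breaks
the run. The peak is the minimum q (ties: larger DCMS, then smaller
position). An optional maximum bp gap (off by default) can break runs
on sparse panels. Genes overlapping a region are ranked by distance to
the peak SNP (0 inside the gene, else distance to the nearer
boundary; ties by gene start; top 10 kept). Missense SNPs among region
members are flagged: `peak_missense` (the region's peak), `fst_support`
(smoothed F_ST ≥ 0.3), `haplotype_support` (H12 or H2/H1 empirical
p < 0.01 — a configurable operationalization of "strong haplotype
support", which has no canonical number).

Per-sample CNV calls with normal dosage (CN 1–3) are discarded; CN 0
(losses) and CN ≥ 4 (gains) are consolidated separately per group and
chromosome by single-linkage over the ≥50%-reciprocal-overlap graph;
connected components supported by ≥ 3 distinct samples become CNVRs
spanning the union of their calls; identical CNVRs are deduplicated
and touching/overlapping CNVRs merged (support sets united). Any
selection region sharing ≥ 1 bp with a same-group CNVR is moved to an
excluded list with the offending CNVR recorded; retained + excluded
always partition the input.

## The synthetic-data generator

The generator emulates breed-structured livestock data: an ancestral
population at mutation–drift equilibrium splits into breed-like demes
that exchange rare migrants, and a study samples a few dozen animals
per deme. Standing variation at the split is supplied by a coalescent
simulation (msprime) at the ancestral size — a forward burn-in of 4N
generations would converge to exactly that state while dominating the
runtime — and the forward Wright–Fisher engine (non-overlapping
generations, fitness-weighted parent sampling, Poisson crossovers on
an integer bp grid, infinite-sites mutation with collision redraws,
fixed/lost columns pruned) owns everything after: deme formation,
migration, and selection.

A planted sweep is hard (one new copy) or soft (standing variation at
a start frequency); fitness is additive, 1 + s per copy in the focal
deme and, by default, 1 − s per copy elsewhere — divergent selection,
the standard model of local adaptation, without which migration
exports the allele and the sweep is not breed-private. Runs restart
from the introduction point (fresh randomness, up to 50 times) when
the allele is lost, or, when `require_frequency` is set, when the
focal frequency at sampling falls short — conditional-on-establishment
(and optionally on near-fixation) sampling.

Default study conditions (`experiments.SWEEP_STUDY`): two demes of 400
diploids from an 800-diploid ancestor, 50 diploids sampled per deme,
150 forward generations, migration 0.001, μ = 2.5×10⁻⁷ per bp per
generation, r = 2.5×10⁻⁷ per adjacent pair, a 1 Mb forward chromosome plus
four coalescent neutral chromosomes of the same length and demography.
These numbers are chosen from first principles rather than realism:

* A sweep outruns drift only when N·s ≫ ln 2N; at 50-diploid demes
  N·s = 5 ≈ ln 2N and the footprint refills as fast as it forms, so
  breeds must be larger than the sequenced sample (as in reality).
* The footprint width ≈ s/(r·ln 2N) (~60 kb here) must span several
  25-SNP windows, and the mostly-clean core ≈ 1/(r·T_fix) (~30 kb).
* Sampling happens at/near fixation (T_fix ≈ (2/s)·ln 2N ≈ 130
  generations after the split): at these population sizes the
  signature decays on the 2N-generation timescale.
* The swept footprint must be a small fraction of the genome-wide
  panel, as it is of a real multi-chromosome genome; genome-wide
  empirical ranks saturate otherwise. Hence the neutral chromosomes,
  generated directly with the coalescent under the same demography.

What the generator does *not* emulate: realistic ovine demography or
recombination maps, genotyping error, multi-allelic sites, sex
chromosomes, gene conversion, background selection. Passing tests show
the pipeline's statistics are correct and that it finds strong fresh
sweeps in clean data; they do not show field performance on real
genomes.

## Measured operating characteristics

The acceptance machinery (tests/test_acceptance.py,
scripts/acceptance.py) recomputes, per run: agreement of the five
statistics with first-principles oracles (≤10⁻⁹), FAST-MCD vs
exhaustive subset search (100 bivariate trials), Huber-fit parameter
recovery (±0.05; ≤5% under 1% contamination), neutral calibration
(fraction of SNPs at q < 0.01 under the null; ~10⁻⁴ observed), and
sweep-detection power at the study conditions. Power is the honest
weak point of desk-scale data: with s = 0.1, 50-diploid samples and a
5 Mb panel, roughly half of near-fixed sweeps yield a q < 0.01 region
at the sweep (the development runs measured 10/20). Three structural
reasons, in decreasing order: the right-tailed H2/H1 term actively
cancels H12 at hard sweeps (a hard sweep minimizes H2/H1, so its
log-odds contribution is negative); the empirical-rank floor 1/n caps
every statistic's contribution at log10(n)/w_s, so a desk-scale panel
cannot accumulate the extreme composite scores a multi-million-SNP
genome can; and the sweep's own plateau (~2% of the panel) inflates
the Huber σ estimate, deflating every z-score. Detections that do
occur are essentially always at the planted sweep — the neutral
false-positive rate at q < 0.01 is ~0.01% of SNPs.

## Pipeline and reproducibility

`pipeline.run_scan` orchestrates load → QC → per-group statistics →
DCMS → regions → gene ranking → missense flags → CNVR masking →
writers from a JSON manifest; every stage is a pure function of
(inputs, manifest, seed), outputs are TSVs with fixed column order
plus a provenance JSON, and each written file is sha256-logged. The
`sweepscan` command exposes `simulate`, `run` and `cnvr`. Haplotype
statistics require fully phased input; unphased VCFs are rejected with
an instruction to phase upstream (synthetic data is born phased).
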