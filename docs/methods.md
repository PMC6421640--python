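# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the `coldgwas` pipeline. Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Phenotype construction

The temperature-maintenance phenotype is the area under an animal's
body-temperature curve over a five-day cold window, in °C·h. Readings
arrive at a nominal 15-minute cadence; we average them within clock hours,
linearly interpolate hours without readings (flagging them) and reject a
series outright when more than 20% of window hours are empty — RFID
dropouts are expected in field telemetry, and a harder failure should not
silently produce a phenotype. The window is the contiguous five-day span
minimising mean ambient temperature (ties to the earliest start); if no
ambient record is supplied the caller passes the window explicitly.
Integration uses the trapezoid rule on the 120 hourly means, so a constant
38.0 °C animal scores 38.0 × 119 = 4522 °C·h.

The NAWAC allowable core-temperature band for cattle (36.5–40.5 °C) is
applied to hourly means within the analysis window, boundary values
inclusive-keep. Applying it to hourly means rather than raw readings is a
choice: hourly means are the analysis unit, and raw 15-minute spikes are
dominated by sensor noise.

## Sample and marker QC

Sample filters run before marker filters: NAWAC exclusion, then per-sample
heterozygosity (> 70% of called genotypes heterozygous ⇒ likely
contamination; the threshold is strict-greater, so exactly 0.70 keeps).
Marker filters run in a fixed order — unplaced contigs, sex chromosomes,
call rate (> 10% missing fails), MAF (< 0.05 fails, computed on non-missing
calls), exact Hardy–Weinberg test (p < 10⁻⁶ fails) — and the removal ledger
telescopes by construction; the order is fixed for determinism of that
ledger since a single command-line invocation of the usual tooling does not
define one. The HWE test is the exact conditional (Wigginton-style) test:
the sum of probabilities of all heterozygote-count configurations, given
the allele counts, no more probable than the observed one; it is evaluated
in log-space with a 1+10⁻¹² tie tolerance and cached per genotype triple.

PCA standardizes dosages per SNP by 2p̂ and √(2p̂(1−p̂)) with mean
imputation of missing calls, takes the SVD, and verifies breed labels by
nearest-centroid assignment on (PC1, PC2) with centroids from the declared
labels — a reproducible analogue of reassigning labels by eye from a
cluster plot. Degenerate inputs (no genetic variance, coincident
centroids) refuse reassignment rather than guessing. LD pruning follows
sliding-window semantics (window 100 SNPs, step 5, r² > 0.7 removes the
later SNP of a pair).

## Mixed-model GWAS

The association model is y = μ + Xβ + α + e with α ~ N(0, K σ²ₐ) and
e ~ N(0, I σ²ₑ); sex, breed and the allele dosage are fixed effects. The
kinship matrix is the Balding–Nichols-normalized (standardized)
relationship matrix, K_ij = m⁻¹ Σₛ (x_is − 2p̂ₛ)(x_js − 2p̂ₛ)/(2p̂ₛ(1−p̂ₛ)),
with per-SNP frequencies from the analyzed samples and mean imputation of
missing dosages. This is the form implied by the Balding–Nichols
frequency model (between-population dosage variance 2Fp(1−p)): diagonals
sit near 1 + inbreeding, off-diagonals near zero for unrelated pairs
(up to a −1/(n−1) sample-centering offset), and every entry is invariant
to allele-orientation flips. K is symmetrized and stabilized by adding
εI (ε = 10⁻⁶·tr(K)/n) if its smallest eigenvalue is negative.

REML maximizes the restricted likelihood over δ = σ²ₑ/σ²ₐ after rotating
by the eigenvectors of K, on a 100-point grid over log δ ∈ [−10, 10]
followed by bounded local refinement (tolerance 10⁻⁸); a boundary hit is
flagged, not hidden. Per-SNP tests hold the null variance components fixed
(the EMMAX approximation) and compute the GLS coefficient of the dosage by
weighted residualization in the rotated basis — algebraically identical to
an explicit V⁻¹ solve per SNP, which the test suite verifies to 10⁻⁸.
Wald p-values use the standard normal reference, matching the convention
of the approximation's reference implementation; at n ≈ 200 the difference
from a t reference is negligible relative to the tolerances used anywhere
downstream. Collinear or monomorphic SNPs are flagged with missing p.
Under strong two-breed structure with realistic LD the REML profile in δ
is flat, so single-dataset heritability estimates scatter widely around
the truth; the test suite therefore checks that the estimator is centered
across seeds rather than tight per draw.

Inflation is λ = median(χ²)/0.4549 over the per-SNP 1-df chi-squares;
multiplicity uses Benjamini–Hochberg q-values with 0.05/0.10 as the
significant/suggestive thresholds.

## Haplotype blocks and trend regression

Blocks are called on phased haplotypes by the solid-spine rule: a block
[i..j] requires D′ ≥ 0.8 between SNP i and every SNP in (i, j] and between
SNP j and every SNP in [i, j). The scan is greedy left-to-right per
chromosome, taking for each feasible start the largest valid end
(the first-SNP condition is prefix-monotone, which bounds the search);
emitted blocks have ≥ 2 SNPs and never overlap, and a block-size cap
(default 200 SNPs) bounds worst-case work. Monomorphic markers have
undefined D′ and can never satisfy a spine, so they are excluded from the
scan rather than allowed to break otherwise-solid blocks — without this, a
single fixed site inside a swept region fragments every block around it.
Haploview's additional block-size and MAF sub-rules are deliberately not
replicated; the spine criterion is applied pure.

Within a block, haplotypes are exact SNP-string classes over the 2n
chromosomes; classes at frequency ≤ 1% are dropped, and each individual is
scored 0/1/2 copies of each retained class. The phenotype is adjusted by
OLS on [1, sex, breed] and the residual regressed on the haplotype dosage
matrix. Because the full dosage matrix is collinear with the intercept
(rows sum to 2), the most frequent haplotype is dropped as the reference
and the joint F-test runs on the remaining h−1 coefficients
(df₁ = h−1, df₂ = n−h) — the standard identifiable form of haplotype trend
regression. For a two-haplotype block this reduces exactly to dosage
regression. Genomic control (rescaling 1-df chi-squares so λ → 1) is
applied to the HTR scan only when λ > 1; the kinship-corrected SNP scan is
left unadjusted, mirroring the asymmetric treatment appropriate when only
the uncorrected scan is inflated.

## Selection statistics and DCMS

Per focal SNP a centered window of 31 SNPs (configurable; truncated at
chromosome edges, missing below 5 SNPs) yields H1 = Σpᵢ²,
H12 = (p₁+p₂)² + Σ_{i>2}pᵢ² over the window's haplotype frequency
spectrum, π (mean pairwise difference per site) and Tajima's D with the
1989 constants computed from the haplotype count. The window size is a
desk-scale default chosen for stability of the haplotype spectrum at
2n ≈ 400 chromosomes and is flagged prominently in the configuration; no
single published value governs it. Tail directions are fixed a priori from
sweep expectations: upper for H1/H12, lower for π and D.

Each statistic becomes a one-sided fractional-rank p-value
(rank/(N+1) genome-wide, average ties, complemented for upper-tail
statistics so extremes are small). DCMS combines them as
Σₛ wₛ⁻¹ ln((1−p)/p) with wₛ the row sum of absolute Pearson correlations
among the raw statistic values (pairwise-complete); duplicated statistics
therefore collapse to a single contribution, and a missing p contributes
nothing with the remaining weights renormalized. The natural log is used;
the choice of log base rescales scores without reordering them. Scores are
calibrated by a Huber M-estimate of location (c = 1.345, iterated to
10⁻⁸ — the rlm-style fit of scores on an intercept) and a 1.4826×MAD scale
(IQR fallback if the MAD degenerates), then converted to upper-tail normal
p-values and Storey q-values (π₀ from the smoother over λ = 0.05..0.95,
implemented as a cubic fit evaluated at λ = 0.95 and clipped to (0, 1];
`method="bh"` forces π₀ = 1 and reproduces Benjamini–Hochberg exactly).

## Region calling and annotation

Regions are maximal runs of SNPs with adjusted p ≤ 0.1 containing at least
one seed (p < 0.05); a missing p acts as a boundary, single-SNP regions
are allowed, and touching extensions merge so output regions never
overlap. GWAS SNPs take genes within ±250 kb (interval intersection,
1-based closed coordinates; BED input is shifted on read). Selection
regions take genes within one σ of the peak, where σ is the standard
deviation of member-SNP positions weighted by their minimum-shifted
composite scores — the reading of "one σ of the statistic distribution"
under which sharp single-SNP peaks give σ → 0 and few genes while broad
plateaus give many, which is the behaviour the procedure is meant to have.
Genes are ranked by distance from the peak (0 if spanning it), ties by
name. Overlap reports give pairwise and full-set interval intersections
with the member SNPs shared by all participants.

## The synthetic-data generator

The generator defines the study conditions; it is not a tuning dial.

* **Population.** Two breeds of 100 individuals each (≈ 200 animals, the
  scale of the motivating design). Ancestral allele frequencies are
  Uniform(0.05, 0.95); each breed's frequencies are Balding–Nichols draws
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.05 by default — closely related
  breeds with moderate differentiation, enough for PCA to separate them.
* **LD.** Each breed has a pool of 30 founder haplotypes whose alleles
  follow an AR(1) Gaussian copula along the chromosome (correlation 0.9
  per SNP step, restarting at chromosome boundaries), thresholded at the
  per-site frequency so marginals are exact. Individuals' haplotypes are
  recombinant mosaics of the pool (switch probability 0.02 per SNP step).
  This produces solid-spine blocks with a median of ~3 SNPs covering most
  of the genome — chip-like block structure — while remaining desk-scale
  and dependency-free; it was chosen over a coalescent simulator for
  exactly that controllability.
* **Phenotype.** Latent mean temperature = 38.5 °C + 0.1 (sex 2)
  + 0.15 (breed 2) + genetic value + per-animal environmental deviate;
  genetic values (β·dosage at one causal SNP plus a 100-SNP polygenic
  background with N(0, σ_g²/100) effects, σ_g = 0.15 °C) are centered so
  38.5 °C is the population mean. The environmental variance is set from
  the realized genetic variance to hit the target heritability (default
  0.3); reading noise (sd 0.3 °C per 15-minute reading) contributes
  negligibly to the AUC after hourly averaging. Fourteen days of readings
  are emitted; designated misplaced-sensor animals read ~35 °C (below the
  NAWAC floor) and overheating ones 41.5 °C, so the phenotype module flags
  them by construction. The default QTL site is the mid-genome SNP with
  MAF in [0.2, 0.45], so the planted signal survives the MAF filter.
* **Sweeps.** A hard sweep replaces a chosen fraction of haplotypes in an
  interval with one donor haplotype. For the "QTL inside a sweep"
  scenario, the causal SNP is chosen after sweep planting among interval
  SNPs still segregating at MAF ∈ [0.15, 0.45] (a swept-to-fixation QTL
  has no association signal to recover), and genetic values are recomputed
  from the post-sweep genotypes. That scenario uses sweep fraction 0.8 and
  β = 0.3 °C — a strong sweep that leaves the large-effect variant
  segregating.
* **Ledger fixtures.** Two deterministic fixtures mirror chip-scale
  bookkeeping: a 139,376-marker table whose planted failures trip exactly
  one filter each (24 samples, genotype patterns chosen so the HWE-exact
  failure is unambiguous at p < 10⁻⁷), and a 197-animal telemetry set with
  11 low and 1 high misplaced sensors plus 2 planted 80%-heterozygosity
  samples among the survivors.
* **Seeding.** One global seed fans out to per-stage substreams
  (map, frequencies, pools, mosaics, genetics, temperature, ambient), so
  every stage is bit-reproducible in isolation.

What the generator does **not** emulate: realistic bovine recombination
maps, X chromosomes, genotyping error, array ascertainment bias, selection
acting during the simulation (sweeps are planted post hoc), or weather
more structured than a smooth cold dip with noise. Passing tests therefore
demonstrate the pipeline's internal correctness and calibration under the
assumed statistical structure, not performance on real chip data.

## Problem sizes used by the tests and the reproduction script

Unit tests run at desk scale (tens of samples, hundreds of markers) with
brute-force oracles. The acceptance suite uses 200 animals × 2,000 SNPs
for the GLS-oracle comparison, 200 × 5,000 × 3 seeds for null calibration
(≥ 10⁴ pooled tests; DCMS tails evaluated on window-thinned SNPs so the
binomial reference is meaningful), and 20 seeds at 400 animals × 3,000
SNPs for recovery. `scripts/acceptance.py` reruns the same designs with
10 seeds per recovery rate. These sizes were chosen as the smallest at
which the statistical claims have adequate power; all scale linearly if
raised.

## Known limitations

* Phasing is consumed, never computed; real data must be phased externally
  (the simulator emits truth phase).
* The HTR F-test assumes independent residuals; it does not correct for
  relatedness (hence the genomic-control step), matching the method it
  implements rather than improving on it.
* Storey's π₀ smoother is a cubic fit to π₀(λ), a close but not identical
  stand-in for a smoothing spline; on null data it agrees with BH within
  a few percent.
* The windowed selection statistics share SNPs between adjacent windows;
  their p-values are locally correlated by construction and should be
  interpreted region-wise, which is how the region caller consumes them.
* `overlap_report` enumerates region combinations and is intended for the
  handful of significant regions a scan produces, not for thousands.
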