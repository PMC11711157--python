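# Methods

`tetrahap` analyses targeted-amplicon genotyping data (DArTag-style MADC
read-count exports) for autotetraploid crops such as alfalfa
(*Medicago sativa*, 2n = 4x = 32). This note records the statistical
model behind every stage, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the places
where the design was genuinely open.

## Input model and filtering

An MADC file lists, per amplicon locus, every distinct microhaplotype
sequence observed and its read depth in every sample. Haplotypes are
classed `Ref`/`Alt` (reference/alternative base at the designed target
SNP, no other variants) or `RefMatch`/`AltMatch` (additional off-target
SNPs). Because each short amplicon with a unique SNP combination behaves
as one allele of a multiallelic marker, a locus can segregate for
several microhaplotypes in a tetraploid.

Retention rules, applied in order (each threshold configurable in
`FilterConfig`):

1. **Microhaplotype level.** `RefMatch`/`AltMatch` records are kept only
   when (a) at least 10 samples carry at least 2 reads of them, and (b)
   they globally align to their locus's reference microhaplotype with
   identity > 0.90 and coverage > 0.90. Identity is matches over columns
   where both sequences contribute a base; coverage is the fraction of
   reference positions aligned to query bases. Alignment is
   match = 1 / mismatch = 0 with a linear −0.5 gap penalty, so gaps only
   open when they buy matches and ties resolve toward fewer gaps.
2. **Sample level.** Samples with zero reads at ≥ 95 % of loci are
   dropped. "Missing" means zero depth; sub-threshold depth is handled
   at the locus rule instead.
3. **Locus level.** A locus needs ≥ 10 samples with ≥ 10 total reads.
   Retained loci still carrying ≥ 10 microhaplotypes are collapsed to
   `Ref` + `Alt` only, since that excess usually signals paralogous
   amplification rather than allelic diversity.

Inclusive vs strict inequalities follow the rule statements exactly
(support/depth thresholds inclusive, alignment thresholds strict).
Whether sample exclusion should precede the haplotype rule is not
determined by the data model; the order above is the default and the
stages are individually callable.

## Dosage calling

Genotypes are integer dosage vectors `d` (non-negative, summing to the
ploidy k = 4). For a locus with A alleles the caller scores all
C(k+A−1, A−1) candidate vectors by posterior
`log P(reads | d) + log P(d | prior)`:

* `P(reads | d)` is Dirichlet-multinomial around expected proportions
  `q_a = (1−ε) d_a/k + ε (1 − d_a/k)/(A−1)` — sequencing errors from
  carried alleles land uniformly on the other alleles — with
  overdispersion ρ (`ρ = 0` is the plain multinomial, α = q(1−ρ)/ρ
  otherwise).
* `P(d | prior)` is multinomial(k, p) at the prior allele frequencies,
  i.e. tetrasomic Hardy–Weinberg with no double-reduction term.

The reported genotype is the MAP vector (ties broken toward the higher
prior probability, then the lexicographically largest vector, i.e.
toward the reference allele), because every downstream statistic
consumes discrete allele counts. Zero total reads give a missing call,
never an error.

**Iterated priors.** Round one uses uniform frequencies; each later
round recomputes per-population allele frequencies from the current
calls (0.5 pseudocount per allele so observed alleles are never zeroed
out) and re-calls with those as priors. Two rounds are the default;
calls typically stabilise after the second. This captures the essential
behaviour of population-structure-aware Bayesian genotypers: ambiguous
read ratios are pulled toward the genotypes plausible in that
population.

**Overdispersion.** ρ is selected from the grid
{0, 0.01, 0.02, 0.05, 0.1} by maximising the summed Dirichlet-
multinomial log-likelihood of high-depth cells (≥ 30 reads, up to 2,000
cells) at provisional maximum-likelihood dosages; fewer than 50 usable
cells fall back to ρ = 0 with a warning. ε defaults to 0.001, a typical
Illumina per-base scale.

**Target-SNP mode** re-calls using only `Ref` and `Alt` read depths
(off-target haplotype reads discarded), giving the biallelic 0–4 dosage
of the designed SNP; loci without an `Alt` record are monomorphic. Note
this conditions on the Ref/Alt haplotype families, which is the
convention of the upstream platform, not a marginal target-SNP
genotype.

## Diversity statistics

Per population (mean over loci unless stated), for ploidy k:

* `H_O`: within-individual gene diversity,
  `1 − Σ_a C(d_a,2)/C(k,2)` — the probability two of the individual's
  allele copies differ; this polyploid definition (rather than the
  fraction of non-homozygous individuals) is the one compatible with
  near-zero F_IS in outcrossing tetraploids.
* `H_S`: small-sample-corrected gene diversity
  `(c/(c−1))(1 − Σ p²)`, c = k × called individuals.
* `N_E`: per-locus `1/(1 − H_S,l)`, then averaged. The pooled form
  `1/(1 − mean H_S)` is systematically smaller (Jensen); the per-locus
  average is the one consistent with effective-allele counts reported
  alongside gene diversities in crop-panel tables.
* `F_IS = 1 − ΣH_O,l / ΣH_S,l` (ratio of sums ≡ ratio of means), so
  monomorphic loci — zero in both — cannot destabilise it.
* `PIC` (Botstein): `1 − Σp_i² − Σ_{i<j} 2 p_i² p_j²`.
* `H_T`: gene diversity of unweighted mean across-population
  frequencies (populations weighted equally, not by sample size).
* `Mon`: percentage of loci with a single observed allele; monomorphic
  loci stay in the H/PIC means (contributing 0) since Mon is tabulated
  separately.

## Differentiation

* `F_ST = (H_T − H_S)/H_T` (Wright / Nei G_ST form).
* `Rho = (H_T − H_S)/(H_T − H_O (k−1)/k)`: subtracting part of the
  observed heterozygosity removes the within-population diversity that
  polysomic inheritance shields from drift, making the statistic
  comparable across ploidy levels and insensitive to double reduction.
  Whenever H_O > 0 and both are defined, Rho ≥ F_ST.
* Multi-locus combining is ratio-of-sums (Σ numerators / Σ
  denominators), the standard guard against small-H_T instability;
  mean-of-ratios is available via `combine="mean"`. Negative estimates
  are floored at 0 and flagged, never silently.
* Pairwise matrices use, per pair: H_S = mean of the two corrected
  within-population diversities, H_T from unweighted mean frequencies,
  H_O = pair mean. Locus-wise F_ST uses all populations, flagging loci
  above 0.2 (the conventional "large effect" cut).
* Private alleles: non-zero in exactly one population with frequency
  > 0.05 there.
* Neighbor joining (Saitou–Nei, via scikit-bio) on the Rho matrix;
  negative branch lengths are floored at 0 with the deficit moved to
  the sibling edge.

### AMOVA

Two strata: among populations (AP) and within populations (AI/WP),
variance components from the standard mean-square identities with the
unequal-size coefficient n0, significance by permuting whole
individuals among populations (sizes preserved). The permuted
among-component is compared to the *unfloored* observed component so
the test stays calibrated when the estimate is negative.

Two unit levels are provided because they estimate different scales:

* `units="copies"` (default): each individual contributes its k allele
  copies as one-hot vectors, so within-individual heterozygosity enters
  the within stratum. %Var among populations then estimates the
  F_ST-scale differentiation (an F = 0.10 cohort yields ≈ 10 %).
* `units="individuals"`: squared Euclidean distance between whole
  dosage vectors. The among term scales with k² while the within term
  scales with k, so %Var lands on the ploidy-corrected (Rho) scale,
  ≈ 4F/(1+3F) for tetraploids — the behaviour of GenoDive-style
  polyploid AMOVA. Useful when results must sit on the same scale as
  Rho matrices.

Missing loci are pairwise-deleted: each pair's squared distance over
shared typed loci is rescaled by total/shared locus counts.

## Population structure

PCA is a column-centred (optionally unit-scaled) SVD; percent variance
from squared singular values; deterministic up to sign. Population-level
PCA runs on the populations × allele-frequency matrix (loci typed in
all populations).

DAPC is deliberately simplified: k-means (10 seeded restarts) on PCs
retaining 80 % of variance, k chosen by the Gaussian-model BIC
`n ln(WSS/n) + k·d·ln n` with d the retained-PC count, then a linear
discriminant projection onto k−1 axes with nearest-centroid
membership. The lighter penalty `k·ln n` (ignoring centroid
dimensionality) was tried first and rejected: it reliably over-splits
well-separated clusters and even single Gaussian blobs, because a
k-means split always buys a WSS reduction worth more than one ln n.
This is an approximation to, not a re-implementation of, adegenet's
`find.clusters`/`dapc`.

## LD decay

r² between biallelic target SNPs is the squared Pearson correlation of
dosages (0–4) over pairwise-complete samples — the composite-LD
analogue needing no phase. Markers below 5 % MAF are excluded; only
same-chromosome pairs within 1 Mb (default) are formed. The decay curve
is the Hill–Weir drift-recombination expectation

    E(r²) = [(10+C)/((2+C)(11+C))] · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]

with C = 4·a·d. A variant of the second factor that circulates in the
applied literature — `(12+4C+C²)` over `n(2+C(11+C))` — is exposed as
`formula="as_printed"`; the standard form is the default, and both are
tested to differ measurably. The fit is nonlinear least squares over
the single coefficient `a` in log space, grid-seeded (25 log-spaced
starts, best SSE) so it is deterministic; the decay distance is the
root of `E(r²)(4ad) = threshold` (default 0.1). Because E(r²) → 1/n at
large distance, thresholds at or below the sampling floor are flagged
as infinite rather than fitted.

## Synthetic cohorts

The generator draws, per locus, an ancestral frequency vector π from a
symmetric Dirichlet (concentration 1), and per population
p ~ Dirichlet(π(1−F)/F) — the multiallelic Balding–Nichols model, whose
analytic variance π(1−π)F ties the F parameter to expected F_ST and
makes parameter-recovery tests possible. F may be one value or one per
population. Individuals are multinomial(k, p) per locus (tetrasomic
HWE); double reduction is not simulated, which is also why Rho is the
appropriate target statistic. Read depth is negative-binomial (mean
100, size 5, matching ~100× amplicon panels with realistic spread);
allele counts are Dirichlet-multinomial around the error-adjusted
proportions of the true dosage (ε = 0.001, ρ = 0 by default); an
adaptor can be appended to a configurable fraction of sequences to
exercise trimming. All draws flow from one seed; identical configs give
byte-identical MADC files.

Presets: `small` (4 populations × 40 plants × 500 loci — the scale used
throughout the test suite and the acceptance script) and `paper_like`
(28 × 44 × 3,000, the scale of a full alfalfa panel).

What the generator does **not** emulate: linkage between loci (loci are
independent, so LD-decay fitting is validated on curve-generated pairs,
not on simulated cohorts), pedigree or selection structure, null
alleles, locus-specific amplification bias, and paralog contamination
beyond what the ≥10-haplotype collapse rule sees. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to every artefact of real amplicon data.

## Numerical choices and degenerate inputs

* MAP ties: posterior ties (within 1e−9 log units) resolve by prior,
  then lexicographically largest dosage vector.
* H = 1 loci are capped in N_E with a warning; H_T = 0 makes F_ST
  undefined (reported missing), as does a non-positive Rho denominator.
* Populations of one individual are excluded from diversity tables and
  AMOVA with warnings; a locus without a `Ref` record is an error.
* Negative pairwise estimates and negative AMOVA components floor at 0
  with flags.
* Missing MADC count cells parse as depth 0 (counted and reported);
  genotype missingness is decided only by read totals.

## Known limitations

* The dosage caller is a self-contained Dirichlet-multinomial MAP
  genotyper; it shares the overdispersion-plus-population-prior design
  of polyRAD-style estimators but makes no claim of call-level numeric
  equivalence with them.
* GenoDive's exact small-sample corrections for polyploid H_S/H_T are
  not public in detail; third-decimal agreement with GenoDive tables is
  not guaranteed.
* Target-SNP mode inherits the platform's conditioning on Ref/Alt
  read families (see above), which inflates SNP-mode differentiation
  slightly relative to the marginal SNP frequencies when off-target
  haplotypes are common.
* The DAPC is a documented approximation, not adegenet.
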