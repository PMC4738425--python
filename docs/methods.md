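# Methods

This note records the models `wildqg` implements, the numerical choices
behind them, what the synthetic-data generator does and does not emulate,
and the problem sizes the test suite runs at.

## Mixed-model engine

The animal model is y = Xb + Σₖ Zₖuₖ + e with uₖ ~ N(0, σ²ₖKₖ) and
e ~ N(0, σ²ₑI).  The restricted log-likelihood
L = −½[log|V| + log|XᵀV⁻¹X| + yᵀPy] is maximised by average-information
(AI) updates with step-halving; when the AI step fails to improve L or
leaves the parameter space, a multiplicative EM-style update
σ²ₖ ← σ²ₖ·√(yᵀPCₖPy / tr(PCₖ)) is used instead.  Variances are projected to
zero at the boundary (the mixture-null LRT assumes boundary fits);
covariance-type components (the cross-population genetic covariance) are
left unconstrained.  Convergence is declared when the change in L falls
below 1e-6; the AI gradient norm at convergence is recorded on the fit.  A
ridge of 1e-6·var(y) is added to V before factorisation.  Standard errors
come from the inverse AI matrix; h² = σ²ₐ/Σσ² carries a delta-method SE.

Models with exactly one relatedness-structured term and one record per
individual use a profiled one-dimensional solver after a single
eigendecomposition of K (cached across fits on the same matrix); it
maximises the identical restricted likelihood, so its L values mix freely
with the general path in likelihood-ratio tests.

Boundary LRTs for one variance use p = ½P(χ²₁ ≥ LRT) (p = 1 when LRT ≤ 0).
The equality-of-variances test between populations fits one model over the
merged data with population-masked genetic components
σ²₁(K∘P₁) + σ²₂(K∘P₂) + c(K∘P₁₂) (c free to be negative) and
per-population residuals, against the σ²₁ = σ²₂ constraint; because the
constraint is interior, the reference distribution is the full χ²₁.

**Expected phenotypic values.** The GWAS response is the per-individual mean
of (observed value − fitted fixed effects − year/nest BLUPs), standardised
to mean 0, variance 1.  The permanent-environment term is deliberately *not*
fitted in the EPV model: with the additive term absent, an individual-level
random effect would absorb precisely the between-individual (genetic) signal
the EPV must retain.

## Relatedness matrices

A is built by the tabular recursion over the subset's full ancestor closure
(inbreeding handled by the recursion).  The raw GRM centres dosages by 2p
(p from the chosen frequency source — the subset, a named population, or the
generator's founder frequencies) and normalises by Σ2p(1−p), with
pairwise-complete sums when dosages are missing.  The GRM is then calibrated
against the pedigree: off-diagonal deviations are rescaled by
var(A)/cov(G, A) over pedigree-linked pairs.  This anchors the *scale* of
relatedness without the shrinkage that a direct variance match would induce
(the spread of G among linked pairs includes Mendelian-sampling variance and
marker noise on top of var(A), so matching standard deviations would bias an
unbiased GRM's regression slope on A below 1).  Blending uses
G\* = wG + (1−w)A with the default w = M/(M + 100): per-pair GRM sampling
variance scales as 1/M while the spread of true relatedness among linked
pairs is ~1e-2, so the entrywise shrinkage optimum signal/(signal + noise)
corresponds to a constant near 100 (configurable).  The cross-population matrix centres each individual's dosages by its own
population's frequencies, which removes the between-population block mean
that pooled centring leaves behind.  A ridge of 1e-6 is available for
factorisation.  The close-relative sub-pedigree keeps genotyped individuals
whose pedigree relatedness to another genotyped individual reaches the
requested degree class (degree k ≈ A ≥ 0.5ᵏ, with a 0.75 factor to absorb
compounded relationships), plus their linking ancestors.

## IBD on a map grid

Expected pairwise IBD at a grid position conditions on the two flanking
markers.  A sequential importance sampler processes individuals
parents-first: founders receive phased alleles consistent with their
observed dosages (phase uniform; missing alleles from the population
frequency), and each non-founder's two meioses are drawn jointly from their
exact local conditional given the parents' phased two-marker haplotypes —
all 16 segregation combinations weighted by their Haldane prior times the
genotype-match indicator — while the particle weight accumulates the local
predictive probabilities.  Keeping parental phase as shared particle state
preserves sib–sib descent correlations.  Indicators at interior grid
positions are then drawn from the exact bridge distribution given the
flanks, and relationship-scale sharing (self ≥ 1, range [0, 2]) is averaged
over weighted particles.  The sampler is unbiased for the
flanking-marker-conditioned expectation (it is not full multipoint); far
from informative markers it reverts to the pedigree expectation, and on
nuclear families it matches brute-force enumeration over segregation vectors
and founder alleles.  Default 300–500 particles per marker interval;
effective sample sizes are logged.  A pre-filter can drop one member of any
marker pair with r² above a cap (default 0.95) before IBD estimation.

## Genome-scan thresholds

LOD = LRT/(2 ln 10).  Nominal significance solves ½P(χ²₁ ≥ q) = 0.05
(LOD 0.588).  Genome-wide levels solve the dense-map expected-exceedance
equation μ(t) = [C + 2ρG(2 ln 10)t]·½P(χ²₁ ≥ (2 ln 10)t) = target by
bisection on (0, 100), with ρ = 1 and targets 1 (suggestive) and 0.05
(significant); values are rounded to 3 decimals for display.  For a
31-chromosome, 19.16-morgan map this gives 1.620 and 3.057 (and 1.86/3.30
for a human-sized 23-chromosome, 33-morgan map — the textbook values).  Scan
calibration is checked empirically: on null scans over the synthetic map the
suggestive threshold is exceeded by about one run of grid positions per
scan.

The power/bias simulation places a QTL at a random grid position, simulates
phenotype = QTL (covariance = the IBD matrix there) + polygenic + residual
on a unit scale, scans, and tabulates detection rates per threshold plus the
mean estimated variance share among significant detections — which exceeds
the simulated share (winner's curse), the reason significant linkage effect
sizes from small pedigrees should not be taken at face value.

## GWAS

The null EPV ~ N(Xb, σ²ₐK + σ²ₑI) is fitted once per trait (K = blended GRM
by default; any relatedness matrix can be passed).  Per SNP,
T = (gᵀV⁻¹r)²/(gᵀV⁻¹g) with the centred dosage g and null residual r,
referred to χ²₁; the effect estimate is gᵀV⁻¹r/(gᵀV⁻¹g).  λ is the median T
over the χ²₁ median.  The effective number of tests is
Σⱼ√(1 − max r²(j, preceding SNPs in a 50-SNP same-chromosome window)), with
an eigenvalue-based count (Σ min(λᵢ, 1) of the SNP correlation spectrum) as
the cross-check; the genome-wide threshold is α/K_eff.  The merged scan
concatenates within-population-standardised EPVs and adds a population
indicator and the top-10 kinship eigenvectors as fixed covariates.
Effect-size correlations compare |β| across SNPs with a one-sided
permutation p (plus-one rule).

## BVSR

y = μ + X_γβ_γ + ε with β_γ ~ N(0, σ²σ²ₐI) and
σ²ₐ = h/((1−h)·π·Σⱼs²ⱼ) — the effect scale anchored through the expected
model size π·p rather than the realised |γ|, so adding SNPs does not cheapen
further additions.  μ and σ² integrate out (flat priors), leaving a marginal
likelihood over (γ, h, π) sampled by Metropolis–Hastings: add/remove/swap
proposals at 40/40/20%, random-walk updates of h (uniform prior, reflected)
and log π (log-uniform on (1/p, 1), reflected).  Per recorded iteration the
model size |γ| and the Rao-Blackwellised PVE — E[Var(Xβ) | y, γ] =
Var(Xβ̂) + E[σ²|y]·tr(XᵀX A⁻¹), scaled by Var(y) — are stored.  Summaries
are medians/means with 95% equal-tail intervals over thinned samples pooled
across chains; each chain must pass a split-half potential-scale-reduction
check (threshold 1.1) on both traces or it is excluded and reported.  The
sampler is validated against exact enumeration of all 2³ models on a 3-SNP
problem.  Missing dosages are mean-imputed for this stage only.  Relatedness
is not modelled here; an option to pre-regress EPVs on top kinship
eigenvectors exists upstream via the merged-scan covariate machinery.

## Concordance tests

Scan-versus-scan correlation permutes whole chromosome blocks of one scan
across the chromosome slots of the other (pairing positions in map order and
truncating the longer block), so the null preserves within-chromosome
autocorrelation; p uses the plus-one rule and can never be 0.  LOD scores
are interpolated linearly at SNP positions (nearest endpoint beyond the
grid, flagged), with p from the mixture null of the implied LRT.  Overlap of
nominal significance between GWAS and interpolated QTL p-values is a 2×2 χ²
(Fisher's exact when an expected cell < 5; degenerate margins are reported
as skipped).  Partitioning-versus-QTL agreement is a two-tailed Fisher test
on significance flags.  The shared-significant-chromosome test reports
P(X ≥ k) with X ~ Binomial(n_sets, (n_A/n_sets)(n_B/n_sets)) by default and
an exact hypergeometric mode as the alternative; the hypergeometric mode
matches exhaustive enumeration.  The between-population correlation of
posterior median SNP counts uses Pearson's r with a t-test on n−2 df,
one-sided by default (the sharing alternative is directional), with the
two-sided value also reported.

## Synthetic data

The generator emulates a two-population nest-box study: random within-
population pairing by cohort, one brood per pair-year, Poisson brood sizes,
per-year survival producing overlapping generations and relatively few
close-relative pairs; Haldane (no interference) recombination along a
configurable map; founder allele frequencies drawn once and perturbed
per-population to a configurable correlation (0.98 by default, which with
drift over ~4 generations yields Hudson F_ST ≈ 0.01–0.02); polygenic,
oligogenic or null architectures with causal SNPs placed uniformly or in
proportion to chromosome gene counts, and a configurable fraction of causal
effects shared between populations; repeated measures; maternal traits
(records attach to the mother's genotype); year, nest and
permanent-environment effects.  Every variance component is rescaled so its
realised fraction matches the request (the residual is additionally
orthogonalised against the breeding values), which is why realised h² hits
the configured value to ~1e-3 — real data offer no such control.  Not
emulated: mutation, selection, migration, genotyping error, pedigree error
(synthetic pedigrees are error-free, so tests say nothing about
misassigned paternity), LD beyond that generated by linkage and drift, and
non-Gaussian traits.  Passing tests therefore demonstrate correctness of
the estimators under the model's own assumptions, not robustness to field
realities.

## Problem sizes in the test suite

Simulation-based checks run at desk scale, chosen to keep the statistical
assertions meaningful: REML recovery uses one population of ~500 individuals
with 10 replicates per h² ∈ {0.2, 0.4, 0.6} for both the pedigree and
blended-GRM estimators under an infinitesimal architecture — every panel SNP
causal, so the GRM's covariance is the generating covariance and the check
isolates estimator bias (assertion: replicate mean within 2 empirical SE of
truth); partitioning discrimination uses 10 chromosomes spanning 20–170 Mbp,
~400 individuals, a polygenic trait at h² = 0.7 with 600 gene-count-weighted
causal SNPs versus a single-QTL trait at h² = 0.3, 10 replicates per
architecture; QTL calibration uses a
~155-individual pedigree over 8 × 60 cM chromosomes, a 5-cM grid, 300
particles, 30 null scans and 6 power replicates per effect size
{0.05, 0.2, 0.4}; GWAS calibration pools 8 null scans of 600 SNPs on 300
related individuals; BVSR coverage uses 10 datasets (n = 1000, 400 SNPs, 20
causal SNPs with Gaussian effects, realised PVE fixed at 0.5 exactly) with
3 chains × 25,000 iterations each, against the production default of
3 × 110,000.  The A-matrix oracle uses 20 random pedigrees with 400,000
gene-drop replicates (tolerance 0.005).

## Known limitations

- The IBD sampler conditions on flanking markers only; multipoint
  information from more distant markers is ignored, costing some precision
  between widely spaced markers.
- BVSR's posterior model size counts every included SNP; in dense panels
  with many undetectably small effects, the interval brackets the number of
  *detectable* contributors plus a noise-driven remainder rather than the
  literal causal count.
- Marker-based h² is mildly biased upward (~+0.03 at h² = 0.6 in our
  simulations) when the causal set is much sparser than the GRM panel: the
  all-marker GRM understates the causal subset's Mendelian-sampling
  deviations, and REML compensates by inflating the genetic variance.  The
  recovery benchmark therefore uses the infinitesimal design; on sparse
  architectures the pedigree model is the less biased of the two.
- The REML engine is dense (O(n³) per iteration) and comfortable to a few
  thousand observations; it makes no attempt at sparse-pedigree shortcuts.
- The cross-population model estimates a single genetic covariance scale;
  it does not fit a full genetic correlation structure per trait pair.

## Repository shape

The package is a library: the importable API plus `examples/` scripts are
the interface, and `wildqg.pipeline.run_pipeline` drives full multi-stage
runs from a single config; no shell entry point is installed because the
intended use is from Python.
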