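# Methods

This note documents the models and numerical choices behind `admixscan`:
what each stage computes, the assumptions it makes, and what the synthetic
cohort generator does and does not emulate.

## The synthetic admixed cohort

The generator emulates a two-population admixture study: a short-statured
forest hunter-gatherer ancestry (P, "Pygmy-like") and an agriculturalist
ancestry (B, "Bantu-like"), with an optional East-African outgroup (M,
"Maasai-like") for three-way branch-length scans.

**Allele frequencies.** Each SNP draws an ancestral alternate-allele
frequency p ~ Uniform(0.05, 0.95); each population then draws its own
frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) — the Balding–Nichols model —
where F is that population's drift from the common ancestor (default 0.1
per population). The Weir–Cockerham ratio-of-averages estimator recovers F
under this model, which is how the generator's differentiation dial is
validated.

**Haplotypes and linkage disequilibrium.** Rather than simulating
genealogies, each population keeps a pool of founder haplotypes
(independent Bernoulli draws from its frequencies) and every output
haplotype is a founder mosaic: it copies one founder and switches to a
random founder as a Poisson process along the genetic map (default 1
switch per Morgan). Two haplotypes share long identical segments exactly
when they copy the same founder, which is what gives extended-haplotype
statistics something to measure. The founder pool holds 50 haplotypes: the
stationary probability that two haplotypes copy the same founder is then
1/50 = 0.02, safely below the conventional 0.05 EHH truncation cutoff, so
null EHH curves decay below the cutoff within roughly a centimorgan. (With
a pool of 20 the sharing floor sits exactly at the cutoff and null
integrals extend across whole chromosomes.)

**Admixture tracts.** An admixed haplotype carries a two-state ancestry
process: crossover events arrive at rate g per Morgan (g = 50 generations
since admixture onset by default) and each event re-draws the ancestry as
Bernoulli(π_i), where π_i is the individual's stationary Pygmy proportion,
drawn once per individual from Beta(6.5, 3.5) (mean 0.65, matching a
cohort whose admixed members carry roughly 27–49% agriculturalist
ancestry). Every crossover is recorded as a tract boundary, so recorded
truth tracts have mean length 1/g Morgan (2 Mb at 1 cM/Mb) even though
adjacent tracts may share ancestry; a merged-block view is available for
comparison with inferred ancestry blocks, whose observable scale is set by
the thinned switch rate 2gπ(1−π). g is deliberately a free parameter: the
admixture is old and ongoing and no single-pulse time fits it.

**Sweeps.** `plant_sweep` overwrites a carrier fraction of one
population's haplotypes with a single template over a core window
(default 0.5 cM), forcing the derived allele at the core. The core SNP is
the nearest SNP to the requested position whose pre-sweep derived
frequency is at most 0.5 — a sweep lifts a low-to-moderate-frequency
allele; anchoring on an already-common allele would push the post-sweep
frequency past the scans' minor-allele cutoff.

**Phenotype.** Height (cm) = 160 + 11·I[male] + β_anc·π_i + Σ_q γ_q·(local
P dosage at QTL q) + N(0, σ_e²). With the cohort design of 67 admixed
individuals (mean π 0.65) and 58 unadmixed agriculturalists (π = 0), the
cross-group ancestry variance is Var(π) ≈ 0.116; β_anc = −14 cm and σ_e =
4.3 cm then give expected sequential variance shares of ≈0.42 for sex and
≈0.32 for ancestry (full model ≈0.74). A slope of −13 cm cannot reach both
shares simultaneously under this design, which is why the default is −14.
The sign encodes the core biology: more hunter-gatherer ancestry, shorter
stature.

**What the generator does not emulate:** genealogical coalescent
structure, mutation and genotyping error, recombination-rate variation
(the map is linear), background selection, X chromosomes, and real
marker ascertainment. Passing tests therefore demonstrate that the
*methods* behave correctly on data with the right first-order structure
(drift, LD, tracts, ancestry–trait confounding), not that real data would
yield the same power.

## Quality control

* **Missingness:** SNPs with more than 5% missing genotypes are removed.
* **Relatedness:** PLINK-style method-of-moments IBD. Observed IBS0/1/2
  counts over shared non-missing SNPs (MAF ≥ 0.01) are equated with their
  expectations under IBD states 0/1/2 and solved sequentially; the three
  probabilities are clamped to [0,1] and renormalized; π̂ = P(IBD=1)/2 +
  P(IBD=2). The finite-sample allele-frequency corrections are omitted
  (frequencies may be supplied externally); gene-drop simulation confirms
  calibration (grandparent–grandchild mean 0.250 ± 0.01 at 20k SNPs).
  Relative removal is greedy on the π̂ > 0.25 graph: remove the
  highest-degree individual (ties: higher missingness, then smaller id)
  until no edge remains — the removal order is therefore deterministic.
* **Kinship:** K_ij is the mean per-SNP IBS fraction (0, ½, 1). Because
  1 − K is an L1 distance, the doubly-centered K is positive semidefinite,
  which the mixed model requires.
* **LD pruning:** sliding windows of 100 SNPs with offset 50; within a
  window the SNP with the largest VIF = 1/(1−R²) against the other
  retained window SNPs is removed until all VIF ≤ 2. A ridge of 1e−8 on
  the correlation matrix handles exact collinearity; monomorphic SNPs are
  removed first; removals are global.

## Global structure

PCA operates on mean-imputed genotypes centered and scaled by
√(2p(1−p)). Admixture proportions come from the maximum-likelihood
admixture model (binomial likelihood in Q and F) fitted by EM — the
deterministic counterpart of Bayesian clustering point estimates. The EM
updates are multiplicative and keep the likelihood non-decreasing; the
best of several random restarts is kept and clusters are relabelled post
hoc by the unadmixed reference panel. Two-cluster fits should exclude
genuine third populations (the outgroup), which otherwise distort both
clusters. The ancestry–height regression is OLS of height on sex and
global ancestry; the sequential r² enters sex first, so r²_sex +
r²_ancestry = r²_full exactly.

## Selection scans

* **F_ST:** per-SNP Weir–Cockerham (1984) θ̂ with the full diploid
  variance components a, b, c (including observed heterozygosity);
  negative estimates clamp to 0.
* **LSBL:** (d_AB + d_AC − d_BC)/2 on clamped F_ST; negative branch
  lengths clamp to 0; the pre-clamp identity LSBL_A + LSBL_B = d_AB holds
  by construction.
* **Empirical tails:** the high threshold is the linear-interpolation
  empirical (1 − tail) quantile and only strictly greater values are
  flagged, so ties at the threshold are excluded.
* **Blocks:** maximal runs of ≥4 high SNPs with every adjacent gap
  strictly under 100 kb.
* **Bin enrichment:** non-overlapping 500-SNP bins within chromosomes;
  the binomial success probability is the realized genome-wide high
  fraction, and the p-value is the exact upper tail.
* **EHH family:** EHH is computed by incremental group refinement
  (haplotypes remain grouped while identical from the core outward), with
  flat stretches advanced in blocks for speed; the result is exactly the
  pair-counting definition. iHH integrates EHH over genetic distance by
  the trapezoid rule, truncating after the first marker below EHH = 0.05,
  at chromosome ends, and before any physical gap ≥ 200 kb (the segment
  that crosses the cutoff is included; these conventions are configurable).
  iHS = ln(iHH_ancestral/iHH_derived), standardized within 2%-wide
  derived-allele-frequency bins (bins under 50 SNPs merge with a
  neighbour; the scan output records each SNP's standardization bin).
  XP-EHH fixes the integration interval where the *pooled* panel's EHH
  falls below 0.05, integrates each population over that same interval and
  standardizes ln(iHH_A/iHH_B) genome-wide; positive scores mean longer
  homozygosity in panel A. SNPs with MAF < 5% (per population for iHS,
  pooled for XP-EHH) or unknown ancestral state are excluded. Ancestral
  states come from the first non-missing outgroup allele in the priority
  chimpanzee → orangutan → macaque, and only when it matches ref or alt.
* **Small-genome caveat:** on a synthetic genome of a few thousand SNPs a
  planted 0.5 cM sweep contributes ~50 hitchhiking SNPs — a visible
  fraction of the whole scan — so the extreme tail of the empirical
  distribution is composed of the sweep's own SNPs and detection is
  asserted at the sweep-window level (a swept SNP carries the high flag),
  not for the core SNP against its own hitchhikers.
* **Sequence diversity:** π as the mean per-site pairwise difference with
  pairwise N-exclusion, Watterson's θ = S/a₁, and Tajima's D with the
  standard a₁…e₂ constants (undefined at S = 0).

## Local ancestry

Windows of 50 consecutive SNPs (never spanning chromosomes; terminal
remainders dropped). Per window, a linear-kernel support-vector classifier
separates the admixed (Pygmy-labelled) haplotypes from the single
available reference panel (Bantu); the admixed haplotypes furthest from
the hyperplane on the Pygmy side (signed Euclidean distance) are taken as
window-specific ancestral proxies; a second classifier trained on proxies
vs. reference yields decision values calibrated to probabilities by a
logistic (Platt) map fitted on the training decisions. The features are
the window's raw 0/1 alleles. The proxy fraction ρ is one global
constant, chosen by bisection so the genome-wide mean Pygmy call fraction
matches the target global ancestry (the global admixture estimate),
within 0.01. Degenerate windows (no variation, or collapsed decision
values) emit 0.5 with a flag.

The per-window scores act as emission likelihood ratios s : (1−s) in a
two-state chain whose transitions use the crossover-thinning form — an
event with probability c per window step re-draws ancestry with the
stationary Pygmy probability — so the prior equals the stationary
distribution. Posteriors come from scaled forward–backward; c can be
re-estimated by up to 20 Baum–Welch iterations bounded in [1e−6, 0.2].
Hard calls are the posterior argmax; the high-confidence mask requires
max posterior ≥ 0.9. Tracts merge consecutive same-call windows with
boundaries at bp midpoints between opposite-call windows.

A self-training caveat: with a small proxy fraction, ordinary (non-proxy)
haplotypes of the target ancestry can fall outside the proxy-hugging
margin and score low before smoothing; the calibration of ρ against the
global ancestry target is what keeps window calls unbiased.

## Mixed-model association

The null model y = Xβ + u + ε with Var(u) = σ_g²·K_c (K_c the centered
IBS kinship) is fitted by REML: after projecting out the covariates, the
profile likelihood depends only on δ = σ_e²/σ_g², maximized on a log₁₀
grid over [−10, 10] with bounded Brent refinement (tolerance 1e−8). Flat
profiles (δ unidentifiable, e.g. K = I where only σ_g² + σ_e² is
determined) resolve toward the largest δ, assigning the variance to the
residual; GLS results are invariant to this tie. Per-marker tests are
Wald t-tests under GLS with the variance components fixed from the null
model; markers below 90% call rate or 1% MAF are skipped. Admixture
mapping runs the same machinery on diploid local-ancestry dosages
(0/1/2 = number of haplotypes confidently called Pygmy; windows with
under 80% callable samples are dropped, and each window's GLS restricts
the null covariance to its callable samples). FDR is Benjamini–Hochberg,
recomputed within each analysis (and within any a-priori marker subset)
separately.

## Pathway enrichment

Candidate genes are those whose interval, extended 100 kb both ways,
contains a signal SNP (inclusive boundary). Over-representation is the
hypergeometric upper tail against a user-supplied GMT database, with a
Bonferroni threshold of 0.05 divided by the number of pathways holding at
least two genes. The cumulative pathway statistic CA sums a scan's
per-SNP scores over the pathway's SNPs; the null re-draws equal-sized
score sets with replacement 10,000 times; a skew-normal fitted by maximum
likelihood smooths the null and supplies the upper-tail p (empirical
resampling p is reported alongside and used if the fit fails). Note the
skew-normal shape parameter is weakly identified near zero — on Gaussian
nulls the fitted shape wanders while the fitted law stays normal — so
sanity checks should examine implied moments, not the shape parameter.
The top-two test draws random gene lists of the observed size without
replacement, computes each pathway's 2×2 chi-squared (no continuity
correction) and reports the fraction of draws in which any designated
pathway ranks among the two largest statistics, floored at 1/n_reps.

## Problem sizes

The test-suite cohort uses 4,000 SNPs on one 40 Mb chromosome with 67
admixed, 58 + 30 reference and 45 outgroup samples; detection suites use
20 seeded replicates of 1,000–1,500-SNP cohorts; calibration suites use
20,000 independent SNPs. These sizes were chosen so every stochastic
check runs at well-resolved sample sizes while the whole suite stays
lightweight.

## Known limitations

* The generator's LD is mosaic-founder LD: EHH decays on the right scale
  but the site-frequency spectrum and long-range LD are not coalescent.
* iHS at a few thousand SNPs has heavier-than-normal tails at extreme
  derived frequencies where carrier counts are small; bin merging limits
  but does not remove this.
* Only one reference ancestry is used for local ancestry (by design,
  mirroring the single available ancestral panel); three-way local
  ancestry is out of scope.
* The mixed model implements the IBS kinship only, and the Wald GLS
  approximation with null-model variance components (no per-marker REML
  refit).
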