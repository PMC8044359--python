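# Methods

This note documents the models implemented in `tgrm`, the assumptions they
make, the synthetic-data generator used for validation, and the numerical
choices that were genuinely open.

## 1. Phenotype adjustment (augmented block designs)

**Model.** Plot-level records are modelled as

y = μ + DTH·β + check + new:entry + block + batch + e,

with replicated check varieties as fixed effects (unreplicated entries
anchor the intercept), a random iid entry term whose variance σ²_g is the
genetic variance, random iid block and batch (measurement-order) effects,
and an optional fixed heading-date-style covariate that is included only
when the records carry one. Entries are treated as unrelated at this
stage; marker information enters only downstream. When records span
several trials, fixed trial contrasts are added.

**Estimation.** Variance components are estimated by REML. The default
algorithm takes average-information (AI) steps with step halving and falls
back to a monotone EM step whenever an AI step would leave the parameter
space or decrease the restricted likelihood; components pinned at the
lower floor with negative score are held out of the AI system (an active
set). Pure EM is retained (`fit(algorithm="em")`) because its
likelihood-monotonicity is a useful correctness check, but EM alone crawls
when a component approaches zero, which happens regularly for the batch
term in realistic designs. Convergence is declared at a relative component
change below 1e-8 (default cap 200 iterations). BLUPs and their prediction
error variances (PEV) come from the dense inverse of the mixed-model-
equation coefficient matrix at the converged components; panel sizes of at
most a few thousand plots make the dense solve unproblematic.

**Deregression.** ĝ* = ĝ / r² with reliability r² = 1 − PEV/σ²_g,
interpreting the "total genetic variance" as the entry variance component
of the adjustment model. Entries with r² at or below a floor (default 0.1)
are excluded rather than inflated without bound; entries with PEV ≥ σ²_g
are always excluded. When σ²_g itself collapses to ~0 — the REML optimum
in a low-heritability, single-replicate design can genuinely sit at the
boundary — the whole trait yields no deregressed values; downstream
experiment drivers treat such a trait/replicate as unusable rather than
substituting a fallback response.

## 2. Whole-genome regression (the Bayesian alphabet)

All five methods share y = μ1 + W a + e with e ~ N(0, σ²_e I) and a flat
prior on μ; the response is not centered internally. Updates are
single-site Gibbs with a running residual, giving O(nP) per sweep (the
inner loop is compiled with numba; randomness is drawn outside the
compiled code from one seeded generator, so chains are bit-reproducible).

Priors on marker effects:

- **BRR** — a_p ~ N(0, σ²_a), σ²_a common with a scaled-inv-χ² prior.
- **BayesA** — per-marker σ²_p, scaled-inv-χ²(df, S); marginally scaled-t.
- **BayesB** — point mass at zero with probability π, scaled-t slab.
- **BayesCπ** — point mass with probability π, Gaussian slab with common
  variance.
- **BL** — Park–Casella hierarchy: a_p ~ N(0, τ²_p σ²_e),
  1/τ²_p inverse-Gaussian, λ² with a Gamma hyperprior.

π parameterises the **point mass (exclusion)** probability — some software
parameterises inclusion — and is sampled under Beta(1, 1). Indicators and
effects are updated jointly, with the effect integrated out of the
inclusion odds.

**Hyperparameter scales.** A proportion `prior_r2` (default 0.5) of
var(y) is allocated to markers; scaled-inv-χ² scales are solved from the
prior mode given `df_prior = 5`, dividing by the summed column variances
of W (and by the prior inclusion fraction for the mixture methods). For
BayesA/B the scale S additionally carries a Gamma(1.1, ·) hyperprior
updated by Gibbs: with a fixed S these methods cannot shrink a null signal
below the prior level (the classic BayesA criticism), whereas the
hyperprior lets the data pull S down. λ² of BL likewise has a Gamma
hyperprior centered at 2(1−R²)·ΣVar(w_p)/R².

**Chain settings.** Defaults are 20 000 iterations, 5 000 burn-in,
thinning 5. The "test" preset (3 000/1 000/2) is used throughout the
validation suite; posterior means of marker effects stabilise well before
that for the problem sizes used here. Per-marker variance draws are
floored at 1e-10; constant marker columns are excluded with a warning and
keep effect 0.

## 3. Kernels

`G* = M D M′/P` with M centered and scaled to unit sample variance per
column and D the diagonal of squared-effect weights a_p²/Σ a_q². Two
conventions were genuinely open:

- **Weight normalisation.** Raw weights sum to one, which combined with
  the 1/P in the kernel would shrink its trace by ~P. Weights are rescaled
  to sum to P (default), so equal effects reproduce the unweighted kernel
  M M′/P exactly and variance components stay on one scale across weighted
  and unweighted models; `normalize="sum_to_1"` preserves the raw
  convention.
- **Column scaling.** Unit variance rather than 2p(1−p), because the
  weights in D already carry the per-marker importance.

The unweighted baseline is VanRaden's second-style GRM with per-marker
standardisation of (w − 2p)(w − 2p)′. For fully inbred lines the dosage
variance at a marker is 4p(1−p) (no heterozygotes), so the inbred
standardisation is the default — it keeps the mean diagonal near one,
matching the scale of the trait-specific kernel; `inbred=False` recovers
the textbook HWE denominator 2p(1−p).

Markers absent from the training panel's effect table receive weight 0 in
the prediction panel's weighted kernel, and the per-analysis MAF filter
(0.05) is applied to the prediction panel before kernel construction. This
is what makes the rare-allele failure mode reproducible: a large-effect
locus common in the training panel but rare in the prediction panel simply
vanishes from the weighted kernel.

Kernels are bent to positive semidefiniteness by shifting the diagonal so
the minimum eigenvalue is eps = 1e-6; eigenvalues above −1e-8 count as
round-off and trigger no bending. Inside the samplers, eigencomponents
below 1e-6 of the largest eigenvalue are dropped entirely — 1/d weighting
on bent-in eigenvalues is pure noise and destroys the conditioning of the
covariance updates.

## 4. Kernel BLUP and multi-trait GBLUP

Both prediction models are Bayesian and sampled by Gibbs in each kernel's
eigenbasis, where the conditional precision of the rotated effects is
diagonal (single/multi-kernel) or block-diagonal by eigencomponent
(multi-trait). Unobserved phenotypes — including the masked test folds of
cross-validation — are handled by data augmentation, which keeps the
design balanced inside the sampler; masked lines receive genomic values
through their kernel rows only, and their observed phenotypes never enter
the likelihood.

- Trial effects are fixed (flat prior), implemented as per-trial
  intercepts; the reported s_e are deviations from their mean.
- Per-kernel variances have scaled-inv-χ² priors (df 5) with `prior_r2`
  split equally among kernels and scaled by each kernel's mean diagonal.
- The multi-trait model uses matrix-normal genetic values (row covariance
  the kernel, column covariance unstructured) with inverse-Wishart priors
  (df T+2, scale from the pairwise-complete phenotypic covariance split
  by `prior_r2`). Missing cells are drawn from the conditional residual
  normal per missingness pattern. The sampler is warm-started from
  per-trait kernel-ridge solutions (heritability one-half) with missing
  cells filled from that start: from a cold start, augmentation of a large
  missing block mixes extremely slowly.
- Covariance draws are protected against round-off (symmetrisation and
  relative eigenvalue clipping); these guards only act at the 1e-10 level.

A slow, dense-covariance Gibbs sampler in the original basis is kept in
the test suite as an independent oracle for the rotated implementation.

## 5. Cross-validation and the win-rate rule

Five-fold CV with independent random partitions per resampling run; fold
sizes differ by at most one. Lines present in both populations can be
forced into the training portion of every run. Fold accuracy is the
Pearson correlation between predicted genomic values and held-out
observations, computed per trial and averaged with equal weights when the
response is per-trial; fold accuracies average into one accuracy per run.
Method A significantly beats B when A's run accuracy strictly exceeds B's
in at least 90 % of runs (ties are not wins; the threshold comparison is
inclusive). A run in which any method produces a degenerate (constant)
prediction is excluded for all methods, keeping run sets aligned.

The win proportion conditions hard on the one realised dataset: when two
methods are not essentially tied, a single dataset drives the statistic to
0 or 1, and intermediate values appear only near exact parity. The
experiment driver therefore pools run-level wins over independent study
replicates when the question is about the *expected* ordering of methods.

## 6. The synthetic two-panel study

The generator emulates the data structure the workflow assumes, not any
particular organism's genome.

- **Genotypes.** Founder-mosaic LD: markers fall into blocks (default
  2 000 markers in 200 blocks); each block has 8 founder haplotypes with
  allele frequencies uniform on [maf_min, 1−maf_min]; each inbred line
  draws one founder per block (dosage 2 × allele), with a small residual
  heterozygote rate (0.003). Within-block markers are strongly correlated,
  across blocks independent. The model gives controllable LD without a
  coalescent dependency; it has no genome coordinates, recombination map
  or pedigree, and no epistasis or genotype-by-environment interaction.
- **Two panels.** A diverse discovery panel (default 336 lines) and an
  elite panel (default 227) share a small overlap set (12). Elite-only
  lines sample founders with log-normally perturbed probabilities
  (drift sd 0.8), so a marker can be common in one panel and rare in the
  other. If no marker is naturally common-in-discovery/rare-in-elite, one
  is planted by driving the minor allele out of the elite-only lines —
  the rare-allele transfer-failure condition is part of the study design,
  not a lucky draw.
- **Endophenotypes.** Nine traits spanning oligogenic (15–60 QTL) to
  polygenic (all markers) architectures with heritabilities 0.38–0.69;
  three trait pairs share QTL with correlated effects, so the panel is
  genetically correlated. One trait (EP5) is a single large-effect locus
  (45 % of genetic variance) on a polygenic background; because its locus
  is rare in the elite panel, the weighted-kernel advantage should
  collapse for it. Breeding values are rescaled to unit variance per trait
  so weights and heritability targets compose cleanly.
- **Focal trait.** A weighted sum of endophenotype genetic values
  (weights emulating a composition-dominated trait) plus a marker-based
  polygenic term carrying 25 % of the focal genetic variance; target
  heritability 0.5.
- **Field design.** Augmented blocks: every unreplicated entry once per
  trial, three check varieties in every block, consecutive measurement
  batches (emulating injection order), block/batch/trial variance shares
  relative to the plot-level phenotypic variance, and an entry-level
  Gaussian covariate present only in the discovery design. Three checks
  per block (~54 check plots) were chosen because two left the σ²_g/σ²_e
  split fragile for low-h² traits — with ~36 check plots the REML optimum
  collapsed σ²_g to zero in a nontrivial fraction of realisations.

What passing tests on this generator do **not** show: robustness to real
LD decay and population structure, non-additive inheritance, genotype-by-
environment interaction, or the behaviour of the weight estimates at real
marker densities (tens of thousands of markers). In particular the ratio
of markers to effective genome segments is far smaller here than on a real
genotyping panel, which makes squared-effect weight noise relatively more
damaging to the weighted kernel for fully polygenic traits.

## 7. Validation problem sizes

The validation suite runs the two-panel scenario at 400 discovery lines,
250 elite lines, 2 000 markers, with five-fold CV; 5 resampling runs per
replicate pooled over up to six replicates for endophenotype comparisons
and 10 runs for the focal-trait comparison. Chain lengths there are
3 000/1 000/2 for effect estimation, 1 500/500/2 for kernel-model CV fits
and 1 200/400/2 for multi-trait CV fits — sizes at which repeated fits
agree to well within the accuracy differences being compared. The
config-driven pipeline's "test" preset (3 000/1 000/2, 10 runs) matches.

## 8. Known limitations

- The multi-trait model's accuracy for a focal trait observed in only one
  panel is modest on this generator; most of its information path runs
  through the estimated genetic covariances, which are noisy with nine
  endophenotypes and a large augmented block. The multi-kernel model,
  which receives the endophenotype signal through fixed kernels rather
  than estimated covariances, is consistently stronger — consistent with
  its greater parsimony.
- Deregression excludes entries (or entire traits) when reliabilities are
  degenerate rather than re-estimating; the experiment drivers skip such
  replicates explicitly.
- The Bayesian LASSO uses a single global λ²; no per-group extensions.
- No REML (non-Bayesian) path for the kernel prediction models.
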