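# Methods

## The model

`microbopred` partitions the phenotypic variance of growth and
feed-efficiency traits in group-housed animals into genetic and microbial
components, and asks whether gut-microbiota composition improves phenotype
prediction. The core model for a vector of phenotypes **y** is the
univariate microbial mixed ("animal") model

    y = X β + Z_A a + Z_L l + Z_C c + Z_M m + e

with systematic effects β (batch, 5 levels; weaning body-size class, 2
levels), additive genetic effects **a** ~ N(0, A σ²_A) with **A** the
pedigree-derived numerator relationship matrix, birth-litter effects
**l** ~ N(0, I σ²_L), cage effects **c** ~ N(0, I σ²_C), per-animal
microbial effects **m** ~ N(0, M σ²_M) with **M** a microbial relationship
kernel, and iid residuals. Model *M1* omits the microbial term; *M2*
includes it.

Traits come in two kinds. Individual traits (average daily gain under ad
libitum or restricted feeding, ADG_AL / ADG_R, g/day — the within-animal
OLS slope of weekly body weight on age) use indicator incidence matrices.
Cage-average feed-efficiency traits (daily feed intake ADFI, residual feed
intake ADRFI, conversion ratio ADFCR) have one record per cage, so Z_A,
Z_L and Z_M carry the *proportion* of the cage's animals at each effect
level (rows sum to one per factor) and the cage term is dropped. Because a
cage record is a mean over ~7 animals, the residual component is multiplied
by the average cage size (default 7) when it enters the phenotypic
variance, referring it back to the individual scale:

    individual: σ²_P = σ²_A + σ²_L + σ²_C + σ²_M + σ²_e
    cage:       σ²_P = σ²_A + σ²_L + σ²_M + 7 σ²_e

Ratios: heritability h² = σ²_A/σ²_P, litter ratio l², cage ratio c², and
microbiability m² = σ²_M/σ²_P.

## Microbial kernels

From a CSS-normalized OTU table (see below), three between-animal kernels:

* **M_O = O O′**, O the row-normalized (unit Euclidean norm) CSS matrix —
  cosine similarity of microbial profiles, unit diagonal by construction;
* **M_B = 1 − B²/2** elementwise, B the Bray–Curtis distance matrix;
* **M_U = 1 − U²/2**, U the *normalized* weighted UniFrac distance matrix.
  The normalized variant is required because the 1 − d²/2 transform assumes
  d ∈ [0, 1]; UniFrac operates on within-sample relative abundances, so the
  kernel is invariant to per-sample depth.

Distance-derived kernels can be indefinite (distances are pairwise
constructions); they are repaired by eigendecomposition, truncating
negative eigenvalues, *after* the 1 − d²/2 transform. Solvers add a
diagonal jitter of 1e−6 × mean(diag) when a repaired (possibly singular)
kernel must be inverted.

Animals without microbiota data are covered by one of two expansions:
an **identity block** (unit variance, zero covariance — such an animal's
predicted microbial effect is exactly zero), or **cage-average imputation**
of the missing animals' CSS profiles by the mean of their assessed cage
mates before kernel construction. Kernel rows/columns are always ordered by
sorted animal id so repeated runs produce bit-identical linear algebra.

### Prior-scale vs realized variance (important caveat)

Microbial kernels have a large common component: cosine similarities
between gut communities sit far above zero, so **M** ≈ (1−ρ)I + ρJ with
substantial ρ. Under **m** ~ N(0, M σ²_M) the *between-animal* variance the
effect actually expresses is roughly (1−ρ) σ²_M; the common part shifts all
animals together and is absorbed by the intercept. Consequently the
prior-scale σ²_M — and with it the printed m² and phenotypic variance — can
be several-fold larger than the realized microbial variance. The package
reports the plain ratio formulas by default (matching how such tables are
conventionally printed, and reproducing the characteristic M2
phenotypic-variance inflation), and offers `ratio_reference="sample"`,
which rescales each kernel component by (mean diag − mean offdiag) of
Z K Z′. Sample-referenced ratios are the right scale for comparing
estimates across kernels or against simulation ground truth, and are used
wherever the tests do exactly that.

## Estimation

**EM-REML** iterates the closed-form EM updates in the n×n phenotypic
covariance parameterization V = Σ_k σ²_k Z_k K_k Z_k′ + σ²_e I:

    σ²_k ← σ²_k + σ⁴_k (y′P G_k P y − tr(P G_k)) / q_k,   G_k = Z_k K_k Z_k′

with P the REML projection of V. This is the same fixed point as the
MME-based EM (the mixed-model equations are also provided, in
`assemble_mme`) but its per-iteration cost is O(n³) regardless of the
number of effect levels. EM converges slowly, and sublinearly when a
component sits at the zero boundary, so two numerical choices apply:
convergence is declared when the largest absolute component change per
sweep falls below `tol` × (total variance), and an Aitken geometric
extrapolation is attempted every five sweeps (bounded to a ×10 move,
disabled near convergence). BLUPs use û_k = σ²_k K_k Z_k′ P y; effects of
animals present in the kernel but absent from the records (validation
animals) are obtained through the kernel covariance, which reduces to
K_val,train K_train,train⁻¹ û_train.

**Gibbs sampling** draws each effect block jointly from its
multivariate-normal full conditional and each variance from its scaled
inverse chi-square full conditional under improper flat priors bounded at
zero (variance conditionals S_k/χ²_{q_k−2}). For speed, each term's
conditional precision Z′Z/σ²_e + K⁻¹/σ²_k is diagonalized *once* through
the generalized symmetric eigenproblem (Z′Z, K⁻¹); a block draw then costs
two matrix–vector products per sweep. Default desk-scale chain: 50,000
iterations, 10,000 burn-in, thin 10 (any length can be configured).
Posterior summaries of components and ratios are computed per kept sample;
the full trace is attached for diagnostics (`effective_sample_size` gives
an autocorrelation-based ESS).

A REML point estimate and a posterior mean differ systematically (mode vs
mean of a right-skewed posterior), so cross-method agreement is asserted on
the scale of the posterior SD, not the Monte-Carlo SE of the chain.

## OTU processing

Raw counts go through: (1) doubleton removal — OTUs with total count ≤ 2
across all samples (singletons included); (2) a prevalence/abundance
filter — keep OTUs non-zero in at least ⌈5%⌉ of samples *and* holding
strictly more than 0.01% of the grand total count (computed on counts,
before normalization); (3) cumulative-sum-scaling (CSS) normalization —
sample i's counts are divided by s_i, the sum of its counts at or below its
own q-th positive-count quantile, times a scale constant (1000). The
quantile is chosen per run by a relative-instability rule (the smallest
grid quantile at which the median absolute deviation of per-sample quantile
functions from their mean jumps by >10%), falling back to 0.5; a fixed
quantile can be supplied and is what the tests pin down.

## Predictive-ability protocol

For each trait, 100 (configurable) cross-validation replicates. Individual
traits: animals go to validation with probability 0.1, then any validation
animal whose litter or cage would vanish from training is forced back, so
every validation litter/cage is represented in training. Cage traits: whole
cages are assigned train/validation with probabilities 0.8/0.2, stratified
within batch. Both models are trained per replicate by EM-REML on the
training records only; predictive ability is the Pearson correlation
between predicted and observed validation phenotypes. M2-vs-M1 comparison:
a one-sided empirical bootstrap paired t test (differences centred to zero,
1000 resamples, p = share of bootstrap mean differences ≥ the observed
one), Bonferroni-adjusted across the kernels compared per trait (BH-FDR
available); plus the share of replicates where M2's correlation is strictly
higher. "Declared superior" requires adjusted p < 0.05 *and* win rate
≥ 0.8.

## Sparse PLS and relevant OTUs

sPLS (soft-thresholded direction vectors with an active-set PLS1 refit):
per component, z = X′y_res, w_j = sign(z_j)(|z_j| − η max|z|)₊; the active
set accumulates supports, an ordinary PLS1 is refit on the active columns,
and y is deflated. Predictors are centred and unit-scaled inside each
learning fold. (η, K) are tuned on a grid — desk default η ∈ {0.1…0.9},
K ∈ {1…10}; the full (0.01–0.99) × (1–20) ranges are configurable — by
internal 5-fold CV minimizing MSPE, ties to smaller K then larger η.
Stability selection repeats tune-and-fit over 20 seeds × 5 folds = 100
replicates; OTUs active in ≥ 80 are "stable". "Relevant" OTUs for a trait
are those in the tails of the loading weights (below the 5th or above the
95th *percentile* — read as percentile, not per-mille, since the latter
would flag ~1 OTU in ~950; configurable) under *every* kernel model, with
mean regression coefficients across replicates serving as the loading
weights. `fit_microbial_effect_targets` applies the same machinery with the
M2 posterior means of per-animal microbial effects as the response.

## Synthetic-data generator

The generator is first-class, tested code and defines the conditions under
which everything else is exercised. It emulates: a multi-generation
pedigree from random monogamous pairings (founders unrelated; litter sizes
1 + Poisson); cages of 6–8 kits, one feeding regime per cage, at most two
kits per litter per cage (greedy most-space-first packing), five batches,
big/small labels from a median split of simulated weaning weight;
microbiota assessed in 2 kits per cage by default; OTU counts drawn
multinomially from softmax(log-normal baseline [sd 1.5] + normal cage
shift + normal individual noise) at log-normal depths on a random-join
binary tree; and phenotypes built as

    gain_i = μ + batch + size + regime + a_i + l_i + c_i + m_i + e_i

with a drawn through the pedigree covariance A, iid litter/cage/residual
effects, and the microbial effect linear in the row-normalized CSS
abundances, m = O b. Every effect is rescaled after drawing so that its
*realized* per-animal variance equals its configured target exactly
(correlation structure preserved): the configured fractions are then the
fractions actually simulated, and parameter-recovery checks measure
estimator error rather than draw-to-draw wobble of the effect variances. Weekly body weights are linear in age plus measurement
noise (so the fitted ADG slope recovers the latent gain, exactly when the
noise is zero); weekly feed intake is emitted for ad-libitum cages, and
restricted cages receive the offered amount from the 0.75-of-last-week's-AL
rule plus 10%.

Defaults mirror the emulated study's conditions: 963 OTUs, 5 batches,
cages of 8 with 2 assessed per cage, mean depth 35,000 reads, ad-libitum
gain averaging 55 g/day with phenotypic variance 41 (g/day)², variance
fractions (h², l², c², m²) = (0.2, 0.1, 0.1, 0.4). What the generator does
*not* emulate: taxonomy beyond arbitrary labels, sequencing error or
chimeras, mortality/variable cage occupancy, and any real phylogenetic or
compositional signal linking specific taxa to function — so passing tests
demonstrate the statistical machinery under the assumed model, not
biological findings.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the machinery at reduced
scale as the package's own choice of desk-scale defaults: recovery
experiments use ~1,000 animals with 946 OTUs and 10 replicates (the
kernel's effective rank is bounded by the OTU count, which governs how
well the microbial and residual variances separate);
cross-validation checks use ~400 animals (946 OTUs for the protocol check)
and 10–20 replicates; Gibbs chains in tests run 6,000–10,000 iterations.
The parameter-recovery harness deliberately isolates h² and m² (litter and
cage fractions set to zero, cage-level microbiome shift off): with
cage-structured compositions the microbial kernel legitimately absorbs cage
variance, a property of the design rather than an estimation defect, and
the confounded setting is exercised separately by the end-to-end pipeline.

## Known limitations

* Single-trait models only; no AI-REML, no sparse MME solvers — dense
  linear algebra bounds practical size to a few thousand records.
* EM-REML near a zero-variance boundary converges sublinearly; fits report
  `converged=False` with the last iterate rather than failing.
* The bootstrap paired test's sidedness is fixed to "microbial model
  better" (one-sided), matching how the comparison is posed.
* CSS quantile selection is a documented approximation of the
  relative-instability idea, not a line-for-line port of any particular
  implementation; supply a fixed quantile for exact reproducibility.
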