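# Methods

## The force and power decompositions

The package analyses hovering flight through the stroke-averaged vertical
force balance F_V = W = ½ρŪ²S·C̄_V. The time averaging assumes wing area
and air density constant through the stroke and factorises the
velocity–coefficient product, which holds for hummingbirds (near-rigid
wings, harmonic stroke). With a cosine stroke profile the mean angular
speed is 4Φf, so Ū = 4ΦfR₂ with Φ the cosine amplitude — half the
pronation-to-supination amplitude that wingbeat digitisation yields.
Records therefore store the pronation-to-supination amplitude;
`mean_wing_velocity` halves it internally, while the actuator-disc area
A = Φ_p2s·R² uses it unhalved. Wing area S is the combined area of both
wings and R a single wing, which puts C̄_V in the conventional O(1) range;
the derivation validator warns when C̄_V leaves [0.1, 20], the signature of
a unit mix-up. Both conventions are configurable flags because source data
sets do not always state theirs.

Taking log₁₀ of the balance gives the summation constraint
b_F = b_ρ + 2b_Ū + b_S + b_C̄V with b_F ≡ 1 for weight support. Specific
induced power uses P* = n·v̄_ind·(1+τ+σ), v̄_ind = √(F/2ρA); the Ellington
temporal/spatial correction factors τ, σ are accepted as numeric inputs
(default 0), never computed here. The inflow-ratio exponent b_λ defaults
to 0 on the grounds that morphologically and kinematically similar birds
share an inflow ratio; the assumption is logged whenever applied.

Air density comes from the International Standard Atmosphere troposphere
law ρ(h) = ρ₀(1 − Lh/T₀)^(gM/RL − 1), constants configurable, valid for
0 ≤ h < 11 km; weight uses g = 9.80665 m s⁻² everywhere (elevation
dependence < 0.2%).

## The hierarchical interspecific model

For one bivariate relationship on the log₁₀ scale:

* observations within species i: (x_ij, y_ij) ~ N₂((μx_i, μy_i), Ω), with
  Ω given a minimally informative inverse-Wishart prior (df = 3,
  scale = 10⁻⁴·I; the scale magnitude matches realistic within-species
  log₁₀ variances — an identity scale would dominate any realistic data
  set and force within-species sds near 0.2);
* latent x means: μx ~ N(α_x·1, σx²·Σ_λx);
* regression: μy = a + b·μx + e, e ~ N(0, σ²·Σ_λ);
* Σ_λ = λΣ + (1−λ)I, Σ the Brownian shared-path correlation of the tree
  (unit diagonal). The x-signal λx and the residual λ are separate
  parameters, each uniform on [0, 1]: body size is strongly phylogenetic
  while regression residuals need not be, and a shared λ would impose
  tree-structured weighting on independent residuals, inflating estimator
  variance;
* priors: slopes/intercepts normal with precision 10⁻⁶; standard
  deviations uniform on (0, 1000).

Sampling is Gibbs with conjugate conditionals for the latent means,
coefficients, variances (uniform sd priors induce truncated inverse-gamma
conditionals) and Ω, and reflected random-walk Metropolis for each λ.
Four chains of 10 000 iterations with 5 000 burn-in are the default
(20 000 pooled draws). Convergence is monitored by split potential scale
reduction on the slope with a 1.05 threshold; exceedance attaches a
warning to the fit, never silently. Summaries use posterior means and
95% equal-tailed intervals with the standard linear-interpolation
quantile rule, fixed for reproducibility of summaries at a given seed.

Phylogenetic uncertainty: each MCMC iteration draws a tree uniformly from
the ensemble (each source tree replicated four times; replicates record a
randomly designated representative individual per species). Because the
likelihood involves species only through latent means, the replicate's
representative choice does not enter the likelihood and replication is an
ensemble-preparation bookkeeping step. Per-chain tree assignment is
available (`tree_assignment="chain"`); the test suite checks both modes
agree within Monte-Carlo error. Fixing λ (for example 0 or 1) reduces the
model exactly to ordinary or phylogenetic generalised least squares on
species means, which the tests verify against direct matrix-algebra
oracles.

Species observed once are retained by default (their latent mean is
informed by the within-species covariance); `drop_singletons` removes
them. Clade-wise fits use the same machinery on a single tree pruned to
the clade, with informative priors (slope normal with precision 1, mean 1
for wing area or 0 otherwise; gamma(10⁻³, 10⁻³) on precisions), because
small clades cannot support flat priors.

## Intraspecific fits

Within-species exponents use within-species centring: species empirical
means are subtracted from both log variables, centred points pooled, and
a single slope fitted with the same flat priors by conjugate Gibbs.
Species with fewer than two individuals carry no within-species
information and are excluded (logged). Centring consumes one degree of
freedom per species; with the default ten individuals per species the
residual-variance understatement is ~5% and is accepted.

## Summation diagnostics and error injection

Independently fitted exponents come from overlapping but distinct data
subsets, so their posteriors are combined by independent resampling; the
draw-wise sum b_ρ + 2b_Ū + b_S + b_C̄V is summarised by its mean, 95% CI
and a consistency verdict against the target (1 for weight support). Both
the posterior-mean sum and the resampled-mean sum are reported.

The error-injection simulation shows the constraint is not circular:
starting from species means that satisfy the balance exactly, Gaussian
noise (sd = 0.1 of each value by default) is added to a chosen subset of
{ρ, Ū, S, W}, C̄_V is recomputed from the noisy values, and the four
exponents are refit by OLS against the fixed true log weight. Noise in a
single component among {ρ, Ū, S} lands in C̄_V with opposite sign and the
sum equals the target to machine precision in every replicate; once the
weight measurement itself is noisy, its error enters only the C̄_V
numerator and the replicate sums spread around the target with mean
converging to it. Keeping the true weight as regressor is what makes the
single-component case an exact identity while leaving the multi-error
case unbiased; regressing on the noisy weight would instead make the sum
identically 1 and the simulation vacuous.

## Tree space

Kendall–Colijn encodings use lexicographic tip-pair order, root-to-MRCA
depths in edge counts (topology) or branch lengths, pendant entries per
tip, and a mixing parameter defaulting to 0 (topology-focused, matching
clade-level interpretation). Distances are Euclidean; projection is
classical PCoA (scikit-bio); clustering is partitioning-around-medoids on
the full distance matrix with deterministic BUILD/SWAP steps, the cluster
count chosen by silhouette width over k = 2…6 (ties resolved to 4); each
cluster is summarised by its geometric-median tree — the member
minimising the summed distance to its group, which for an ensemble member
coincides with the medoid. An all-identical ensemble yields one cluster
and zero variance rather than an error.

## Synthetic data

The generator emulates a hovering-flight comparative data set: a
pure-birth tree (rate 1), Brownian log₁₀ mass linearly rescaled to span
one decade (25 species, 10 individuals each by default), lognormal
species- and individual-level biological scatter, and components whose
expected slopes follow the among-/within-species exponent presets
(−0.06, 0.01, 1.01, 0.03) and (−0.07, 0.27, 0.42, 0.11); the force
coefficient is never sampled but implied by the balance, so the preset
sums are exactly 1 and latent records satisfy the balance exactly. Wing
velocity is realised through its sub-allometries with constant stroke
amplitude and r̂₂: wing length carries half the area exponent (constant
aspect ratio) and stroke frequency the remainder, so frequency declines
with wing length among species and rises weakly within. Load factor is
size-invariant among species (b = −0.01, reference n = 1.8) and declines
within species (b = −0.24) under the declining-load-factor model.
Elevations are obtained by inverting the ISA law from the sampled air
densities, keeping records physically consistent.

Measurement noise is Gaussian on the natural scale (sd proportional to
the value) applied independently to every recorded variable after the
latent force balance is fixed, so derived force coefficients absorb the
injected errors exactly as in real data. The default error profile is
per-variable — 1% for balance-measured mass, 2% for wing length and
elevation, 3% for photo-digitised areas and stroke amplitudes, 1% for
stroke frequency, 5% for burst force — because instruments differ by
orders of magnitude in precision; a uniform 10% on body mass would be
unrealistic and, since centring does not model x-error, would attenuate
intraspecific slopes by ~25%. Passing a scalar `measurement_noise`
applies one fraction uniformly (the sum-to-one acceptance run uses 0.1
uniformly on every variable). Small lognormal/normal discrepancies at
these fractions are negligible and accepted.

What the generator does not emulate: collector-specific biases, sex
structure, clade-specific mass ranges, non-Brownian trait evolution, and
within-species kinematic exponents beyond the qualitative
constant-amplitude pattern. Passing tests therefore demonstrate correct
recovery under a well-specified data-generating process, not robustness
to every field-data pathology.

## Problem sizes and numerical choices

Default study conditions (25 species × 10 individuals, 100 trees,
4 × 10k MCMC) run in ~10–15 s per interspecific fit and ~2 s per
intraspecific fit on one CPU; the full acceptance recomputation takes a
few minutes. The replicate-calibration test uses 12 within-preset
replicates at reduced chain lengths; the estimator's replicate-level
standard deviation under the default conditions is ~0.025, so a single
replicate's 95% CI misses its generating exponent in a few percent of
data realisations — recovery tests therefore require coverage in 2 of 3
replicates where a single fixed realisation would make the check a coin
flip on the tail. Seeds derive from a single user seed; identical
configuration and seed reproduce records byte-for-byte and posterior
draws draw-for-draw. Degenerate inputs (zero-variance ensembles,
all-equal posterior draws, empty clades) return well-defined results or
logged skips rather than errors; hard errors are reserved for broken
invariants (non-positive values where logs are needed, tip-set
mismatches, unbalanced presets without an explicit override).

## Known limitations

* The tree-ensemble integration samples trees from their prior per
  iteration (mixture over tree hypotheses) rather than conditioning on
  the data — matching the stated integrate-over-trees intent, but trees
  are never reweighted by likelihood.
* A single inverse-Wishart within-species covariance is shared across
  species; strongly heteroscedastic species would violate it.
* Within-species centring does not model measurement error in x; with
  the default error profile the attenuation is < 1%.
* The burst kinematics (frequency and amplitude escalation factors) are
  fixed multipliers, adequate for exponent recovery but not for studying
  burst kinematics themselves.
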