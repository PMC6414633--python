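# Methods

## The model

Let `y` be log₁₀ cecal length (cm, after adding 0.1 cm) for `n` species on
a rooted phylogeny, and `X` a fixed-effect design with an intercept, log₁₀
body mass (g), and treatment-coded categorical cofactors.  The GLS model is

    y ~ N(X β, σ² V),

where `V` encodes the assumed residual-evolution process on the tree whose
Brownian covariance matrix is `C` (`C_ij` = branch length shared by tips
`i` and `j` from the root; `C_ii` = tip depth):

| model       | V                                   | extra parameter |
|-------------|-------------------------------------|-----------------|
| independent | diag(C)                             | —               |
| brownian    | C                                   | —               |
| ou          | exp(−α·d), d = patristic distance   | α > 0 (ML)      |
| lambda      | off-diagonals of C scaled by λ      | λ (signal test) |

The OU structure is a *correlation* matrix (unit diagonal); its stationary
variance is absorbed into σ².  The independent transform keeps diag(C)
rather than the identity; on the ultrametric trees this package builds
(all tip depths equal) the two differ by a scalar, so β̂, the maximized
likelihood, and AIC coincide exactly with OLS.

Estimation is full ML throughout: β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, σ̂² with divisor
`n`, and the exact multivariate-normal log-likelihood.  REML is deliberately
not offered: AIC is compared across designs with different fixed effects,
and REML likelihoods are not comparable across fixed-effect structures.
Standard errors use the unbiased divisor `n − p` so they pair with t-tests
on `n − p` degrees of freedom (155 species with the 14-column diet+clade
design give df = 141).  AIC = −2ℓ + 2k with k = fixed effects + 1 (σ²)
+ 1 more when α is estimated; candidates with ΔAIC ≥ 3 from the minimum
(computed on unrounded AICs) are flagged as substantially weaker,
equivalent to roughly p = 0.051.

## Branch-length schemes

Composite topologies assembled from supertrees carry no usable branch
lengths, so two assignment schemes are provided.  The arbitrary-ultrametric
("time-proportional") scheme sets every internal edge to 1 and stretches
each terminal edge so all tips sit at the same depth — the maximum number
of edges on any root-to-tip path.  The literature describes this method
only as producing "arbitrary ultrametric" branches; the operation is
isolated in one function so an alternative (e.g. node height by descendant
count) can be swapped in without touching anything else.  The unity-branch
scheme sets every edge to exactly 1 (not ultrametric; used as a robustness
variant for the λ estimates).  Polytomies are retained, never randomly
resolved: the covariance construction and the parsimony engine both handle
them natively.  Zero-length terminal branches are allowed with a warning.

## Pagel's λ

λ multiplies the off-diagonals of C; μ and σ² are profiled analytically at
each λ, leaving a bounded scalar likelihood search (tolerance 1e-8,
deterministic) on [0, λ_max] with λ_max = max(diag C)/max(off-diag C) — the
largest value keeping the transform interpretable, which permits estimates
slightly above 1 on near-ultrametric trees.  Boundary candidates (0, 1,
λ_max) are always evaluated so a boundary optimum cannot be missed.
Significance is a likelihood-ratio test against λ = 0 on one χ² degree of
freedom; the tiny p-values this produces for strongly Brownian traits match
the magnitudes reported for the real data.  On a star phylogeny all
off-diagonals are zero and the likelihood is flat in λ — the estimate is
meaningless there by construction, not by failure.

## PTP test

The parsimony length of a multistate character is computed by the exact
unordered (unit-cost) algorithm, generalized to multifurcations by the
counting rule: at a node with m children, each state is counted across the
child candidate sets, the node keeps the states attaining the maximum count
k, and m − k steps are charged.  On bifurcating trees this is the familiar
intersection/union rule; on polytomies it remains exact, which the test
suite verifies against an independent Sankoff dynamic-programming oracle on
500 random instances.  Step counts depend only on topology, so the depth of
the randomized trees cannot affect them (asserted across rescalings).

The null distribution maps the observed character onto independent Yule
topologies over the same taxa (uniform pure-birth; depth rescaled to 10 to
match the randomization setting used for the study), with the classical
tip-state shuffle available as an alternative scheme.  The p-value is
#{null ≤ observed}/n_perm; when the count is zero the reported value is
10/n_perm rather than an exact zero.  Note the floor's consequence: at
n_perm = 199 the smallest reportable p is 0.0502, so the conventional 0.05
threshold is unreachable — use the standard 999 or 9,999 permutations.
All permutation streams derive from a single seed; replicates advance a
counter, never system entropy.

## Synthetic data

The generator emulates the study's structure: a 155-tip Yule tree of depth
10; seven monophyletic clades obtained by repeatedly splitting the largest
subtree and labeling blocks by decreasing size (the two largest get the
labels of the study's dominant clades); diet (7 states, per-pair rate
0.025 — chosen to give a few dozen parsimony steps at n = 155, like the
real diet character) and flight (3 states, rate 0.008) under an equal-rates
Markov process; log₁₀ body mass by Brownian motion (rate 0.064 per unit
depth, root 2.7 ≈ 500 g, spanning roughly 10 g–30 kg); and

    log_cecum = −1.324 + (1/3)·log_mass + clade offset + diet offset + ε,

with offsets set to the study's best-model estimates and ε drawn MVN with
covariance σ²·exp(−0.17·d) (σ² = 0.20 on the log₁₀ scale, residual SD
≈ 0.45, matching the order of the published coefficient SEs at n = 155).
Raw cecal length is back-transformed as 10^log_cecum − 0.1 and clipped at
0, so species with "essentially absent" ceca arise and exercise the
+0.1 cm constant.  What the generator does *not* emulate: correlated
evolution of diet and mass, realistic clade-specific mass distributions,
unequal diet transition rates, and measurement error — so passing recovery
tests demonstrate the estimators work when their assumptions hold, not that
the real data meet those assumptions.

## Numerical choices and calibration caveats

- Covariance solves use Cholesky factorization; non-positive-definite
  transforms raise rather than being silently regularized.  Simulation
  falls back to an eigendecomposition with clipped eigenvalues only for
  exactly semidefinite generators (e.g. λ = 0 with zero-length tips).
- The OU α profile is a 40-point log-spaced grid on [1e-6, 500/depth]
  followed by bounded refinement (tolerance 1e-6); rank deficiency in any
  ladder cell is reported per cell without aborting the ladder.
- Design matrices span the factor levels actually present; a missing
  *reference* level is an error (its contrasts would be undefined), and the
  pipeline substitutes the modal level with a logged notice.
- **α is upward-biased when clade effects are in the design.**  Clade
  dummies absorb deep phylogenetic variance, so the profile-ML decay rate
  roughly doubles relative to its generating value on synthetic replicates,
  shrinking clade-contrast standard errors below nominal (≈85% coverage of
  95% intervals).  With the residual correlation fixed at the generating
  rate, coverage is nominal (≈95%) — the interval machinery itself is
  calibrated.  Fitted α values from clade-bearing designs should therefore
  be read as effective weighting parameters, not as estimates of an
  evolutionary rate, and clade-contrast p-values as mildly anti-conservative.
- Reported ΔAIC is rounded to one decimal but computed unrounded;
  printed p-values below 1e-4 should be read as "< 1e-4", not as zero.

## Problem sizes

Recovery experiments use what a single desk run affords and what makes the
statistics readable: 200 replicates on 200-tip trees for λ recovery, 200
replicates of the 155-taxon design for coefficient coverage, 999–9,999
permutations for PTP, 500 random instances for the parsimony oracle.  The
analysis drivers default to the study-scale 155 taxa.

## Known limitations

Single-optimum OU only; no measurement-error (within-species) PGLS; no
mixed effects; λ is a signal statistic here, not a residual structure
offered inside the regression ladder (the ladder compares independence,
Brownian, and OU, which is how the original model set was framed).  The
alignment step matches species names exactly after whitespace/underscore
unification — deliberately no fuzzy matching, since a silent mismatch is
worse than an error.
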