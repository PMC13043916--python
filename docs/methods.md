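# Methods

This note documents the models, numerical choices and known limitations
behind eyevol's analyses. All trait values are log10-transformed before
any modeling (eye surface area in mm², forewing length in mm); the
transform is applied exactly once, guarded by a table flag.

## Trees and covariance

A `Phylogeny` is a rooted tree in flat preorder arrays (parent index,
branch length, label). The Brownian variance–covariance matrix has entry
`V[i,j]` equal to the shared root-to-MRCA path length; a nonzero root edge
(which pruning can create when one side of the root is removed) is shared
by every pair of tips and is added to all entries, so pruning followed by
VCV equals VCV followed by row/column subsetting exactly. Structure
transforms operate elementwise on `V`:

* Pagel's λ multiplies off-diagonals by λ (diagonal untouched);
* OU uses the non-ultrametric form
  `σ²/(2α)·exp(−α·d_ij)·(1 − exp(−2α·t_ij))` with `d_ij` the patristic
  distance and `t_ij` the shared depth, which reduces to the familiar
  stationary form on ultrametric trees and to BM as α → 0;
* EB maps shared depths through `(exp(r·t) − 1)/r`, `r ≤ 0`;
* white noise is `σ²·I`; the trend model keeps the BM covariance and puts
  the drift in the mean (`z0 + μ·depth_i`), so it is unidentifiable on
  ultrametric trees and is flagged as such rather than fitted.

Zero-length branches are allowed; positive semidefiniteness is verified
with a relative tolerance of 1e−10. Non-ultrametric trees work
throughout. Newick I/O goes through dendropy; a missing branch length is
an error, never a silent zero.

## Regressions

Everything is fit by full maximum likelihood, never REML, because model
comparison spans different fixed-effect structures; log-likelihoods carry
all normalization constants so AIC/AICc values are comparable across
correlation structures.

**PGLS.** `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` via Cholesky whitening; σ² profiles
analytically, and the structure's single free parameter (λ, α or the EB
decay) is profiled with bounded Brent, with the exact interval boundaries
re-checked (bounded Brent stays interior); a boundary optimum is reported,
not hidden. When a known sampling-variance diagonal `D` is supplied
(measurement-error PGLS), the covariance is `σ²·R(θ) + D`, σ² no longer
profiles in closed form and is optimized on a log scale inside the
structure-parameter search. Coefficient p-values are Wald t with `n − k`
degrees of freedom, labeled approximate.

**PGLMM.** The individual-level model
`y ~ N(Xβ, σ²ₚ·ZCZᵀ + σ²ₑ·I)` is profiled through a single
eigendecomposition of `ZCZᵀ`: for a variance ratio `γ = σ²ₚ/σ²ₑ` the
rotated model is heteroscedastic least squares, so β and σ²ₑ have closed
forms and γ is found by a coarse log-grid plus Brent refinement, with the
γ = 0 boundary checked explicitly. Species missing from the tree raise an
error; they are never dropped silently. Family contrasts use treatment
coding with Hesperiidae as the reference level when present; the
three-way wing×family×sex model is deliberately not offered. p-values use
the normal approximation, flagged as such.

**Phylogeny R².** `R² = 1 − exp(−(2/n)(ℓ_full − ℓ_reduced))` (the
likelihood-based flavor), comparing the phylogenetic mixed model against
the ordinary regression with the same fixed effects; clipped to [0, 1]
and guarded against nesting violations.

**Relative eye size** is the raw (response-scale) residual of the
species-level Brownian PGLS of eye on wing — used downstream only where a
covariate cannot enter the model (signal, trait-evolution fits, the
multi-rate models), since residuals-as-data is otherwise fragile.

## Signal and trait-evolution models

Pagel's λ is estimated by scanning the profile likelihood on a grid over
[0, 1] (mean and rate profiled analytically at each λ) and refining with
Brent; the grid is exported for plotting, and the p-value against λ = 0
is a χ²(1) likelihood-ratio test. λ̂ is invariant to affine trait
transformations.

The five homogeneous-rate models are MVN likelihoods with at most one
free covariance parameter; AICc is `AIC + 2k(k+1)/(n−k−1)`; Akaike
weights are computed over converged fits only, and non-converged fits
(including the trend model on ultrametric trees) are retained in output
with a flag but excluded from weights.

The default OU attraction bound is `α ∈ [1e−8, 10/tree height]`. Above
that ceiling the OU phylogenetic half-life drops under ~7% of tree
height, where the OU covariance is statistically indistinguishable from
white noise at these sample sizes; allowing it creates a degenerate ridge
on which OU spuriously outranks the true white-noise model in a
substantial fraction of datasets. The bound is an argument, not a
constant.

Posterior-tree sensitivity re-estimates λ (or the AICc-best model) per
tree; note that when a single empirical trait is evaluated across jittered
trees, every jittered tree is mildly misspecified for that trait, which
inflates the win rate of flexible models — a real feature of such
sensitivity analyses, not an artifact.

## Variable rates (rjMCMC)

The model regresses species-mean eye size on wing length with covariance
built from branch lengths times per-branch rate scalars, then
λ-transformed and scaled by the background rate σ². Priors: scalars
gamma(shape 1.1, scale rescaled so the prior median is exactly 1);
coefficients uniform on [−100, 100]; λ uniform on [0, 1]; σ² uniform on
(0, S] with S generous relative to the data scale. Shifts live on
discrete slots — one per branch and one per internal clade (stem
included) — each occupied independently a priori with probability
`expected_shifts / n_slots`; the default expected count (8) is
deliberately permissive, matching the behavior of reference rjMCMC
implementations whose posteriors carry many diffuse scalars. Under
rate-homogeneous data this still leaves essentially all branch medians at
r = 1.

Moves: 50% single-parameter random-walk updates (β, log σ², reflected λ),
50% reversible-jump (25% birth, 25% death, 50% log-normal perturbation of
an existing scalar; clade vs branch slots chosen 50/50 on birth). Birth
values are proposed from a heavy-tailed log-normal rather than the prior,
with the proposal density in the Hastings ratio, so large shifts are
reachable in one jump.

The likelihood is invariant to multiplying σ² by c while dividing every
scalar by c (the covariance is linear in the scalars), so the chain can
wander along that scale ridge. Recorded samples are therefore rebased by
the median edge scalar — pinning r = 1 to the majority of branches, which
is what "background rate" means — leaving the likelihood untouched and
making per-branch summaries identifiable. The consensus tree multiplies
each branch by the posterior mean of its (rebased) scalar.

Marginal likelihoods use stepping-stone sampling over a Beta(0.3, 1)
temperature ladder (`β_k = (k/K)^(1/0.3)`, default K = 32 for the
generic estimator; the pipeline uses a shorter ladder); the rung at β = 0
draws exact independent prior samples, and random-walk steps widen as
`1/√β` at low temperatures so near-prior rungs mix. The Bayes factor is
`2·(Δ log marginal likelihood)`, > 2 read as support for the variable
rates model. Diagnostics (bulk ESS, split-R̂) come from arviz; the
conventional targets are ESS > 1000 and R̂ ≤ 1.2.

Desk-scale default: 3 chains × 200,000 single-proposal iterations,
burn-in 20,000, thinning 20 — about a minute at 59 tips. Production-scale
runs are a config override, not a different code path.

## Penalized multi-rate BM

One log-rate η per node; the rate of an edge is
`exp((η_parent + η_child)/2)`. The objective is the exact trait
log-likelihood (ancestral state profiled by GLS) plus
`λ_pen · Σ_edges log N(η_child − η_parent; 0, branch length)` — the
log-density of the log-rates themselves evolving by unit-rate BM.
Gradients are analytic (the derivative of the MVN log-likelihood with
respect to each edge rate is a quadratic form in the edge's tip-mask
vector); optimization is L-BFGS-B from the homogeneous ML rate. Large
penalties (50) shrink the rate surface toward homogeneity; the standard
sweep is {0.1, 1, 10, 50}.

## Habitat and community-weighted means

Transect segments are buffered 10 m each side with rounded caps and
joins; each raster cell's coverage fraction is the exact area fraction of
the cell inside the buffer (shapely polygon intersection — no
supersampling error). Cells with fraction < 0.002 or the missing-data
marker are excluded from numerator and denominator alike; a segment with
no retained cells is flagged and excluded downstream. The segment habitat
value is `Σ f_i v_i / Σ f_i`.

Species habitat is presence-based: every species recorded on a segment
inherits the segment value once (duplicate records collapse), and the
species' metric is the median of its distribution. Abundance enters only
the community-weighted means, `Σ aₛtₛ / Σ aₛ`, with per-segment abundance
the mean across years. Coordinates are planar meters; no geodesy.

The habitat-effect PGLS standardizes the habitat predictor (and wing
covariate) to mean 0, SD 1, and by default profiles Pagel's λ *and* adds
each species mean's known sampling variance (`var(log10 eye)/n`) to the
covariance diagonal. Both matter: on trees with short terminal branches,
ignoring even ~1% white noise in species means makes the plain BM PGLS
wildly anti-conservative (test statistics inflated ~3×), while the
measurement-error λ-PGLS is calibrated (95% CI coverage ≈ 0.95–0.98 in
null simulations). CWM regressions are ordinary least squares across
segments and are intrinsically anti-conservative (segments share
species); they are reported as the field does, with that caveat.

## Synthetic data: what it emulates, and what it does not

The generator draws a Yule tree (59 species, depth normalized to 1),
designates the most stem-isolated clade of roughly 6–12 tips as the fast
"skipper-like" clade — mirroring an early-diverging family on a long stem
— and partitions the remaining tips into clade-consistent families, the
largest named Nymphalidae. Species log10 wing evolves by BM (rate 0.03
from root value 1.3 ≈ 20 mm); the eye-size deviation evolves by BM at
rate 0.02, multiplied by 10 inside the fast clade. Individuals (6–9 per
species, alternating sexes, ~443 total) get their own wing draw
(within-species SD ≈ 0.045 log10 units, i.e. ~10% of wing length — a
realistic level of intraspecific size variation), an eye value on the
individual-level allometry (slope 0.55, intercept −0.30), a +0.11 male
offset, and residual noise (SD ≈ 0.045). Posterior tree sets jitter
branch lengths by i.i.d. log-normal factors (SD 0.1). Monitoring data use
a Gaussian-smoothed cover raster (mean 50%, SD 30%, 10 m cells), straight
transects split into 50 m segments, Gaussian niche occupancy around each
species' cover optimum, 1 + Poisson abundance, and two species withheld
to emulate incomplete survey coverage. The trait–habitat coupling
`habitat_effect` interpolates between independence (0, the default) and
deterministic coupling (1).

Not emulated: real geography or spatial survey bias, temporal dynamics,
observation error in occupancy, family-correlated body-size structure
beyond what the tree induces, and the anatomical distinctness of
superposition eyes (the fast clade is fast in *rate*, not shifted in
*intercept*). Passing tests therefore demonstrate estimator correctness
and calibration under a faithful statistical caricature — not robustness
to every feature of field data.

## Problem sizes

Tests and the acceptance script run at the study's own scale — 59
species, ~443 individuals, 240 monitoring segments — with MCMC at the
desk-scale default (3 × 200k, or 10 seeded single-chain 200k runs for the
shift-recovery check) and stepping-stone ladders of K = 8 rungs × 8k
iterations in the pipeline; the generic stepping-stone estimator is
validated against a conjugate-model closed form at K = 32.
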