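# Methods

This note documents the statistical model, the synthetic data generator,
and the numerical choices behind `paleoniche`, in enough detail to audit
or re-implement any piece.

## 1. The modelling framework

### Presence/background design

Occurrences are treated as presence-only data. For each collapsed
presence, `ratio` (default 50) background points are drawn uniformly,
with replacement, from the land, ice-free cells of the presence's time
slice; the draw is repeated `n_repetitions` (default 25) times with
seeds spawned from one master seed, and every downstream analysis is
repeated per draw. Time matching makes the background represent *what
was available when the animal was observed*; with-replacement sampling
from cells is unbiased and presence cells remain eligible (background is
availability, not absence).

The per-slice presence:background ratio is therefore constant (1:ratio),
but the **normalization** of the presence intensity is not: the total
suitable area and the number of ice-free land cells change through the
glacial cycle, so the implied per-slice intercept of the logistic
contrast varies with time. Both model formulas therefore include a
univariate smooth of time, `g(t)`, to absorb this offset. Without it the
offset leaks into the environment × time interaction terms and
masquerades as niche change (we observed systematic false selections of
the changing-niche model on constant-niche truth before adding it).

### Smooths

All smooths are penalized regression splines: cubic B-spline bases on
equally spaced knots spanning the training range, with second-order
difference penalties on the coefficients (P-splines). The penalty null
space contains exactly the constant and linear functions of the
covariate. Basis dimensions default to k = 16 for BIO6 and k = 10 for
the other environmental variables (BIO6 response curves need the extra
resolution; these are also the caps suggested by the basis-dimension
check), k = 5 for time margins and the time smooth. A `basis="linear"`
option gives a single unpenalized centered-linear column, which reduces
the term to ordinary logistic regression — used for oracle tests.

Tensor-product interactions `f(x, t)` take the row-wise Kronecker
product of the two marginal bases with one penalty per margin
(`S_x ⊗ I` and `I ⊗ S_t`), so wiggliness in the environment and time
directions is penalized separately. Two identifiability choices:

* the **environment margin is centered** (sum-to-zero over training
  rows) before the product. This removes every pure function of time
  from the tensor's span. Rationale: (i) a pure time effect belongs to
  `g(t)`, not to the interactions; (ii) with five tensors, the
  unpenalized linear-time function in each would otherwise be exactly
  collinear across terms, making the penalized normal equations
  singular. Environment main effects (functions constant in time)
  remain exactly representable and cost nothing under the time penalty,
  so a changing-niche tensor can shrink freely back to a constant-niche
  term.
* every block carries an overall sum-to-zero constraint against the
  intercept, absorbed by a QR reparameterization stored with the block.

A coefficient field constant along the time margin has zero time-margin
penalty (null-space property), which is what makes "no change" the
cheap default rather than an accident of smoothing.

### Fitting

For fixed smoothing parameters λ the coefficients solve penalized IRLS
(convergence: relative change of the penalized deviance < 1e-8, cap 200
iterations, with step-halving; a step search that finds no descent
direction terminates as numerically stationary). The λ are selected by a
REML-type (Laplace-approximate marginal likelihood) criterion using the
generalized Fellner–Schall multiplicative update

λⱼ ← λⱼ · [tr(S_λ⁻ Sⱼ) − tr((XᵀWX + S_λ)⁻¹ Sⱼ)] / (βᵀ Sⱼ β),

one linear solve per penalty per outer iteration. Updates are accepted
only if they improve the criterion and are damped in log space
otherwise; the loop stops on λ stagnation or criterion convergence
(outer cap 40). AICc and GCV are available as alternative criteria via
coordinate golden-section search.

Two numerical details matter:

* the pseudo-determinant and pseudo-inverse of each block's total
  penalty use the block's **structural rank**, computed once at unit λ.
  An adaptive eigenvalue cutoff makes the criterion discontinuous when a
  tensor's two λ differ by many orders of magnitude, and the
  discontinuity systematically rewards λ_env → 0 (spuriously wiggly
  environment margins).
* the complexity guard γ (default 1.4) tempers the likelihood during
  selection (equivalent to fitting with penalties γλ), the standard REML
  semantics; under AICc/GCV it multiplies the effective degrees of
  freedom instead.

### Scores and model choice

Effective degrees of freedom are tr(A) with A = (XᵀWX + S)⁻¹XᵀWX the
influence matrix, per-term edf the partial traces. **AIC uses the
smoothing-bias-corrected degrees of freedom tr(2A − A²)** (≥ tr A, equal
for unpenalized fits): partially shrunk directions cost extra because
their smoothing parameters were estimated from the same data. With plain
tr(A) the changing-niche model wins small spurious AIC margins on
constant-niche truth (4/10 repetitions in our calibration at ~300
presences); the corrected penalty restores the null selection rate to
0/10 while leaving the change-point selection margins (ΔAIC ≈ 40–90)
untouched. Deviance explained is 1 − D/D₀ against the intercept-only
fit; Nagelkerke R² is [1 − (L₀/L₁)^(2/n)]/[1 − L₀^(2/n)]. "Better
supported" is only called decisive at |ΔAIC| > 2; the winner is the
AIC argmin regardless.

### Evaluation, ensembles, importance

The Continuous Boyce Index slides 101 windows of width 0.1 × range over
the available-cell predictions (all land, ice-free cells of all slices);
per window F = (presence share)/(availability share); BCI is the
Spearman correlation of F with window midpoints, windows with zero
availability dropped. Fits with BCI > 0.8 enter mean and median
ensembles; the higher-BCI ensemble is used for projection. At the
default study scale (~650 presences) member BCIs run ≈ 0.83–0.97 across
seeds; at substantially smaller presence samples the BCI estimate is
noisy enough that the 0.8 gate occasionally rejects sound fits.

Variable importance partitions deviance: *total* = deviance explained by
a model containing only that variable (keeping its time tensor and
`g(t)` so the family is unchanged), *unique* = full-model deviance
explained minus the drop-one model's, *shared* = total − unique.
Penalization can push unique a hair negative; values are clipped at 0
(observed slack ≪ 0.01).

### Diagnostics

* Pearson correlation screen over the environmental variables, fail at
  |r| ≥ 0.7.
* Concurvity per term: R² of projecting the fitted term component onto
  the span of the intercept and all other terms' columns; gate 0.8. The
  time smooth routinely shows elevated concurvity with the tensors —
  expected, since tensors carry time structure — and is reported, not
  failed.
* Randomized-quantile (PIT) residuals from 250 simulated response
  vectors: KS uniformity test; dispersion via the observed Pearson χ²
  against its simulated distribution; outliers (observations outside
  the simulated range) tested two-sided against a Poisson with mean
  Σᵢ[μᵢ(1−μᵢ)^n_sim + (1−μᵢ)μᵢ^n_sim] — the continuous-response outlier
  rate 2/(n_sim+1) is wrong for Bernoulli data. Marginal residual tests
  for 0/1 responses have limited power against mean misspecification
  that preserves prevalence; they chiefly catch overconfident or
  miscalibrated fits.
* Moran's I on residuals: inverse great-circle-distance weights within
  a time slice, zero across slices, row-standardized; coincident points
  floored at 1 km; permutation p from label shuffles (default 999).
  Pass if p ≥ 0.05 or |I| < 0.1 (both configurable).

### Projection

The ensemble is evaluated on all land, ice-free cells per slice (ice
masked **before** thresholding; ice is treated as non-habitat
throughout). One species-level MPA threshold — the largest t with
≥ 99% of presence predictions ≥ t, equal to the ⌊n(1−c)⌋-th smallest
prediction — binarizes all slices. Period summaries average the binary
maps within pre-LGM/LGM/Late Glacial/Holocene over cells that are land
in every member slice, carrying the union ice mask as display metadata;
boundary slices belong to the older period (18 kya is LGM).

## 2. The synthetic data generator

The generator produces the study conditions, not climatological realism:

* **Grid and time axis**: 1° cells over 10°W–30°E, 35–60°N (desk scale;
  the real reconstructions are 0.5°), slices every 1000 y to 22 kya and
  2000 y before, i.e. 27 slices in the 7.5–47 kya window. A static
  land/sea mask (~85% land) comes from a seeded smooth random field.
* **Climate**: each variable is baseline + latitudinal/longitudinal
  gradient + a static seeded smooth noise field + trend_amplitude ·
  g(t), with the glacial index g(t) ramping 0→1 between 10 and 20 kya.
  Defaults (BIO5 −6 °C, BIO6 −10 °C, BIO12 −250 mm, NPP −150 at full
  glacial; rugosity static) keep all pairwise correlations below the
  0.7 screen; a `collinear` scenario intentionally violates it. An ice
  sheet descends from 70°N to 54°N with g(t), monotone through the
  deglaciation.
* **Niche**: a product of per-variable Gaussian response curves (so
  suitability is in [0,1] and bounded by every marginal). The default
  change-point scenario shifts the BIO6 optimum from −12 °C to −2 °C at
  16 kya; the constant scenario has no change point.
* **Sampling**: 25 presences per slice (~650 after collapse, matching
  the scale of well-sampled late-Quaternary megafauna datasets, whose
  collapsed per-species counts run 400–800), drawn with probability ∝
  suitability × an east–west logistic effort ramp, placed at cell
  centers with ages jittered uniformly within just under half the
  slice's minimum neighbour gap — so nearest-slice assignment provably
  round-trips to the generating slice.

**What the generator does not emulate**, hence what passing tests do not
show about real data: spatially correlated climate change, coastline
change, dating error beyond uniform jitter (no calibration-curve
structure), taphonomic loss, or species interactions. One interaction of
the generator's own ingredients is worth flagging: a *time-constant*
spatial sampling bias under a *drifting* climate changes the
environmental profile of the well-sampled region through time — a
genuine change in the realized, sampled niche. The default change-point
scenario keeps the bias (robustness to it is part of what the framework
claims); the constant scenario samples unbiased, because its role is a
null-calibration condition and the aliasing would otherwise be a true
signal, not a false positive. On real archaeological data this aliasing
is indistinguishable from niche change within this framework.

## 3. Validation experiments and problem sizes

The canonical experiments (module `paleoniche.experiments`, run by
`scripts/acceptance.py` and the end-to-end test suite) use these sizes,
chosen to give stable statistics at desk scale:

* GLM equivalence: n = 5000, linear-basis GAM vs an independent plain
  IRLS logistic solver; agreement ~1e-12 in fitted probabilities.
* Detection: 10 background repetitions at ~300 presences (12/slice),
  change-point and constant truths; selection rates 10/10 and 0/10 in
  our runs, mean ΔAIC ≈ +50 and −2…−7.
* Change-time localization: 3 repetitions at study scale with a finer
  time margin (k_time = 10; localizing a transition to one slice needs
  the resolution). The statistic is the steepest-transition point of
  the contrast effect(x = pre-optimum) − effect(x = post-optimum) on a
  100-year time grid — robust to additive level shifts and smoothing
  smear that bias a plain zero crossing. Errors 0–600 y on most seeds,
  occasionally ~1200 y on unlucky realizations.
* Boyce and MPA: exact equality with brute-force double-loop oracles on
  50 random fixtures each; BCI = 1 on an exactly monotone construction;
  null BCI mean within 3 SE of 0 over 100 draws.
* Moran's I: 200 trials, 50 points, 199 permutations — permutation p
  uniform (KS), mean permuted I within 3 SE of −1/(n−1).
* Residual calibration: 100 well-specified fits (n = 500); uniformity
  non-rejection ≥ 95% at α = 0.01 (observed 100%).
* End-to-end: 5-repetition pipeline at study scale — changing-niche
  selected, ensemble BCI ≈ 0.79–0.95 across seeds, ≥ 99% of presence
  cells recovered by the binary maps, and re-runs byte-identical.

## 4. Known limitations

* Thin-plate regression splines are not implemented; P-splines are the
  basis family. Both are low-rank penalized smoothers; results that
  depend on the basis family rather than the penalty structure should
  not be trusted from either.
* The Fellner–Schall/LAML optimizer is first-order; on small or nearly
  separable datasets it can stop at slightly different λ than a full
  Newton marginal-likelihood optimizer would.
* The AIC comparison conflates any unmodelled time-varying sampling
  process with niche change (see the bias-aliasing note above); this is
  a property of the framework, not of this implementation.
* No uncertainty bands on interaction surfaces; surfaces are point
  estimates averaged over background repetitions.
* No regridding or interpolation between slices; observations are
  assigned to the nearest slice (ties to the older).
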