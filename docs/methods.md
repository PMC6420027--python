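# Methods

## Task model

The arm is a planar three-segment chain with lengths (0.55, 0.225, 0.225)
in arm-length units and no joint limits; postures are real-valued joint
triples and are never wrapped ("unfolded" angles), although the reach
endpoint is 2π-periodic in every joint. Sixteen training targets lie on a
regular polar grid (radii 0.25/0.45/0.65/0.85 × angles π/4…3π/4) in the
upper quadrant; nine test targets (five interior, four exterior) probe
interpolation and extrapolation. The two home postures H₁ = (¾π, 1.99, π)
and H₂ = (1.51, 1.99, 0) reach the same goal point (−0.39, 0.39) but sit
in different parts of motor space: in H₁ the distal joint is folded back so
the endpoint rests on top of the q₂ joint, making q₂ locally ineffective;
in H₂ the distal joint is extended, making q₂ maximally effective.

Two interior test targets are listed in the source task description at
polar angle 4/3π, outside the trained quadrant, while being described as
lying within the training array; the default geometry uses the
presumed-intended 1/3π ("corrected" variant), and the verbatim listing is
retained as the "printed" variant for audits. Nothing downstream depends
on which variant is chosen.

The baseline posture q\* = (1.93, 1.99, π/2) is the level-fingers posture
of the manual-control interface. It is *almost* exactly the H₁–H₂ midpoint
in motor space (its projection coordinate on the H₁–H₂ line is 0.5002, not
0.5000, because q\*₁ = 1.93 is a rounded value); tests assert the midpoint
property at 10⁻³.

## Goal Babbling learner

The inverse model g is a blend of K = 16 local affine maps, one centred on
each training target, with normalized Gaussian responsibilities in goal
space. The bandwidth defaults to the median nearest-neighbour spacing of
the training targets (≈ 0.17 arm lengths), the scale below which the local
models are effectively independent. At initialization all gains are zero
and all offsets equal the home posture, so the model maps *every* goal to
the home posture — the minimal inverse model that learning expands.

Each training step executes q⁺ = g(x\*) + e at the current sub-target x\*,
observes x_obs = f(q⁺), and takes one stochastic-gradient step of rate η
on the responsibility-weighted squared posture error, pulling g(x_obs)
toward q⁺. Regressing onto the observed outcome rather than the intended
one is the defining Goal Babbling trick: executed movements are always
valid training pairs for the inverse model regardless of whether they hit
their goal.

Two per-sample weights multiply the learning rate, both on by default and
individually switchable:

- **direction weight** max(0, cos θ) between the intended movement
  direction (x\* − x_prev) and the achieved direction (x_obs − x_prev):
  samples that move the endpoint away from the goal do not reinforce the
  model;
- **efficiency weight** min(2, ‖x_obs − x_prev‖ / ‖q⁺ − q_prev‖), the
  goal-space progress per unit of motor-space movement. This implements
  the effort-sensitivity of the weighted-regression scheme used in the
  Goal Babbling literature. It is what makes degree-of-freedom use
  condition-dependent: in H₁, movements dominated by (goal-ineffective)
  q₂ noise travel far in motor space but nowhere in goal space and are
  down-weighted, so q₂ noise is not absorbed into the model, whereas in
  H₂ the same movements produce goal progress and are retained. Without
  this weight the simulated populations lose both the faster first-block
  learning in H₂ and the larger end-of-training |q₂| loading in PC1 in
  H₂ — the two condition signatures of the learning rule.

### Exploratory noise

Exploration is a goal-linear perturbation e = A·(x, y, 1) whose nine
coefficients follow a Gaussian random walk with per-step standard
deviation σΔ = 0.005. After every step each joint's coefficient row is
rescaled so that the root-mean-square of the induced perturbation over
the training-target distribution equals σ = 0.5 rad, which bounds the
walk and makes the marginal amplitude equal across joints by
construction. Because the amplitude constraint is enforced over the
target *region*, the marginal standard deviation at a single fixed goal
varies with the goal's position (≈ 0.7–1.1 σ across the target region);
tests check the amplitude at representative training targets. The walk's
mixing time scales as (σ/σΔ)², so amplitude statistics are tested with a
faster-mixing walk (σΔ = 0.05) while continuity (mean step size ∝ σΔ) is
tested at the default.

### Schedules and populations

A block presents 40 targets drawn i.i.d. from the 16 training targets,
each draw replaced by the home endpoint with probability 0.1; transitions
interpolate linearly in goal space over 25 steps (24 intermediate
sub-targets + the target), giving exactly 1000 online updates per block.
Ten blocks are run, each followed by a feedback-free evaluation of the
nine test targets with noise and learning disabled. Populations use 100
agents per condition with per-agent seed = base seed + index; the seed
stream does not depend on condition, so the two conditions see paired
noise.

## Synthetic human sessions

The human-like generator is *not* a model of human learning; it plants
the statistical structure the analysis is meant to detect so each
pipeline stage has recoverable ground truth:

- **location bias**: per block b the central posture is
  c_b = H + λ_b (q\* − H), λ defaulting to 0.3 — solutions sit between
  the condition's home posture and the baseline posture;
- **planted synergy plane**: expert reach postures are computed by
  damped-least-squares inverse kinematics *constrained to a 2-D plane*
  through c_b, so noiseless sessions are exactly rank-2 in motor space.
  The default plane is spanned by the shoulder-rotation direction (pure
  q₁) and the fold/extend direction of q₂/q₃ — the branch (toward 0 or
  2π per joint) is chosen automatically so the in-plane radius sweep
  covers all target radii, which makes the in-plane IK solvable for
  every target from both home postures (residuals < 0.01; a coarse
  65×65 grid seeds the iteration to avoid folded-arm local minima,
  preferring near-centre seeds). A per-block rotation schedule can tilt
  the plane (default: none);
- **noise schedules**: executed posture = expert + in-plane Gaussian
  noise (std 0.6 → 0.2 rad across the 24 blocks) + out-of-plane noise
  (0.3 → 0.05 rad), emulating high-variance early exploration that
  consolidates onto two synergies;
- **missing trials**: each test reach is dropped whole (no posture, no
  endpoint) with probability 0.014, emulating sensor dropouts.

What recovery tests show — and what they do not: the pipeline reads back
the planted plane (principal angle < 15° in the final window), the
two-dimensionality (PC1+PC2 > 0.9), the declining summed variance, and
the condition-signed location bias. Because experts must genuinely reach
all nine targets, the between-target expert spread contributes a large,
condition-dependent constant to the summed variance (the folded H₁ plane
needs wider in-plane excursions than H₂'s), and the mean in-plane IK
offset shifts the realized projection coordinate away from λ itself; the
generator therefore guarantees *ordinal* ground truth (decline, sign of
the condition difference), not the literal λ value. None of this implies
anything about real human data beyond testability of the pipeline.

## Analysis pipeline

PCA is covariance-based on mean-centred, unscaled posture matrices.
Windows pool 3 consecutive test blocks for 24-block human-style sessions
(27 reaches) and single blocks for 10-block agent sessions (9 reaches in
3-D suffice); both are configuration options. Loading signs are fixed by
making each component's largest-magnitude entry positive. Windows with
fewer than 4 usable rows or zero variance are flagged degenerate and
excluded from population summaries rather than imputed. The location
measure is s = ⟨c − H₁, H₂ − H₁⟩/‖H₂ − H₁‖², so s = 0 at H₁ and 1 at H₂.
The "central posture" of a session is the centroid of its last analysis
window.

## Statistics

The two-way repeated-measures ANOVA uses the classical fully-within
decomposition: each factor is tested against its own factor-by-unit
interaction; partial eta-squared is SS_effect/(SS_effect + SS_error); no
sphericity correction is applied (uncorrected degrees of freedom are
reported). The repeated-measures unit defaults to the grouping key of the
analysis design — for counterbalanced human-style data the finger mapping
(each mapping occurs once per condition, giving a within-unit condition
contrast). Units with incomplete cells are dropped listwise. The sign
test doubles the smaller exact binomial tail (capped at 1). The Wilcoxon
signed-rank test drops zeros, mid-ranks ties, reports the
tie-corrected-variance normal z without continuity correction, and uses
exhaustive sign-assignment enumeration for p when n ≤ 12. The Friedman
statistic uses within-row mid-ranks with the tie-corrected denominator.
All four are calibrated under a seeded Gaussian null (empirical size
0.03–0.07 at α = 0.05, 1000 replicates each).

## Problem sizes and numerical choices

The test suite and the acceptance script run the full study-scale
experiment — 100 agents × 10 blocks × 1000 updates per condition (a few
minutes on one CPU); pilot-scale variants in unit tests use smaller
populations. Monte-Carlo checks use 10⁶ samples (redundancy map), 3–4×10⁴
steps (noise statistics), and 10⁴ draws (binomial rates). Damped least
squares uses damping 0.1 with residual tolerance 10⁻⁸ and a hard
iteration cap of 200. Predictions at goals numerically outside all
responsibility support fall back to the nearest prototype.

## Known limitations

- The local-linear-map learner follows the cited Goal Babbling family but
  is not a bitwise re-implementation of any specific reference code; all
  population-level claims are statistical, not trajectory-exact.
- An explicit effort-minimizing cost term is not implemented; effort
  sensitivity enters only through the efficiency weight.
- The exploratory-noise random walk is affine in the goal; purely
  joint-space walks are not provided.
- The synthetic generator leaves training-phase kinematics schematic
  (target tours are recorded; no tracking-error model).
- The deposited-archive importer is schema-mapping-driven and validated
  against synthetic mock archives only; field names for a real archive
  must be supplied from its legend file.
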