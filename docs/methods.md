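# Methods

## The model

`tsbisse` implements the binary-state speciation and extinction (BiSSE)
model with piecewise-constant rates in time.  A lineage in state
*i* ∈ {0, 1} speciates at rate λ_i, goes extinct at rate μ_i and switches
state at rate q_ij (all Myr⁻¹).  Time-slicing replaces each rate by a step
function of age with shared breakpoints (e.g. a single cut-off at 2.6 Ma
separating Quaternary from pre-Quaternary dynamics), giving per-epoch rate
sets {λ0, λ1, μ0, μ1, q01, q10}.

Along a branch, the per-state extinction probability E_i(s) and data
partial D_i(s) obey the usual BiSSE ordinary differential equations,
integrated in age s (towards the past):

    dE_i/ds = μ_i − (λ_i + μ_i + q_ij) E_i + q_ij E_j + λ_i E_i²
    dD_i/ds = −(λ_i + μ_i + q_ij) D_i + q_ij D_j + 2 λ_i E_i D_i

Incomplete sampling is the skeletal-tree correction applied at the tips
only: a tip observed in state i is initialized with D_i = f_i,
D_{1−i} = 0 and E_j = 1 − f_j for both j, where f_j is the probability
that an extant species in state j is present in the tree.  At internal
nodes D_i ← λ_i(node age) · D_i^left · D_i^right; a node exactly at a
breakpoint uses the older epoch's rate (deterministic tie-break).  At the
root the states are aggregated with state-weighted ("FitzJohn") weights
w_i = D_i / ΣD_j by default (equal weights and a fixed prior are options),
and survival conditioning divides state i's contribution by
λ_i (1 − E_i(T))², T the root age.  Both root knobs are exposed so their
sensitivity can be checked; the defaults mirror common practice for this
model family.

## Numerics

* Branch ODEs are integrated with an adaptive embedded Dormand–Prince
  5(4) pair, rtol 1e-8 / atol 1e-10, restarted exactly at every epoch
  boundary (slicing is therefore inert when the two epochs share rates;
  this is tested to 1e-8).  E components are clamped to [0, 1] against
  round-off drift.
* D partials are rescaled to unit maximum at every branch end and node,
  with the log factor accumulated separately; trees with thousands of
  tips would underflow otherwise.
* A per-segment step-size floor (span/1500) bounds the cost of any
  single branch integration; it only binds at extreme rate × span
  products far from plausible optima, where overflowing or persistently
  inaccurate steps make the evaluation fail cleanly (the optimizers see
  -inf).  Within the box bounds actually visited near optima the floor
  is inert.
* Zero-length branches skip integration and pass values through
  (posterior tree samples may contain them).
* Ultrametricity is validated at parse time with a relative tolerance of
  1e-6 of tree height; tip ages are then snapped to exactly 0.
* The constant-rate reductions have closed forms used as independent
  oracles: the reconstructed birth–death likelihood (with the λ → μ limit
  handled analytically) and the 2-state Mk pruning likelihood built from
  the exact 2×2 transition matrix.  With state-independent rates the
  BiSSE likelihood factorizes into birth–death × Mk; the test suite
  checks this identity to 1e-6, and checks the adaptive integrator
  against a fixed-step RK4 pruning oracle to 1e-5.

## Model space and selection

A candidate model maps the twelve two-epoch rate slots onto shared free
parameters.  Per rate family (λ, μ, q) the generator supports: shared or
state-dependent, each either time-constant or shifting at the breakpoint,
plus one-state-only shifts (the rate of a single state changes across the
boundary).  The canonical set contains 43 models: the 8 time-constant
combinations, 24 single-family shift models, 8 one-state-only extinction
or transition shifts on uniform backgrounds, the 2 joint μ+q shift
models, and the fully free 12-parameter model.  The composition is a
documented, auditable choice — the exact historical composition of such
model sets is rarely published in full — and every selection entry point
accepts a user-supplied list instead.

Nested pairs are compared with likelihood-ratio tests (χ² with df = Δk;
nesting is verified structurally as a partition coarsening); non-nested
models with AIC.  The final pick follows the parsimony rule: among models
within ΔAIC < 2 of the optimum, take the fewest parameters, breaking ties
by lower AIC and then model name.  The significance level defaults to
0.05 and is configurable.

## Inference

Maximum likelihood works on log-rates inside [1e-8, 1e3] Myr⁻¹ with
L-BFGS-B followed by a Nelder–Mead polish, from multiple starts perturbed
around a character-independent heuristic (r̂ = log(n/2)/T; λ ≈ 2r̂,
μ ≈ r̂, q ≈ r̂/5).  SSE likelihood surfaces can be multimodal under
constraints, hence the multi-start default (5; heavy batch analyses use
fewer with informed initial values).

The Bayesian sampler is a univariate stepping-out slice sampler, one
coordinate sweep per generation, with independent exponential priors of
mean 2r̂ on every free rate (configurable).  Chains start at the MLE;
step widths are tuned during a 500-generation warm-up that is not part of
the returned trace; burn-in defaults to 10%.  On the tractable Yule
speciation-rate posterior (exponential prior ⇒ Gamma posterior) the
sampled 5/50/95% quantiles match the analytic quantiles at 10 000
generations, which is the calibration check for the whole MCMC path.

Posterior summaries pool post-burn-in samples across trees and report
5/25/50/75/95% quantiles per rate slot and epoch, plus the derived net
diversification r_i = λ_i − μ_i.

## Simulators

Three designs cover the validation studies:

1. **Neutral traits on fixed trees** — exact CTMC simulation with
   exponential waiting times; the full branch-segment history is kept.
2. **Birth–death trees conditioned on tip count and age** — the n−2
   non-crown branching ages are drawn i.i.d. from their closed-form
   conditional density (CDF ∝ (1−e^{−rt})/(λ−μe^{−rt}), inverted
   analytically, λ→μ limit included) and the topology by uniform
   sequential splitting.  This gives exact conditioning — 1774 tips and
   105 Ma every draw — where naive rejection would be infeasible near
   λ ≈ μ.
3. **Joint tree+trait simulation under time-sliced BiSSE** — forward
   Gillespie simulation from a single lineage at the origin age (crown
   start available), with per-state rates switching at breakpoints,
   extinct lineages pruned, and a tip-count acceptance window.  Exact-n
   conditioning has no tractable construction under state dependence, so
   a window (300–500 tips in the scaled-down shift studies) is used and
   the acceptance count recorded.

The shift studies fix the stated rates (extinction 0.02 → 0.3; transition
0.005 → 0.34 at 2.6 Ma).  Values the designs leave open are chosen once
as realistic for a palm-like radiation and documented here: speciation
0.2 Myr⁻¹ (matching the neutral-trait study's birth–death trees), a
baseline transition rate of 0.02 (the neutral study's rate) for the
extinction-shift design, origin age 35 Ma so that the 300–500 tip window
is reached with useful acceptance rates, and a 50/50 random root state.
Recovery fits use the model structure matching the generating process
(state-and-time-dependent in the shifted family, shared elsewhere), the
standard design for power studies of this kind.

## Ancestral states

Marginal probabilities are exact by construction: the pruning likelihood
is recomputed with each internal node clamped to each state and the two
clamped likelihoods normalized — O(n) prunings per tree, affordable to a
few thousand tips.  Stochastic character maps are sampled under the Mk
reduction (trait-only process): node states root-to-tips from their
conditional distributions, then endpoint-conditioned branch paths by
uniformization (exact; retry cap 10⁴ per branch guards pathological
inputs).  Map node frequencies converge to the matched marginal
reconstruction within 2/√n_maps, which the suite checks at n = 10 000.
The root prior for maps defaults to the stationary distribution of the
transition rates and is configurable.

## The time-window pipeline

Model structure is selected once at the reference cut-off (2.6 Ma) on a
reference tree, then held fixed while the breakpoint moves across the
grid (25, 20, 15, 10, 5, 2.6, 1, 0.5 Ma); at each cut-off an MCMC runs on
each sampled tree and the pooled recent-epoch quantiles form the
rate-through-time table.  "The rate of a time slice" is read as the
recent-epoch (younger than the cut-off) rate of the two-epoch model with
the breakpoint at that cut-off — the only reading consistent with
plotting one box per slice.  Regional analyses prune trees to region
members and recompute per-state sampling fractions from supplied regional
totals (without totals, unscored tips are allocated proportionally, which
cannot encode differential missingness — a documented limitation).
Trend flatness on null data is assessed with a Mann–Kendall test on the
per-cut-off posterior medians.

## The synthetic-data generator

The generator emulates the statistical structure of the palm dataset: a
birth–death tree (speciation 0.2, extinction 0.19 — high relative
extinction produces the right branch-length imbalance), posterior-like
replicates by relative log-normal node-age jitter (σ = 2%), fruit lengths
from two log-normal components on either side of the 4 cm threshold (so
the 3.5/4.5 cm sensitivity path is exercisable end to end), a
megafaunal-fruited root with transition rates calibrated so the measured
state-1 share hits the 12% target after per-state missingness (32% of
small-fruited and 18% of megafaunal species unmeasured), a
phylogenetically clustered two-region partition hitting ~16%/~10%
regional prevalences by clade-level swap optimization, and a taggable
clade (98 species at full scale) for exclusion runs.  The full profile is
2539 species × 100 trees; the desk profile (300 species × 10 trees, used
throughout the test suite) keeps runs light.

What the generator does **not** emulate: real palm taxonomy and
biogeography beyond these statistical targets, rate variation across
clades, diversity dependence, fossil information, or phylogenetic error
beyond node-age jitter.  Passing recovery tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to their violation.

## Problem sizes

The test suite and the acceptance script run everything at the scales
stated above: shift-recovery studies at 300–500 tips × 10 replicates,
neutral-trait studies at the full 1774 tips × 10 trees (Mk fits and
two-epoch LRTs), MCMC calibration at 10 000 generations, and
stochastic-map consistency at 10 000 maps.  The pipeline null runs at
the neutral-trait study's full 1774-tip scale across the 8-point cut-off
grid: smaller trees leave the youngest slices so data-poor that the
posterior medians shrink toward the exponential-prior mean, creating an
artifactual monotone trend that is a property of the scale, not of the
method.  Affordability comes from short chains (40 generations after a
15-generation warm-up — only per-cut-off medians are consumed) and
relaxed solver tolerances (rtol 3e-7), which leave the posterior
unchanged at that precision.  All other sizes are the package's chosen
desk-scale study conditions; the machinery accepts the full-scale
settings (2539 tips, 100 trees, 10 000 generations) unchanged.

## Known limitations

* Extinction rates are weakly identified from extant-only trees; MLEs of
  μ frequently hit the lower box bound on single trees (a well-known
  property of this model class, visible in the recovery studies'
  spread).
* The 43-model canonical space is a reconstruction of a conventional
  constrained model family, not a transcription of any specific published
  set; use the custom-list entry point to reproduce an exact historical
  analysis.
* Slice sampling is serial (one likelihood per coordinate step); very
  long chains on large trees are CPU-bound.
* No hidden-state (HiSSE-style) extension: trait-independent rate
  heterogeneity will masquerade as state effects, exactly as in the
  original model class.
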