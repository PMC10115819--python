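# Methods

## The extended pairwise maximum-entropy model

The package models the joint occurrence of N community components —
n_m binary genus presence/absence states and n_c chemical levels scaled
to [0, 1] — conditional on a per-sample environment ε = (ε_a, ε_s),
where ε_a ∈ {0, 1} indicates antibiotic treatment and ε_s ∈ [0, 1] a
scaled growth stage (days 3/30/60 → 0/0.53/1; the 0.53 midpoint is used
as a literal constant of the encoding, not derived from a formula).
The energy is

E(σ|ε) = −( Σ_{i<j} J_ij σ_i σ_j + ε_a Σ g_i^a σ_i
            + ε_s Σ g_i^s σ_i + Σ h_i σ_i ).

Two conventions are fixed here and tagged in all exports: the pair sum
counts each unordered pair once (double-counting would only rescale J),
and ε is a per-sample scalar pair shared by all components.  Continuous
components enter the same energy linearly; their conditional density on
[0, 1] is therefore a truncated exponential with a closed-form inverse
CDF, which is what both the Gibbs sampler and the synthetic generator
draw from.

### Estimation

The default estimator is Robbins–Monro stochastic approximation: with
observed sufficient-statistic means t̄ (per-component means, pairwise
products, and environment-weighted means), iterate
θ ← θ + a_t (t̄ − t̂_θ), where t̂_θ is estimated by one Gibbs sweep over
persistent chains — 50 chains per distinct environment, weighted by the
environment's sample share.  The gain decays as a_t = a0/(1 + t/τ) with
a0 = 0.1, τ = 500 over 5000 iterations, and the final estimate averages
the last 25 % of iterates (Polyak averaging), which removes most of the
residual simulation jitter.  These defaults recover U(−1,1) parameters
at r ≈ 0.98 on an 8-component system with 2000 samples per environment
and are exposed in `FitSettings`.

For all-binary systems with N ≤ 14 an exact backend computes model
moments and the Fisher information by state enumeration and maximises
the same likelihood by damped Newton ascent.  The two backends agree to
sampling error; the exact one exists because the significance machinery
refits thousands of times and the landscape module needs exactly
enumerable systems anyway.

Identifiability guards: if an environment column is constant its g
parameters are frozen at zero (they are absorbed into h, with a warning
when the constant is nonzero); a component observed always present or
always absent has a divergent h, capped at ±h_max = 10 so landscapes
stay finite.

### Significance

"Repeat the estimation many times and read p-values off the replicate
estimates" is implemented as parametric resampling: after the base fit,
each of n_reps repetitions re-simulates a dataset of the same size and
environmental design from the fitted model with an independent RNG
stream and refits it (warm-started).  The two-sided p-value of a
parameter is 2·min(frac(θ̂ ≤ 0), frac(θ̂ ≥ 0)), floored at
1/(n_reps + 1).  Re-running the optimiser on the *same* data would
measure only Monte-Carlo noise of the optimiser and could not be
calibrated; resimulation makes the replicate spread track the
estimator's sampling variability, and the null rejection rate at the
5 % level lands at ~5–7 % in the calibration experiment (200 datasets of
360 samples over the six-environment study grid).  A nonparametric
bootstrap over samples is available via `resample="nonparametric"`.

## Landscapes

A stable state is a binary state strictly lower in energy than all N
single-flip neighbours; plateaus are reported via a `flat` flag, never
silently merged.  Basins are computed by steepest single-flip descent
(ties broken toward the lowest component index) with pointer doubling
over the enumerated state space.  Continuous components have no
single-flip move, so they are clamped — by default at their dataset
means — and folded into the effective fields h_i + Σ_c J_ic σ_c of the
binary subsystem; the dropped additive constant shifts all energies
equally.  Minima are ordered by energy, which is also how the gradient
surface table indexes them (the ordering of states along a 1-D
"community state" axis is otherwise arbitrary).

## Network and response classes

Edges of the signed interaction network are pairs with p(J_ij) ≤ α
(α = 0.05 by default); an optional |J| threshold exists but is off, so
the network is thresholded on significance alone.  Response classes are
pure sign quadrants of (g^s, g^a) with a dead-zone half-width δ = 0 by
default — a raw scatter of fitted values carries no natural cutoff, and
δ > 0 is available when a conservative classification is wanted.  The
growth-stage axis is the same quantity whether written g^s or g^d.

## Association rules

Samples are itemised as: binary taxa (present items only), continuous
phenotypes split at their per-variable median (ties read "high",
deterministically), an age item, and a "CTC" item on treated samples.
Mining is a level-wise a-priori search with exact support counts and
rules generated from every antecedent/consequent split of each frequent
itemset; `max_len` caps itemset size on dense data.  Default thresholds
min_support = 0.2, min_confidence = 0.8 are configuration, not claims —
they are reported in output headers and should be tuned per dataset.
The miner is tested for exact agreement with brute-force enumeration
over random small instances.

## Causal inference

DirectLiNGAM assumes x = Bx + e with acyclic B and independent
non-Gaussian disturbances.  The causal order is found by repeatedly
selecting the most exogenous variable: for a candidate, each pairwise
comparison scores the difference of the two factorisations' approximate
joint entropies (maximum-entropy approximation with the log-cosh and
Gaussian-moment contrasts), and the candidate minimising the summed
squared losses min(0, LR)² wins; the winner is regressed out and the
search recurses on residuals.  Strengths are ordinary least squares of
each variable on its predecessors — no pruning, so small strengths are
reported as-is.  Residuals are screened with a normality test and
near-Gaussian cases are flagged: with Gaussian disturbances the
direction is unidentifiable and order recovery demonstrably degrades
toward chance (a documented property, not an error).

Changes from baseline ("delta") tables subtract each animal's day-3
value per variable; baseline rows (exactly zero) are retained by
default since the analysed change trajectories include day 3, and can
be dropped.  Internal standards — taxonomically nested family/genus
pairs whose direct strength should be ≈ 1 (tolerance 0.1) — validate a
run; a disconnected pair reports 0 and fails.  Because such pairs are
nearly collinear, orienting them reliably needs on the order of
thousands of rows; at 36 samples the orientation of the standard itself
is unstable, which is why the validation experiment runs at SEM scale.

Run configurations (which variables and rows enter an estimation) are
deliberately user-supplied.  The packaged end-to-end check uses
(treatment, growth stage, butyrate change) over all days: the stage
variable absorbs the large day-to-day drift that otherwise masks the
treatment effect, mirroring an analysis conducted with growth stages
included.  Configurations that include raw genus-abundance changes
order the binary treatment variable poorly — the generator's presence
effects are multiplicative, hence non-linear in abundance space, and a
linear non-Gaussian model misreads the heavy-tailed abundance deltas as
exogenous.  This is a real limitation of linear causal discovery on
abundance data, not a defect of the search.

## The synthetic study generator

`generate_study` emulates the target design: 12 animals in two balanced
groups, one sample per animal at days 3/30/60.  Genus intensities are
log-normal — per-genus baseline, growth-stage slope, treatment×stage
slope, an animal random effect (sd 0.3) and residual noise (sd 1.0) on
the log scale — normalised to relative abundances, which yields the
heavy-tailed, sparse tables that make the 0.001 presence threshold
meaningful (≈ 36 of 47 genera survive the prevalence window in a
typical draw).  Treatment effects scale with growth stage, so day-3
samples are unaffected.  The planted biology in the "dysbiosis"
profile: a methanogen-like genus strongly promoted under treatment
(log-slope +5), a butyrate-producing genus suppressed (−5), about a
third of the remaining genera mildly responsive (|slope| ≈ 1), fecal
butyrate reduced up to 50 % at the last stage, IGF-1 mildly raised and
serum IgA lowered under treatment.  Chemical and physiology values are
trend × lognormal-noise products, clipped nonnegative.  The "null"
profile zeroes every treatment term while keeping stage dynamics.

What the generator does *not* emulate: sequencing depth and read-level
noise, compositional coupling beyond closure, phylogenetic correlation
among genera, time-autocorrelated animal trajectories, or missing
samples.  Passing tests therefore demonstrate that the pipeline
recovers planted effects of realistic size from tables with realistic
sparsity and skew — not that it is robust to every artefact of real
16S data.

## Problem sizes and numerical choices

Experiments are sized so the whole suite replays quickly while keeping
each check statistically meaningful: sampler agreement uses a
5-component system (where 10⁵ sweeps resolve a total-variation distance
of 0.02; at N = 12 the empirical TV of even iid exact samples against
4096 states is ~0.08, so TV checks at that size are uninformative);
recovery uses N = 8 with 2000 samples per environment; calibration uses
200 datasets × 200 repetitions at 360 samples; causal recovery 100
seeds at n = 5000; the end-to-end pipeline 20 study seeds at the full
36-sample, ~44-component scale with a 3000-iteration fit.  Ties,
degenerate inputs and caps are handled as described above; probability
normalisation in the exact backend is done in log space via
log-sum-exp.
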