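# Methods

`poplearn` implements a probabilistic population-code observer for
near-horizontal motion-direction discrimination and estimation, the
machinery to fit it to individual observers and compare reduced
variants, and the nonparametric statistics used to characterize pre- vs
post-training behavior. This note records the model, the numerical
choices, and the places where the design was genuinely open.

## The observer model

**Encoding.** A stimulus direction s ∈ (−180°, 180°] (boundary at 0°,
rightward horizontal; CW = positive) is encoded by n = 10 neurons with
independent Poisson spike counts. Each canonical tuning curve is a
single cycle of a raised cosine, `[cos²(Δ/2)]^p`, with the exponent p
solved in closed form so the full width at half maximum equals
w_t = 71° (p = ln(1/2)/ln cos²(w_t/4) ≈ 7.096). Each neuron fires at
`b + gain·canonical(Δ)` with baseline b and per-neuron gain.

**Efficient-coding warp.** Neuron anchors are equally spaced in a
homogeneous coordinate; the encoding evaluates each curve at warped
positions, so more neurons (with proportionally narrower tuning)
represent directions near the horizontal boundary. The warp is the
rescaled cumulative integral of a neural-density template

    h(s) = a + 2·[Φ((s + w_b/2)/σ_b) − Φ((s − w_b/2)/σ_b)],

a flat base `a` plus a soft box of height 2 and width `w_b` centered on
the boundary with edge softness `σ_b` (Φ is the standard cumulative
Gaussian). h is floored at 10⁻¹² and numerically normalized to unit
integral. Small `a` concentrates most neurons near 0° (density ratio
(a+2)/a), producing strong repulsive biases; large `a` approaches a
uniform (unbiased) code. The cumulative integral uses periodic
trapezoid segments so the map is exactly the identity for a uniform
density and maps 0° to 0° exactly for any symmetric density.

**Learning as gain modulation.** Only gains change with training. After
training, gains follow a Gaussian profile *across the population*:
`g_i = g_pre + (g_post − g_pre)·exp(−x_i²/(2σ_g²))` where x_i is the
neuron's anchor in the homogeneous coordinate and σ_g defaults to one
inter-neuron spacing (360/n = 36°). In a strongly warped population the
boosted anchors are exactly the neurons preferring directions within a
few degrees of the boundary — i.e. those encoding the trained ±4°
stimuli — and the profile's footprint in stimulus space is about the
local preferred-direction spacing (≈4° at the default neuron count in
that regime). The neuron anchored at 0° reaches peak rate b + g_post.

**Decoding (warp-unaware, gain-aware).** The decoder assumes the
anchors are the true preferred directions (it never sees the warp) but
knows each neuron's current gain. Its likelihood is the exact Poisson
form under that assumed model,

    log L(s) = Σ_i r_i·log f̃_i(s) − Σ_i f̃_i(s),

with f̃ the assumed (homogeneous-position) curves. Before training the
assumed gains are flat, the rate-sum term is constant, and the familiar
spike-weighted sum of log tuning curves results. After training the
assumed rate sum peaks near the boundary, so observing ordinary spike
counts from high-gain boundary neurons is evidence *against*
near-boundary directions: internal evidence near 0° is suppressed.
This is what lets a gain increase simultaneously sharpen the category
judgment and preserve (or amplify) the repulsive estimation bias; a
decoder frozen at pre-training gains would instead be attracted toward
the boundary after learning. In our synthetic cohorts the net
post-training shift of correct-side estimates is parameter-dependent
(slightly inward for most draws, outward for strongly warped
observers), mirroring individual differences rather than a uniform
outward shift.

**Responses.** Discrimination reports CW iff the log mass ratio
d = log(CW mass / CCW mass) is positive (|d| capped at 700; an exact
tie is broken by a seeded fair coin; the grid points at 0° and 180° lie
on the boundary line and belong to neither category). Lapses scale the
aggregate accuracy: p = max(0.5, (1−λ)·p(Correct)) — the floor-at-chance
reading of the lapse constraint. Estimation multiplies the likelihood
by a conditional prior that is 1 on the side of the (implicit) category
choice and 0 elsewhere, reports the posterior mean, and adds N(0, σ_m²)
motor noise. Estimates are averaged linearly within the chosen
half-circle; no circular statistics are needed because posterior mass
near ±180° is negligible in all regimes used.

**Grids and determinism.** The direction grid is uniform on
(−180°, 180°] with step 0.1° by default; behavioral summaries are
insensitive to the step below ≈1°, so fitting uses 1–2° grids (see
"Problem sizes"). Every stochastic stage draws from a named child
stream of one seed (spiking, tie-breaks, motor noise, task sampling,
permutations, optimizer restarts), so all outputs are bit-reproducible.

## Model variants

`full` (warp + conditional inference + gain change), `no_GC` (g_post ≡
g_pre), `no_BA` (identity warp), `no_CI` (unconditional posterior
mean), and two tuning-change alternatives in which learning re-allocates
neurons instead of gain: the post-training density gains additive
Gaussian bumps A·[N(s; +4°, σ_TC) + N(s; −4°, σ_TC)] before
renormalization (`TC` fits A and σ_TC; `TC_reduced` fixes σ_TC = 4°).
In the TC variants the decoder's assumed curves are identical across
sessions. g_post is parameterized as g_pre + dg with dg ≥ 0, making the
ordering constraint a box bound.

## Fitting

The per-observer loss is `w_disc·Σ|acc_data − acc_model| +
w_est·Σ energy(est_data, est_model)` over 3 collapsed magnitudes × 2
sessions. The energy distance is the V-statistic
`2E|X−Y| − E|X−X′| − E|Y−Y′|`, computed in O((n+m) log(n+m)) by
sorting. Weights are set once per observer so both terms equal 1 at a
seeded mid-bound initial parameter vector, then frozen — including
across variants within a model comparison, so CV losses are
commensurable.

The model side of the loss is simulated (the loss is stochastic), and
the optimizer is `scipy` differential evolution — derivative-free and
population-based — with box bounds a ∈ [0,100], w_b ∈ [0,90]°,
σ_b ∈ [0.5,30]°, g_pre ∈ [1,100], dg ∈ [0,200], λ ∈ [0,0.5]. Within a
restart every evaluation re-uses one simulation seed (common random
numbers), making the surrogate objective deterministic; restarts vary
both the starting population and the simulation seed, and the best of
10 restarts is kept. A small population (2 per free parameter) with
recombination 0.9 spends a fixed ~300-evaluation budget on more
generations; on recovery benchmarks this configuration reaches the
sampling-noise floor of the loss where broader populations stall in
deceptive basins (e.g. compensating a too-wide w_b with inflated
gains). By the model's mirror symmetry only positive stimuli are
simulated, and one simulation per (magnitude, session) supplies both
the accuracy and the estimate sample.

**Cross-validated comparison.** Iterated stratified k-fold CV (k = 3;
strata session × task × direction; the study-scale setting is 34
iterations, desk-scale runs use 5). Each variant is first fit once on
the observer's complete data; per-fold fits then warm-start from that
solution with a small refinement budget. The warm start is applied
identically to every variant, so relative CV losses remain a fair
comparison while the fold budget stays affordable; absolute test
losses inherit a small optimistic bias from it. Test losses for all
variants within a fold share one evaluation seed.

## Behavioral statistics

**Collapsing.** Downward trials are negated (stimulus and estimate;
discrimination labels flipped) and merged with upward trials, so a
positive estimate always means "correct side". Estimates exactly at 0°
belong to neither category and are excluded from signed estimation
accuracy (numerator and denominator).

**AUROC.** Rank-based P(post > pre) with ties at ½, on correct-side
estimates only; two-tailed permutation p from 1000 label swaps
preserving group sizes, with the (b+1)/(n+1) correction; two-stage
Benjamini–Krieger–Yekutieli FDR (statsmodels `fdr_tsbky`) across the
observer × direction table.

**Cluster-mass test.** Collapsed estimates are binned in 5° bins on
[−70°, 70°] (left-closed, last bin closed; out-of-range estimates are
dropped and counted). Per bin, a Poisson GLMM
`count ~ session + (1|participant)` (or `group*session + (1|participant)`
for the interaction) yields a Wald z. Step 1 marks bins whose z falls
outside that bin's own two-tailed permutation quantiles (a
pooled-across-bins mode is available); step 2 scores maximal runs of
adjacent same-sign significant bins by summed z and calibrates |mass|
against the per-permutation maximum. Labels are swapped within, never
across, participants, jointly for all bins; the interaction design
additionally permutes group assignment (implemented as a subject
permutation under a fixed design, valid because the random intercept is
exchangeable). Flags are reported at p < 0.05 and the marginal p < 0.10.

The GLMM is fitted by Laplace-approximation maximum likelihood (the
same approximation as lme4's `glmer`, against which the implementation
is validated on a frozen fixture): vectorized inner Newton for the
per-subject modes, damped finite-difference Newton for (β, log τ),
observed-information Wald standard errors. Fits are *batched* across
bin × permutation problems sharing a design, which is what makes a
GLMM-based permutation statistic affordable. τ is bounded below
(log τ ≥ −6); a boundary fit is the plain-GLM regime and is flagged,
as are all-zero-count problems (z = 0).

**Modality.** Gaussian mixtures with 1–3 components (10 restarts each)
selected by BIC; the selected component count is reported as the
distribution's modality label even though components and modes are not
identical in general.

## Synthetic-data generator

The mechanistic generator draws per-observer parameters and simulates
the full three-group study (control, discrimination-training,
estimation-training; 7 observers each; pre/post sessions; both tasks;
±2°, ±4°, ±8°; 60 trials per signed direction per task per session —
30,240 trials in all). Draw ranges: a ∈ [0, 2], w_b ∈ [10, 30]°,
σ_b ∈ [1, 6]°, g_pre ∈ [3, 10], λ ∈ [0, 0.1], σ_m ∈ [1, 4]°; training
groups draw g_post/g_pre ∈ [1.5, 3], control observers have
g_post = g_pre exactly. The gain range is calibrated so pre-test
discrimination accuracy falls in the study's reported band
(≈0.70/0.80/0.90 at 2/4/8°) instead of saturating; under these
conditions most per-observer estimate distributions at ±4° are
multi-modal, training raises ±4° accuracy by ≈3–7 points, and signed
estimation accuracy rises while control observers are stable. Lapses
are realized at the trial level by replacing a fraction λ of
discrimination responses with the incorrect label, the single-trial
counterpart of scaling aggregate accuracy by (1−λ). A ground-truth
sidecar (seed + all drawn parameters) is emitted and suffices to
re-simulate the identical table.

What the generator does *not* emulate: motion-coherence noise and
thresholds (coherence is not modeled at all), session-order and
practice effects, reaction times, response timeouts, dropout, and any
between-session drift other than the gain change. Passing tests on
synthetic cohorts therefore validate the pipeline's statistical
machinery and the model's internal consistency, not claims about human
data.

A separate parametric generator draws estimates from a two-component
Gaussian mixture (primary mode μ₊ > 0, secondary "misclassified" mode
μ₋ < 0, weight w₋) and is used to unit-test the statistics in
isolation with known structure.

## Problem sizes

Simulation-heavy checks are scaled to run on one CPU: decoding grids of
0.5–2° and trial budgets of 300–1500 for fitting (the study-scale
defaults remain 0.1° and 1500 with 10 restarts), 200 permutations × 200
datasets for type-I calibrations (12 bins, 7 subjects), 20,000-trial
simulations for phenomenology checks, and k = 3 × 5 iterations × 3
observers for the model-comparison ordering. The public API exposes all
of these as parameters with the study-scale values documented.

## Known limitations

- The Laplace GLMM z differs from lme4's by ~1% on small samples
  (finite-difference curvature and a bounded τ); permutation
  calibration absorbs this for the cluster test.
- Differential evolution at a 300-evaluation budget occasionally stalls
  in a deceptive basin for the 6-parameter full model; best-of-10
  restarts makes this rare but not impossible. Fits report all restart
  losses so stalls are visible.
- The conditional-prior estimate is undefined when the chosen side has
  zero likelihood mass; this cannot occur when the choice came from the
  same likelihood, and the library raises rather than guessing.
- With strong warps and a = 0 the density underflows far from the
  boundary (floored at 10⁻¹²); anchors then map to extreme directions
  and estimates can exceed ±70°, which the binning stage drops (and
  counts) by design.
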