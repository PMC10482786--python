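# Methods

## Task designs

Both sessions use the same compound number figures: all ordered pairs of
digits 2..9. The comparison session excludes equal pairs (neither level is
larger), leaving 56 stimuli, each presented 8 times across 4 blocks of 112
(448 trials). Congruent means the global digit is numerically larger;
numerical distance is |global − local|. For binned summaries distance is
collapsed to three levels {1–2}, {3–4}, {5–7}, chosen to keep stimulus counts
roughly balanced (26/18/12); other binnings can be passed everywhere a `bins`
argument exists.

The gamble session keeps equal pairs (64 lotteries), crosses them with two
framing conditions (GGLL: gain at the global level; GLLG: loss at the global
level), and presents each lottery 4 times per condition in 4
condition-alternating blocks of 128 (512 trials; block order counterbalanced
across subjects as GGLL-first / GLLG-first). Every gamble is 50/50 against a
certain 0, so EV = 0.5·gain − 0.5·loss. Within-block trial order is a seeded
permutation. Equal-amount (EV = 0) gambles enter the preference likelihood by
default (they constrain λ and θ jointly); `include_equal=False` drops them.

## Preference model

Acceptance probability is logistic in β·U with

    U = gain·θ_pref − loss·λ      (GGLL)
    U = gain − loss·λ·θ_pref      (GLLG)

Losses are stored as positive magnitudes and signed only inside the utility,
avoiding double negation. The value function is linear (no curvature
parameter) and there is no lapse term; a probability floor of 1e−10 guards
the log-likelihood. Fitting maximises the Bernoulli likelihood over
(log β, log λ, log θ) with L-BFGS-B, box bounds β∈[0.01,20], λ∈[0.2,10],
θ∈[0.2,5], and 10 Latin-hypercube starts by default. All-accept/all-reject
tables and solutions pinned to a box bound are returned with
`converged=False`. The rival heuristic (accept iff gain > loss, lapse rate
ε) has the closed-form MLE ε = inconsistency rate on unequal trials, clipped
to [1e−3, 0.5−1e−3]. Models are compared by AIC (BIC reported as well).

## Comparison model

The three-layer network (input fields, number-line fields, two response
units; 15 units per field as in the place-coding source model) is integrated
by Euler–Maruyama with dt = 0.01 model-time units and a cap t_max = 30.
Noise enters the response layer only, scaled by σ√dt. The response-layer
weights w_j = 1.1 − 10^(−(j−1)/(n−1)) are concave increasing and span
[0.1, 1.0] exactly.

Because the X and Y layers are linear and noise-free, the drive to the
response difference factorises exactly as (θ_perc·c_g − c_l)·g(t), where
c_d = Σ_j w_j·e^(−|d−j|) and g(t) is the Euler response to a unit input
(this is an identity of the discrete scheme, verified in tests against the
literal layer-by-layer update). Trial simulation therefore integrates a
single scalar SDE, which makes per-evaluation simulation cheap; a numba
kernel runs the inner loop, and a pure-numpy implementation of the same
process is kept as an independently-coded reference, with statistical
agreement between the two asserted in tests.

RT in seconds is t_nd + time_scale·t_cross. Timed-out trials (no crossing by
t_max) respond by the sign of the difference, carry the capped RT, are
flagged, excluded from RT quantiles, and counted for accuracy.

### Fitting

The fit statistic is a Ratcliff-style quantile chi-square over congruency ×
distance-bin cells. Per cell, observed trials are partitioned into correct-RT
bins bounded by the observed .1/.3/.5/.7/.9 quantiles (mass
.1/.2/.2/.2/.2/.1 of the correct non-timeout proportion), error-RT bins
likewise when at least 10 errors exist (a single error-mass bin otherwise;
cells with fewer than 5 errors never get error quantiles in summaries), and
a timeout bin. Predicted masses come from model simulation —
`sims_per_cell` simulated trials per unique stimulus per evaluation — and
the statistic is Σ_cells N_cell·Σ_bins (p_obs − p_pred)²/max(p_pred, 1e−3).

Free parameters are θ_perc, threshold, t_nd and time_scale; σ is fixed at 1
(σ and threshold trade off almost perfectly in this regime), and dt, t_max
are fixed scheme constants. Because RT is linear in (t_nd, time_scale),
those two are profiled out inside every objective evaluation by weighted
least squares mapping simulated crossing-time quantiles onto observed RT
quantiles (t_nd clipped to [0, min observed RT]); Nelder–Mead with an
explicit initial simplex then searches only (log θ_perc, log threshold),
multistarted. A fixed pool of pre-drawn normals (common random numbers)
makes the objective deterministic across evaluations. Degenerate tables
(no correct responses, or >20% timeouts) are flagged and returned
unconverged.

Likelihood-free fitting is used because the network's first-passage density
has no closed form. Defaults of 500 sims per cell suit final estimates; the
recovery studies in the test suite use 24–40 sims per cell with 1–2 starts
and ≤60 Nelder–Mead iterations, which already recover θ_perc with r ≈ 0.9
across 30 synthetic subjects while keeping a per-subject fit near a second.

## Model-free indices

Congruency effects: accuracy difference (congruent − incongruent) and median
correct-RT difference (incongruent − congruent). Medians are used for all RT
summaries (robustness); no RT trimming is applied by default, with optional
cutoffs available. Global-consistent fraction: (accepts in GGLL + rejects in
GLLG) / all trials; equal-amount trials are included since the condition
still defines which level is the gain. Loss aversion: method 1 is the
rejection rate among EV = 0 gambles; method 2 the overall acceptance rate
(both 0.5 under loss neutrality on this symmetric design); a
logistic-indifference variant (EV at p(accept) = 0.5) is available
separately. Cousineau–Morey within-subject SEs are provided for plotting
only. Correlations are Pearson with a two-sided t-test p; pipeline reports
add Spearman as a robustness column because θ estimates are right-skewed.

## Synthetic populations

Individual differences are placed on log θ so bias magnitudes are symmetric
around θ = 1: (log θ_perc, log θ_pref) are bivariate normal with mean 0, SD
0.2 (θ mostly within [0.67, 1.5]; median θ = 1) and correlation `rho_theta`
(default 0.8, the regime of a strong shared trait; set 0 for the null).
λ ~ lognormal(ln 1.5, 0.3) gives typical moderate loss aversion;
β ~ lognormal(ln 0.8, 0.3) yields acceptance curves that are steep in EV but
clearly stochastic. Accumulator nuisance parameters are uniform: threshold
U(2.2, 2.6), t_nd U(0.25, 0.35) s, time_scale U(0.04, 0.06) s/unit, σ = 1
(matching the fitting constraint). These defaults were calibrated once, by
simulation, to produce qualitatively realistic behaviour — overall accuracy
≈ 0.78 with clear distance and congruency effects, median correct RTs of
0.5–1.0 s, and < 10% timeouts — and then frozen. One caveat of the fixed
weight scale with σ = 1 is that small-distance accuracy is modest (~0.65);
empirical small-distance accuracy in comparable tasks is higher, so absolute
accuracy levels in synthetic data should not be read as human-calibrated.
Directional effects and the individual-differences structure are the
emulation target.

One seed draws the population; per-subject simulation seeds derive
deterministically from (seed, subject id), so any subject regenerates in
isolation and CSV output is byte-identical across reruns.

What the generator does **not** emulate: stimulus laterality and masking,
session timing and payment, sequential effects (trials are exchangeable by
construction), RT contamination (anticipations, lapses), and any model
misspecification — synthetic subjects follow the fitted model families
exactly. Passing recovery tests therefore demonstrates that the estimation
machinery works, not that the models describe human data.

## Numerical and design choices

* Euler step dt = 0.01 model units; halving dt changes noise-free RTs by
  <1% (tested). t_max = 30 bounds a trial at 3000 steps.
* The network weight formula is adopted in the form that actually spans the
  stated [0.1, 1] range and is concave increasing; j is 1-based.
* Fit objectives are deterministic given their seed (CRN); reported values
  are therefore reproducible to the last digit for a fixed config.
* A scale family (c·σ, c·threshold) does *not* leave choice probabilities
  invariant here, because the drift amplitude is pinned by the fixed weight
  scale; the invariance holds only asymptotically in the noise-dominated
  (near-zero drift) regime. Fixing σ = 1 is nonetheless the right
  identifiability constraint in practice: σ and threshold are nearly
  unidentifiable jointly from 448 trials.
* Heuristic nesting: the value model contains the heuristic's deterministic
  core in the limit β→∞, θ=λ=1, so on heuristic-generated data the
  one-parameter heuristic can beat the value model by at most its 4-point
  AIC parameter penalty (asserted in tests).

## Known limitations

* The quantile chi-square is a simulation-based minimum-distance estimator;
  its absolute value is not a calibrated goodness-of-fit p-value.
* θ_perc and threshold interact in the objective; very low sims-per-cell
  (<16) noticeably inflates estimator variance.
* Per-subject fits only — no hierarchical shrinkage.
* Group inferential statistics (ANOVA, mixed-effects logistic regression)
  are out of scope; the package computes per-subject quantities and simple
  correlations.
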