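# Methods

## The task and its simulator

The simulated experiment is a probabilistic two-armed-bandit task with six
blocks of 40 trials (240 trials per subject). Three block contexts —
reward-only, punishment-only, mixed — each occur twice; the context order
repeats an alternating base order, and `counterbalance_index` selects one
of the 3! base orders. Every block holds two symbol pairs with 20 trials
each. The "good" option of a reward pair wins (+1) with probability 0.75
(behavioral version) or 0.70 (fMRI version) and yields nothing otherwise;
the "good" option of a punishment pair is the one with the *low* loss
probability. Mixed blocks pair one reward and one punishment pair, so the
four analysis conditions are reward/punishment × mixed/only, with 40
(mixed) or 80 (only) trials per condition.

Within a block, pair order is a uniform shuffle rejected until no pair
runs longer than four consecutive trials — the simplest sampler satisfying
the design constraint. Response times are a constant placeholder (0.5 s):
no latency model is claimed, and latency analyses on simulated data are
descriptive only. Missed trials are off by default (agents do not time
out); `miss_rate` injects invalid rows to exercise the real-data handling,
and invalid trials never enter likelihoods or summaries.

## The model

Option values follow a Rescorla–Wagner update restricted to the chosen
option: δ = ρ·r − Q(chosen), Q ← Q + α·δ with α = α⁺ for δ > 0 and α⁻ for
δ < 0. δ = 0 leaves the value unchanged (both branches give α·0; the
update is therefore defined as zero change). Choices follow the two-option
logistic softmax with inverse temperature β, computed overflow-safely
(argument clipped at ±700, probabilities floored at 1e−12 inside logs —
far outside the region where optima live at realistic β). Initial values
are +0.5 / −0.5 by pair valence (the `signed_half` scheme); `zero` and
`free` (one value per valence) schemes are available. The sensitivity
variant scales outcomes by ρ before the prediction error; ρ = 1 reproduces
the base model bit-for-bit.

Condition streams are fit separately (four fits per subject for the main
model). The context-scheme variants — used to ask whether a context effect
lives in the learning rate or the decision noise — use a single learning
rate and fit a valence's mixed and separate streams jointly: `null`
(shared α, β; k = 2), `alpha_only` (α varies by context; k = 3),
`beta_only` (β varies; k = 3), `full` (both vary; k = 4).

## Fitting

Per-fit objective: the trial-replay negative log-likelihood (MLE) or the
likelihood minus log priors (MAP; Beta(1.1, 1.1) on each learning rate,
Gamma with shape 15 and scale 0.75 on β — mean 11.25, mode 10.5, matching
the fixed-β = 10 robustness check). Optimization is bounded L-BFGS-B on
the natural scale with analytic gradients, propagated forward through the
value-update recursion (the valence branch makes the objective piecewise
smooth; the kink set has measure zero and does not trouble the
quasi-Newton steps — gradients are verified against finite differences to
1e−7, and the optimum against an exhaustive grid oracle to 1e−3 on random
datasets).

Defaults: 10 starts (first at the prior modes α = 0.5, β = 10.5, the rest
drawn from the priors), bounds α ∈ [0, 1], β ∈ [0, 50], ρ ∈ [0, 3],
minimum 10 valid trials. A β estimate at the upper bound flags the fit as
non-converged (the likelihood is flat upward in β for near-deterministic
subjects — see Limitations). A MAP fit of an empty stream returns the
prior modes. With the same config and seed, refits are bit-identical.

## Model selection

BIC = 2·nll + k·ln(n) with n the valid-trial count; per-subject log model
evidence is approximated as −BIC/2 (natural logs throughout). The
random-effects model selection treats the generating model as varying
across subjects: a variational Dirichlet–multinomial scheme (prior α₀ = 1
per model, convergence 1e−6 on α, max 500 iterations) yields expected
model frequencies; exceedance probabilities come from 10⁵ seeded Dirichlet
draws (sampling rather than the K = 2 closed form, so K > 2 works
uniformly). The Bayes omnibus risk compares the free energy of this model
against the fixed equal-frequency null, and the protected exceedance
probability is EP·(1 − BOR) + BOR/K. Evidence can be supplied per
condition or summed across conditions before selection; both modes are
exposed because the aggregation level is an analysis choice.

## Behavioral statistics

Accuracy is the proportion of "good"-option choices over valid trials.
Positive feedback = win or avoided loss; negative = reward omission or
delivered loss; stay/switch proportions are computed within pair across
consecutive presentations, and the single stay/switch index is the mean of
stay-after-positive and switch-after-negative (the raw proportions are
also emitted because a ratio reading is possible). Learning slopes regress
the correct flag on the within-pair trial index (linear by default;
a logistic fit would need per-subject separation handling and adds nothing
at 20 points).

The 2 × 2 within-subject ANOVA is computed by difference-score
decomposition: each effect's F equals the squared paired t of its
per-subject contrast, with df (1, n − 1). Effect sizes report classical
η² (SS_effect / SS_total including the subject source) as the headline —
partial η² is also emitted — because the classical variant is the one
consistent with F-to-η² relations observed in this literature at n ≈ 100.
Zero-variance contrasts report F = ∞, p = 0, flagged. Bonferroni
adjustment multiplies by the caller-supplied family size and caps at 1.
One-tailed contrasts (replication-style) are a flag, default two-tailed.
Subject screening implements the prespecified poor-learning filter:
below-chance accuracy in every block, or below 40% in the first 10 trials
of every block. Trial-level mixed-model analyses are supported by a
long-format export only; the estimator itself is out of scope.

## Validation studies

Parameter recovery simulates virtual cohorts, refits them with the same
procedure, and correlates generating with recovered parameters per
condition (mean over simulations; bias and RMSE alongside). Ground-truth
parameters default to the cohort's *estimated* parameters (recovery from
estimates); prior draws or explicit lists are accepted. The goodness-of-fit
check re-simulates each subject from their fitted parameters (100
replicates by default) and correlates observed with simulated cohort-mean
20-point learning curves per condition.

Desk-scale defaults are 50 recovery simulations of a 102-subject cohort
(≈ 7 minutes on one core); the reported floor of the recovery correlations
should be read against those sizes.

## Synthetic BOLD and the history analysis

Epochs span −2…+8 volumes around outcome onset (TR 2 s, 11 volumes),
baseline-normalized over −4…0 s and scaled to percent signal change (the
baseline mean of every normalized epoch is 0 by construction). "6 s
post-outcome" is the volume 3 TRs after onset and "0 s" the onset volume —
exact samples on the TR grid.

History labels for mixed-block reward trials: a punishment counter
(deliveries, r = −1) accumulates within block and resets at each reward
delivery (r = +1); count bins are 0 / 1 / 2+. Recency is trials since the
most recent punishment (trial count proxies time in simulated data; wall
clock is supported when onsets are given), undefined when no punishment
occurred since the last reward, and split into per-subject equal-count
(±1) tertiles across mixed blocks, ties resolved by trial order, extras to
the earlier bins. The slope test averages the trial measure (6 s amplitude
or 0→6 s ramp) per bin level (1–3), fits a per-subject OLS slope, and
tests the slopes against zero with a one-tailed t (positive direction);
subjects with fewer than two non-empty bins are excluded and logged.

The generator builds each trial's trace as amplitude × h(t) + noise, with
h a double-gamma response (shapes 7 and 17, scale 1; unit value at its 6 s
peak) and amplitude = baseline + gain × (bin level − 1). Noise-free, the
per-subject slope equals the gain exactly, which pins the analysis code to
the generator's ground truth. What the generator does *not* emulate:
scanner drift, autocorrelated noise, hemodynamic overlap between adjacent
trials, or motion — passing tests show the binning/slope machinery is
correct, not that it would survive raw-fMRI confounds.

## Meta-analysis

Study indicator maps are unions of 10 mm spheres (MKDA convention; the
radius and 2 mm isotropic grid are configurable) around reported foci,
assigned to nearest voxels; foci outside the analysis mask are clipped to
the nearest mask voxel with a warning. Density maps are weighted
proportions of active studies, weights √n_participants normalized to sum
to one (uniform available). FWE thresholds: each permutation relocates
every study's foci uniformly within the mask, preserving per-study focus
counts; the critical value is the conservative (1 − α) quantile of the
permutation maxima and significance is strict exceedance. Category
imbalance is handled by bootstrap subsampling of the larger category
(defaults 500 iterations, subset 9); each iteration thresholds both
categories separately and marks voxels significant for mixed but not for
the only category (a direct density-difference permutation mode is the
alternative), and the final map keeps voxels at or above the 5%
consistency frequency. Overlap between two binary maps within a region is
100·|A∩B∩R|/|A∩R|.

The synthetic corpus generator plants one focus per mixed-context study
near a fixed cluster center (3 mm spread) and scatters the rest uniformly
in the mask, with ~8 foci and ~28 participants per study for a 16-vs-9
corpus (≈ 204 coordinate sets, ≈ 700 participants). Test grids are small
(20³–32³ voxels at 2 mm); on grids much smaller than that the 10 mm kernel
saturates the mask and nothing can reach significance, so the drivers
default to 32³.

## Design choices and limitations

- **Near-deterministic agents bound two validation numbers.** Parameters
  drawn from the stated priors give β ≈ 8–15 on values in [−1, 1], so
  post-learning choice probabilities are ≈ 0.99. The MLE of β is then
  weakly identified upward (55–77% of estimates at any bound in [15, 50]),
  which caps β's recovery correlation near 0.4–0.55 (learning rates:
  0.66–0.90) and caps MLE-vs-MAP trialwise-PE agreement near 0.96–0.98,
  because the two estimators settle on different points of the α–β ridge
  for low-noise subjects. Human cohorts are noisier and do not hit this
  ceiling. The recovery study therefore defaults to estimated-parameter
  ground truth (the standard recovery-from-estimates design); the numbers
  are reported as measured.
- **Learning-rate manipulations only matter on the rising limb.** At
  β ≈ 11, accuracy as a function of α rises steeply below α ≈ 0.15,
  plateaus near 0.3, and declines for large α (value-chasing of
  probabilistic omissions). Cohorts built to carry a +0.15 context effect
  on α therefore draw base rates from U(0.02, 0.15), where the
  manipulation has behavioral consequences.
- The counterbalancing order set is the six alternating base orders; any
  scheme respecting "each context twice, alternating" would do.
- The free-initial-value scheme estimates one value per valence
  (configurable), and ρ fits run MLE only, mirroring its role as a
  rejected extension.
- Recency tertiles pool across a subject's mixed blocks (within-block
  tertiles would often have < 3 defined trials).
- The permutation and bootstrap machinery uses seeded generators
  end-to-end; every reported quantity is bit-reproducible given the seed.
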