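# Methods

This note documents the models, defaults, and numerical choices behind
`devalsim`, and what the simulations can and cannot establish about real
behavioral data.

## Study design encoding

`StudyConfig` holds the full design. Two presets reflect the two
data-collection protocols: `cohortA` (50 learning trials/shape, 40 rewarded
+ 10 zero-reward, 4 blocks; 36 treatment trials/shape in 8 blocks) and
`cohortB` (72 = 60 + 12 in 6 blocks; 44/shape in 11 blocks). Both share the
0.75 stop fraction on stop-paired shapes, the 250 ms initial SSD with
±50 ms steps, the four trained means (40, 80, 160, 320 cents, ±25 c uniform
dispersion), and the five six-amount bid sets spanning 34–324 c — a range
that covers all trained means. The zero-reward counts are explicit config
fields rather than a derived percentage, because the two protocols use
different effective rates (20% vs 16.7%).

Schedule generation is a pure function of `(config, stimuli, seed)`:
re-running produces byte-identical CSVs. Quadrants (learning) and sides
(treatment) are stratified exactly when counts divide evenly, i.i.d. uniform
otherwise; stop trials are stratified across hands with the odd trial
assigned at random. Blocks are contiguous equal slices after one global
shuffle; runs of identical conditions are not constrained. Whether the
original experiment balanced these factors exactly or sampled them
independently is not documented; stratification was chosen where possible
because it removes incidental confounds from the schedule itself.

## The simulated participant

**Motor behavior** follows the independent race model. Go RTs and stop
latencies are ex-Gaussian — the standard right-skewed family for RT data —
with per-agent parameters drawn from a population distribution. Defaults
place the mean go RT at 470 ms (μ = 410, σ = 60, τ = 60; between-agent SDs
25/8/15), inside the 400–650 ms monitoring band, and the mean stop latency
(the agent's true SSRT) at 195 ms (μ = 160, σ = 25, τ = 35), inside the
typical 120–300 ms range for auditory stop signals. Keeping the exponential
tails moderate matters: the mean-method SSRT estimate inherits a bias equal
to the mean-minus-median of the go−stop difference distribution, so very
heavy go tails would inflate it. With the defaults the estimator is
accurate to ~5 ms on average (verified by the recovery tests). A stop wins
ties (`ssd + stop_latency == go_rt`), a one-line convention. Go responses
slower than the 1000 ms deadline, and attentional lapses (default miss rate
0.6%), produce no response — on stop trials these count as successful
stops. Direction errors (0.2%) are applied to go responses only. The SSD
staircase is clamped to [0, 900] ms; the experiment only documents a
monitoring rule (SSD > 100 ms), so the ceiling was set just below the
response deadline.

**Value learning.** The internal value estimate per shape is the mean of
the non-zero rewards observed for it; scheduled zero-reward trials are
treated as omissions rather than evidence of zero value. The experiment
does not document how knowledge accrues trial by trial; any consistent
monotone estimator would serve, and the mean of rewarded trials is the
simplest one whose asymptote is the trained mean. This is a modeling
convenience, not a claim about the true learning mechanism.

**Valuation.** On each auction trial the subjective worth of a shape is

    worth = value_sensitivity × internal_value × (1 − devaluation) + ε

with ε ~ N(0, bid_noise_sd) and the chosen bid the offered amount closest
to worth (ties to the lower amount; impossible within a strictly increasing
set, asserted not handled). `devaluation` applies to stop-paired shapes
only. It is allowed to differ between shapes whose value the agent can
explicitly name and the rest: defaults are 0.05 for implicit learners and
for unnamed shapes of explicit learners, 0.18 for named shapes (between-
agent SDs 0.03/0.05, truncated at 0). Tying the larger effect to the named
shapes — rather than to group membership wholesale — is what makes the
within-subject named-pair contrast recoverable, and mirrors the account
that devaluation rides on explicit value representations. Bid noise is 50 c
(SD 10) for unnamed shapes and 25 c (SD 5) for named ones, so explicit
knowledge reduces bidding variance; 10% of agents are "erratic bidders"
with 2.5× noise, a heavy-tail ingredient that gives the IQR outlier filter
something realistic to remove.

**Knowledge and debrief.** `round(explicit_fraction × n)` agents (default
22/65) are explicit by construction: they hold 1–4 named value levels
(probabilities 0.45/0.30/0.20/0.05), always including an extreme (lowest or
highest) level, matching the observation that explicit knowledge invariably
involved the extreme values; per known level they name one or both shapes.
The simulated debrief reports a feeling of knowing and the named shapes
with their correct relative values; implicit agents report nothing. This
guarantees classifier ground truth. A `stop_contingency_aware` flag (12% of
agents) is recorded but, as in the analysis this package follows, not used
to exclude anyone.

## Analysis pipeline

**Stop task.** Go RT averages correct non-missed go trials; mean SSD pools
all stop trials across hands (per-hand means are emitted for diagnostics);
SSRT = go RT − mean SSD, an identity that holds exactly on every log. Race
validity requires mean failed-stop RT < mean go RT per participant, with a
cohort-level paired t-test (df = n − 1, Cohen's d_z). Default exclusion
bounds — p(stop) in [0.4, 0.6], SSRT in [120, 300] ms, race validity — are
config-exposed because the original bounds are described as approximate.
The block-level monitoring targets (go RT 400–650 ms, p(stop) 0.4–0.6,
SSD > 100 ms) are a warning report, never an exclusion.

**Mixed ANOVA.** No installed Python package computes a three-way mixed
design with two within-subject factors, so the classical univariate
partition is implemented directly via orthonormal within-subject contrasts
(Helmert bases): the between factor is tested against subjects-within-
groups, and each within effect against its own effect × subject stratum.
With unequal group sizes the within main effects use unweighted group means
(the SPSS Type III convention, presumably what produced the published
F values); with a single between factor the between-subjects SS is
unambiguous. The tests verify the partition against an independent textbook
cell-means computation on balanced designs (where all SS types coincide) to
1e-8, and the parametric p against a sign-flip permutation oracle.
The implicit-learner subgroup analysis reuses the same machinery with no
between factor (the published account labels it "2 × 3" but reports the
four-level VALUE factor with df = 3; it is implemented as 2 × 4).

**Nonparametrics.** Wilcoxon signed-rank and Mann–Whitney U delegate
p-values to scipy: exact enumeration for tie-free samples up to n = 25,
tie-corrected normal approximation above. The Z reported alongside (and
used for r = Z/√N, with N all supplied pairs/observations) is always the
tie-corrected normal approximation without continuity correction. Zero
differences are discarded (classic Wilcoxon treatment).

**Outliers.** Devaluation scores (go minus stop mean level, positive =
devaluation — the sign convention is fixed here since the verbal definition
is direction-free) are filtered per knowledge group with 1.5 × IQR Tukey
fences, linear-interpolation quartiles (the most common default; the
quantile method is config-exposed). Groups under 4 members are skipped with
a warning. The implicit-learner regression drops points with Cook's
distance > 4/N (computed via statsmodels OLSInfluence); the threshold is
read as the standard 4/N rule. The within-subjects percent-devaluation
contrast uses the never-stopped shape's mean level as denominator and takes
per-condition medians across qualifying pairs; participants with all four
pairs in one condition are excluded; the explicit-vs-implicit pair contrast
is one-sided (explicit > implicit), per the directional hypothesis.

## Problem sizes and what the tests show

The test suite exercises the full pipeline at the study's own sizes (65
agents, 22 explicit) for direction and significance of the injected
effects, estimator recovery over 200 agents, and type-I error of the
STOPPING test over 200 null cohorts of 24 agents — a size chosen to keep
the replicate count high while preserving a usable between-subjects factor.
The acceptance script simulates 65 agents through the cohort-B treatment
phase.

Passing simulations show that the *pipeline* is correct and well calibrated
under the generator's assumptions: stationary ex-Gaussian RTs, exact race
independence, noiseless knowledge of the schedule means, Gaussian bid
noise. Real data violate all of these to some degree — sequential effects
(post-error slowing), fatigue and drift, learning during the treatment
phase, non-Gaussian and value-dependent bid noise, partially correct verbal
reports — so recovery here does not certify recovery in human datasets.
The generator deliberately omits these features; they are listed as
non-goals, not oversights.

## Known limitations

- The mean-method SSRT carries a small skew-dependent bias (~+5 ms at
  default parameters); the integration method is not implemented.
- The VALUE effect in simulated cohorts is far stronger than in human data
  (ηp² ≈ 0.98 vs ≈ 0.15) because agents' internal values are essentially
  exact; add value-estimate noise or lower `value_sensitivity` to soften it.
- Knowledge classification in the simulator is noiseless by default
  (`misreport`-style errors are not injected), so classifier accuracy is
  exercised by unit tests, not by the cohort simulation.
- YAML configs require pyyaml (installed lazily); JSON needs nothing extra.
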