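# devalsim

Simulator and analysis pipeline for **stopping-induced stimulus devaluation**
experiments: a three-phase behavioral paradigm in which geometric shapes
acquire monetary value through an implicit reward schedule, half of the
shapes are then paired with action stopping in a stop-signal task, and the
subjective value of every shape is finally elicited with a BDM-style auction.
The package is for cognitive/behavioral researchers who want to stress-test
this paradigm's design and statistics — power, type-I error, estimator
recovery, exclusion rules — without collecting human data, and for analyzing
trial logs produced by real experiment software in the same CSV schema.

## The paradigm and its statistics

**Learning phase.** Eight color-shape stimuli, two per value level, are
rewarded according to fixed schedules: integer cents uniform on
[mean − 25, mean + 25] around trained means of 40, 80, 160, and 320 cents,
with a fixed number of zero-reward trials per shape. Error and miss trials
are re-presented until answered correctly.

**Treatment phase.** A stop-signal task on the same shapes. One shape per
value level is paired with stop signals on 75% of its trials (37.5% of all
trials); the other is never stopped. The stop-signal delay (SSD) is tracked
separately per responding hand with a ±50 ms staircase starting at 250 ms,
which drives the probability of successful stopping p(stop) toward 0.5.
Behavior follows the independent horse-race model: the response is cancelled
iff the stop process finishes before the go process, which implies
failed-stop responses are faster than go responses. The stop-signal reaction
time is estimated with the **mean method**:

    SSRT = mean GoRT − mean SSD

**Auction phase.** Each shape is presented 10 times; on each trial the
participant picks one of six offered cent amounts (five ascending bid sets
spanning 34–324 c). The dependent variable is the **bidding level**, the
rank 1–6 of the chosen amount in its set. The headline test is a mixed
ANOVA, STOPPING (2, within) × VALUE (4, within) × KNOWLEDGE (2, between:
explicit vs implicit learners classified from a debrief questionnaire),
with effect sizes in partial η² = SS_effect / (SS_effect + SS_error).
Control analyses use Wilcoxon signed-rank and Mann–Whitney U tests with
r = Z/√N, a within-subject contrast of percent devaluation
100·(L_go − L_stop)/L_go between named-value and unnamed shape pairs, and a
Cook's-distance-filtered regression of devaluation on bidding variance.

The built-in agent simulator injects a configurable devaluation effect —
larger for explicitly represented values — and the analysis pipeline is
expected to recover it.

## Worked example

```bash
devalsim replicate --seed 1
```

simulates 65 participants (22 explicit learners) through the full cohort-B
protocol and analyzes them:

```
Treatment phase: GoRT 471 ms, failed-stop RT 420 ms, p(stop) 0.50, SSD 274 ms, SSRT 196 ms
Knowledge: 22 explicit / 43 implicit
Mean bidding level by cell:
                       value_1  value_2  value_3  value_4
knowledge stop_paired
explicit  False           1.34     2.06     3.66     5.89
          True            1.26     1.94     3.31     5.51
implicit  False           1.44     2.04     3.79     5.79
          True            1.53     1.95     3.61     5.73
Mixed ANOVA (mean bidding level):
                           effect  ss_effect  df  ss_error  df_error         F      p  eta_p_sq
                        knowledge     1.5114   1   12.1583        62    7.7074 0.0073    0.1106
                      stop_paired     2.4418   1    7.5675        62   20.0057 0.0000    0.2440
            knowledge:stop_paired     0.8400   1    7.5675        62    6.8823 0.0109    0.0999
                      value_level  1300.5546   3   29.1401       186 2767.1262 0.0000    0.9781
            knowledge:value_level     0.9105   3   29.1401       186    1.9372 0.1251    0.0303
          stop_paired:value_level     1.2912   3   18.7317       186    4.2736 0.0060    0.0645
knowledge:stop_paired:value_level     0.3092   3   18.7317       186    1.0235 0.3834    0.0162
```

Reading the output: go responses average 471 ms with failed stops ~50 ms
faster (the race-model signature); the staircase held p(stop) at 0.50, and
the mean method puts SSRT at 196 ms. In the auction, bids rise steeply with
trained value (the `value_level` effect), stop-paired shapes draw lower bids
(`stop_paired`, the devaluation effect), and the devaluation is larger in
the explicit group (`knowledge:stop_paired`) — the injected pattern, fully
recovered. Other entry points: `devalsim simulate` (write a dataset
directory of CSV logs + manifest), `devalsim analyze` (run the pipeline on
such a directory), `devalsim schedules` (emit one participant's randomized
trial schedules).

## Layout

- `devalsim.config` / `devalsim.schedules` — study configuration (presets
  `cohortA`, `cohortB`) and reproducible trial schedules for all phases
- `devalsim.agents` — the simulated participants (ex-Gaussian race model,
  staircase, value learning, bidding) and cohort generator
- `devalsim.stop_analysis` — stop-task metrics, race-model validity,
  participant exclusions
- `devalsim.valuation` — bidding-level DVs, knowledge classification, mixed
  ANOVA, nonparametrics, variance and correlation analyses
- `devalsim.pipeline` / `devalsim.io` / `devalsim.cli` — end-to-end
  analysis, dataset CSV/JSON round trips, command line

See `docs/methods.md` for the modeling choices and their rationale.
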