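# trialcea

Trial-based cost-effectiveness analysis for two-arm randomised trials
with repeated measures, built around the kind of evaluation used for
guided internet-delivered psychological treatments: remission and
EQ-5D utility (QALY) outcomes, TIC-P-style self-reported resource use
costed under nested analytic perspectives, mixed-model
difference-in-differences estimation, and a participant bootstrap of
the joint (Δcost, Δeffect) distribution with net-benefit acceptability
curves.

It is written for health economists and trial statisticians who want a
reproducible, tested pipeline rather than a one-off analysis script.
Because participant-level trial data of this kind are rarely shareable,
the package includes a first-class synthetic-trial generator whose
default calibration mimics a 47-per-arm, three-timepoint trial (pre,
post at 3 months, follow-up at 6 months) with realistic right-skewed
costs and missing-at-random dropout.

## The model

For an outcome `y` (EQ-5D index, or period cost under a perspective)
observed on participant *i* in arm *g* at timepoint *t*:

```
y_igt = β₀ + β_g + β_t + β_gt + b_i + ε_igt ,   b_i ~ N(0, σ_b²),  ε ~ N(0, σ²)
```

fitted by maximum likelihood (missing-at-random values are handled by
the likelihood; no imputation). Time is categorical with pre-treatment
as reference, so the group × time coefficient `β_gt` *is* the
difference-in-differences: (intervention change from pre) − (control
change from pre). The incremental cost-effectiveness ratio is
`ICER = ΔC / ΔE`, the net monetary benefit at willingness-to-pay λ is
`NMB(λ) = λ·ΔE − ΔC`, and the acceptability curve (CEAC) is the
fraction of bootstrap replicates with `NMB(λ) > 0`.

Costing follows the resource-use questionnaire's 4-week recall:
amounts are extrapolated ×3 to the 12-week between-assessment period,
priced in SEK (2014 Swedish tariffs: gross wage 188 SEK/h for
human-capital productivity losses, domestic work at €14/h,
unemployment fixed at 24 000 SEK per period) and converted to USD at
the 2014 purchasing-power parity of 6.861 SEK/USD. Categories are
additive and the perspectives nest: clinic (treatment provision only)
⊆ health care (+ visits, medication) ⊆ societal (+ sick leave,
domestic cutback, unemployment).

## Worked example

```python
from trialcea import CostEffectivenessModel, TrialConfig

model = CostEffectivenessModel.simulate(TrialConfig(), seed=1)
res = model.fit(bootstrap_reps=1000, seed=1, bootstrap_method="cellmeans")
print(res.summary())
```

Excerpts of the output (abridged):

```
Difference-in-differences contrasts (mixed models, ML)
    outcome timepoint  estimate       se  pvalue
 eq5d_index      post    0.0639   0.0364  0.0790
 eq5d_index  followup    0.1564   0.0384  0.0000
   societal      post 1938.9409 688.9247  0.0049

Incremental cost-effectiveness (USD per unit effect)
  outcome perspective timepoint  delta_effect  delta_cost    icer
remission    societal      post         0.277      1939.0  7010.0
     qaly    societal  followup         0.156       311.0  1988.0

Cost-effectiveness plane quadrant proportions (bootstrap)
  outcome perspective timepoint    NE    NW    SE  SW
remission    societal      post 1.000 0.000 0.000 0.0
     qaly    societal  followup 0.573 0.000 0.427 0.0
```

Reading this: in the simulated trial the intervention arm gained 0.064
utility-index points more than control by post-treatment (0.156 by
follow-up), at an extra societal cost of about $1,900 over the
treatment period, i.e. roughly $7,000 per additional case in remission
at post-treatment. All 1,000 bootstrap replicates of the post-treatment
remission analysis land in the northeast quadrant of the
cost-effectiveness plane (more effective *and* more costly); by
follow-up the cost difference is uncertain enough that 43% of
replicates are cost-saving.

`CEAResults.save(outdir)` writes the descriptive table, contrast and
ICER tables, replicates, CEAC curves and quadrant proportions as
CSV/JSON. The same pipeline is scriptable from the shell:

```bash
trialcea simulate --seed 1 --out trial.csv
trialcea cost trial.csv --out costs.csv
trialcea analyze --participants trial.csv --seed 1 -B 1000 --out results/
trialcea sensitivity --seed 1 --out results/   # complete-case + unemployment exclusion
```

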