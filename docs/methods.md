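# Methods

## Scope and design

`trialcea` implements a trial-based (as opposed to model-based, e.g.
Markov) economic evaluation of a two-arm randomised trial with three
assessment points. The package is organised statsmodels-style: a
`CostEffectivenessModel` is constructed from a participant × timepoint
table, and `fit()` returns a `CEAResults` object carrying estimates,
uncertainties and report tables. The functional layers underneath
(`simulate`, `costing`, `outcomes`, `inference`, `cea`, `sensitivity`,
`reporting`/`cli`) are public and usable on their own.

## Outcomes

**Remission** is a binary status from a diagnostic interview, defined
only from post-treatment onwards. The incremental effect at a
timepoint is the arm difference in remission proportions (no
pre-treatment value exists to difference against). A random-intercept
logistic model (variational Bayes fit) provides conditional
(subject-specific) odds ratios; a marginal 2×2 odds ratio with a
Haldane–Anscombe 0.5 correction under empty cells is reported as a
cross-check. The two are on different scales — conditional ORs are
attenuated toward the marginal only when the intercept variance is
small — so they are never compared numerically. The weakly-informative
VB prior doubles as the penalised fallback under complete separation
(flagged on the result). The random-effects design holds one column
per participant, so the mixed logistic targets trial-sized samples.

**Utility** is the EQ-5D index: full health (1.0) minus value-set
decrements over five domains. The value set is a pluggable CSV table;
a uniform synthetic "toy" set ships for testing (floored at 0; real
national sets allowing states worse than dead are accepted when
supplied). The incremental QALY effect is operationalised as the
difference-in-differences of index values — the group × time
interaction — not a time-integrated area under the curve; an AUC
helper (`qaly_auc`) exists but is not used by the pipeline, because
the DiD convention matches how trial reports of this design divide
incremental cost by incremental index change.

## Costing

Resource use is recorded over a 4-week recall window and extrapolated
linearly (×3) to the 12-week between-assessment period; SEK amounts are
converted to USD at the 2014 PPP rate of 6.861. Category rules:

| category            | rule                                          | default |
|---------------------|-----------------------------------------------|---------|
| treatment provision | fixed per arm, costed once at post-treatment  | $946 intervention / $461 control |
| other health care   | visits × unit tariff (SEK)                    | 1700 / 1500 / 2000 SEK per primary-care / specialist / psychiatric visit |
| medication          | units × unit tariff                           | 300 SEK |
| sick leave          | days × 8 h × 188 SEK/h (human capital)        | — |
| domestic cutback    | hours × €14 × EUR→SEK                         | EUR→SEK 9.10 |
| unemployment        | fixed 24 000 SEK (≈ $3498) per 12-week period if flagged | — |

Decisions where the convention was open: the workday is 8 h (only the
hourly tariff is standard); the EUR→SEK rate is the 2014 average 9.10
(configurable); the unemployment amount is *not* recall-extrapolated —
it is already a per-period quantity (80% of a monthly gross salary
scaled to the period), and extrapolating it would triple a figure that
is defined per period; medication costs are extrapolated identically to
visits. Visit/medication unit costs are editable placeholder tariffs in
the style of official Swedish listings, shipped as defaults and
overridable by CSV. Money is kept at full precision internally and
rounded only in reports. No discounting is applied (6-month horizon).

Perspectives nest additively: clinic ⊆ health care ⊆ societal, plus a
`societal_excl_unemployment` variant used by the sensitivity analysis.
Clinic costs arise in the post-treatment period only; because the
treatment-cost difference is a one-off, the clinic-perspective contrast
at follow-up carries the post-period value forward rather than
reporting a zero.

## Estimation

Linear mixed model per outcome (EQ-5D index and each stochastic cost
perspective): fixed effects of group, categorical time (pre reference)
and their interaction, plus a participant random intercept, fitted by
ML so that missing-at-random outcomes enter through the likelihood with
no imputation. The outcome is standardised internally before
optimisation (costs are in the thousands; this prevents ill-conditioned
Hessians) and estimates are rescaled back. Optimisers are tried in the
order lbfgs → bfgs → powell; non-convergence raises, never passes
silently. Convergence uses statsmodels defaults with `maxiter=200`.
On balanced complete data the LS means equal cell means exactly (the
saturated fixed-effects projection is invariant to the error
covariance), which is the oracle the tests exploit.

Deterministic cost columns (the clinic perspective is constant within
every arm × timepoint cell) are estimated by cell means: a mixed model
has no residual variation to estimate there.

The interaction (DiD) test is the joint Wald chi-square on both
group × time coefficients against the asymptotic χ² reference. At 47
per arm this is mildly liberal (measured ≈6% at nominal 5% in the
null simulation the acceptance suite runs); per-coefficient z-tests
are also exposed.

Cohen's *d* divides a model contrast by a sigma. The default sigma is
the residual SD; `sigma="total"` uses
√(intercept variance + residual variance). Both are reported options
because "the residual standard deviation of the random-effects model"
is ambiguous between the two; within-group *d* standardises the
pre-to-t change in one arm, between-group *d* the DiD contrast.

Costs are modelled on the raw dollar scale (arithmetic mean
differences are the decision-relevant quantity in economic evaluation);
no log transform.

## Bootstrap, ICER, CEAC

The bootstrap resamples participants (all their rows together) with
replacement, stratified by arm with arm sizes preserved — the standard
choice for trial-based CEA. Per replicate the default re-fits the
mixed models (`method="mixed"`); `method="cellmeans"` substitutes the
cell-mean DiD, an approximation that is exact on balanced complete
data and which the heavy simulations and default reports use for
speed. A non-converging replicate is redrawn and counted
(`attrs["n_redrawn"]`). Remission Δeffect per replicate is always the
model-free arm proportion difference.

`ICER = ΔC/ΔE` raises at ΔE = 0 (reported as undefined, never a silent
infinity). Quadrant proportions classify replicates by the signs of
(ΔE, ΔC) with zeros assigned to the positive side; they sum to exactly
1. The CEAC reports the fraction of replicates with λ·ΔE − ΔC strictly
positive over a λ grid of $0–$60,000 in $1,000 steps by default
(covering commonly cited QALY thresholds); a net benefit of exactly
zero counts as not cost-effective (a measure-zero tie-break).

## Synthetic trial generator

The generator is the package's test bed and emulates the study
conditions the analysis assumes: 47 per arm; remission Bernoulli with
arm × timepoint probabilities (defaults 2%/32% control/intervention at
post, 9%/40% at follow-up); EQ-5D from a participant random intercept
(SD 0.18) plus residual noise (SD 0.14), clipped to the value-set
range [−0.59, 1] — the pre-clipping location is solved numerically so
the *post*-clipping cell mean equals the configured mean (defaults
0.75/0.67/0.67 control, 0.71/0.73/0.80 intervention). Costs are
right-skewed and zero-inflated: negative-binomial visit counts,
medication units and sick-leave days (dispersion 1.5), gamma domestic
hours (shape 1.2), a persistent per-participant unemployment flag
(probability 0.20), and a gamma-distributed per-participant cost
propensity (CV 0.5) that induces the within-person cost correlation a
random-intercept cost model expects. Item rates are solved from
per-cell category dollar targets chosen so societal cell means land
near $4354/$4052/$3808 (control) and $4657/$5585/$5199 (intervention).

Missingness is applied per instrument (diagnostic interview, EQ-5D,
TIC-P) at observed completion rates (e.g. 85% follow-up diagnostics in
the intervention arm; pre-treatment is never missing). The default
mechanism is MAR: missingness is logistic in *baseline* utility
(slope −3 on the logit; lower baseline health → more dropout), with
the intercept solved by root-finding to hit the marginal completion
rate exactly; slope 0 gives MCAR. A `heteroscedastic` knob inflates
residual SDs in low-utility cells for misspecification robustness
checks.

What the generator does **not** emulate: correlated missingness across
instruments, remission–utility within-person correlation, informative
(MNAR) dropout, seasonal or learning effects, and any symptom-scale
trajectory. Passing tests therefore demonstrate correctness of the
estimators under a correctly-specified MAR world, not robustness to
every real-data pathology.

## Problem sizes used by the test suite

Law-of-large-numbers checks run at 10,000 per arm (tolerance ±0.01–
0.02); the null-calibration simulation runs 1,000 trials at 47 per arm;
parameter recovery averages 500 trials at 1,000 per arm with the
cell-mean estimator; bootstrap property checks use B = 1,000 replicates
at the default 47 per arm. These sizes make the Monte-Carlo error small
relative to each tolerance while keeping a full run of the suite in the
minutes range.

## Known limitations

* No multiple imputation, GEE or Bayesian alternatives; ML mixed models
  are the single missing-data strategy (complete-case is a sensitivity
  variant, deliberately per-analysis rather than global listwise).
* The mixed logistic OR uses a mean-field variational posterior: the
  follow-up OR's SE ignores the (typically small) posterior
  cross-covariance between the arm and interaction coefficients.
* No Fieller or bootstrap-percentile confidence interval for the ICER
  itself; uncertainty is communicated through the plane and the CEAC.
* The joint Wald interaction test is asymptotic and slightly liberal at
  small n; no Satterthwaite/Kenward–Roger correction is implemented.
* Tariffs ship as editable placeholders, not a reproduction of any
  official listing; results in dollars are only as good as the tariff
  CSV supplied.
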