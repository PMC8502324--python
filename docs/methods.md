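# Methods

## Outcomes and reference values

Each hospitalization carries a DRG code linking it to two national reference
stays: the *benchmark* (national mean LOS for that DRG, a dynamic annual
value) and the *threshold* (a fixed ministerial outlier cutoff, always above
the benchmark). A stay is **long** when LOS strictly exceeds its benchmark
and an **outlier** when it strictly exceeds its threshold; ties are labelled
0 in both cases, since both outcomes are defined by exceedance. The ordering
of the two references makes outliers a subset of the long stays — an
invariant validated at reference-table load and asserted in the test suite.
All discharge modes (home, transfer to another hospital, death, other) are
included in both outcomes.

## Design matrix

Covariates are encoded fully one-hot, with no reference level dropped: a
perceptron imposes no identifiability constraint, and keeping every dummy
makes the per-dummy importance readout (below) direct. Fixed column order:
sex (1), age class (4), cancer (1), admission type (3), time slot (3),
weekday (7), diagnosis group (top-10 by count plus one residual, 11), giving
30 macro columns; per-unit (micro) models add the internal-transfer flag
(31). Ties at the top-10 diagnosis boundary break lexicographically. Micro
models filter on the admitting unit and recompute their own unit-specific
top-10 diagnoses.

## Network and training

One hidden layer (sufficient by universal approximation), `tansig` or
`logsig` hidden activation, linear output, targets coded 0/1, classification
cutoff ½ on the linear score (boundary counts as positive). Training
minimizes the mean squared output error by full-batch gradient descent;
weights and biases initialize from a seeded uniform(−0.5, 0.5) draw, so every
replication is reproducible. Stops at a training MSE of 1e-4 or after 2000
epochs by default.

Numerical choices:

* The step size adapts each epoch — grow ×1.05 after an improving step,
  shrink ×0.7 and reject any step that worsens the MSE by more than 4%.
  A fixed step diverges (overflow) on small batches at learning rates large
  enough to be useful; the accept/reject rule makes training stable for any
  starting rate while remaining plain full-batch gradient descent. With a
  small fixed rate the MSE decreases monotonically (property-tested).
* Hidden-layer width is found empirically when not given: grid
  {⌈p/2⌉, p, 2p+1} over the input count p, scored by validation balanced
  accuracy, ties to the smaller net. Studies in this package pass explicit
  small widths (6–8 neurons) as their problem-size choice.
* Gradients are exact: back-propagation is checked against central finite
  differences to 1e-6 on random small networks, for both activations, and
  the identity tansig(z) = 2·logsig(2z) − 1 ties the two architectures.

## Constrained bootstrap selection

The estimation sample splits 2/3–1/3, stratified by outcome so both classes
appear on both sides (⌈2n/3⌉ training rows with ⌈2·n_pos/3⌉ positives). The
split is fixed; each of R replications (default 100) then resamples the
training rows with replacement, re-initializes weights, and trains. A
resample missing a class is redrawn up to 10 times, then the replication is
skipped with a warning.

Sensitivity and specificity are measured on the full training split (the
stable reading of a selection that "runs in the training phase"; the
validation third is reserved for reporting). Replications clearing both
ex-ante floors (defaults 0.80 sensitivity, 0.70 specificity) form the
eligible pool; the pool's oriented maximum (sensitivity or specificity, the
analyst's choice) is selected, ties to the smaller replication id. With an
empty pool the overall oriented maximum is returned, flagged
`floors_met=False` — note that a sensitivity-oriented fallback can
degenerate to the all-positive classifier when the covariates carry little
signal; the flag and the warning make this visible rather than hiding it.
Replication randomness is keyed by (seed, replication id), so growing R
extends the same pool and never worsens the selected oriented metric.
Reported metrics come from the single selected network (the replication-wise
table is kept on the results object), and the validation rows never enter
any resample (asserted).

## Evaluation indexes

Eight indexes: incorrect classification ((1−sens)·occ + (1−spec)·(n−occ))/n,
sensitivity, specificity, FPR = 1−spec, FNR = 1−sens, LR+ = sens/(1−spec)
(+∞ flagged at spec = 1), LR− = (1−sens)/spec (undefined at spec = 0), and
AUC. For a single hard classifier the ROC is the degenerate three-point
curve {(0,0), (FPR, sens), (1,1)}, whose trapezoidal area is (sens+spec)/2;
this identity is what published tables of this kind print, so it is the
default AUC, with a score-based Mann–Whitney ROC AUC available alongside.
Sensitivity/specificity carry Wald standard errors (denominators: positive
and negative counts respectively) and 95% intervals built as p ± 1.96·SE
with the SE rounded to three decimals first — the convention that exactly
reproduces printed-table intervals. Displayed rounding is half away from
zero.

## Importance and signs

Garson's absolute-weight algorithm on the trained net: c_ij = |w_ij|·|v_j|,
normalized within each hidden neuron (neurons with zero inflow skipped),
summed over neurons, rescaled to percent (sums to 100; the output bias
carries no input information and is excluded). Direction of effect is the
sign of the summed connection-weight products Σ_j w_ij·v_j (the Olden
quantity). Each dummy column is scored separately — e.g. afternoon and night
admissions get distinct contributions and signs. Properties tested:
invariance to per-neuron rescaling (w·a, v/a), permutation equivariance,
|w|-proportionality for a single hidden neuron, sign invariance under joint
negation of a neuron's in/out weights.

## Impact simulation

Assume fully efficient interventions on every predicted positive: its stay
shortens to min(observed, reference), the reference being the DRG benchmark
by default (the threshold is available as an option for the outlier model —
the published account does not say which was used there, so both are
implemented). False positives therefore cost nothing in days. Per group
(unit, diagnosis group, diagnosis code, or overall): freed bed-days =
round(n·(mean observed − mean supported)) with rounding after aggregation;
additional hospitalizations = round(unrounded freed days / mean supported
LOS) — dividing by the *post-intervention* mean is the only convention that
reproduces the published group totals (1437.4/7.195 → 200, 1061.7/8.377 →
127, 1381.8/11.952 → 116); additional revenue = additional hospitalizations
× the group's case-mix mean DRG reimbursement. Monotonicity (interventions
never lengthen a stay; freed days never decrease as flags are added) is
property-tested.

## Synthetic cohorts

The generator emulates the marginal structure of a department of internal
and emergency medicine:

* **Unit mix** — thirteen clinical units; the seven modelled ones (internal
  medicine, cardiology, emergency medicine, geriatrics, respiratory
  diseases, neurology, oncology) in their observed relative sizes, the six
  small ones sharing the remainder equally.
* **Covariates** — drawn independently per unit from the published per-unit
  prevalences (department-level defaults for the small units): age class,
  cancer, sex, admission type, time slot, weekday, internal transfer.
* **Diagnoses** — fourteen groups with a realistic case mix (top-10 cover
  85%), each mapped to one DRG with a benchmark between 4.8 and 14 days and
  a tariff between €2.9k and €4.5k.
* **LOS** — log-normal: LOS = exp(μ_DRG + β·x + σ·ε). The planted effect
  vector β defaults to modest log-scale shifts (age>75 +0.15, cancer +0.20,
  planned admission +0.10, night −0.10, weekend +0.08) — plausible drivers
  at plausible magnitudes for administrative LOS data; recovery studies
  override them with one dominant effect (cancer +2.0, σ 0.3) so the
  selection floors are attainable and ground truth is unambiguous.
  `planted_truth` exposes β exactly.

The DRG reference table comes from the generating model, not the sample: the
benchmark is the exact model marginal mean per DRG (the finite distribution
of β·x is computed by discrete convolution over the independent covariate
blocks, mixed over units), and the threshold is the per-DRG upper quantile
whose exceedance equals the configured outlier rate (3.74%), found by root
solving on the log-normal mixture CDF. When σ is unset it is calibrated the
same way so the expected long-stay fraction hits the configured 40.06%; with
the benchmark equal to the model mean this fraction is independent of the
per-DRG baselines, which are then back-solved from the benchmark targets.
With all effects zero the calibration reduces to the closed form
P(long) = Φ̄(σ/2), used as a test oracle.

What the generator does **not** emulate: joint covariate dependence beyond
the unit mixture (real age/diagnosis/admission correlations), seasonal or
weekday arrival dynamics, within-DRG case-severity heterogeneity, and any
real link between covariates and LOS beyond the planted log-linear effects.
Passing recovery tests therefore show that the estimation machinery finds
structure that is present by construction — not that such structure exists,
or is this strong, in any real department.

## Problem sizes

Tests and the acceptance script use cohorts of 4,000–20,000 records, 25
bootstrap replications, 6–8 hidden neurons and 80–150 epochs for the fitted
studies — sizes chosen so the full suite replicates the qualitative behavior
of the full-scale procedure (100 replications, 2000 epochs) while remaining
quick to run; the selection and calibration logic is identical at any scale.

## Known limitations

* The constrained selection optimizes training-sample rates; with weak
  signal and an unreachable floor pair, the oriented fallback is degenerate
  by design (see above) and should be read together with `floors_met`.
* Wald intervals are poor near 0/1 proportions and small denominators; they
  are kept because they are the printed-table convention this package
  reproduces, not because they are optimal.
* The revenue conversion prices marginal admissions at average
  reimbursement and ignores queueing, seasonality and bed-capacity
  constraints.
* No class rebalancing is applied to the rare outlier outcome by default;
  heavy imbalance typically leaves the floors unmet, which the fit reports
  honestly.
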