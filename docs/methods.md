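# Methods

## The problem

Prognostic modelling of newly diagnosed multiple myeloma asks for a single
continuous risk score per patient, learned from gene-expression profiles
(~19,000–24,000 features) plus two clinical covariates (age, ISS stage),
against right-censored progression labels. Standard regressors cannot
consume a (time, status) pair directly, and classical survival models
(Cox, random survival forests) discard the information in pairs where the
earlier patient is censored.

## The hazard-rank transform

The package's core is a complete hazard ranking of a censored cohort.
Every unordered patient pair (A, B) distributes a total mass of 1 between
its members. With `r(t)` the Kaplan–Meier survival estimate of the cohort
and, for `t_A < t_B`,

    p = (r(t_A) − r(t_B)) / r(t_A)

— the conditional probability that a patient at risk at `t_A` progresses
before `t_B` — the split is:

| situation (A earlier)       | A receives        | B receives  |
|-----------------------------|-------------------|-------------|
| both events                 | 1                 | 0           |
| A event, B censored         | 1                 | 0           |
| A censored, B event         | p                 | 1 − p       |
| both censored               | p + (1 − p)/2     | (1 − p)/2   |
| tied time, same status      | 0.5               | 0.5         |
| tied time, mixed            | event patient 1   | censored 0  |

Accumulated masses are min–max normalized to [0, 1] and used as a plain
regression target. The accumulation admits a closed form (two case-split
sums over the cohort, implemented vectorized); the explicit pairwise
accumulation is kept as an oracle and the two are asserted to agree to
1e-10 on random cohorts across censoring fractions 0–1.

Numerical choices:

- **KM tie convention.** At a tied time, events precede censorings:
  subjects censored at `t` count as at risk for the events at `t`.
- **Zero-survival guard.** If the last observation is an event, `r`
  reaches 0 and ratios `r(t_A)/r(t_B)` would be undefined; inside rank
  ratios the curve is floored at its smallest positive step. Only the
  terminal patient's mass is perturbed, and totals remain exact.
- **Degenerate normalization.** If all raw masses coincide (e.g. everyone
  censored at one time) all scores are set to 0.5.
- **Ties of stored times** use exact float equality; inputs are expected
  in integral days.

## Preprocessing

Missing expression values are imputed with the per-gene mean across
patients (an all-missing gene becomes constant 0), then each sample column
is quantile-normalized onto the mean-of-sorted-columns reference. Ties
receive the mean of the reference values at the ranks they occupy, making
the map idempotent. In cross-validation the reference and imputation means
come from the training fold only and held-out samples are projected onto
them; across cohorts each cohort is normalized independently, which is
what renders different platforms comparable. An optional `log2(x+1)`
transform is exposed for count-scale matrices (default off). Clinical
encoding is the raw (age, ISS) pair with mean imputation; an all-missing
ISS column falls back to the ordinal midpoint 2.

## Models

- **GPR** (`gpr-guanrank`, `gpr-status`): scikit-learn
  `GaussianProcessRegressor`, kernel `C · RBF + White`, `normalize_y`,
  5 restarts by default (tests and harness examples use 1–2 for speed;
  restarts affect only the hyperparameter search, not the contract).
  Features are standardized per gene at fit time. Because pairwise
  distances between standardized p-dimensional samples concentrate near
  `sqrt(2p)`, the isotropic length-scale search is initialized there and
  bounded to `[0.3·sqrt(2p), 1e4·sqrt(2p)]`; without the lower bound the
  marginal-likelihood optimizer frequently selects a degenerate
  diagonal-Gram optimum whose held-out predictions are constant.
- **Clinical model**: OLS with intercept on (age, ISS); rank-deficient
  designs fall back to the minimum-norm solution.
- **Stacking**: `w · expression + (1 − w) · clinical`, default `w = 0.5`.
- **Signature extraction**: random-forest regression on the hazard-rank
  target (500 trees, p/3 features per split), impurity importances
  normalized to sum 1, combined across cohorts with cohort-size weights.
  The selection threshold is a parameter (default 0.01): because
  importances sum to 1, a fixed threshold's meaning depends entirely on
  the gene count, so no constant can be canonical.

## Evaluation

- **C-index**: Harrell's estimator over comparable pairs; at tied observed
  times only event-vs-censored pairs are comparable; tied risks count 0.5.
- **Time-dependent AUC**: cumulative cases / dynamic controls with inverse
  probability-of-censoring weights from the censoring distribution's KM
  estimate; case weight `1/G(T⁻)` (left limit), control weight `1/G(t)`,
  G floored at its smallest positive step. Agrees with scikit-survival's
  `cumulative_dynamic_auc` to ~1e-2 on random data (the residual gap is
  tie handling) and exactly with brute-force enumeration on censor-free
  data.
- **Integrated AUC**: grid defaults to 14, 16, 18, 20, 22 months
  (1 month = 30.44 days, configurable), weights proportional to
  `2 · S(t) · f(t)` where `S` is the event-survival KM curve and `f` is
  discretized as the KM mass falling in midpoint-bounded grid cells,
  renormalized over usable grid points. Grid points with no cases or no
  controls are dropped with a warning; if no event mass falls in the
  grid's span the average falls back to uniform weights.

## Validation harnesses

`run_cv` performs repeated stratified k-fold CV (default 5×5, stratified
by event status, with an unstratified fallback when events are scarce).
Everything — imputation, quantile reference, hazard ranks, model — is fit
on the training fold; corruption of held-out labels provably leaves
predictions unchanged, and a construction test asserts exactly that.
`run_cross_cohort` intersects gene sets, preprocesses each cohort
independently, trains on the whole training cohort and evaluates on the
whole test cohort; with four cohorts the full matrix yields 12 ordered
pairs.

## The simulator

`simulate_cohort` draws independent standard-normal genes, plants
`n_informative` of them (panel fixed by a separate `panel_seed`, so equal
gene counts share one panel across cohorts), and generates Weibull
proportional-hazards event times from

    eta = effect_size · Σ x_g / sqrt(n_informative) + 0.3·z(age) + 0.3·z(iss)

with shape 1.2 and a baseline scale set per preset so the marginal median
event time matches the corresponding study population. Censoring times
are independent exponentials whose rate is calibrated numerically to the
target censored fraction. The four presets mirror the reference cohorts'
characteristics (sizes 559/282/636/147; progression rates
44.5/66.7/32.7/98.0 %; age 57.2±9.5, 55.1±7.7, 64.1±10.9, 66.4±9.9 y;
reported ISS mixes renormalized over the three stages).

Defaults chosen where nothing is stated: `effect_size = 1` (one SD of the
aggregate gene signal doubles the hazard ≈ e-fold — a strong but
realistic expression signature), `n_informative = 20`, `missing_frac =
0.01`, generic `censoring_rate = 0.5` (between the study populations'
33–98 % event rates).

What the simulator does *not* model: gene–gene correlation, platform or
batch effects, non-proportional hazards, informative censoring. A green
test therefore establishes that the pipeline recovers planted additive
signal under independent censoring at desk scale — not that it reproduces
clinical performance on real cohorts, whose headline numbers come from
access-restricted data.

Note that under this design the censoring *indicator* necessarily
correlates with risk (high-risk patients rarely survive long enough to be
censored) even though the censoring *time* is drawn independently; the
independence test is therefore asserted on the raw censoring draw exposed
in `SimTruth`.

## Known limitations

- The hazard-rank transform is O(n²) in cohort size (vectorized); fine to
  a few thousand patients, not for biobank scale.
- Exact GPR is O(n³) in samples and O(n²p) in features; the optional
  top-k variance filter exists purely for speed and is off by default.
- The Heagerty–Lumley–Pepe nearest-neighbour AUC variant is not
  implemented; the IPCW cumulative/dynamic estimator is this package's
  declared choice among the family of time-dependent AUC definitions.
- Lasso-Cox and random-survival-forest baselines are not re-implemented.
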