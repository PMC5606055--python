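# Methods

This note records the modelling choices behind `nnfca`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic cohorts do and do not emulate, and the limitations we
know about.

## Cohort model and preprocessing

A cohort is N subjects × F features with a binary outcome (1 = high CHD
risk). The outcome is either given directly or derived from five component
conditions — hypertension, dyslipidemia, stroke, myocardial infarction,
angina — with high risk declared when any one is present.

Loading applies two exclusion rules in a fixed order: records with any
missing field (empty cell or the literal `Null`) first, then records with
age under 30 among the remainder. Each record is counted once, in the
first rule it violates; the `ExclusionReport` identity
`n_final = n_raw − n_missing − n_age` is enforced on every input. The
precedence is a convention — nothing in the data forces missing-first —
but it makes the two counts well defined when a record violates both
rules.

All features are mapped to [0, 1] before any training or sensitivity
computation: continuous features min-max scaled with training-set bounds
(reused verbatim on validation data; a constant feature maps to 0 and is
flagged), binary features to {0, 1}, and the three-level diabetes status
(none / impaired fasting glucose / diabetes) to {0, 0.5, 1}. The common
scale is not cosmetic: the sensitivity probe adds the *same* δ magnitude
to every feature, which is only meaningful when one δ unit means the same
fraction of a feature's range everywhere.

Splits are stratified 70/30 by outcome, seeded (default seed 20170906)
and exhaustive.

## The masked perceptron

The predictor is a single-hidden-layer network
`p(x) = σ(w_out · σ(Wᵀx + b_h) + b_out)` with logistic activations in both
layers, trained by full-batch gradient descent on cross-entropy. An
explicit binary input→hidden mask defines the architecture: masked weights
are zero at initialisation and their gradients are zeroed every step, so
the connectivity contract holds exactly (bit-wise zero, not approximately)
after any number of epochs. A dense mask recovers an ordinary MLP.

Defaults: 4 hidden units, learning rate 1.0, 2000 epochs, uniform ±0.5
initialisation, seeded. The learning rate deserves a comment: with the
*mean* cross-entropy gradient over thousands of records, steps at rate 0.1
are so small that 2000 epochs leave the network near its random
initialisation (we measured validation AUCs barely above chance on clearly
separable data). Rate 1.0 converges with a strictly decreasing loss curve
on all our cohorts; rates ≥ 2 oscillate. Divergence (non-finite loss) is
detected per epoch and raised as an error naming the epoch. Analytic
gradients are verified against central finite differences at 1e-5 relative
tolerance in the test suite.

## Perturbation sensitivity

`Sen(X, x_i) = (1/N) Σ_k |f(X_(x_i+δ))_k − f(X)_k|` with δ drawn uniformly
from [1e-4, 1e-3] on the scaled-feature scale. Choices worth recording:

* **Absolute differences.** The signed mean would allow cancellation
  between records moving in opposite directions; sensitivities are meant
  to be magnitudes.
* **One δ shared by all features** of an evaluation (the default `shared`
  mode). The draw range spans a factor of 10; giving each feature its own
  δ multiplies its sensitivity by a random factor up to 10× and scrambles
  every cross-feature comparison — ranks and change-matrix columns alike.
  Per-feature and per-record modes remain available
  (`PerturbationSpec.mode`).
* **The lower bound 1e-4** is a convention; only the order of magnitude
  matters, since a shared δ scales all sensitivities equally and every
  downstream decision is a comparison.

Ranks are descending (1 = most sensitive); ties keep the original feature
order (stable sort).

## Stepwise elimination

At each stage: train a dense network on the remaining features, compute
the sensitivity profile, drop the lowest-ranked feature, retrain, and
record validation accuracy (threshold 0.5). Sensitivities are recomputed
after every removal — the retrained network changes, so frozen first-round
ranks would be wrong. The full curve up to `max_remove` stages is kept and
the selected subset is the stage with maximum accuracy, ties resolved
toward fewer removals. Two early-stopping variants (stop when accuracy
drops below the previous stage, or below the all-features baseline) are
available behind `stop_rule`, but the default computes the whole curve:
accuracy curves under retraining are noisy, and stopping at the first dip
regularly discards the global optimum.

`EliminationTrace.from_accuracies` replays an externally recorded removal
order and accuracy curve, which makes the best-stage decision testable as
a pure function (the packaged reference curve selects 7 removals of 16
features, leaving the nine-feature subset the correlation stage uses).

## Correlation analysis and coupled connections

`cell[i][j] = |Sen(X_(x_j+δ), x_i) − Sen(X, x_i)|`: the sensitivity of
feature i recomputed after the whole table has feature j amplified by δ,
minus its baseline, in absolute value. Feature i keeps the *same* probe δ
in both evaluations so the first-order effect of the draw cancels and a
forced δ_amp = 0 yields an exactly zero matrix.

Candidacy: feature i is a correlation candidate of j when
`cell[i][j] ≥ column_mean[j] − tol`. The column mean includes the diagonal
cell; the diagonal is excluded from candidacy (a feature is never its own
candidate). `tol` is 0 for freshly computed matrices; for printed fixtures
rounded to 3 decimals a slack of 5e-4 (half an ulp of the printed
precision) is used so decisions made on unrounded values survive the
rounding. A matrix loaded from a file keeps the stored `Average` row as
its thresholds — published candidacy decisions were made against the
published averages, and for one column of the packaged reference matrix
the recomputed mean differs from the printed one by more than the rounding
slack (0.0178 recomputed vs 0.017 printed; the printed value is
truncated).

One cell of the packaged reference matrix is irreconcilable with its own
printed candidate row: in the triglyceride column, BMI's change (0.037) is
far above the printed column average (0.010), yet BMI is not listed as a
candidate. No threshold rule reproduces that column; the package
reproduces the other eight columns exactly and all three published mutual
pairs, and the discrepancy is asserted explicitly in the tests rather than
glossed over.

Mutuality: pair {i, j} is correlated iff i is a candidate of j *and* j a
candidate of i. Groups are connected components of the pair graph —
shared members chain pairs into one group (a `--pairwise-blocks`-style
alternative of one block per pair was considered and rejected: with
chained pairs it duplicates features across blocks without a principled
width rule). The coupled-connection mask gives each group
`hidden_per_group` hidden units (default 1) that only that group's
features feed; all hidden units feed the output.

### What the detection does — and does not — measure

The leading term of `cell[i][j]` for a smooth predictor is
`δ_amp · δ_probe · ∂²f/∂x_i∂x_j` averaged over records, and for a logistic
network the mixed partial contains `σ''(g) · (∂g/∂x_i)(∂g/∂x_j)` — a
product of the two features' output gradients. Columns of the change
matrix therefore tend to flag *pairs of strong features* whether or not
they are statistically associated. We measured this on the default
synthetic cohort (20 replicates at full size): the planted,
interaction-carrying SBP–DBP pair is detected in about a third of
replicates — well above any spurious weak-feature pair — but the pair of
the two strongest main-effect features (SBP–age) is flagged in essentially
every replicate despite having no planted association. Mutuality
thresholds do not remove this bias because it is symmetric. Conclusion:
the analysis discovers features that act *jointly and strongly* on the
predictor's output; it is not a substitute for a statistical dependence
measure, and results should be read as "coupled in the model", not
"correlated in the population". This also explains why the detected
groups in published analyses coincide with the top of the sensitivity
ranking.

## Evaluation

PPV, NPV and accuracy from the confusion matrix at threshold 0.5, reported
as percentages; undefined ratios (empty predicted class) are returned as
NaN with a flag rather than raised. AUC is the rank statistic (probability
that a random positive outscores a random negative, ties ½) computed via
scikit-learn and cross-checked in the tests against exhaustive pair
counting. The 95% CI is a seeded percentile bootstrap over records
(single-class resamples are redrawn); coverage was verified by simulation
at a known AUC of 0.75. The logistic baseline is an unpenalised
maximum-likelihood fit; perfect training separation sets a `separation`
flag since the MLE is then unbounded.

## Synthetic cohorts

Generation is Gaussian-copula style: one standard-normal latent per
feature with planted pairwise correlations, transformed marginally —
truncated normals for continuous features (so bounds are respected without
probability mass piling at them), threshold coding for binaries, quantile
cuts for ordinals. The outcome is Bernoulli with
`logit = intercept + Σ β_i z_i + Σ γ_ab z_a z_b` on the latent scale, so
effects are log-odds per SD and a planted pair can carry both a marginal
correlation ρ and a joint interaction γ. The intercept is calibrated by
bisection on a 20 000-draw probe sample to hit a target prevalence within
±0.01.

The default nine-feature configuration uses the reference cohort's
marginal scales (age mean 52.5, SBP mean 119, …), smoking prevalence
0.199, the three-level diabetes distribution, main effects β = 0.8 (age),
1.0 (SBP), 0.7 (diabetes), one planted pair SBP–DBP with ρ = 0.7 and
γ = 0.5, and prevalence calibrated to 0.269. The γ term is part of what
"correlated" means here: the detection stage targets features that
contribute jointly to the output, so a planted pair must carry a joint
term to be a meaningful target. Effect sizes are in the range of strong
epidemiological risk factors (odds ratios ≈ 2–2.7 per SD).

What the synthetic cohorts do *not* emulate: survey design and sampling
weights, missingness mechanisms, measurement error, non-Gaussian marginal
shapes (e.g. the heavy right tail of triglycerides beyond what a wide
truncated normal gives), and realistic inter-feature correlation beyond
the planted pairs. Passing recovery tests therefore demonstrates that the
algorithms behave as specified under their own assumptions — not that
they would make the same selections on real survey data.

## Problem sizes used in the test suite

Simulation-backed tests run at reduced sizes chosen to keep the suite
quick while leaving comfortable statistical margins: signal/noise ranking
and elimination checks use 600-record cohorts with 800 training epochs
(recovery is 20/20 at these sizes); the structured-vs-dense comparison
uses 2000-record cohorts; the 20-replicate parameter-recovery check runs
at the full default size (4146 records, 2000 epochs) because the
correlation stage's detection power depends on it.

## Known limitations

* Full-batch gradient descent without momentum or regularisation; very
  large cohorts or many hidden units would want a better optimiser.
* The sensitivity probe is strictly finite-difference; no analytic
  saliency is provided, by design.
* Correlation detection is gradient-product biased (see above) and its
  magnitude is second-order in δ, so it relies on float64 headroom;
  matrices computed in reduced precision would be noise.
* The coupled-connection architecture constrains capacity: with singleton
  groups it is close to an additive model, which can trail a dense
  network when the true signal has interactions the grouping missed.
* `hidden_per_group` is a free knob with no data-driven rule; the default
  of 1 matches the worked examples but is not tuned.
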