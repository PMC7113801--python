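# Methods

## The model

The package estimates, at every prediction hour of an ICU stay, the full
distribution of the remaining time until cardiac arrest. The distribution
family is Weibull with shape k and scale λ (hours); the estimator is a
recurrent network reading the patient's accumulated history as a
right-aligned window of up to `horizon_steps` (default 48) hourly vectors of
`n_vars` (default 45) standardized clinical variables:

    masking → GRU(50, tanh) → dense(20, tanh) → {shape head, scale head}

The shape head applies a softplus link, the scale head an exponential link,
so both parameters are strictly positive; both are additionally floored at
1e-6 inside the loss to guard against underflow at extreme pre-link values.
A time step whose entire variable vector is missing is masked: the
recurrent state is carried through unchanged, so the parameters read at the
final step are those of the last observed step. An observation with every
step masked is refused, never silently scored. With the default
architecture the network has 3(45+50+1)·50 + (50+1)·20 + (20+1)·2 = 15,462
learnable scalars.

### Objective

Training minimises the mean right-censored negative log-likelihood. An
observation with remaining time t and event indicator u contributes

    u = 1 (arrest observed):  −log f(t)
    u = 0 (censored):         −log S(t) = (t/λ)^k

computed in log space. Censored remaining times are capped at the safety
threshold τ (default 72 h, the median stay length the cohort emulates)
before entering the likelihood, so very long censored stays cannot bias the
fit downward. The mean (not sum) over the batch decouples the learning rate
from the batch size. The analytic gradients of the loss with respect to the
pre-link head outputs, and the full backpropagation-through-time gradients
of the network, are verified against central finite differences in the test
suite.

### Optimisation and checkpointing

Adam (default learning rate 0.01, here usually 0.003; β₁ = 0.9, β₂ = 0.999)
with global gradient-norm clipping at 5. Weights use Glorot-uniform
initialisation except the output kernel, which starts at zero, and the
output biases, which start at the marginal censored-Weibull fit of the
training labels (a two-parameter L-BFGS fit of the same likelihood). The
network therefore begins exactly at the best covariate-free solution and
moves away from it only where the covariates help. When validation data are
supplied the per-epoch validation cost is recorded and the weights of the
best-validation epoch are restored, with the untrained model itself as the
first candidate — so the returned model never scores worse than the
marginal fit on validation likelihood. Training aborts with a diagnostic
if the cost is non-finite for three consecutive epochs. Reproducibility is
promised per device (fixed seed ⇒ identical history), not across BLAS
implementations.

Training to a large fixed epoch count with a heuristic stop is the
historical protocol for this model class; best-validation checkpointing is
the package default because it is reproducible and robust to the cost
instability that long runs of this loss exhibit. The fixed-epoch protocol
remains available (`restore_best: false`).

## Preprocessing

Long-format series (patient, hour, variable, value) are pivoted to a wide
per-(patient, hour) table on each patient's full hourly grid. Daily
variables (labs, organ-failure scores) are forward-filled onto the hourly
grid with a 23 h carry limit *before* missingness is scored; without this
step daily sampling alone would push every patient past the 20% missingness
threshold, which cannot be the intent of the filter. Per patient, P_id
counts the missing cells of the (hours × variables) grid and
P_ir = P_id / grid size; patients with P_id > 1000 or P_ir > 20% are
excluded, each exclusion logged with the violated criterion.

Windows are right-aligned: the observation at prediction hour t holds hours
t−47…t, left-padded with masked steps when the history is shorter. Event
patients contribute prediction hours with remaining time ≥ 1 h (the
"observed at least one hour before arrest" rule); censored patients any
hour strictly before censoring. When a patient has more eligible hours than
`horizon_steps`, the latest `horizon_steps` windows are kept (configurable:
`window_selection: first`), reproducing the 48-windows-per-patient
arithmetic of the emulated cohort (759 patients × 48 = 36,432
observations). Within a window, a partially missing step is completed by
last-observation-carried-forward using only hours inside that window; cells
still missing after carry-forward are treated as the variable mean
(zero after standardisation); only an entirely missing step is masked.

Standardisation is per-variable z-scoring fitted on training-fold
observations only and reused on validation folds — the paper-trail of
cross-validation hygiene is asserted in tests by recomputation. Zero-variance
variables are centred and scaled by 1, with a warning.

## Cross-validation and evaluation

Folds (default 5) are assigned at the patient level, stratified by event
indicator, so no patient's observations straddle folds and each validation
fold carries its share of the rare event patients. Per fold: standardise on
the training patients, train a fresh network monitoring the held-out fold,
predict Weibull parameters for every validation observation. The pooled
validation predictions (each observation predicted exactly once) feed the
ROC analysis.

The risk score at horizon h is P(arrest within h hours) = CDF(h) at the
predicted parameters (a density-valued score is exposed as an option).
Cases at horizon h are event observations whose remaining time, binned to
the nearest hour (the resolution of the clinical grid), equals h; controls
are censored observations with τ-capped remaining time ≥ h (risk-set
convention; exact matching is available but discards most controls). AUC is
the midrank Mann–Whitney statistic; the operating point maximises Youden's
J. A horizon with an empty case or control side is flagged not-computable,
never dropped from the table. Point predictions of remaining time use the
distribution median λ(ln 2)^{1/k}.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; it
is the package's substitute for non-public hospital records.

* **Composition.** Defaults: 37 event + 722 censored patients, 45 variables
  in six categories (15 vitals and 5 medication variables sampled hourly,
  5 organ-failure scores and 10 labs daily, 10 static
  demographic/diagnosis variables), τ = 72 h.
* **Event times.** Accelerated-failure-time Weibull: patient i draws
  T_i ~ Weibull(true_shape = 1.5, scale = baseline_scale · exp(w·b_i)) with
  b_i the patient's per-variable severity offsets (standard normal) and w
  the hazard weights (default −0.25 on 8 variables; higher severity ⇒
  earlier arrest). baseline_scale defaults to 96 h.
* **Censored stays.** Log-normal around a 72 h median (σ = 0.5), floored at
  `min_outcome_hours` (default 2 h) and capped at `max_stay_hours`
  (default 240 h), independent of the event mechanism.
* **Trajectories.** Per-variable AR(1) noise (coefficient 0.8, innovation
  SD 0.6) around the severity offsets. Event patients additionally drift:
  the first 10 variables ramp linearly by 3 SD over the final 16 h before
  arrest. The drift strength is deliberately in the strong-signal regime —
  the learnability contract of the generator is that a trained model
  separates the groups almost perfectly one hour out (AUC > 0.9) while
  horizons beyond the drift window fall toward chance, giving the
  characteristic AUC decay with horizon.
* **Missingness.** Daily variables keep values only every 24th hour;
  remaining cells are deleted independently (hourly rate 0.15, daily rate
  0.05). The final pre-arrest hour of every event patient retains at least
  one observation so the inclusion rule stays satisfiable.

What the generator does **not** emulate: physiologic waveform realism,
pharmacokinetics, inter-variable causal structure beyond the shared hazard
signal, treatment feedback (deteriorating patients being rescued), or
inter-site heterogeneity. Passing tests on this cohort demonstrate that the
estimator recovers the signal it is pointed at under realistic missingness
and censoring — not that the clinical performance figures of any real
cohort transfer.

## Desk-scale experiment design

The reference experiments (`wtte_icu.experiments`, driven by
`scripts/acceptance.py` and the acceptance tests) are sized for a single
CPU core, a few minutes in total:

* **Structural counts** — full-size cohort (759 patients) with
  `min_outcome_hours` = 49 so every patient contributes all 48 windows;
  fully observed. Checks the 36,432 × 48 × 45 tensor arithmetic (1,776
  event / 34,656 censored observations) exactly.
* **Parameter recovery** — 300 + 300 patients, covariate-free event times
  Weibull(1.5, 20 h), 8-step windows, a small probe network (8 GRU / 8
  dense units, learning rate 0.003, 60 epochs, single stratified
  train/validation split). The pooled predicted parameter medians are
  compared with a direct censored maximum-likelihood fit of the same pooled
  labels (lifelines, an independent implementation). The probe network is
  an experiment-design choice: recovery of the marginal fit is a property
  of the likelihood, and a low-capacity head reaches it without first
  memorising the 45 noise channels, which the full 50-unit network does.
* **Discrimination** — 40 event + 300 censored drift patients, 24-step
  windows, the full 50/20 architecture, 25 fixed epochs at learning rate
  0.003 under 5-fold patient-level CV; AUC at horizons {1, 6, 12, 18, 24}
  from the pooled validation predictions, plus ten independently seeded
  train/test replicates (12/80 training patients scored on a fresh 40/80
  cohort, horizons {1, 4, 8, 12, 16}) for the horizon-decay correlation.
  This experiment uses the fixed-epoch protocol rather than
  best-validation restore: the quantity measured is ranking, and the
  likelihood checkpoint deliberately prefers the calibration-optimal
  (often barely trained) model.
* **Exact checks** — Weibull identities against closed forms (the numeric
  density mass is compared with the closed-form CDF at the truncation
  point, since a finite integration range necessarily misses the true tail
  mass), loss gradients against finite differences, AUC against an O(n²)
  pairwise oracle, and the P_id/P_ir/τ rules on constructed fixtures.

## Numerical choices and edge cases

* Density at x = 0: k/λ for k = 1, 0 for k > 1; for k < 1 the singularity
  is replaced by a large finite sentinel with a warning.
* Score ties in ROC use the midrank convention; case matching bins
  real-valued remaining times to the nearest hour.
* Hours are 0-based integers; windows are closed at both ends; remaining
  time is measured from the prediction hour, so the final pre-event
  observation of an integer-timed event has remaining time 1.
* One global seed fans out to per-stage seeds by fixed offsets
  (cohort +0, model +10007, evaluation +20011).
* float64 is the default estimator dtype; the reference experiments use
  float32, which halves runtime at no observable cost to the reported
  quantities.

## Known limitations

* The NLL-based checkpoint favours calibration over discrimination; on
  strong-drift cohorts the restored model is often from a very early epoch,
  and ranking metrics could likely be improved by checkpointing on AUC.
* The Weibull family is unimodal with monotone hazard; competing risks and
  multimodal remaining-time distributions are out of scope.
* Single-device determinism only; bit-identity across BLAS builds is not
  promised.
* The P_id threshold (1000) is an absolute count whose effect depends on
  grid size; it is implemented per patient as specified and is worth a
  sensitivity analysis on real data.
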