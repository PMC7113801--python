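# wtte-icu

Real-time cardiac-arrest risk prediction for intensive-care patients, built
as a Weibull time-to-event recurrent model with a censoring-aware likelihood
and horizon-indexed ROC evaluation — plus a seeded synthetic ICU-cohort
generator so the whole pipeline is testable without access to hospital
records.

## The problem and the model

Unexpected cardiac arrest is the most serious adverse event in an ICU.
Rather than classifying "arrest within the next *w* hours" for a fixed
window, this package models the **distribution of the remaining time to
arrest**. At every prediction hour *t*, the accumulated clinical history of
a patient (up to 48 hourly vectors of 45 common variables) is mapped by a
masked GRU network to the two parameters of a Weibull distribution

$$f(x) = \frac{k}{\lambda}\Big(\frac{x}{\lambda}\Big)^{k-1} e^{-(x/\lambda)^k},\qquad k>0,\ \lambda>0,$$

where *x* is the time to failure in hours, *k* the shape (k < 1: falling
failure rate; k > 1: rising) and λ the scale. The network is
masking → 50 GRU units (tanh) → 20-unit dense (tanh) → two heads, with a
softplus link for the shape and an exponential link for the scale, trained
with Adam on the right-censored negative log-likelihood

$$\mathcal{L} = -u \log f(t_{\text{rem}}) - (1-u)\log S(t_{\text{rem}}),$$

with *u* the event indicator and censored remaining times capped at the
safety threshold τ = 72 h. Patients with excessive missingness are excluded
by two filters (P_id ≤ 1000 missing cells, P_ir ≤ 20% missing ratio).
Discrimination is summarised by the time-dependent AUC: at each horizon *h*
(1…48 h) the risk score P(arrest within *h* hours) = CDF(h) separates event
observations with remaining time *h* from censored observations still under
observation, pooled over 5 patient-level, event-stratified
cross-validation folds.

The recurrent network, its backpropagation-through-time gradients and the
Adam loop are implemented directly in NumPy; the estimator follows the
scikit-learn `fit`/`predict` convention and composes with sklearn model
selection.

## Worked example

```python
import numpy as np
from wtte_icu import (CohortSpec, generate_cohort, inject_missingness,
                      cohort, preprocess, model, evaluate)

spec = CohortSpec(n_event=12, n_censored=60, horizon_steps=16,
                  min_outcome_hours=17, seed=3)
records = inject_missingness(generate_cohort(spec), spec)
series, patients = cohort.cohort_frames(records)

catalog = cohort.variable_catalog(spec.n_vars)
wide, _ = preprocess.select_common_features(series, list(catalog.variable), patients)
wide = preprocess.resample_daily_to_hourly(
    wide, catalog.loc[catalog.sampling == "daily", "variable"])
ws = preprocess.build_windows(wide, patients, horizon_steps=16, max_windows=16)

cfg = model.ModelConfig(epochs=15, batch_size=128, seed=1)
models, pooled, folds, scalers = model.run_cv(ws, patients, cfg)
print(evaluate.tauc_table(pooled, horizons=(1, 4, 8, 12, 16)))
```

prints (abridged):

```
   horizon       auc  sensitivity  specificity  n_cases  n_controls  computable
0      1.0  0.888948     1.000000     0.649142        7         932        True
1      4.0  0.931128     0.750000     0.945479       12         752        True
2      8.0  0.879964     1.000000     0.593750       12         512        True
3     12.0  0.691023     0.916667     0.514706       12         272        True
4     16.0  0.535156     1.000000     0.218750       12          32        True
```

Discrimination is strong in the final hours before the (synthetic) arrest —
the generator's pre-arrest covariate drift is visible to the network — and
decays toward chance at horizons beyond the drift window, the qualitative
signature of this model class. (At this toy size each AUC rests on only a
dozen cases; the reference experiments in `scripts/acceptance.py` use larger
cohorts.) Each row also reports the Youden-point sensitivity/specificity
and the case/control counts behind the AUC.

The same flow is available from the shell:

```bash
wtte-icu run-all --config configs/demo.yaml --seed 7 --out demo_run
```

which writes `series.csv`, `labels.csv`, per-fold training histories and
checkpoints, `predictions.csv`, `tauc.csv`, trajectory/CDF tables, plots,
and a `manifest.json` with content digests (same seed ⇒ same digests).

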