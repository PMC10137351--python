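# airkerma

GMDH polynomial-network regression of the air-kerma field around a
diagnostic X-ray tube.

Air kerma — the kinetic energy released per unit mass of air by the beam —
is the working measure of beam intensity in diagnostic radiology, used for
equipment calibration and skin-dose estimation. It is far from uniform
across an X-ray tube's field of view: the anode heel effect depresses it
toward the target side, it falls with the inverse square of distance, and
it rises with tube voltage. Transport-code simulation maps the field
accurately but takes hours per voltage. This package is for medical
physicists and radiation-dosimetry researchers who want a fast, trainable
predictor of kerma at any position and voltage from a limited set of
simulated samples.

Three pieces:

* **`GMDHRegressor`** — a scikit-learn-style estimator implementing the
  Group Method of Data Handling: a self-organising network of bivariate
  quadratic units Z = c₁ + c₂xᵢ + c₃xⱼ + c₄xᵢ² + c₅xⱼ² + c₆xᵢxⱼ, each
  fitted by least squares and retained or discarded by its error on a
  held-out selection subset (the external criterion). Stacked layers
  realise Kolmogorov–Gabor polynomials of increasing order.
* **Kerma surrogate** — an analytic model
  K = k_ref · h(φ) · (r_ref/r)² · (V/40)^p of the field (heel profile,
  inverse-square law, voltage power law, optional ≤4% multiplicative
  noise), anchored to a packaged 324-row reference table, plus the
  standard detector grid (11 tangent angles × 25 polar angles ×
  5 distances × 6 voltages = 8250 samples).
* **Evaluation & CLI** — the MRE/RMSE criteria, a seeded 70/30
  train/test harness, and `airkerma generate|train|predict|eval` for
  shell use.

See `docs/methods.md` for the model details and their rationale.

## Worked example

```python
import dataclasses
import numpy as np
from airkerma import GridSpec, SurrogateParams, generate_dataset, run_experiment

params = dataclasses.replace(SurrogateParams(), noise_sigma=0.0)
dataset = generate_dataset(GridSpec(), params, seed=1)      # 8250 rows
model, train_report, test_report = run_experiment(
    dataset, width=4, max_layers=2, seed=1
)
print([len(layer) for layer in model.layers_])
print(train_report)
print(test_report)
print(model.predict(np.array([[0.0, 0.0, 250.0, 40.0]])))
```

prints

```
[4, 4]
EvaluationReport(n_samples=5775, mre_percent=40.29..., rmse=1.161...e-07, split_seed=1, subset_label='train')
EvaluationReport(n_samples=2475, mre_percent=40.06..., rmse=1.175...e-07, split_seed=1, subset_label='test')
[3.6275...e-06]
```

The network has two hidden layers of four neurons. The RMSE (~1.2e-07) is
about 2.5% of the largest kerma in the grid (4.6e-06 relative units): the
fit tracks the bright part of the field well, and the prediction at the
anchor point (φ=0°, θ=0°, r=250 mm, V=40 kV) comes out at 3.63e-06
against the surrogate's exact 3.73e-06. The *mean relative* error is much
larger (~40%) because kerma spans three decades across the grid and
least squares on the normalized target controls absolute, not relative,
error — the dim cone edge (φ=20°, large r) dominates the MRE. The same
behaviour, and why wider/deeper networks do not remove it, is analysed in
`docs/methods.md`.

The same pipeline from the shell:

```bash
airkerma generate --seed 1 --noise-sigma 0 --out field.csv
airkerma train field.csv --seed 1 --out model.json      # + model.report.json
airkerma predict model.json query.csv --out predictions.csv
airkerma eval field.csv --model model.json --out report.json
```

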