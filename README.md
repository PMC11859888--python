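# fertigation

Water–fertilizer coupling analysis for drip-fertigated field trials, built
around a 2020–2022 split-plot sugar-beet experiment (Wulanchabu, Inner
Mongolia) in which fertilization (main plots, total N+P₂O₅+K₂O of
336–462 kg·ha⁻¹) was crossed with irrigation (subplots, 945–1350 m³·ha⁻¹)
under a conventional-dose control (CK) and unfertilized checks.

The package is for agronomists and biostatisticians who want the whole
chain — from plot observations and a seasonal water budget to a
recommended irrigation/fertilization window — as tested, reusable code:

* **synthetic trials** (`fertigation.synthetic`): split-plot simulation
  with known quadratic truth surfaces and two error strata, so every
  downstream stage can be checked for recovery;
* **water budget** (`fertigation.water`): ET = I + Pr − ΔW by the water
  balance, total water input TWI = I + Pr, exact mm ↔ m³·ha⁻¹ bridging;
* **indices** (`fertigation.indices`): sugar content (0.8 × brix), sugar
  yield, WUE = Y/ET, WUEi = Y/I, FAE = (Y − Y₀)/F, PFP = Y/F and their
  sugar-yield variants, plus CK-relative percent changes;
* **split-plot statistics** (`fertigation.stats`): two-way ANOVA built
  from the sums of squares up with stratum-correct denominators, Fisher
  LSD compact letter displays, Pearson screens;
* **response surfaces** (`fertigation.surface`): ordinary least squares
  for the full quadratic R(F, I) = b₀ + b₁F + b₂F² + b₃I + b₄FI + b₅I²,
  stationary points with Hessian classification, constrained maxima;
* **dose optimization** (`fertigation.optimize`): CK-relative admissible
  regions over (F, TWI), their intersection, bounding window, refined
  iso-curve crossings, and conversion of TWI to irrigation doses;
* **pipeline + CLI** (`fertigation.pipeline`, console script
  `fertigation`): the stages wired together with deterministic,
  seed-stamped CSV/JSON outputs.

The published treatment means, dose tables and fitted-equation summaries
of the reference trial are packaged in `fertigation.trial_data` (only
summaries were published — no plot-level raw data exist publicly).

## Worked example

Fitting the quadratic surface to the twelve published 2020 yield means
(`examples/03_response_surfaces.py`):

```text
coefficients (b0, b1, b2, b3, b4, b5):
  [-3.024531e+01  4.143373e-01 -6.188587e-04  3.193416e-04  7.624927e-05
 -9.358330e-06]
R^2 = 0.872   overall-F p = 0.0118   (n = 12 treatment means)

stationary point: F* = 448.3 kg/ha, I* = 1843.5 m3/ha, predicted yield 62.93 t/ha (maximum)

predicted yield at the conventional dose (420, 1350): 61.22 t/ha (published mean 60.81)
```

R² = 0.872 reproduces the published fit quality exactly, and the
prediction at the control dose lands within 0.7 % of the observed control
mean. The stationary point is reported together with its Hessian
classification because quadratic optima are very sensitive to coefficient
rounding; the companion `constrained_max` restricts the search to the
tested dose box.

The other example scripts simulate a full trial
(`examples/01_simulate_trial.py`), run the split-plot ANOVA and letter
display (`examples/02_indices_and_anova.py`), and build the
multi-criterion dose window on synthetic data
(`examples/04_optimal_window.py`). The same stages are available from the
shell:

```sh
fertigation simulate --seed 1 --trial-out trial.csv
fertigation all --seed 1 --trial trial.csv --out results/
```

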