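# dephenolize

Surrogate-based optimization of rapeseed-cake dephenolization, for food
scientists and bioprocess engineers working on plant-protein isolation.

Rapeseed (canola) oil cake is a cheap, protein-rich by-product whose food
use is blocked by phenolic antinutrients. Washing the defatted cake with
aqueous ethanol (optionally under ultrasound) removes them; the phenolics
recovered in the wash — total phenolic content, TPC, mg gallic-acid
equivalents per 100 g dry cake — is the response to maximize over three
process factors: ethanol concentration (70–90 %), solid-to-liquid ratio
(10–60 mL/g) and sonication time (5–25 min).

The package implements the complete data-driven workflow:

* **Surrogate response surface** — a three-layer perceptron
  `f(x) = b_o + Σ_k w_ho[k]·tanh(b_h[k] + Σ_i w_ih[k,i]·x_i)` on z-scored
  data, trained by a Levenberg–Marquardt iteration with analytic Jacobians;
  hidden-layer size selected by a repeated-run mean-R² plateau rule.
* **Factor attribution** — Yoon connection-weight relative importance
  `RI_i = 100·Σ_k w_ih[k,i]w_ho[k] / Σ_i'|Σ_k w_ih[k,i']w_ho[k]|`
  (signed; |RI| sums to 100).
* **Global optimization** — particle swarm (20 particles, 800 iterations,
  c1 = 1.5, c2 = 2, constant inertia 0.729) over the process box, with
  restart-stability reporting and an exhaustive lattice oracle.
* **Synthetic ground truth** — a calibrated Gaussian × saturation × Gaussian
  surface whose box maximum is 1887.76 mg GAE/100 g at 84 % EtOH, 60 mL/g,
  15 min, with Latin-hypercube designs, seeded replicate noise, and exact
  oracles (`true_optimum`, Sobol `true_main_effects`) for verification.
* **Protein chemistry** — extraction-yield accounting
  (m1 = m0·mp/100, m3 = m2·P/100, yield = 100·m3/m1), Bradford
  concentration (c = Abs·1.9899·dilution/V), Folin–Ciocalteu GAE
  quantitation, amino-acid profile scoring against WHO essential-amino-acid
  thresholds (the measured profiles of five rapeseed protein isolates ship
  as a packaged table), and the TCA-soluble digestibility gain.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
from dephenolize import (PipelineConfig, run_pipeline,
                         SurfaceSpec, make_default_spec)

# noiseless study conditions: 33-run Latin hypercube over the process box
spec = SurfaceSpec(**{**make_default_spec().to_dict(), "noise_sd": 0.0})
report, fit, pso = run_pipeline(PipelineConfig(surface=spec, master_seed=7))
print(report.summary_text())
```

```
Dephenolization optimization report
===================================
data source:       synthetic (latin_hypercube, n=33)
experiments:       33
hidden neurons:    10
training R^2:      1.0000
training MAE:      0.00 mg GAE/100 g
relative importance (Yoon, signed %):
    sl       +65.71
    etoh     +28.51
    time      +5.77
optimal extraction conditions (predicted):
    ethanol        84.4 %
    solid-liquid   60 mL/g
    time           13.1 min
    predicted TPC  1889.06 mg GAE/100 g
restart spread:    0.000 % (OK)
```

Reading the output: the 10-neuron network interpolates the noiseless table
(R² = 1), the solid-to-liquid ratio is the dominant factor followed by
ethanol and then time (all positive: more solvent, stronger ethanol and
longer sonication increase phenolic recovery over this box), and the swarm
locates the ridge at 84.4 % ethanol with the solvent ratio at its 60 mL/g
bound — within 0.1 % of the generator's true maximum of 1887.76 mg
GAE/100 g at (84, 60, 15). Five independent swarm restarts agreed to
machine precision (spread 0 %).

The same stages are available as a CLI:

```sh
dephenolize simulate --n 33 --seed 7 --out runs.csv
dephenolize fit --experiments runs.csv --hidden 10 --out model.json
dephenolize importance --model model.json
dephenolize optimize --model model.json
dephenolize report --seed 7 --out-dir results/
dephenolize yield-calc --m0 100 --mp 40.42 --m2 15 --p 80
dephenolize aa-summary --sample Popt
```

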