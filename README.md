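# linefrap

Diffusion analysis for **line-bleach FRAP** (fluorescence recovery after
photobleaching) in lipid membranes.

Line FRAP bleaches a thin line across a fluorescently labelled membrane
instead of a spot, which allows faster scanning and more localized
diffusion measurements with nothing but a standard laser-scanning confocal.
This package is for membrane biophysicists who want to turn line-FRAP
time-lapse stacks (or pre-extracted recovery curves) into diffusion
coefficients, separate the fast free-dye signal from the membrane probe,
and compare conditions (temperature, lipid composition) — with a fully
ground-truthed Brownian simulator to verify every stage.

## The model

For a Gaussian bleach line of peak dose `K0` and e⁻² radius `r0e` (µm),
imaging PSF radius `r0c` (µm), and lateral diffusion coefficient `D`
(µm²/s), the normalized line-ROI recovery is the closed series

```
F(t)/F0 = Σ_{n≥0} (−K0)ⁿ/n! · r0e · (n·r0c² + r0e² + 8nDt)^(−1/2)
```

extended to mixtures and a mobile fraction `k` by

```
F_obs(t) = F_post0 + k · (M(t) − M(0)),   M(t) = Σ_j w_j F(t; D_j)/F0
```

Fitting this model to a recovery curve yields the diffusion coefficients
`D_j` with weights, the mobile fraction, and diagnostics. In membrane
experiments the fastest fitted component typically reflects unbound
fluorophore in the buffer (tens of µm²/s, versus ~1 µm²/s for a labelled
lipid); it is classified `free_dye` by a configurable threshold and
excluded from membrane statistics. An empirical double-exponential backend
and a rate→D conversion (`D = λ·r0e²/8`) are provided for comparison.

The package contains five parts, all importable from `linefrap`:

| part | contents |
|---|---|
| `model` | closed-form recovery series, small-dose approximation, multi-component model |
| `fitting` | closed-form and double-exponential fits, free-dye classification, curve CSV IO |
| `images` | TIFF stack IO, bleach-frame detection, line-ROI extraction, r0e estimation |
| `simulate` | Brownian membrane simulator: species, gel-domain obstacles, line bleach, camera rendering, ground truth |
| `analysis` | batch fitting over condition manifests, per-condition mean ± SD, trend check |

## Worked example

```python
import numpy as np
from linefrap import (BeamParameters, DiffusionComponent, FitOptions,
                      MultiComponentModel, classify_components,
                      fit_line_frap, synthesize_noisy_curves)

beam = BeamParameters(K0=1.0, r0e=1.0, r0c=0.25)      # calibration
truth = MultiComponentModel(
    components=(DiffusionComponent(30.0, 0.4),        # free dye
                DiffusionComponent(1.0, 0.6)),        # membrane probe
    beam=beam)
times = np.concatenate([[0.0], np.geomspace(5e-4, 20.0, 79)])
curve = synthesize_noisy_curves(truth, times, n_replicates=1, seed=7)[0]

fit = fit_line_frap(curve, beam, FitOptions(n_components=2))
for comp, label in zip(fit.components, classify_components(fit)):
    print(f"D = {comp.D:7.2f} um^2/s  weight = {comp.weight:.2f}  -> {label}")
```

prints

```
D =   28.09 um^2/s  weight = 0.42  -> free_dye
D =    0.99 um^2/s  weight = 0.58  -> membrane
```

i.e. from a single ~2%-noise curve the fit recovers both coefficients
(truth 30 and 1 µm²/s) and the classifier flags the fast component as
buffer dye, which batch analysis then excludes from membrane statistics.

The `examples/` directory holds one short script per capability
(forward model, curve fitting, synthetic dataset generation, the image
pipeline, and a temperature-series batch). `examples/05_temperature_series.py`
ends with, for a membrane whose gel-domain area fraction falls with
temperature:

```
DOPC-DPPC-chol_2-2-1 @ 22 C: membrane D = 0.360 +- 0.080 um^2/s (n = 4)
DOPC-DPPC-chol_2-2-1 @ 30 C: membrane D = 0.495 +- 0.052 um^2/s (n = 4)
DOPC-DPPC-chol_2-2-1 @ 38 C: membrane D = 1.040 +- 0.148 um^2/s (n = 4)
Trend verdict: increasing (Kendall tau = 0.82, means monotone = True)
```

A thin CLI mirrors the pipeline stages:

```bash
linefrap simulate --seed 0 --out-dir data/
linefrap extract data/stack.tif --roi 60 10 110 --out curve.csv
linefrap fit curve.csv --k0 0.5 --r0e 1.0 --r0c 0.25 --out fit.json
linefrap batch manifest.csv --out-dir report/
```

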