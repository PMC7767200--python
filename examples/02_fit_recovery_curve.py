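"""Fit a noisy recovery curve and separate free dye from membrane probe.

Synthesizes a two-component curve (fast free dye + slow membrane lipid)
with ~2% photon noise, fits the closed-form model with two components,
classifies the components, and compares with the empirical
double-exponential backend.
"""

import numpy as np

from linefrap import (
    BeamParameters,
    DiffusionComponent,
    FitOptions,
    MultiComponentModel,
    classify_components,
    fit_double_exponential,
    fit_line_frap,
    rates_to_diffusion,
    synthesize_noisy_curves,
)

beam = BeamParameters(K0=1.0, r0e=1.0, r0c=0.25)
truth = MultiComponentModel(
    components=(DiffusionComponent(30.0, 0.4), DiffusionComponent(1.0, 0.6)),
    beam=beam,
)
times = np.concatenate([[0.0], np.geomspace(5e-4, 20.0, 79)])
curve = synthesize_noisy_curves(truth, times, n_replicates=1, seed=7)[0]

fit = fit_line_frap(curve, beam, FitOptions(n_components=2))
labels = classify_components(fit, threshold_D=10.0)
print("Closed-form two-component fit (truth: D = 30 and 1 um^2/s):")
for comp, label in zip(fit.components, labels):
    print(f"  D = {comp.D:7.2f} um^2/s  weight = {comp.weight:.2f}  -> {label}")
print(f"  mobile fraction k = {fit.k_hat:.3f}, residual rms = "
      f"{fit.residual_rms:.4f}")
print("The fast component is attributed to unbound dye in the buffer and")
print("would be excluded from membrane statistics.\n")

de = fit_double_exponential(curve)
d_est = rates_to_diffusion(np.array(de.rates), beam)
print("Empirical double-exponential backend:")
print(f"  rates = {de.rates[0]:.2f}, {de.rates[1]:.3f} 1/s "
      f"-> D = {d_est[0]:.1f}, {d_est[1]:.2f} um^2/s (convention D = l r0e^2/8)")
print("The empirical conversion is approximate; the closed form is the")
print("quantitative backend.")
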