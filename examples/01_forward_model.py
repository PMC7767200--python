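"""Evaluate the closed-form line-FRAP recovery model.

Builds a beam configuration (bleach dose K0, bleach-line radius r0e,
imaging PSF radius r0c), evaluates the recovery for a membrane-like
diffusion coefficient, and shows the mobile-fraction extension.
"""

import numpy as np

from linefrap import (
    BeamParameters,
    DiffusionComponent,
    MultiComponentModel,
    multi_component_recovery,
    recovery_fraction,
)

beam = BeamParameters(K0=1.0, r0e=1.0, r0c=0.25)
t = np.array([0.0, 0.1, 0.5, 2.0, 10.0])

f = recovery_fraction(t, 1.0, beam)
print("Single species, D = 1 um^2/s:")
for ti, fi in zip(t, f):
    print(f"  t = {ti:5.1f} s   F/F0 = {fi:.4f}")
print("The dip at t = 0 reflects the bleach depth; the signal climbs back")
print("toward 1 on the timescale r0e^2 / (8 D) ~ 0.125 s.\n")

model = MultiComponentModel(
    components=(DiffusionComponent(30.0, 0.2), DiffusionComponent(1.0, 0.8)),
    beam=beam, k=0.8,
)
g = multi_component_recovery(t, model)
print("Two species (20% fast free dye) with mobile fraction k = 0.8:")
for ti, gi in zip(t, g):
    print(f"  t = {ti:5.1f} s   F = {gi:.4f}")
print("The immobile 20% caps the plateau below full recovery.")
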