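"""Recover planted rotation frequencies from a synthetic population tensor.

Builds a 60-unit population whose latent dynamics are exact rotations at
2.0 Hz and 0.5 Hz plus additive noise, then runs the full analysis: PCA
reduction, skew-constrained and unconstrained dynamical fits, and plane
extraction.  The recovered frequencies should sit within a few percent of
the planted ones, and the unconstrained fit should outperform the
constrained one (noise adds non-rotational structure).
"""

import numpy as np

from armdyn.jpca import jpca
from armdyn.synth import PlantedDynamicsSpec, planted_rotation_population

spec = PlantedDynamicsSpec(
    n_units=60, n_conditions=8, n_steps=100,
    frequencies=(2.0, 0.5), noise_sd=0.05, seed=1,
)
tensor, truth = planted_rotation_population(spec)
res = jpca(tensor, softnorm=0.0, n_components=4)

print("planted frequencies (Hz):", spec.frequencies)
print("recovered frequencies (Hz):", np.round(np.sort(res.plane_frequencies)[::-1], 3))
print(f"R^2 skew-constrained:  {res.r2_constrained:.3f}")
print(f"R^2 unconstrained:     {res.r2_unconstrained:.3f}")
print(f"top-2 plane VAF:       {100 * res.plane_vaf[:2].sum():.1f}%")
print()
print("The two fastest planes should match the planted 2.0 / 0.5 Hz; their")
print("VAF is the share of population variance living in those rotations.")
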