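"""Test rotational structure against a tensor-maximum-entropy null.

A population with genuinely shared rotational dynamics should beat
surrogates that merely preserve its unit, condition and time covariances.
The p-value uses add-one smoothing: with 200 surrogates the smallest
attainable p is 1/201.
"""

import numpy as np

from armdyn.synth import PlantedDynamicsSpec, planted_rotation_population
from armdyn.tme import tme_test

spec = PlantedDynamicsSpec(
    n_units=60, n_conditions=8, n_steps=30,
    frequencies=(2.0, 0.5), noise_sd=0.05, seed=2,
)
tensor, _ = planted_rotation_population(spec)
null = tme_test(tensor, n_surrogates=200, seed=0)

print(f"observed skew-constrained R^2:   {null.observed_constrained:.3f}")
print(f"median surrogate constrained R^2: {np.median(null.surrogate_constrained):.3f}")
print(f"p (constrained):                  {null.p_constrained:.4f}")
print(f"p (unconstrained):                {null.p_unconstrained:.4f}")
print()
print("A small p says the rotational fit quality is not explained by the")
print("population's mode-wise covariances alone - the rotation is an")
print("emergent, shared dynamical property.")
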