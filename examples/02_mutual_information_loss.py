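"""Why mutual information, not intensity difference, drives the registration.

The two modalities render the same anatomy through different monotone
transfer functions, so voxelwise correlation is broken while the intensity
*distributions* stay coupled. This script prints the MI of an aligned pair,
a shuffled pair, and the full registration objective at the true solution.
"""

import numpy as np

from mrgart import (
    PhantomSpec, RegistrationConfig, generate_case, mutual_information,
    total_loss,
)

case = generate_case(PhantomSpec(seed=1, deformation_amplitude=0.0, noise_sigma=0.02))
f, m = case.fixed.data, case.moving.data

corr = np.corrcoef(f.ravel(), m.ravel())[0, 1]
mi_aligned, _ = mutual_information(f, m, bins=32)
rng = np.random.default_rng(0)
mi_shuffled, _ = mutual_information(f, rng.permutation(m.ravel()), bins=32)
mi_soft, _ = mutual_information(f, m, bins=32, estimator="soft", sigma_ratio=0.25)

print(f"voxelwise correlation (aligned pair): {corr:.3f}  — not 1: modalities differ")
print(f"hard-binned MI (aligned pair):        {mi_aligned:.3f} nats")
print(f"hard-binned MI (shuffled pair):       {mi_shuffled:.4f} nats — near zero")
print(f"soft (Parzen) MI, narrow kernel:      {mi_soft:.3f} nats — tracks the hard value")

value, comps = total_loss(case.fixed, case.moving,
                          np.zeros((3, *f.shape)), RegistrationConfig())
print(f"\nregistration objective at zero displacement: {value:.3f}")
print(f"  similarity (-MI) {comps['similarity']:.3f}, "
      f"smoothness {comps['smoothness']:.1f}, L2 {comps['l2']:.1f}")
print("The objective is minimized by warps that raise MI while keeping the field smooth.")
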