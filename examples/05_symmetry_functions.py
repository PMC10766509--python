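"""Symmetry-invariant features of a point environment.

G2 counts neighbours in a radial shell, G5 probes their angular arrangement;
both use a Fermi distance cutoff and are normalized by the expected counts
of an ideal isotropic gas, so a structureless environment gives values near
1 and inputs land roughly in [0, 1].
"""

import numpy as np

import tpslearn as t
from tpslearn.datasets import point_cloud
from tpslearn.featurize import SymmetryFunctionParams, g2_probe_volume_quadrature

p2 = SymmetryFunctionParams(kind="G2", r_s=0.5, eta=25.0, alpha_c=100.0,
                            r_cut=1.5, rho_N=2.0)
p5 = SymmetryFunctionParams(kind="G5", r_s=0.5, eta=25.0, alpha_c=100.0,
                            r_cut=1.5, rho_N=2.0, zeta=2, lam=-1)

rng = np.random.default_rng(0)
vals2, vals5 = [], []
for _ in range(400):
    cloud, _ = point_cloud(p2.rho_N, 4.0, rng)
    vals2.append(t.g2(np.zeros(3), cloud, p2))
    vals5.append(t.g5(np.zeros(3), cloud, p5))
print(f"ideal-gas mean of normalized G2: {np.mean(vals2):.3f} "
      f"(s.e. {np.std(vals2)/np.sqrt(len(vals2)):.3f})")
print(f"ideal-gas mean of normalized G5: {np.mean(vals5):.3f}")

ratio = g2_probe_volume_quadrature(p2) / (8 * np.pi * p2.r_s**2 * np.sqrt(2 / p2.eta))
print(f"quadrature / closed-form probe volume at eta = {p2.eta}: {ratio:.3f}")
print("(the closed form is a small-eta approximation; the quadrature oracle")
print(" quantifies the bias of the normalization for any parameter set)")

# invariance: rotating, translating and permuting the cloud leaves G2/G5 fixed
cloud, _ = point_cloud(p2.rho_N, 4.0, rng)
Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
moved = cloud @ Q.T + np.array([1.0, -2.0, 0.5])
same = np.isclose(t.g2(np.array([1.0, -2.0, 0.5]), moved, p2),
                  t.g2(np.zeros(3), cloud, p2), atol=1e-12)
print(f"invariant under rigid motion + permutation: {bool(same)}")
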