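"""Fit diffusion tensors and derive the maps the ALPS protocol reads.

Noise-free signals invert exactly; at SNR 30 the per-voxel diagonal
diffusivities carry ~4% error, which ROI averaging later suppresses.
"""

import numpy as np

import glymphalps as ga
from glymphalps.phantom import LABELS

scheme = ga.make_gradient_scheme(32, 1000.0, seed=1)
truth = ga.build_tensor_phantom(ga.PhantomSpec(alpha=0.25))

dwi = ga.simulate_dwi(truth, scheme, s0=1.0, noise_sigma=0.0)
field = ga.fit_tensor(dwi)
err = np.abs(field.tensors - truth.tensor_field).max()
print(f"noise-free fit: max abs tensor error {err:.2e} (exact inversion)")

maps = ga.tensor_to_maps(field)
proj = truth.labels == LABELS["projection_tract_left"]
print(f"projection tract: Dxx {maps.dxx[proj].mean():.3f}, Dyy {maps.dyy[proj].mean():.3f}, "
      f"Dzz {maps.dzz[proj].mean():.3f} (x boosted by alpha, z axial)")
print(f"projection tract FA {maps.fa[proj].mean():.4f}; dominant color channel: "
      f"{'RGB'[np.argmax(maps.color_fa[proj].mean(axis=0))]} (blue = z-oriented fibers)")

noisy = ga.simulate_dwi(truth, scheme, s0=1.0, noise_sigma=1 / 30, noise_model="gaussian", seed=2)
nfield = ga.fit_tensor(noisy)
rel = np.abs(nfield.tensors[..., 0, 0] - truth.tensor_field[..., 0, 0])[proj] / 0.71
print(f"SNR 30: median per-voxel Dxx error {100 * np.median(rel):.1f}%")
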