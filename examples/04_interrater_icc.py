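"""Inter-rater agreement of ALPS measurements via ICC(2,1).

Two raters are emulated by running the ROI refinement from different
initial placements on the same subjects; agreement is summarized with
the two-way random-effects, absolute-agreement, single-measures ICC.
"""

import numpy as np

import glymphalps as ga

scheme = ga.make_gradient_scheme(32, 1000.0, seed=1)
rng = np.random.default_rng(0)

ratings = []
for subject in range(12):
    alpha = float(np.clip(rng.normal(0.25, 0.07), 0.0, None))
    truth = ga.build_tensor_phantom(ga.PhantomSpec(alpha=alpha))
    dwi = ga.simulate_dwi(truth, scheme, s0=1.0, noise_sigma=1 / 30, noise_model="rician", seed=100 + subject)
    maps = ga.tensor_to_maps(ga.fit_tensor(dwi))
    base = ga.default_roi_set(truth.labels)
    pair = []
    for jitter in (0, 1):  # rater 2 starts one voxel off along the tract
        start = ga.ROISet(
            slice_index=base.slice_index,
            rois=tuple(
                ga.ROI(r.fiber, r.hemisphere, (r.center[0], r.center[1] + jitter, r.center[2]))
                for r in base.rois
            ),
        )
        placed = ga.place_rois(maps, start, search_radius=3)
        pair.append(ga.compute_alps(ga.extract_roi_means(maps, placed)).alps_bilateral)
    ratings.append(pair)

res = ga.icc_interrater(np.array(ratings))
print(f"ICC(2,1) = {res.estimate:.3f} [95% CI {res.ci_low:.3f} to {res.ci_high:.3f}]")
print(f"({res.n_subjects} subjects x {res.n_raters} raters; 1.0 = perfect absolute agreement)")
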