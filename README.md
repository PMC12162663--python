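# glymphalps

Analysis of brain glymphatic function from diffusion MRI via the
**DTI-ALPS index** (diffusion-tensor-image analysis along the
perivascular space), packaged with a synthetic diffusion phantom and
the full cohort-statistics ladder used in clinical sleep studies.

## Who this is for

Researchers quantifying glymphatic activity in cohort studies (e.g.
insomnia, neurodegeneration) who need (a) a tested, deterministic
implementation of the ALPS measurement chain, and (b) a ground-truth
phantom to validate that chain end to end — something patient data can
never provide, because the true perivascular diffusivity of a living
brain is unknown.

## The index

At the level of the lateral-ventricle body, medullary vessels and
their perivascular spaces run left–right (the image **x** axis), while
projection fibers run inferior–superior (**z**) and association fibers
anterior–posterior (**y**). Diffusivity along x in those tracts is
therefore attributable to perivascular water movement. With mean
diagonal diffusivities from four 5-mm ROIs (projection/association ×
left/right):

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

ALPS ≈ 1 means no preferential perivascular diffusion; larger values
indicate greater presumed glymphatic activity. `Dyy_assoc` and
`Dzz_proj` are measured and reported but do not enter the ratio.

The package implements the whole chain:

1. **phantom** — axis-aligned tract/ventricle geometry with a known
   perivascular boost `alpha`, giving an analytic index
   `(λ⊥ + alpha)/λ⊥`; Stejskal–Tanner signal simulation with Rician or
   Gaussian noise; a three-group pre/post cohort generator with known
   sleep-metric associations.
2. **tensor fitting** — log-linear OLS per voxel; diagonal diffusivity
   maps, FA, and color-FA.
3. **ALPS core** — color-FA-guided ROI refinement, disc-mean
   extraction, the index, and inter-rater ICC(2,1) with F-based CI.
4. **cohort statistics** — ANOVA + Tukey HSD, χ² tests, univariate
   screen (p < 0.2), backward elimination (p-removal 0.1) with forced
   adjustment sets, paired pre/post t tests.
5. **pipeline/CLI** — `glymph-alps {simulate,fit,index,stats,run}`
   with checksummed, seed-reproducible manifests.

## Worked example

```python
import glymphalps as ga

scheme = ga.make_gradient_scheme(32, 1000.0, seed=1)      # 32 dirs + b0
truth = ga.build_tensor_phantom(ga.PhantomSpec(alpha=0.23))  # ALPS_true = 1.5
dwi = ga.simulate_dwi(truth, scheme, s0=1.0, noise_sigma=1/30,
                      noise_model="rician", seed=42)
maps = ga.tensor_to_maps(ga.fit_tensor(dwi))
rois = ga.place_rois(maps, ga.default_roi_set(truth.labels), search_radius=4)
res = ga.compute_alps(ga.extract_roi_means(maps, rois))
print(res.alps_bilateral)
```

This prints `1.4895`: the measured bilateral index for a phantom whose
true index is 1.5000, i.e. the full simulate → fit → place → extract →
compute chain recovers the ground truth to about 0.01 at SNR 30.
Applying the bare formula to group-mean diffusivities typical of
healthy controls (0.64, 0.79, 0.46, 0.49) gives `1.5053`, and of
insomnia patients (0.50, 0.77, 0.49, 0.45) gives `1.3511` — lower
perivascular diffusion in patients. The scripts in `examples/` walk
through each capability and print what the numbers mean.

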