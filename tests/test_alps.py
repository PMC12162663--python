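import numpy as np
import pytest

import glymphalps as ga
from glymphalps.alps import ROIMeans, alps_from_means


def _means(dxx_p, dxx_a, dyy_p, dzz_a, dyy_a=1.0, dzz_p=1.0):
    out = {}
    for h in ("left", "right"):
        out[("projection", h)] = ROIMeans(dxx=dxx_p, dyy=dyy_p, dzz=dzz_p, n_voxels=5)
        out[("association", h)] = ROIMeans(dxx=dxx_a, dyy=dyy_a, dzz=dzz_a, n_voxels=5)
    return out


class TestIndexFormula:
    def test_healthy_control_group_means(self):
        """Index of the mean diffusivities typical of healthy controls;
        note this is arithmetic on group means, distinct from a group's
        mean of per-subject indices."""
        assert alps_from_means(0.64, 0.79, 0.46, 0.49) == pytest.approx(1.5053, abs=1e-4)
        assert alps_from_means(0.64, 0.79, 0.46, 0.49) == pytest.approx(0.715 / 0.475, abs=1e-12)

    def test_insomnia_group_means(self):
        assert alps_from_means(0.50, 0.77, 0.49, 0.45) == pytest.approx(1.3511, abs=1e-4)
        assert alps_from_means(0.50, 0.77, 0.49, 0.45) == pytest.approx(0.635 / 0.47, abs=1e-12)

    def test_equal_inputs_give_unity(self):
        res = ga.compute_alps(_means(0.7, 0.7, 0.7, 0.7))
        assert res.alps_bilateral == pytest.approx(1.0)
        assert res.alps_left == pytest.approx(1.0)

    def test_unused_means_retained_but_ignored(self):
        a = ga.compute_alps(_means(0.7, 0.8, 0.5, 0.45, dyy_a=1.0, dzz_p=1.0))
        b = ga.compute_alps(_means(0.7, 0.8, 0.5, 0.45, dyy_a=2.0, dzz_p=0.3))
        assert a.alps_bilateral == b.alps_bilateral
        assert b.means[("association", "left")].dyy == 2.0

    def test_scale_invariance(self):
        base = _means(0.71, 0.71, 0.46, 0.46)
        scaled = _means(3 * 0.71, 3 * 0.71, 3 * 0.46, 3 * 0.46)
        assert ga.compute_alps(base).alps_bilateral == pytest.approx(
            ga.compute_alps(scaled).alps_bilateral, rel=1e-12
        )

    def test_conventions_agree_on_symmetric_input(self):
        m = _means(0.71, 0.71, 0.46, 0.46)
        a = ga.compute_alps(m, "per_hemisphere_then_average")
        b = ga.compute_alps(m, "pool_bilateral")
        assert a.alps_bilateral == pytest.approx(b.alps_bilateral)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            ga.compute_alps(_means(0.7, 0.7, -0.1, 0.5))
        with pytest.raises(ValueError):
            ga.compute_alps(_means(0.7, 0.7, 0.5, 0.5), convention="bogus")


class TestROIGeometry:
    def test_roiset_requires_all_four(self):
        rois = [
            ga.ROI("projection", "left", (5, 5, 8)),
            ga.ROI("projection", "right", (25, 5, 8)),
            ga.ROI("association", "left", (3, 5, 8)),
            ga.ROI("association", "left", (29, 5, 8)),  # duplicate combination
        ]
        with pytest.raises(ValueError, match="fiber x hemisphere"):
            ga.ROISet(slice_index=8, rois=tuple(rois))

    def test_disc_membership_matches_enumeration(self, noisefree_maps, phantom_default):
        """5-mm disc at 2-mm voxels = the 5-voxel plus shape (centers
        within 2.5 mm), enumerated brute-force."""
        rois = ga.default_roi_set(phantom_default.labels)
        means = ga.extract_roi_means(noisefree_maps, rois)
        for roi in rois.rois:
            cx, cy, cz = roi.center
            expected = [
                (x, y)
                for x in range(32)
                for y in range(32)
                if (2.0 * (x - cx)) ** 2 + (2.0 * (y - cy)) ** 2 <= 2.5**2
            ]
            assert len(expected) == 5
            m = means[(roi.fiber, roi.hemisphere)]
            assert m.n_voxels == 5
            manual = np.mean([noisefree_maps.dxx[x, y, cz] for x, y in expected])
            assert m.dxx == pytest.approx(manual, rel=1e-12)

    def test_constant_map_mean(self, phantom_default):
        shape = phantom_default.labels.shape
        maps = ga.DiffusivityMaps(
            dxx=np.full(shape, 0.7),
            dyy=np.full(shape, 0.7),
            dzz=np.full(shape, 0.7),
            fa=np.zeros(shape),
            color_fa=np.zeros((*shape, 3)),
            valid=np.ones(shape, bool),
            voxel_size=(2.0, 2.0, 2.0),
        )
        means = ga.extract_roi_means(maps, ga.default_roi_set(phantom_default.labels))
        for m in means.values():
            assert (m.dxx, m.dyy, m.dzz) == (0.7, 0.7, 0.7)

    def test_phantom_roi_means_match_construction(self, noisefree_maps, phantom_default):
        rois = ga.place_rois(noisefree_maps, ga.default_roi_set(phantom_default.labels), 4)
        means = ga.extract_roi_means(noisefree_maps, rois)
        for h in ("left", "right"):
            assert means[("projection", h)].dxx == pytest.approx(0.71, abs=1e-6)
            assert means[("projection", h)].dzz == pytest.approx(1.05, abs=1e-6)
            assert means[("association", h)].dyy == pytest.approx(1.05, abs=1e-6)

    def test_all_invalid_roi_rejected(self, noisefree_maps, phantom_default):
        rois = ga.default_roi_set(phantom_default.labels)
        broken = ga.DiffusivityMaps(
            dxx=noisefree_maps.dxx,
            dyy=noisefree_maps.dyy,
            dzz=noisefree_maps.dzz,
            fa=noisefree_maps.fa,
            color_fa=noisefree_maps.color_fa,
            valid=np.zeros_like(noisefree_maps.valid),
            voxel_size=noisefree_maps.voxel_size,
        )
        with pytest.raises(ValueError, match="no valid voxels"):
            ga.extract_roi_means(broken, rois)


class TestPlacement:
    def test_zero_radius_is_noop(self, noisefree_maps, phantom_default):
        init = ga.default_roi_set(phantom_default.labels)
        assert ga.place_rois(noisefree_maps, init, 0) == init

    def test_recovers_offset_centers(self, noisefree_maps, phantom_default):
        """Start 2 voxels off the tract; refinement must come back to
        within 1 voxel of the label-map centroid."""
        true_set = ga.default_roi_set(phantom_default.labels)
        shifted = ga.ROISet(
            slice_index=true_set.slice_index,
            rois=tuple(
                ga.ROI(r.fiber, r.hemisphere, (r.center[0] + (2 if r.hemisphere == "left" else -2), r.center[1] + 2, r.center[2]))
                for r in true_set.rois
            ),
        )
        placed = ga.place_rois(noisefree_maps, shifted, search_radius=4)
        from glymphalps.phantom import LABELS

        tract_of = {"projection": "projection_tract", "association": "association_tract"}
        for r in placed.rois:
            t = true_set.get(r.fiber, r.hemisphere)
            # the cross-tract (x) coordinate must recenter; along the tract
            # axis any in-tract position is equivalent
            assert abs(r.center[0] - t.center[0]) <= 1
            label = phantom_default.labels[r.center]
            assert label == LABELS[f"{tract_of[r.fiber]}_{r.hemisphere}"]

    def test_deterministic(self, noisefree_maps, phantom_default):
        init = ga.default_roi_set(phantom_default.labels)
        assert ga.place_rois(noisefree_maps, init, 4) == ga.place_rois(noisefree_maps, init, 4)

    def test_monotone_in_alpha_noisefree(self, scheme32):
        """Raising the perivascular boost strictly raises the computed index."""
        indices = []
        for alpha in (0.0, 0.1, 0.2, 0.3):
            truth = ga.build_tensor_phantom(ga.PhantomSpec(alpha=alpha))
            dwi = ga.simulate_dwi(truth, scheme32, s0=1.0, noise_sigma=0.0)
            maps = ga.tensor_to_maps(ga.fit_tensor(dwi))
            placed = ga.place_rois(maps, ga.default_roi_set(truth.labels), 4)
            indices.append(ga.compute_alps(ga.extract_roi_means(maps, placed)).alps_bilateral)
        assert all(b > a for a, b in zip(indices, indices[1:]))
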