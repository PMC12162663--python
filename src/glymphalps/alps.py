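"""DTI-ALPS index: ROI placement, diffusivity extraction, the index
itself, and inter-rater agreement.

The index compares diffusivity along the perivascular (left-right, x)
axis against diffusivity perpendicular to the dominant fiber direction
in two tract types at the lateral-ventricle body:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

A value near 1 means no preferential x-axis diffusion; higher values
indicate greater presumed glymphatic activity. Dyy_assoc and Dzz_proj
are measured and reported but do not enter the formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .tensorfit import DiffusivityMaps

__all__ = [
    "ROI",
    "ROISet",
    "ROIMeans",
    "ALPSResult",
    "ICCResult",
    "default_roi_set",
    "place_rois",
    "extract_roi_means",
    "compute_alps",
    "icc_interrater",
]

FIBERS = ("projection", "association")
HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class ROI:
    fiber: str  # "projection" | "association"
    hemisphere: str  # "left" | "right"
    center: tuple[int, int, int]  # 0-based voxel coordinates (x, y, z)
    diameter_mm: float = 5.0


@dataclass(frozen=True)
class ROISet:
    """Exactly one ROI per fiber x hemisphere, all on one axial slice."""

    slice_index: int
    rois: tuple[ROI, ...]

    def __post_init__(self) -> None:
        keys = [(r.fiber, r.hemisphere) for r in self.rois]
        expected = {(f, h) for f in FIBERS for h in HEMISPHERES}
        if set(keys) != expected or len(keys) != 4:
            raise ValueError("need exactly one ROI per fiber x hemisphere")
        for r in self.rois:
            if r.diameter_mm <= 0:
                raise ValueError("ROI diameter must be positive")
            if r.center[2] != self.slice_index:
                raise ValueError("ROI centers must lie on slice_index")

    def get(self, fiber: str, hemisphere: str) -> ROI:
        for r in self.rois:
            if r.fiber == fiber and r.hemisphere == hemisphere:
                return r
        raise KeyError((fiber, hemisphere))


@dataclass(frozen=True)
class ROIMeans:
    dxx: float
    dyy: float
    dzz: float
    n_voxels: int


@dataclass(frozen=True)
class ALPSResult:
    """Six diffusivity means per hemisphere plus the index values."""

    means: dict  # (fiber, hemisphere) -> ROIMeans
    alps_left: float
    alps_right: float
    alps_bilateral: float
    convention: str


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def default_roi_set(truth_labels: np.ndarray, slice_index: int | None = None) -> ROISet:
    """ROIs at the centroids of the labeled tract regions on one slice.

    Convenience for phantoms, standing in for an operator's initial
    placement; real use supplies coordinates directly.
    """
    from .phantom import LABELS

    if slice_index is None:
        slice_index = truth_labels.shape[2] // 2
    rois = []
    for fiber, tract in (("projection", "projection_tract"), ("association", "association_tract")):
        for hemi in HEMISPHERES:
            mask = truth_labels[:, :, slice_index] == LABELS[f"{tract}_{hemi}"]
            if not mask.any():
                raise ValueError(f"{tract}_{hemi} absent on slice {slice_index}")
            xs, ys = np.nonzero(mask)
            center = (int(round(xs.mean())), int(round(ys.mean())), slice_index)
            rois.append(ROI(fiber=fiber, hemisphere=hemi, center=center))
    return ROISet(slice_index=slice_index, rois=tuple(rois))


def place_rois(maps: DiffusivityMaps, initial: ROISet, search_radius: int = 4) -> ROISet:
    """Refine ROI centers on the color-FA map.

    Automates the manual adjustment step of the protocol: each
    projection ROI moves to the centroid of the locally bright blue
    (z-dominant) voxels within an in-plane square window of
    ``search_radius`` voxels around its initial center; association
    ROIs use the green (y-dominant) channel. "Bright" means at or above
    the window median of the channel, computed over valid voxels. The
    slice is never changed and the operation is deterministic.
    """
    if search_radius < 0:
        raise ValueError("search_radius must be >= 0")
    if search_radius == 0:
        return initial

    z = initial.slice_index
    nx, ny = maps.color_fa.shape[:2]
    new_rois = []
    for roi in initial.rois:
        channel = 2 if roi.fiber == "projection" else 1  # blue / green
        cx, cy, _ = roi.center
        x0, x1 = max(0, cx - search_radius), min(nx, cx + search_radius + 1)
        y0, y1 = max(0, cy - search_radius), min(ny, cy + search_radius + 1)
        if x0 >= x1 or y0 >= y1:
            raise ValueError(f"empty search window for ROI {roi.fiber}/{roi.hemisphere}")
        window = maps.color_fa[x0:x1, y0:y1, z, channel]
        valid = maps.valid[x0:x1, y0:y1, z]
        if not valid.any():
            raise ValueError(f"all voxels invalid in search window for {roi.fiber}/{roi.hemisphere}")
        vals = np.where(valid, window, -np.inf)
        thresh = np.median(window[valid])
        # strictly above the window median; in a constant window (nothing
        # strictly above) every valid voxel counts, leaving the center put
        bright = vals > thresh
        if not bright.any():
            bright = vals >= thresh
        xs, ys = np.nonzero(bright)
        # centroid of bright voxels, rounded half-up for determinism
        ncx = x0 + int(np.floor(xs.mean() + 0.5))
        ncy = y0 + int(np.floor(ys.mean() + 0.5))
        new_rois.append(replace(roi, center=(ncx, ncy, z)))
    return ROISet(slice_index=z, rois=tuple(new_rois))


def _disc_mask(shape_xy: tuple[int, int], center_xy: tuple[int, int], radius_mm: float, voxel_size: tuple[float, float, float]) -> np.ndarray:
    """In-plane membership: voxel centers within radius_mm of the ROI center."""
    nx, ny = shape_xy
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx = (ix - center_xy[0]) * voxel_size[0]
    dy = (iy - center_xy[1]) * voxel_size[1]
    return dx**2 + dy**2 <= radius_mm**2


def extract_roi_means(maps: DiffusivityMaps, rois: ROISet) -> dict:
    """Mean dxx/dyy/dzz over each ROI disc, invalid voxels excluded.

    A voxel belongs to the ROI if its center lies within diameter/2 mm
    of the ROI center in-plane on the ROI slice (no partial-volume
    weighting). An ROI whose disc contains no valid voxel is an error.
    """
    z = rois.slice_index
    out = {}
    for roi in rois.rois:
        disc = _disc_mask(maps.dxx.shape[:2], roi.center[:2], roi.diameter_mm / 2.0, maps.voxel_size)
        mask = disc & maps.valid[:, :, z]
        if not mask.any():
            raise ValueError(f"ROI {roi.fiber}/{roi.hemisphere} contains no valid voxels")
        out[(roi.fiber, roi.hemisphere)] = ROIMeans(
            dxx=float(maps.dxx[:, :, z][mask].mean()),
            dyy=float(maps.dyy[:, :, z][mask].mean()),
            dzz=float(maps.dzz[:, :, z][mask].mean()),
            n_voxels=int(mask.sum()),
        )
    return out


def alps_from_means(dxx_proj: float, dxx_assoc: float, dyy_proj: float, dzz_assoc: float) -> float:
    """The index formula on four diffusivity means."""
    denom = (dyy_proj + dzz_assoc) / 2.0
    if dyy_proj <= 0 or dzz_assoc <= 0:
        raise ValueError("denominator diffusivities must be positive")
    return ((dxx_proj + dxx_assoc) / 2.0) / denom


def compute_alps(means: dict, convention: str = "per_hemisphere_then_average") -> ALPSResult:
    """ALPS index from the per-ROI means.

    ``per_hemisphere_then_average`` (default) computes the index in each
    hemisphere and averages the two; ``pool_bilateral`` first averages
    each diffusivity across hemispheres and takes a single ratio.
    """
    if convention not in ("per_hemisphere_then_average", "pool_bilateral"):
        raise ValueError(f"unknown convention {convention!r}")
    for key in [(f, h) for f in FIBERS for h in HEMISPHERES]:
        if key not in means:
            raise KeyError(f"missing ROI means for {key}")
        m = means[key]
        if min(m.dxx, m.dyy, m.dzz) <= 0:
            raise ValueError(f"non-positive mean diffusivity in ROI {key}")

    per_hemi = {
        h: alps_from_means(
            means[("projection", h)].dxx,
            means[("association", h)].dxx,
            means[("projection", h)].dyy,
            means[("association", h)].dzz,
        )
        for h in HEMISPHERES
    }
    if convention == "per_hemisphere_then_average":
        bilateral = float(np.mean([per_hemi["left"], per_hemi["right"]]))
    else:
        bilateral = alps_from_means(
            np.mean([means[("projection", h)].dxx for h in HEMISPHERES]),
            np.mean([means[("association", h)].dxx for h in HEMISPHERES]),
            np.mean([means[("projection", h)].dyy for h in HEMISPHERES]),
            np.mean([means[("association", h)].dzz for h in HEMISPHERES]),
        )
    return ALPSResult(
        means=means,
        alps_left=float(per_hemi["left"]),
        alps_right=float(per_hemi["right"]),
        alps_bilateral=float(bilateral),
        convention=convention,
    )


def icc_interrater(ratings: np.ndarray, ci: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the mean squares of the subjects x raters two-way
    layout (McGraw & Wong), with the F-based confidence interval. This
    is the appropriate model for a fixed panel of raters each rating
    every subject once. Zero between-subject variance makes agreement
    undefined; the estimate is reported as 0 with a degenerate flag.
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2:
        raise ValueError("ratings must be a subjects x raters matrix")
    n, k = Y.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 raters and >= 3 subjects")
    if np.isnan(Y).any():
        raise ValueError("ratings must have no missing cells")

    grand = Y.mean()
    msr = k * ((Y.mean(axis=1) - grand) ** 2).sum() / (n - 1)  # between subjects
    msc = n * ((Y.mean(axis=0) - grand) ** 2).sum() / (k - 1)  # between raters
    sse = ((Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))

    if msr <= 0:
        warnings.warn("zero between-subject variance: ICC undefined, reporting 0", stacklevel=2)
        return ICCResult(0.0, np.nan, np.nan, "ICC(2,1)", n, k, degenerate=True)

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based CI (McGraw & Wong); zero residual MS is handled by the
    # analytic limit fj -> inf, where v -> (k-1)(n-1)
    alpha = 1.0 - ci
    if mse <= 1e-12 * max(msr, msc):
        v = (k - 1) * (n - 1)
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd if vd > 0 else (k - 1) * (n - 1)
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return ICCResult(float(icc), float(lo), float(hi), "ICC(2,1)", n, k)
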