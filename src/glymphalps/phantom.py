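"""Synthetic diffusion-tensor phantoms for ALPS validation.

The phantom mimics the tissue geometry the ALPS protocol reads at the
level of the lateral-ventricle body: projection fibers running
inferior-superior (z), association fibers running anterior-posterior
(y), a CSF-filled ventricle, and isotropic background. Perivascular
(glymphatic) flow along the medullary vessels adds diffusivity on the
left-right (x) axis inside both tract types; the additive x-axis term
``alpha`` is the phantom's ground-truth glymphatic parameter, so every
simulated subject has an analytically known ALPS index.

All diffusivities are in units of 1e-3 mm^2/s (um^2/ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientScheme

__all__ = [
    "Box",
    "PhantomSpec",
    "GroundTruth",
    "DWIVolume",
    "default_region_layout",
    "build_tensor_phantom",
    "simulate_dwi",
    "analytic_alps",
]

# region label codes in the label map
LABELS = {
    "background": 0,
    "ventricle": 1,
    "projection_tract_left": 2,
    "projection_tract_right": 3,
    "association_tract_left": 4,
    "association_tract_right": 5,
}

BACKGROUND_DIFFUSIVITY = 0.8  # 1e-3 mm^2/s, isotropic parenchyma-like

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def default_region_layout(grid_shape: tuple[int, int, int] = (32, 32, 16)) -> dict[str, Box]:
    """Axis-aligned boxes (half-open voxel ranges) for a 32x32x16 grid.

    Tracts are mirror-symmetric about the mid-sagittal plane; the
    ventricle occupies the center. Scaled proportionally for other grids.
    """
    nx, ny, nz = grid_shape
    sx, sy = nx / 32.0, ny / 32.0

    def xr(a: int, b: int) -> tuple[int, int]:
        return (int(round(a * sx)), int(round(b * sx)))

    yr = (int(round(6 * sy)), int(round(26 * sy)))
    zr = (0, nz)
    return {
        "ventricle": (xr(13, 19), yr, zr),
        "projection_tract_left": (xr(6, 10), yr, zr),
        "projection_tract_right": (xr(22, 26), yr, zr),
        "association_tract_left": (xr(1, 5), yr, zr),
        "association_tract_right": (xr(27, 31), yr, zr),
    }


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of a tensor phantom.

    lambda_parallel / lambda_perp are the tract axial/radial
    diffusivities; alpha is the additive perivascular x-axis diffusivity
    applied inside both tract types (all in 1e-3 mm^2/s).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    region_layout: dict[str, Box] | None = None
    lambda_parallel: float = 1.05
    lambda_perp: float = 0.46
    csf_diffusivity: float = 3.0
    alpha: float = 0.25
    s0: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_layout is None:
            self.region_layout = default_region_layout(self.grid_shape)
        self.validate()

    def validate(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape axes must all be >= 16")
        if not (self.lambda_parallel >= self.lambda_perp > 0):
            raise ValueError("require lambda_parallel >= lambda_perp > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.s0 <= 0 or self.noise_sigma < 0:
            raise ValueError("s0 must be positive and noise_sigma >= 0")
        required = set(LABELS) - {"background"}
        missing = required - set(self.region_layout)
        if missing:
            raise ValueError(f"region_layout missing regions: {sorted(missing)}")
        # tract regions must be pairwise disjoint and non-empty
        occupied = np.zeros(self.grid_shape, dtype=bool)
        for name in sorted(required):
            (x0, x1), (y0, y1), (z0, z1) = self.region_layout[name]
            if x1 <= x0 or y1 <= y0 or z1 <= z0:
                raise ValueError(f"region {name} is empty")
            if x0 < 0 or y0 < 0 or z0 < 0 or x1 > self.grid_shape[0] or y1 > self.grid_shape[1] or z1 > self.grid_shape[2]:
                raise ValueError(f"region {name} exceeds the grid")
            block = occupied[x0:x1, y0:y1, z0:z1]
            if block.any():
                raise ValueError(f"region {name} overlaps another region")
            block[...] = True
        self._check_symmetry()

    def _check_symmetry(self) -> None:
        nx = self.grid_shape[0]
        for fiber in ("projection_tract", "association_tract"):
            (lx0, lx1), ly, lz = self.region_layout[f"{fiber}_left"]
            (rx0, rx1), ry, rz = self.region_layout[f"{fiber}_right"]
            # mirror of [lx0, lx1) about the midline is [nx-lx1, nx-lx0)
            if (nx - lx1, nx - lx0) != (rx0, rx1) or ly != ry or lz != rz:
                raise ValueError(f"{fiber} regions are not mirror-symmetric")


@dataclass
class GroundTruth:
    """Noise-free tensor field with region labels and the analytic index.

    ``alps_true`` is the ALPS index implied by the constructed tract
    tensors: mean tract Dxx over mean(projection Dyy, association Dzz).
    """

    tensor_field: np.ndarray  # (nx, ny, nz, 3, 3), 1e-3 mm^2/s
    labels: np.ndarray  # (nx, ny, nz) int region codes
    alps_true: float
    spec: PhantomSpec


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal with its acquisition scheme."""

    signal: np.ndarray  # (nx, ny, nz, n_volumes), >= 0
    voxel_size: tuple[float, float, float]
    affine: np.ndarray  # 4x4 image-to-world
    scheme: GradientScheme

    def __post_init__(self) -> None:
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError("4th dimension must match the scheme length")
        if np.any(self.signal < 0):
            raise ValueError("signals must be non-negative")


def analytic_alps(spec: PhantomSpec) -> float:
    """ALPS index implied by the phantom construction.

    Projection tensors are diag(l_perp + alpha, l_perp, l_par) and
    association tensors diag(l_perp + alpha, l_par, l_perp), so
    mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
    = (l_perp + alpha) / l_perp.
    """
    dxx_proj = dxx_assoc = spec.lambda_perp + spec.alpha
    dyy_proj = dzz_assoc = spec.lambda_perp
    return float(np.mean([dxx_proj, dxx_assoc]) / np.mean([dyy_proj, dzz_assoc]))


def build_tensor_phantom(spec: PhantomSpec) -> GroundTruth:
    """Construct the noise-free tensor field and label map from a spec."""
    spec.validate()
    nx, ny, nz = spec.grid_shape
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    tensors = np.zeros((nx, ny, nz, 3, 3))
    tensors[..., 0, 0] = BACKGROUND_DIFFUSIVITY
    tensors[..., 1, 1] = BACKGROUND_DIFFUSIVITY
    tensors[..., 2, 2] = BACKGROUND_DIFFUSIVITY

    lp, lt, a = spec.lambda_parallel, spec.lambda_perp, spec.alpha
    region_tensors = {
        "ventricle": np.diag([spec.csf_diffusivity] * 3),
        "projection_tract_left": np.diag([lt + a, lt, lp]),
        "projection_tract_right": np.diag([lt + a, lt, lp]),
        "association_tract_left": np.diag([lt + a, lp, lt]),
        "association_tract_right": np.diag([lt + a, lp, lt]),
    }
    for name, D in region_tensors.items():
        (x0, x1), (y0, y1), (z0, z1) = spec.region_layout[name]
        labels[x0:x1, y0:y1, z0:z1] = LABELS[name]
        tensors[x0:x1, y0:y1, z0:z1] = D

    return GroundTruth(tensor_field=tensors, labels=labels, alps_true=analytic_alps(spec), spec=spec)


def _attenuation(tensors: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """exp(-b g^T D g) with D in 1e-3 mm^2/s and b in s/mm^2."""
    g = scheme.directions
    b = scheme.b_values
    # quadratic form per voxel per direction: g_i D g_i
    quad = np.einsum("...jk,ij,ik->...i", tensors, g, g)
    return np.exp(-b * 1e-3 * quad)


def simulate_dwi(
    truth: GroundTruth,
    scheme: GradientScheme,
    s0: float = 1.0,
    noise_sigma: float = 0.0,
    noise_model: str = "rician",
    seed: int = 0,
) -> DWIVolume:
    """Stejskal-Tanner forward simulation with optional noise.

    Noise-free, the per-voxel signal is s0 * exp(-b g^T D g). Gaussian
    noise is added to the magnitude and clipped at zero; Rician noise is
    generated physically as |signal + complex Gaussian|, which is the
    correct model for magnitude MR images and is positively biased at
    low SNR.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise_model {noise_model!r}")

    clean = s0 * _attenuation(truth.tensor_field, scheme)
    if noise_sigma == 0:
        signal = clean
    else:
        rng = np.random.default_rng(seed)
        if noise_model == "gaussian":
            signal = np.clip(clean + rng.normal(0.0, noise_sigma, clean.shape), 0.0, None)
        else:
            re = clean + rng.normal(0.0, noise_sigma, clean.shape)
            im = rng.normal(0.0, noise_sigma, clean.shape)
            signal = np.hypot(re, im)

    vx = truth.spec.voxel_size
    affine = np.diag([vx[0], vx[1], vx[2], 1.0])
    return DWIVolume(signal=signal, voxel_size=vx, affine=affine, scheme=scheme)
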