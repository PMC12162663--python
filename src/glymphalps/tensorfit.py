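"""Per-voxel diffusion tensor estimation and derived maps.

The estimator is ordinary least squares on log-signals against the
7-parameter log-linear design (log S0 + 6 unique tensor components) —
exactly invertible on noise-free data and adequate at the simulated
SNR. Diffusivity maps report the tensor *diagonal* in image axes (the
quantities the ALPS protocol reads), not eigenvalues; FA and the
color-coded FA map come from the eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradients import design_matrix
from .phantom import DWIVolume

__all__ = ["TensorField", "DiffusivityMaps", "fit_tensor", "tensor_to_maps", "fractional_anisotropy"]


@dataclass
class TensorField:
    """Fitted tensors (1e-3 mm^2/s) with per-voxel validity flags."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3) symmetric
    fit_valid: np.ndarray  # (nx, ny, nz) bool
    log_s0: np.ndarray  # (nx, ny, nz) fitted log baseline
    voxel_size: tuple[float, float, float]


@dataclass
class DiffusivityMaps:
    """Scalar maps the ALPS protocol consumes.

    dxx/dyy/dzz are tensor diagonal entries in image axes; fa in [0,1];
    color_fa channels are FA * |principal eigenvector component| per
    axis (x=red, y=green, z=blue), each in [0,1].
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    fa: np.ndarray
    color_fa: np.ndarray  # (nx, ny, nz, 3)
    valid: np.ndarray
    voxel_size: tuple[float, float, float]


def fit_tensor(dwi: DWIVolume, min_signal: float | None = None) -> TensorField:
    """OLS log-linear tensor fit, vectorized over voxels.

    Signals at or below ``min_signal`` (default 1e-6 of the mean b=0
    signal) are clamped before the log and the voxel flagged invalid
    rather than dropped, so the output keeps the full grid shape.
    """
    X = design_matrix(dwi.scheme)
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        raise ValueError(
            f"gradient scheme is rank-deficient (design rank {rank} < 7); "
            "directions do not span the tensor space"
        )

    sig = dwi.signal
    if min_signal is None:
        b0 = sig[..., dwi.scheme.b_values == 0]
        scale = float(b0.mean()) if b0.size else 1.0
        min_signal = 1e-6 * max(scale, np.finfo(float).tiny)

    flat = sig.reshape(-1, sig.shape[-1])
    low = flat <= min_signal
    valid = ~low.any(axis=1)
    clamped = np.where(low, min_signal, flat)

    # one pseudo-inverse serves every voxel
    pinv = np.linalg.pinv(X)
    coef = np.log(clamped) @ pinv.T  # (n_vox, 7)

    n_vox = flat.shape[0]
    tensors = np.empty((n_vox, 3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = (coef[:, i] * 1e3 for i in range(1, 7))
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz

    shape = sig.shape[:3]
    return TensorField(
        tensors=tensors.reshape(*shape, 3, 3),
        fit_valid=valid.reshape(shape),
        log_s0=coef[:, 0].reshape(shape),
        voxel_size=dwi.voxel_size,
    )


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda|| per voxel.

    Degenerate all-zero eigenvalue sets give FA 0.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def tensor_to_maps(field: TensorField) -> DiffusivityMaps:
    """Diagonal diffusivities, FA, and color-FA from a fitted field.

    Negative eigenvalues (possible under noise) are clamped to zero for
    the FA computation and the voxel flagged invalid; the diagonal maps
    are reported as fitted, because the ALPS index reads diagonals.
    """
    t = field.tensors
    evals, evecs = np.linalg.eigh(t)  # ascending eigenvalues
    neg = (evals < 0).any(axis=-1)
    evals_c = np.clip(evals, 0.0, None)
    fa = np.clip(fractional_anisotropy(evals_c), 0.0, 1.0)
    principal = evecs[..., :, 2]  # eigenvector of the largest eigenvalue
    color = np.clip(fa[..., None] * np.abs(principal), 0.0, 1.0)
    return DiffusivityMaps(
        dxx=t[..., 0, 0].copy(),
        dyy=t[..., 1, 1].copy(),
        dzz=t[..., 2, 2].copy(),
        fa=fa,
        color_fa=color,
        valid=field.fit_valid & ~neg,
        voxel_size=field.voxel_size,
    )
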