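"""Diffusion gradient schemes.

A scheme is the list of b-values and unit gradient directions defining a
DWI acquisition. The emulated protocol is a single-shell acquisition:
32 directions at b = 1000 s/mm^2 plus one unweighted (b = 0) volume.
Directions are spread over the sphere by electrostatic-repulsion
relaxation with antipodal symmetry, which is how scanner vendors
construct single-shell tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientScheme", "make_gradient_scheme", "design_matrix"]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientScheme:
    """b-values (s/mm^2) and unit directions (image axes), one per volume.

    Zero-weighted entries carry a zero direction vector. Directions for
    b > 0 entries must be unit-norm within 1e-6.
    """

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise ValueError("b_values must be (n,), directions (n, 3)")
        if np.count_nonzero(b == 0) < 1:
            raise ValueError("scheme needs at least one b=0 entry")
        nz = b > 0
        if np.count_nonzero(nz) < 6:
            raise ValueError("scheme needs >= 6 diffusion-weighted entries")
        norms = np.linalg.norm(g[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("weighted directions must be unit-norm")

    def __len__(self) -> int:
        return int(self.b_values.size)

    @property
    def n_weighted(self) -> int:
        return int(np.count_nonzero(self.b_values > 0))


def _repulsion_relax(points: np.ndarray, n_iter: int = 200, step: float = 5e-3) -> np.ndarray:
    """Relax unit vectors under antipodally-symmetric 1/r^2 repulsion."""
    p = points / np.linalg.norm(points, axis=1, keepdims=True)
    for _ in range(n_iter):
        # forces from both each point and its antipode
        diff = p[:, None, :] - p[None, :, :]
        diff_anti = p[:, None, :] + p[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        da = np.linalg.norm(diff_anti, axis=-1)
        np.fill_diagonal(d, np.inf)
        np.fill_diagonal(da, np.inf)
        d = np.maximum(d, 1e-9)
        da = np.maximum(da, 1e-9)
        force = (diff / d[..., None] ** 3).sum(axis=1) + (diff_anti / da[..., None] ** 3).sum(axis=1)
        p = p + step * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def make_gradient_scheme(n_directions: int, b_value: float = 1000.0, seed: int = 0) -> GradientScheme:
    """Build a single-shell scheme: one b=0 entry plus ``n_directions``
    well-spread unit directions at ``b_value``.

    Fewer than 6 directions cannot determine the 6 independent tensor
    components and are rejected. Deterministic for a fixed seed.
    """
    if n_directions < 6:
        raise ValueError("n_directions must be >= 6 (tensor under-determined)")
    if b_value <= 0:
        raise ValueError("b_value must be positive")
    rng = np.random.default_rng(seed)
    init = rng.standard_normal((n_directions, 3))
    dirs = _repulsion_relax(init)
    # canonical orientation: flip each vector into the z >= 0 hemisphere
    flip = dirs[:, 2] < 0
    dirs[flip] *= -1.0
    b = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    g = np.vstack([np.zeros(3), dirs])
    return GradientScheme(b_values=b, directions=g)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Log-linear tensor design matrix, one row per volume.

    Columns: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]
    so that log S = X @ [log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] with D in
    mm^2/s.
    """
    b = scheme.b_values
    g = scheme.directions
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )
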