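"""Gaussian-atom rasterization of model coordinates onto a voxel grid.

Each atom contributes an isotropic Gaussian of standard deviation
``sigma`` (Å).  This is the simplest model density adequate both for
simulating reconstructed volumes and for real-space map-model
correlation; it deliberately ignores element-specific scattering
factors, which do not matter for occupancy-style statistics on a
single consistent gray scale.
"""

from __future__ import annotations

import numpy as np

from .density import DensityGrid

__all__ = ["rasterize_atoms", "SIGMA_PER_RESOLUTION"]

# resolution-to-sigma heuristic: sigma = resolution / pi
SIGMA_PER_RESOLUTION = 1.0 / np.pi


def rasterize_atoms(
    positions: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size,
    origin,
    sigma: float,
    weights=None,
    cutoff_sigmas: float = 4.0,
) -> DensityGrid:
    """Sum per-atom Gaussians onto a grid.

    Parameters
    ----------
    positions
        (N, 3) atom coordinates in Å.
    sigma
        Gaussian width in Å; each atom is truncated at
        ``cutoff_sigmas * sigma``.
    weights
        Optional per-atom amplitudes (default 1).
    """
    voxel = np.asarray(voxel_size, dtype=float)
    origin = np.asarray(origin, dtype=float)
    data = np.zeros(shape, dtype=np.float64)
    positions = np.asarray(positions, dtype=float)
    if weights is None:
        weights = np.ones(len(positions))
    weights = np.asarray(weights, dtype=float)
    reach = cutoff_sigmas * sigma
    half = np.ceil(reach / voxel).astype(int)
    axes_cache = {}
    for pos, w in zip(positions, weights):
        if w == 0.0:
            continue
        frac = (pos - origin) / voxel
        lo = np.maximum(np.floor(frac).astype(int) - half, 0)
        hi = np.minimum(np.floor(frac).astype(int) + half + 1, shape)
        if np.any(lo >= hi):
            continue
        exps = []
        for a in range(3):
            coords = np.arange(lo[a], hi[a]) * voxel[a] + origin[a]
            exps.append(np.exp(-((coords - pos[a]) ** 2) / (2.0 * sigma**2)))
        data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += w * (
            exps[0][:, None, None] * exps[1][None, :, None] * exps[2][None, None, :]
        )
    return DensityGrid(data, tuple(voxel), tuple(origin))
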