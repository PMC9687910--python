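"""Density-map I/O, point sampling, Fourier filtering, and solvent masks.

The unit of map data is :class:`DensityGrid`: a 3D scalar field on an
orthogonal voxel lattice, with ``data[i, j, k]`` indexing along the
crystallographic x, y, z axes after any MRC axis permutation has been
undone at read time.  Density values are on whatever gray scale the map
was written with (for unsharpened single-particle reconstructions this
is an absolute scale, which is what makes a single occupancy threshold
meaningful across class maps).

Coordinates are in ångström throughout.  ``origin`` is the position of
the *center* of voxel (0, 0, 0); a point ``p`` maps to fractional voxel
coordinates ``(p - origin) / voxel_size``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

import gemmi

from .errors import EmptyMaskError, MapFormatError, ParameterError

__all__ = [
    "DensityGrid",
    "MaskGrid",
    "read_map",
    "write_map",
    "map_value_at_point",
    "lowpass_filter",
    "make_solvent_mask",
]


@dataclass
class DensityGrid:
    """A 3D density map with voxel geometry.

    Parameters
    ----------
    data
        3D float array; axis 0, 1, 2 run along x, y, z.
    voxel_size
        Å per voxel along each axis; all components > 0.
    origin
        Å position of the center of voxel (0, 0, 0).
    axis_order
        Permutation mapping the array axes to crystallographic axes.
        Always (0, 1, 2) after :func:`read_map`, which canonicalizes.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: tuple[int, int, int] = (0, 1, 2)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ParameterError(
                f"density grid must be 3D with every axis >= 2, got shape {self.data.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size must be positive, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def center(self) -> np.ndarray:
        """Å position of the geometric center of the box."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.voxel_size
        )

    def with_data(self, data: np.ndarray) -> "DensityGrid":
        return DensityGrid(data, self.voxel_size, self.origin, self.axis_order)


@dataclass
class MaskGrid(DensityGrid):
    """A soft mask: same geometry as a density grid, values in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.min() < -1e-6 or self.data.max() > 1 + 1e-6:
            raise ParameterError("mask values must lie in [0, 1]")


_MRC_MODE_OFFSET = 12  # word 4 of the 1024-byte header
_VALID_MODES = {0, 1, 2}


def _peek_mode(path) -> int:
    with open(path, "rb") as fh:
        header = fh.read(16)
    if len(header) < 16:
        raise MapFormatError(f"{path}: file too short to hold an MRC header")
    (mode,) = struct.unpack("<i", header[_MRC_MODE_OFFSET : _MRC_MODE_OFFSET + 4])
    if mode not in _VALID_MODES:
        # the file may be big-endian; re-read before rejecting
        (mode_be,) = struct.unpack(">i", header[_MRC_MODE_OFFSET : _MRC_MODE_OFFSET + 4])
        if mode_be in _VALID_MODES:
            mode = mode_be
    return mode


def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 map, canonicalizing axis order to x, y, z.

    Voxel size comes from the unit cell divided by the grid sampling;
    the origin comes from the ORIGIN header words, falling back to
    ``nstart * voxel_size`` when ORIGIN is all-zero and nstart is not.
    """
    mode = _peek_mode(path)
    if mode not in _VALID_MODES:
        raise MapFormatError(
            f"{path}: header MODE={mode} not supported (expected one of {sorted(_VALID_MODES)})"
        )
    try:
        m = gemmi.read_ccp4_map(str(path))
        m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: {exc}") from exc
    grid = m.grid
    nx, ny, nz = grid.nu, grid.nv, grid.nw
    cell = grid.unit_cell
    if nx < 2 or ny < 2 or nz < 2:
        raise MapFormatError(f"{path}: header NX/NY/NZ degenerate ({nx}, {ny}, {nz})")
    voxel = (cell.a / nx, cell.b / ny, cell.c / nz)
    if any(v <= 0 for v in voxel):
        raise MapFormatError(f"{path}: header CELLA implies non-positive voxel size {voxel}")
    origin = tuple(m.header_float(w) for w in (50, 51, 52))
    if all(abs(o) < 1e-12 for o in origin):
        nstart = tuple(m.header_i32(w) for w in (5, 6, 7))
        origin = tuple(n * v for n, v in zip(nstart, voxel))
    data = np.array(grid, copy=True)
    return DensityGrid(data=data, voxel_size=voxel, origin=origin)


def write_map(grid: DensityGrid, path) -> None:
    """Write a grid as an MRC 2014 map, mode 2 (32-bit float).

    The header is written so that :func:`read_map` inverts it exactly:
    CELLA encodes the anisotropic voxel size, ORIGIN words 50-52 carry
    the Å origin.
    """
    nx, ny, nz = grid.shape
    vx, vy, vz = grid.voxel_size
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.data, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(value))
    m.write_ccp4_map(str(path))


def map_value_at_point(grid: DensityGrid, point) -> float:
    """Trilinear interpolation of the map at an Å position.

    Points outside the grid hull (the box spanned by voxel centers)
    return exactly 0; an atom outside the reconstructed box is by
    definition not supported by density.
    """
    return float(map_values_at_points(grid, np.asarray(point, dtype=float)[None, :])[0])


def map_values_at_points(grid: DensityGrid, points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`map_value_at_point` for an (N, 3) array."""
    points = np.asarray(points, dtype=float)
    frac = (points - np.asarray(grid.origin)) / np.asarray(grid.voxel_size)
    shape = np.asarray(grid.shape)
    inside = np.all((frac >= 0.0) & (frac <= shape - 1), axis=1)
    values = ndimage.map_coordinates(
        grid.data.astype(np.float64), frac.T, order=1, mode="nearest"
    )
    values[~inside] = 0.0
    return values


def _radial_frequency(shape, voxel_size) -> np.ndarray:
    axes = [np.fft.fftfreq(n, d=v) for n, v in zip(shape, voxel_size)]
    kx, ky, kz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(kx * kx + ky * ky + kz * kz)


def lowpass_filter(grid: DensityGrid, resolution: float, edge_width: float = 2.0) -> DensityGrid:
    """Fourier low-pass with a raised-cosine edge.

    Frequencies below ``1/resolution`` pass unattenuated; the transfer
    function then falls as a half-cosine to zero over ``edge_width``
    Fourier pixels.  The DC term is untouched, so the mean density is
    preserved.

    Parameters
    ----------
    resolution
        Cutoff in Å; must exceed twice the largest voxel size (Nyquist).
    edge_width
        Width of the raised-cosine roll-off in Fourier pixels.
    """
    if resolution <= 2.0 * max(grid.voxel_size):
        raise ParameterError(
            f"resolution {resolution} Å is at or below Nyquist for voxel size {grid.voxel_size}"
        )
    k = _radial_frequency(grid.shape, grid.voxel_size)
    kc = 1.0 / resolution
    # one Fourier pixel = finest frequency step of the box
    dk = float(np.mean([1.0 / (n * v) for n, v in zip(grid.shape, grid.voxel_size)]))
    edge = max(edge_width, 1e-9) * dk
    transfer = np.zeros_like(k)
    transfer[k <= kc] = 1.0
    on_edge = (k > kc) & (k < kc + edge)
    transfer[on_edge] = 0.5 * (1.0 + np.cos(np.pi * (k[on_edge] - kc) / edge))
    filtered = np.fft.ifftn(np.fft.fftn(grid.data.astype(np.float64)) * transfer).real
    return grid.with_data(filtered)


def make_solvent_mask(
    grid: DensityGrid,
    sphere_radius: float = 155.0,
    prefilter_resolution: float = 15.0,
    threshold: float = 0.012,
    expand: int = 5,
    soft_edge: int = 5,
) -> MaskGrid:
    """Build a soft solvent mask from a reconstruction.

    Pipeline: (1) zero all density outside a sphere of ``sphere_radius``
    Å centered on the box, (2) low-pass to ``prefilter_resolution`` Å,
    (3) binarize above ``threshold``, (4) binary-dilate by ``expand``
    voxels (Euclidean ball), (5) append a cosine soft edge falling from
    1 to 0 over ``soft_edge`` voxels of Euclidean distance.

    The defaults are the standard recipe for masking a ribosome-scale
    reconstruction: 155-Å sphere, 15-Å prefilter, binarization at 0.012,
    5-voxel expansion, 5-voxel soft edge.
    """
    if sphere_radius <= 0 or prefilter_resolution <= 0 or expand < 0 or soft_edge < 0:
        raise ParameterError("mask parameters must be positive")
    idx = np.indices(grid.shape, dtype=float)
    pos = np.stack(
        [idx[a] * grid.voxel_size[a] + grid.origin[a] for a in range(3)], axis=0
    )
    r2 = np.sum((pos - grid.center()[:, None, None, None]) ** 2, axis=0)
    sphered = np.where(r2 <= sphere_radius**2, grid.data, 0.0)
    filtered = lowpass_filter(grid.with_data(sphered), prefilter_resolution)
    binary = filtered.data > threshold
    if not binary.any():
        raise EmptyMaskError(
            f"threshold {threshold} exceeds the filtered map maximum {filtered.data.max():.4g}"
        )
    if expand > 0:
        # Euclidean dilation: any voxel within `expand` of the binary set
        dist_out = ndimage.distance_transform_edt(~binary)
        dilated = dist_out <= expand
    else:
        dilated = binary
    mask = dilated.astype(np.float64)
    if soft_edge > 0:
        dist = ndimage.distance_transform_edt(~dilated)
        shell = (dist > 0) & (dist < soft_edge)
        mask[shell] = 0.5 * (1.0 + np.cos(np.pi * dist[shell] / soft_edge))
    out = MaskGrid(mask, grid.voxel_size, grid.origin, grid.axis_order)
    out.provenance = {
        "sphere_radius_A": sphere_radius,
        "prefilter_resolution_A": prefilter_resolution,
        "threshold": threshold,
        "expand_voxels": expand,
        "soft_edge_voxels": soft_edge,
    }
    return out
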