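"""Per-feature density occupancy, normalization, category encoding, and
pixel-size calibration.

The occupancy of a structural feature in one class reconstruction is
the fraction of the feature's heavy atoms whose interpolated map value
strictly exceeds a threshold (default 0.05 on the absolute gray scale
of unsharpened reconstructions).  Maps are low-pass filtered (default
5 Å) first, so that small rigid-body misalignments between map and
model do not punish well-ordered features.

Normalization divides each feature row by the larger of (a) that
feature's maximum occupancy across classes and (b) the median of all
matrix entries; this keeps weakly-ordered features from being inflated
to full scale by their own noise floor.

Manual density categories for rRNA helices (near-native, slightly
distorted, highly distorted, disordered) are encoded as 0.1, 0.085,
0.045, and 0 — values on the same gray scale as raw occupancies of the
0.05-threshold statistic — so manual and automated calls can be
clustered together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .density import DensityGrid, lowpass_filter, map_values_at_points
from .errors import ParameterError, ValidationError
from .models import AtomicModel, AtomSelection, FeatureSegmentation, resolve_features
from .raster import SIGMA_PER_RESOLUTION, rasterize_atoms

__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_LOWPASS",
    "OccupancyMatrix",
    "ManualCategory",
    "CATEGORY_ENCODING",
    "feature_occupancy",
    "occupancy_matrix",
    "normalize_matrix",
    "encode_manual_category",
    "apply_manual_categories",
    "PixelSizeResult",
    "refine_pixel_size",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.05
DEFAULT_LOWPASS = 5.0


class ManualCategory(str, Enum):
    """Visual quality call for a helix density."""

    near_native = "near_native"
    slightly_distorted = "slightly_distorted"
    highly_distorted = "highly_distorted"
    disordered = "disordered"


CATEGORY_ENCODING: dict[ManualCategory, float] = {
    ManualCategory.near_native: 0.1,
    ManualCategory.slightly_distorted: 0.085,
    ManualCategory.highly_distorted: 0.045,
    ManualCategory.disordered: 0.0,
}


def encode_manual_category(category) -> float:
    """Numeric encoding of a manual category (0.1 / 0.085 / 0.045 / 0)."""
    try:
        return CATEGORY_ENCODING[ManualCategory(category)]
    except ValueError as exc:
        raise ValidationError(
            f"unknown manual category {category!r}; expected one of "
            f"{[c.value for c in ManualCategory]}"
        ) from exc


@dataclass
class OccupancyMatrix:
    """Features x classes occupancy table.

    ``values[i, j]`` is the occupancy of feature ``feature_ids[i]`` in
    class ``class_ids[j]``.  ``normalized`` distinguishes raw fractions
    from the max/median-normalized form.  ``provenance`` records the
    parameters that produced the matrix.
    """

    values: np.ndarray
    feature_ids: list[str]
    class_ids: list[str]
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.class_ids)):
            raise ParameterError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.class_ids)} classes"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.class_ids)

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "feature_id"
        frame.to_csv(path, sep="\t", float_format="%.6g")

    def column(self, class_id: str) -> np.ndarray:
        try:
            j = self.class_ids.index(class_id)
        except ValueError as exc:
            raise ParameterError(f"unknown class_id {class_id!r}") from exc
        return self.values[:, j]


def feature_occupancy(
    grid: DensityGrid,
    selection: AtomSelection,
    model: AtomicModel,
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Fraction of a feature's atoms sitting in supra-threshold density.

    The caller is responsible for low-pass filtering the grid; the
    statistic itself is a plain count of atoms with interpolated map
    value strictly above ``threshold``, over the number of selected
    atoms.  Atoms outside the grid contribute density 0 but stay in the
    denominator.  An empty selection scores 0 (logged).
    """
    if len(selection) == 0:
        logger.warning("feature %s: empty selection scored 0", selection.feature_id)
        return 0.0
    values = map_values_at_points(grid, model.positions[selection.atom_indices])
    return float(np.count_nonzero(values > threshold)) / float(len(selection))


def occupancy_matrix(
    class_maps: dict[str, DensityGrid],
    model: AtomicModel,
    seg: FeatureSegmentation,
    threshold: float = DEFAULT_THRESHOLD,
    lowpass: float = DEFAULT_LOWPASS,
    model_id: str = "model",
    permissive: bool = False,
    prefiltered: bool = False,
) -> OccupancyMatrix:
    """Occupancy of every feature in every class reconstruction.

    Each map is low-pass filtered to ``lowpass`` Å (unless
    ``prefiltered``), then scored feature by feature.  A class whose
    map cannot be processed aborts the run unless ``permissive`` is
    set, in which case its column is dropped and reported.
    """
    selections = resolve_features(model, seg)
    class_ids = list(class_maps)
    columns = {}
    failed = []
    for cid in class_ids:
        try:
            grid = class_maps[cid]
            filtered = grid if prefiltered else lowpass_filter(grid, lowpass)
            columns[cid] = [
                feature_occupancy(filtered, sel, model, threshold) for sel in selections
            ]
        except Exception as exc:  # noqa: BLE001 - column-level containment
            if not permissive:
                raise
            logger.error("class %s dropped: %s", cid, exc)
            failed.append(cid)
    kept = [cid for cid in class_ids if cid not in failed]
    values = np.array([[columns[cid][i] for cid in kept] for i in range(len(selections))])
    if values.size == 0:
        values = values.reshape(len(selections), 0)
    return OccupancyMatrix(
        values,
        seg.feature_ids(),
        kept,
        normalized=False,
        provenance={
            "threshold": threshold,
            "lowpass_A": lowpass,
            "model": model_id,
            "class_maps": {cid: f"class:{cid}" for cid in kept},
            "failed_classes": failed,
            "empty_features": [s.feature_id for s in selections if len(s) == 0],
        },
    )


def normalize_matrix(m: OccupancyMatrix, median_mode: str = "global") -> OccupancyMatrix:
    """Max/median row normalization.

    Each feature row is divided by ``max(row_max, M)`` where ``M`` is
    the median of all matrix entries (``median_mode="global"``, the
    default) or the median of per-feature medians
    (``median_mode="per_feature"``, provided for sensitivity analysis).
    An all-zero matrix comes back all-zero with a warning.
    """
    if m.normalized:
        raise ParameterError("matrix is already normalized")
    if median_mode not in ("global", "per_feature"):
        raise ParameterError(f"unknown median_mode {median_mode!r}")
    values = m.values
    if values.size == 0 or not np.any(values):
        logger.warning("all-zero occupancy matrix: normalization is identity-on-zero")
        out = values.copy()
    else:
        if median_mode == "global":
            med = float(np.median(values))
        else:
            med = float(np.median(np.median(values, axis=1)))
        row_max = values.max(axis=1)
        denom = np.maximum(row_max, med)
        denom[denom == 0] = np.inf  # all-zero rows below a zero median stay 0
        out = values / denom[:, None]
    return OccupancyMatrix(
        out,
        list(m.feature_ids),
        list(m.class_ids),
        normalized=True,
        provenance={**m.provenance, "normalization": f"max/median ({median_mode})"},
    )


def apply_manual_categories(m: OccupancyMatrix, table: pd.DataFrame) -> OccupancyMatrix:
    """Replace cells of a raw matrix with encoded manual calls.

    ``table`` columns: feature_id, class_id, label.  The encoded value
    replaces (not supplements) the automated occupancy for that cell,
    before normalization.
    """
    if m.normalized:
        raise ParameterError("manual categories must be applied before normalization")
    required = {"feature_id", "class_id", "label"}
    if not required <= set(table.columns):
        raise ValidationError(f"manual-category table needs columns {sorted(required)}")
    values = m.values.copy()
    for _, row in table.iterrows():
        fid, cid = str(row["feature_id"]), str(row["class_id"])
        if fid not in m.feature_ids:
            raise ValidationError(f"manual category for unknown feature {fid!r}")
        if cid not in m.class_ids:
            raise ValidationError(f"manual category for unknown class {cid!r}")
        values[m.feature_ids.index(fid), m.class_ids.index(cid)] = encode_manual_category(
            str(row["label"])
        )
    return OccupancyMatrix(
        values,
        list(m.feature_ids),
        list(m.class_ids),
        normalized=False,
        provenance={**m.provenance, "manual_cells": int(len(table))},
    )


@dataclass
class PixelSizeResult:
    """Outcome of the pixel-size calibration scan."""

    voxel_size: float
    scale: float
    correlation: float
    converged: bool
    scan_scales: np.ndarray
    scan_correlations: np.ndarray


def _masked_correlation(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    x, y = a[mask], b[mask]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)


def refine_pixel_size(
    grid: DensityGrid,
    model: AtomicModel,
    scan_range: tuple[float, float] = (0.97, 1.03),
    steps: int = 13,
    resolution: float = DEFAULT_LOWPASS,
    min_correlation: float = 0.2,
) -> PixelSizeResult:
    """Calibrate the pixel size by scanning the map-model fit.

    For each candidate scale the model coordinates are rescaled about
    the box center, rasterized as Gaussian atoms (sigma tied to the
    working resolution), and correlated with the map over the model
    region.  The best scale (parabolic interpolation through the top
    three samples) converts the nominal voxel size to the calibrated
    one: ``voxel_calibrated = voxel_nominal / scale``.

    A maximum on the scan boundary, or a best correlation below
    ``min_correlation``, flags the result as unconverged.
    """
    lo, hi = scan_range
    if not (lo < 1.0 < hi):
        raise ParameterError(f"scan_range {scan_range} must bracket 1.0")
    if steps < 3:
        raise ParameterError("need at least 3 scan steps")
    sigma = resolution * SIGMA_PER_RESOLUTION
    center = grid.center()
    scales = np.linspace(lo, hi, steps)
    corrs = np.empty(steps)
    for s_i, scale in enumerate(scales):
        pos = center + (model.positions - center) * scale
        raster = rasterize_atoms(pos, grid.shape, grid.voxel_size, grid.origin, sigma)
        mask = raster.data > 0.05 * raster.data.max()
        corrs[s_i] = _masked_correlation(grid.data.astype(float), raster.data, mask)
    best = int(np.argmax(corrs))
    converged = 0 < best < steps - 1 and corrs[best] >= min_correlation
    if converged:
        # parabola vertex through the best three (uniformly spaced) samples
        x0, x1, _x2 = scales[best - 1 : best + 2]
        y0, y1, y2 = corrs[best - 1 : best + 2]
        curvature = y0 - 2 * y1 + y2
        if curvature < 0:
            scale_best = x1 + (x1 - x0) * (y0 - y2) / (2 * curvature)
        else:
            scale_best = x1
    else:
        scale_best = scales[best]
        logger.warning(
            "pixel-size scan unconverged (best at %s, corr %.3f)", scales[best], corrs[best]
        )
    mean_voxel = float(np.mean(grid.voxel_size))
    return PixelSizeResult(
        voxel_size=mean_voxel / scale_best,
        scale=float(scale_best),
        correlation=float(corrs[best]),
        converged=bool(converged),
        scan_scales=scales,
        scan_correlations=corrs,
    )
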