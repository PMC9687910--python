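"""Synthetic ribosome-like models and simulated class reconstructions.

The generator emulates the regime of a heterogeneous set of class
reconstructions of one particle: a shared toy atomic model whose
features (pseudo-helices on a common rRNA-like chain, plus protein
chains) are present at full, partial, shifted, or zero occupancy per
class, rasterized as Gaussian atoms on an absolute-like gray scale
with additive Gaussian noise.  Every dataset ships a truth manifest so
occupancy recovery, clustering recovery, and disassembly-order
recovery are all checkable against planted ground truth.

Geometry is chosen so the occupancy statistic is *calibrated*: atoms
within a feature sit at least ~4.5 Å apart, so that after the 5-Å
low-pass an individual deleted atom's position genuinely falls below
the 0.05 threshold instead of riding on its neighbors' density, and
distinct features are at least 8 Å apart so absent features score
zero.  Partial occupancy is modeled by deleting a seeded random subset
of atoms rather than by scaling density, which makes the expected
recovered occupancy equal the retained fraction independent of where
the threshold sits between the noise floor and the working density.

Density amplitude is calibrated on the low-pass-filtered volume (the
scale on which the threshold operates): a fully occupied feature's
atom-center values average ``peak_density`` (default 0.12) after
filtering to the working resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .density import DensityGrid, lowpass_filter
from .errors import ParameterError, ResourceError
from .models import AtomicModel, Feature, FeatureSegmentation
from .occupancy import DEFAULT_LOWPASS
from .raster import rasterize_atoms

__all__ = [
    "FeatureState",
    "TruthManifest",
    "SyntheticSeries",
    "make_toy_model",
    "simulate_class_map",
    "make_disassembly_series",
]

DEFAULT_VOXEL = 1.1
DEFAULT_PEAK = 0.12
DEFAULT_NOISE = 0.01
DETAIL_SIGMA = 3.5 / np.pi  # Gaussian atom width for a nominal 3.5-A detail level
INTRA_SPACING = 5.5  # atom sub-lattice pitch within a feature (A)
INTRA_JITTER = 0.5
MIN_FEATURE_SEPARATION = 8.0  # closest allowed atoms of distinct features (A)


@dataclass(frozen=True)
class FeatureState:
    """Planted per-feature state in one class."""

    kind: str  # full | partial | shifted | absent
    alpha: float | None = None  # retained fraction for partial
    delta: float | None = None  # rigid shift in A for shifted

    def __post_init__(self) -> None:
        if self.kind not in ("full", "partial", "shifted", "absent"):
            raise ParameterError(f"unknown state kind {self.kind!r}")
        if self.kind == "partial" and not (self.alpha and 0.0 < self.alpha < 1.0):
            raise ParameterError("partial state needs alpha in (0, 1)")
        if self.kind == "shifted" and not (self.delta and self.delta > 0):
            raise ParameterError("shifted state needs delta > 0")

    def expected_occupancy(self, n_atoms: int) -> float | None:
        """Planted occupancy; None where the statistic is uncalibrated."""
        if self.kind == "full":
            return 1.0
        if self.kind == "absent":
            return 0.0
        if self.kind == "partial":
            return round(self.alpha * n_atoms) / n_atoms
        return None  # shifted: depends on delta vs. resolution

    def to_dict(self) -> dict:
        return {"kind": self.kind, "alpha": self.alpha, "delta": self.delta}


@dataclass
class TruthManifest:
    """Ground truth for a simulated class series."""

    seed: int
    classes: dict[str, dict[str, FeatureState]]  # class_id -> feature_id -> state
    noise_sigma: float
    peak_density: float
    voxel_size: float
    box: tuple[int, int, int]
    feature_ids: list[str]
    expected_occupancy: dict[str, dict[str, float | None]]
    present_sets: dict[str, list[str]]
    groups: dict[str, str] = field(default_factory=dict)  # class -> small/medium/large
    hasse_edges: list[tuple[str, str]] = field(default_factory=list)
    maximal_chains: list[list[str]] = field(default_factory=list)
    map_peaks: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "peak_density": self.peak_density,
            "voxel_size": self.voxel_size,
            "box": list(self.box),
            "feature_ids": self.feature_ids,
            "classes": {
                cid: {fid: st.to_dict() for fid, st in states.items()}
                for cid, states in self.classes.items()
            },
            "expected_occupancy": self.expected_occupancy,
            "present_sets": self.present_sets,
            "groups": self.groups,
            "hasse_edges": [list(e) for e in self.hasse_edges],
            "maximal_chains": self.maximal_chains,
            "map_peaks": self.map_peaks,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _feature_radius(n_atoms: int) -> float:
    """Smallest ball radius whose atom sub-lattice holds n_atoms sites."""
    r = INTRA_SPACING
    while True:
        if len(_lattice_sites(r)) >= n_atoms:
            return r
        r += 0.5


def _lattice_sites(radius: float) -> np.ndarray:
    m = int(np.ceil(radius / INTRA_SPACING))
    axes = np.arange(-m, m + 1) * INTRA_SPACING
    grid = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(grid, axis=1) <= radius
    sites = grid[keep]
    order = np.argsort(np.linalg.norm(sites, axis=1), kind="stable")
    return sites[order]


_RNA_ATOMS = [("P", "P"), ("C4'", "C"), ("N1", "N"), ("C2", "C")]
_PROT_ATOMS = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]


def make_toy_model(
    n_features: int = 13,
    atoms_per_feature: int = 20,
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[AtomicModel, FeatureSegmentation]:
    """Toy model: compact atom clusters on a well-separated lattice.

    Even-indexed features are rRNA-helix-like clusters sharing chain
    "A" (distinct residue ranges); odd-indexed features are protein
    chains "B", "C", ...  Clusters are jittered sub-lattices inside a
    ball, guaranteeing >= ~4.5 Å intra-feature atom spacing, and the
    cluster centers sit on a lattice spaced so the nearest atoms of
    different features are >= 8 Å apart (verified by brute force; the
    jitter is re-drawn on the rare violation).

    Coordinates are centered on the origin; callers place the model in
    a box via its bounding sphere.
    """
    if n_features < 1:
        raise ParameterError("n_features must be >= 1")
    radius = _feature_radius(atoms_per_feature)
    spacing = 2 * radius + MIN_FEATURE_SEPARATION + 2 * INTRA_JITTER + 0.5
    per_axis = int(np.ceil(n_features ** (1.0 / 3.0)))
    dims = [per_axis, per_axis, int(np.ceil(n_features / per_axis**2))]
    centers = []
    for a in range(dims[0]):
        for b in range(dims[1]):
            for c in range(dims[2]):
                centers.append((np.array([a, b, c]) - (np.array(dims) - 1) / 2.0) * spacing)
            if len(centers) >= n_features * 2:
                break
    centers = np.array(centers)
    order = np.argsort(np.linalg.norm(centers, axis=1), kind="stable")
    centers = centers[order][:n_features]

    base_sites = _lattice_sites(radius)[:atoms_per_feature]
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        positions = []
        for center in centers:
            jitter = rng.uniform(-INTRA_JITTER, INTRA_JITTER, size=base_sites.shape)
            positions.append(center + base_sites + jitter)
        if _min_inter_feature_distance(positions) >= MIN_FEATURE_SEPARATION:
            break
    else:
        raise ResourceError("could not pack features with the required separation")

    chains, resnums, icodes, resnames, atomnames, elements, coords = (
        [], [], [], [], [], [], [],
    )
    features = []
    helix_cursor = 1
    protein_chain = ord("B")
    n_helix = 0
    for f_i, atom_xyz in enumerate(positions):
        is_helix = f_i % 2 == 0
        n_atoms = len(atom_xyz)
        n_res = int(np.ceil(n_atoms / 4))
        if is_helix:
            n_helix += 1
            fid = f"H{n_helix}"
            chain = "A"
            res_start = helix_cursor
            helix_cursor += n_res + 10
            templates, resname = _RNA_ATOMS, "G"
            kind = "rrna_helix"
        else:
            fid = f"uL{f_i + 1}"
            chain = chr(protein_chain)
            protein_chain += 1
            res_start = 1
            templates, resname = _PROT_ATOMS, "ALA"
            kind = "rprotein"
        for a_i, xyz in enumerate(atom_xyz):
            name, element = templates[a_i % 4]
            chains.append(chain)
            resnums.append(res_start + a_i // 4)
            icodes.append("")
            resnames.append(resname)
            atomnames.append(name if a_i < 4 else f"{name}{a_i // 4}"[:4])
            elements.append(element)
            coords.append(xyz)
        features.append(
            Feature(fid, kind, chain, [(res_start, res_start + n_res - 1)])
        )
    model = AtomicModel(
        np.array(chains),
        np.array(resnums, dtype=int),
        np.array(icodes),
        np.array(resnames),
        np.array(atomnames),
        np.array(elements),
        np.array(coords, dtype=float),
    )
    return model, FeatureSegmentation(features)


def _min_inter_feature_distance(positions: list[np.ndarray]) -> float:
    best = np.inf
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            d = np.linalg.norm(positions[i][:, None, :] - positions[j][None, :, :], axis=-1)
            best = min(best, float(d.min()))
    return best


def _feature_atom_indices(model: AtomicModel, seg: FeatureSegmentation) -> dict[str, np.ndarray]:
    from .models import resolve_features

    return {sel.feature_id: sel.atom_indices for sel in resolve_features(model, seg)}


def suggest_box(model: AtomicModel, voxel_size: float = DEFAULT_VOXEL, margin: float = 9.0) -> tuple[int, int, int]:
    """Cubic box (voxels) holding the model with a margin on every side."""
    span = model.positions.max(axis=0) - model.positions.min(axis=0)
    extent = float(span.max()) + 2 * margin
    n = int(np.ceil(extent / voxel_size))
    n += n % 2
    return (n, n, n)


def simulate_class_map(
    model: AtomicModel,
    seg: FeatureSegmentation,
    states: dict[str, FeatureState],
    voxel_size: float = DEFAULT_VOXEL,
    box: tuple[int, int, int] | None = None,
    peak_density: float = DEFAULT_PEAK,
    noise_sigma: float = DEFAULT_NOISE,
    seed: int = 0,
    calibration_lowpass: float = DEFAULT_LOWPASS,
) -> DensityGrid:
    """Simulate one class reconstruction with planted feature states.

    full features rasterize all atoms; partial(alpha) retains a seeded
    random subset of round(alpha * n) atoms; shifted(delta) rigidly
    translates the feature by a seeded random direction of length
    delta; absent contributes nothing.  The volume is scaled so that a
    fully occupied feature's atom centers average ``peak_density``
    after low-pass filtering to ``calibration_lowpass`` Å, then
    Gaussian noise of ``noise_sigma`` is added.
    """
    if box is None:
        box = suggest_box(model, voxel_size)
    rng = np.random.default_rng(seed)
    index_of = _feature_atom_indices(model, seg)
    unknown = set(states) - set(index_of)
    if unknown:
        raise ParameterError(f"states reference unknown features {sorted(unknown)}")
    center_model = model.positions.mean(axis=0)
    origin = tuple(
        center_model[a] - (box[a] - 1) / 2.0 * voxel_size for a in range(3)
    )
    lo = (model.positions.min(axis=0) - np.asarray(origin)) / voxel_size
    hi = (model.positions.max(axis=0) - np.asarray(origin)) / voxel_size
    if np.any(lo < 0) or np.any(hi > np.asarray(box) - 1):
        raise ParameterError(f"box {box} too small to contain the model")

    positions = []
    weights = []
    for f in seg.features:
        idx = index_of[f.feature_id]
        state = states.get(f.feature_id, FeatureState("full"))
        xyz = model.positions[idx]
        if state.kind == "absent":
            continue
        if state.kind == "partial":
            keep = round(state.alpha * len(idx))
            chosen = rng.choice(len(idx), size=keep, replace=False)
            xyz = xyz[np.sort(chosen)]
        elif state.kind == "shifted":
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            xyz = xyz + direction * state.delta
        positions.append(xyz)
        weights.append(np.ones(len(xyz)))
    sigma = DETAIL_SIGMA

    # amplitude calibration from the all-full reference volume
    reference = rasterize_atoms(model.positions, box, (voxel_size,) * 3, origin, sigma)
    ref_filtered = lowpass_filter(reference, calibration_lowpass)
    from .density import map_values_at_points

    center_values = map_values_at_points(ref_filtered, model.positions)
    scale = peak_density / float(center_values.mean())

    if positions:
        raster = rasterize_atoms(
            np.concatenate(positions), box, (voxel_size,) * 3, origin, sigma
        )
        data = raster.data.astype(np.float64) * scale
    else:
        data = np.zeros(box)
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=box)
    return DensityGrid(data, (voxel_size,) * 3, origin)


@dataclass
class SyntheticSeries:
    """A complete simulated dataset: model, segmentation, maps, truth."""

    model: AtomicModel
    segmentation: FeatureSegmentation
    maps: dict[str, DensityGrid]
    manifest: TruthManifest


def _chain_layout(n_classes: int, n_helper_features: int | None = None):
    """Planted sizes for a linear series in three well-separated blocks."""
    block_sizes = [n_classes // 3] * 3
    for i in range(n_classes % 3):
        block_sizes[i] += 1
    sizes, groups = [], []
    names = ["small", "medium", "large"]
    base = 2
    for b, nb in enumerate(block_sizes):
        for w in range(nb):
            sizes.append(base + w)
            groups.append(names[b])
        base = sizes[-1] + 4  # >= 4-feature gap between blocks
    return sizes, groups


def make_disassembly_series(
    n_classes: int = 6,
    branching: bool = False,
    seed: int = 0,
    atoms_per_feature: int = 20,
    noise_sigma: float = DEFAULT_NOISE,
    peak_density: float = DEFAULT_PEAK,
    voxel_size: float = DEFAULT_VOXEL,
    partial_alpha: float = 0.7,
) -> SyntheticSeries:
    """Simulate a nested (or two-branch) disassembly series.

    Without branching, classes C1..Cn carry nested feature sets whose
    sizes fall into three well-separated blocks (small / medium /
    large particles, the planted k=3 partition); each class's newest
    feature is planted at partial occupancy ``partial_alpha`` so the
    dataset exercises non-binary occupancies.  With branching, a core
    class grows along two disjoint feature pools that reunite in a top
    class, so the planted inclusion order is a diamond with exactly
    two maximal chains.
    """
    if n_classes < 2:
        raise ParameterError("n_classes must be >= 2")
    if branching and n_classes < 4:
        raise ParameterError("branching layout needs n_classes >= 4")

    if not branching:
        sizes, group_names = _chain_layout(n_classes)
        n_features = sizes[-1]
        class_ids = [f"C{i + 1}" for i in range(n_classes)]
        feature_lists: dict[str, list[int]] = {
            cid: list(range(size)) for cid, size in zip(class_ids, sizes)
        }
        groups = dict(zip(class_ids, group_names))
        hasse = [(class_ids[i], class_ids[i + 1]) for i in range(n_classes - 1)]
        chains = [list(class_ids)]
    else:
        core = 3
        n_inner = n_classes - 2
        n_left = (n_inner + 1) // 2
        n_right = n_inner - n_left
        left_pool = [core + 2 * i for i in range(n_left)]
        n_features = core + 2 * (n_left + n_right)
        class_ids = ["C1"]
        feature_lists = {"C1": list(range(core))}
        prev = "C1"
        hasse = []
        left_ids, right_ids = [], []
        acc = list(range(core))
        for i in range(n_left):
            cid = f"L{i + 1}"
            acc = acc + [core + 2 * i, core + 2 * i + 1]
            feature_lists[cid] = list(acc)
            hasse.append((prev, cid))
            left_ids.append(cid)
            prev = cid
        last_left = prev
        prev = "C1"
        acc = list(range(core))
        offset = core + 2 * n_left
        for i in range(n_right):
            cid = f"R{i + 1}"
            acc = acc + [offset + 2 * i, offset + 2 * i + 1]
            feature_lists[cid] = list(acc)
            hasse.append((prev, cid))
            right_ids.append(cid)
            prev = cid
        last_right = prev
        top = "T1"
        feature_lists[top] = list(range(n_features))
        hasse.append((last_left, top))
        if n_right:
            hasse.append((last_right, top))
        class_ids = ["C1"] + left_ids + right_ids + [top]
        groups = {}
        chains = sorted(
            [["C1"] + left_ids + [top]]
            + ([["C1"] + right_ids + [top]] if n_right else [])
        )

    model, seg = make_toy_model(n_features, atoms_per_feature, seed=seed)
    feature_ids = seg.feature_ids()
    index_of = _feature_atom_indices(model, seg)
    box = suggest_box(model, voxel_size)

    classes: dict[str, dict[str, FeatureState]] = {}
    expected: dict[str, dict[str, float | None]] = {}
    present: dict[str, list[str]] = {}
    maps: dict[str, DensityGrid] = {}
    rng = np.random.default_rng([seed, 1])
    for c_i, cid in enumerate(class_ids):
        chosen = feature_lists[cid]
        states: dict[str, FeatureState] = {}
        for f_i, fid in enumerate(feature_ids):
            if f_i not in chosen:
                states[fid] = FeatureState("absent")
            elif chosen and f_i == chosen[-1] and len(chosen) > min(
                len(v) for v in feature_lists.values()
            ):
                states[fid] = FeatureState("partial", alpha=partial_alpha)
            else:
                states[fid] = FeatureState("full")
        classes[cid] = states
        expected[cid] = {
            fid: states[fid].expected_occupancy(len(index_of[fid])) for fid in feature_ids
        }
        present[cid] = [feature_ids[i] for i in chosen]
        maps[cid] = simulate_class_map(
            model,
            seg,
            states,
            voxel_size=voxel_size,
            box=box,
            peak_density=peak_density,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    manifest = TruthManifest(
        seed=seed,
        classes=classes,
        noise_sigma=noise_sigma,
        peak_density=peak_density,
        voxel_size=voxel_size,
        box=box,
        feature_ids=feature_ids,
        expected_occupancy=expected,
        present_sets={cid: sorted(v) for cid, v in present.items()},
        groups=groups,
        hasse_edges=hasse,
        maximal_chains=chains,
        map_peaks={cid: float(m.data.max()) for cid, m in maps.items()},
    )
    return SyntheticSeries(model, seg, maps, manifest)
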