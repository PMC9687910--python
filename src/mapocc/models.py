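"""Atomic-model reading, heavy-atom selection, and feature segmentation.

A *feature* is a named structural element of the large ribosomal
subunit: an r-protein chain, a 23S rRNA helix, or an rRNA domain.
Helices and domains are addressed as inclusive residue-number intervals
on their chain (multi-strand helices are encoded as multiple intervals
of one feature); r-proteins are addressed as whole chains.

Model files are parsed with gemmi, which handles both PDB and mmCIF.
Waters are dropped and, for alternate locations, the highest-occupancy
conformer is kept (ties resolved to the first in file).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import gemmi

from .errors import ModelFormatError, ValidationError

__all__ = [
    "AtomicModel",
    "FeatureSegmentation",
    "Feature",
    "AtomSelection",
    "read_model",
    "select_heavy_atoms",
    "parse_segmentation",
    "resolve_features",
]

logger = logging.getLogger(__name__)

_HYDROGEN = {"H", "D"}
FEATURE_KINDS = ("rprotein", "rrna_helix", "rrna_domain")


@dataclass
class AtomicModel:
    """Flat table of atoms with chain/residue addressing.

    Parallel arrays keep lookup vectorizable; ``positions`` is (N, 3)
    in Å.
    """

    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    insertion_codes: np.ndarray
    residue_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    positions: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, indices) -> "AtomicModel":
        idx = np.asarray(indices, dtype=int)
        return AtomicModel(
            self.chain_ids[idx],
            self.residue_numbers[idx],
            self.insertion_codes[idx],
            self.residue_names[idx],
            self.atom_names[idx],
            self.elements[idx],
            self.positions[idx],
        )


@dataclass
class Feature:
    feature_id: str
    kind: str
    chain_id: str
    ranges: list[tuple[int, int]]

    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.ranges)


@dataclass
class FeatureSegmentation:
    """Ordered list of features; row order is canonical downstream."""

    features: list[Feature]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValidationError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)
            if f.kind not in FEATURE_KINDS:
                raise ValidationError(
                    f"feature {f.feature_id!r}: unknown kind {f.kind!r} (expected {FEATURE_KINDS})"
                )
            for a, b in f.ranges:
                if a > b:
                    raise ValidationError(
                        f"feature {f.feature_id!r}: inverted range {a}-{b}"
                    )
            spans = sorted(f.ranges)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise ValidationError(
                        f"feature {f.feature_id!r}: overlapping ranges {a1}-{b1} and {a2}-{b2}"
                    )

    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def to_tsv(self, path) -> None:
        rows = [
            {
                "feature_id": f.feature_id,
                "kind": f.kind,
                "chain": f.chain_id,
                "ranges": ",".join(f"{a}-{b}" for a, b in f.ranges),
            }
            for f in self.features
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class AtomSelection:
    """Indices of one feature's heavy atoms within an :class:`AtomicModel`."""

    feature_id: str
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)

    def __len__(self) -> int:
        return len(self.atom_indices)


def read_model(path) -> AtomicModel:
    """Parse a PDB or mmCIF model into a flat atom table.

    All ATOM/HETATM records are kept except waters.  Alternate
    locations collapse to the highest-occupancy conformer; on a tie the
    conformer that appears first in the file wins.
    """
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    structure.setup_entities()
    structure.remove_waters()
    chains, resnums, icodes, resnames, atomnames, elements, coords = (
        [], [], [], [], [], [], [],
    )
    if len(structure) == 0:
        raise ModelFormatError(f"{path}: no models in file")
    model = structure[0]
    for chain in model:
        for residue in chain:
            # collapse altlocs: per atom name keep the best-occupancy copy
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif (atom.occ or 0.0) > (prev.occ or 0.0):
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                chains.append(chain.name)
                resnums.append(residue.seqid.num)
                icodes.append(residue.seqid.icode.strip())
                resnames.append(residue.name)
                atomnames.append(name)
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ModelFormatError(f"{path}: no atoms parsed")
    return AtomicModel(
        np.array(chains),
        np.array(resnums, dtype=int),
        np.array(icodes),
        np.array(resnames),
        np.array(atomnames),
        np.array(elements),
        np.array(coords, dtype=float),
    )


def select_heavy_atoms(model: AtomicModel, feature_id: str = "all") -> AtomSelection:
    """All atoms whose element is not hydrogen or deuterium, in file order."""
    heavy = ~np.isin(np.char.upper(model.elements.astype(str)), list(_HYDROGEN))
    return AtomSelection(feature_id, np.flatnonzero(heavy))


def _parse_ranges(text: str, row: str) -> list[tuple[int, int]]:
    ranges = []
    for part in str(text).split(","):
        part = part.strip()
        if not part:
            continue
        try:
            a, b = part.split("-")
            ranges.append((int(a), int(b)))
        except ValueError as exc:
            raise ValidationError(f"row {row!r}: malformed range {part!r}") from exc
    if not ranges:
        raise ValidationError(f"row {row!r}: empty ranges field")
    return ranges


def parse_segmentation(path) -> FeatureSegmentation:
    """Read a feature-segmentation TSV.

    Columns: ``feature_id``, ``kind`` (rprotein | rrna_helix |
    rrna_domain), ``chain``, ``ranges`` ("start-end[,start-end...]",
    1-based inclusive).  '#'-prefixed lines are comments.
    """
    try:
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    required = {"feature_id", "kind", "chain", "ranges"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    features = []
    for _, row in table.iterrows():
        fid = str(row["feature_id"])
        features.append(
            Feature(fid, str(row["kind"]), str(row["chain"]), _parse_ranges(row["ranges"], fid))
        )
    return FeatureSegmentation(features)


def write_model_pdb(model: AtomicModel, path) -> None:
    """Write the atom table as a single-model PDB file (via gemmi)."""
    structure = gemmi.Structure()
    structure.name = "mapocc"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int, str], gemmi.Residue] = {}
    for i in range(len(model)):
        cid = str(model.chain_ids[i])
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        key = (cid, int(model.residue_numbers[i]), str(model.insertion_codes[i]))
        if key not in residues:
            res = gemmi.Residue()
            res.name = str(model.residue_names[i])
            res.seqid = gemmi.SeqId(int(model.residue_numbers[i]), str(model.insertion_codes[i]) or " ")
            chains[cid].add_residue(res)
            residues[key] = chains[cid][-1]
        atom = gemmi.Atom()
        atom.name = str(model.atom_names[i])
        atom.element = gemmi.Element(str(model.elements[i]))
        atom.pos = gemmi.Position(*model.positions[i])
        atom.occ = 1.0
        residues[key].add_atom(atom)
    for chain in chains.values():
        md.add_chain(chain)
    structure.add_model(md)
    structure.setup_entities()
    structure.write_pdb(str(path))


def resolve_features(model: AtomicModel, seg: FeatureSegmentation) -> list[AtomSelection]:
    """Map each feature to its heavy-atom indices in the model.

    R-protein features take the whole chain's heavy atoms regardless of
    their ranges; helix and domain features take heavy atoms of the
    residues inside any listed interval.  A chain absent from the model
    gives an empty selection with a warning, not an error — salt-washed
    particles legitimately lack chains.
    """
    heavy = ~np.isin(np.char.upper(model.elements.astype(str)), list(_HYDROGEN))
    selections = []
    for f in seg.features:
        on_chain = model.chain_ids == f.chain_id
        if not on_chain.any():
            logger.warning(
                "feature %s: chain %s not present in model; empty selection",
                f.feature_id,
                f.chain_id,
            )
            selections.append(AtomSelection(f.feature_id, np.empty(0, dtype=int)))
            continue
        if f.kind == "rprotein":
            mask = on_chain & heavy
        else:
            in_range = np.zeros(len(model), dtype=bool)
            for a, b in f.ranges:
                in_range |= (model.residue_numbers >= a) & (model.residue_numbers <= b)
            mask = on_chain & in_range & heavy
        if not mask.any():
            logger.warning("feature %s matched zero atoms", f.feature_id)
        selections.append(AtomSelection(f.feature_id, np.flatnonzero(mask)))
    return selections
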