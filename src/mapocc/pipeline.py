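"""End-to-end orchestration: profile a set of class maps against a model.

``run_profile`` is the whole analysis in one call: read the class
table, model, and segmentation; low-pass filter and score every class;
optionally splice in manual category calls; normalize; cluster classes
and features; cut the class tree into groups; derive the inclusion
order and candidate disassembly paths; and write a deterministic
artifact bundle (identical inputs and config give byte-identical
outputs).

``run_simulate`` writes a synthetic dataset in exactly the layout
``run_profile`` consumes, so the two compose into a self-contained
round trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import complete_linkage, cut_tree, euclidean_distances, to_newick
from .density import read_map, write_map
from .disassembly import (
    DEFAULT_PRESENCE_THRESHOLD,
    inclusion_order,
    maximal_paths,
    ordered_feature_set,
)
from .errors import ParameterError, ValidationError
from .models import parse_segmentation, read_model, write_model_pdb
from .occupancy import (
    CATEGORY_ENCODING,
    DEFAULT_LOWPASS,
    DEFAULT_THRESHOLD,
    apply_manual_categories,
    normalize_matrix,
    occupancy_matrix,
)
from .synthetic import make_disassembly_series

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_profile", "run_simulate"]


@dataclass
class RunConfig:
    """Effective parameters of one profiling run.

    Every value is echoed verbatim into ``report.json`` so a run is
    auditable from its outputs alone.
    """

    class_table: str
    model_path: str
    segmentation_path: str
    out_dir: str
    manual_path: str | None = None
    threshold: float = DEFAULT_THRESHOLD
    lowpass: float = DEFAULT_LOWPASS
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    slack: int = 0
    n_groups: int = 3
    median_mode: str = "global"
    cluster_raw: bool = False
    permissive: bool = False
    seed: int = 0


def _read_class_table(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"class_id", "map_path"} <= set(table.columns):
        raise ValidationError(f"{path}: class table needs columns class_id, map_path")
    if table["class_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate class_id rows")
    return dict(zip(table["class_id"], table["map_path"]))


def run_profile(config: RunConfig) -> dict:
    """Run the full occupancy-profiling pipeline; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = Path(config.class_table).parent

    class_paths = _read_class_table(config.class_table)
    if not class_paths:
        raise ValidationError("class table lists no classes")
    model = read_model(config.model_path)
    seg = parse_segmentation(config.segmentation_path)
    maps = {}
    for cid, rel in class_paths.items():
        p = Path(rel)
        maps[cid] = read_map(p if p.is_absolute() else base / p)

    raw = occupancy_matrix(
        maps,
        model,
        seg,
        threshold=config.threshold,
        lowpass=config.lowpass,
        model_id=str(config.model_path),
        permissive=config.permissive,
    )
    if config.manual_path:
        manual = pd.read_csv(config.manual_path, sep="\t", comment="#", dtype=str)
        raw = apply_manual_categories(raw, manual)
    norm = normalize_matrix(raw, median_mode=config.median_mode)
    raw.to_tsv(out / "occupancy_raw.tsv")
    norm.to_tsv(out / "occupancy_norm.tsv")

    cluster_input = raw if config.cluster_raw else norm
    class_tree = complete_linkage(
        euclidean_distances(cluster_input, "columns"), cluster_input.class_ids
    )
    feature_tree = complete_linkage(
        euclidean_distances(cluster_input, "rows"), cluster_input.feature_ids
    )
    (out / "classes.newick").write_text(to_newick(class_tree) + "\n")
    (out / "features.newick").write_text(to_newick(feature_tree) + "\n")

    k = min(config.n_groups, class_tree.n_leaves)
    groups = cut_tree(class_tree, k)
    pd.DataFrame(
        {"class_id": list(groups), "group": [groups[c] for c in groups]}
    ).to_csv(out / "groups.tsv", sep="\t", index=False)

    sets = {
        cid: ordered_feature_set(norm, cid, config.presence_threshold)
        for cid in norm.class_ids
    }
    if len(sets) >= 2:
        graph = inclusion_order(sets, slack=config.slack)
        paths = maximal_paths(graph)
        graph_dict = graph.to_dict()
    else:
        graph_dict = {"slack": config.slack, "nodes": {c: sorted(s) for c, s in sets.items()}, "edges": []}
        paths = [[c] for c in sets]
    with open(out / "disassembly.json", "w") as fh:
        json.dump({**graph_dict, "maximal_paths": paths}, fh, indent=2, sort_keys=True)
        fh.write("\n")

    report = {
        "version": __version__,
        "config": asdict(config),
        "defaults": {
            "threshold": DEFAULT_THRESHOLD,
            "lowpass_A": DEFAULT_LOWPASS,
            "presence_threshold": DEFAULT_PRESENCE_THRESHOLD,
            "category_encoding": {c.value: v for c, v in CATEGORY_ENCODING.items()},
        },
        "classes": norm.class_ids,
        "features": norm.feature_ids,
        "failed_classes": raw.provenance.get("failed_classes", []),
        "empty_features": raw.provenance.get("empty_features", []),
        "n_groups": k,
        "n_maximal_paths": len(paths),
        "provenance": {k2: v for k2, v in norm.provenance.items() if k2 != "class_maps"},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_simulate(
    out_dir,
    n_classes: int = 6,
    branching: bool = False,
    seed: int = 0,
    **series_kwargs,
) -> Path:
    """Write a synthetic dataset in the layout ``run_profile`` consumes.

    Layout: ``maps/<class>.mrc``, ``model.pdb``, ``segmentation.tsv``,
    ``classes.tsv`` (class table), ``manifest.json`` (ground truth).
    """
    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    series = make_disassembly_series(
        n_classes=n_classes, branching=branching, seed=seed, **series_kwargs
    )
    rows = []
    for cid, grid in series.maps.items():
        rel = f"maps/{cid}.mrc"
        write_map(grid, out / rel)
        rows.append({"class_id": cid, "map_path": rel})
    pd.DataFrame(rows).to_csv(out / "classes.tsv", sep="\t", index=False)
    write_model_pdb(series.model, out / "model.pdb")
    series.segmentation.to_tsv(out / "segmentation.tsv")
    series.manifest.to_json(out / "manifest.json")
    return out
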