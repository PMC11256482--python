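"""Atlas registration and structure naming for significant clusters.

A label atlas (integer NIfTI plus a CSV naming table) is brought into
template space by rigidly registering its companion intensity reference to
the study template; labels follow with nearest-neighbour resampling. Cluster
voxels are then tallied against the labels to rank the structures underlying
each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .imageio import Volume
from .register import AffineTransform, register_affine, resample_affine
from .stats_voxel import ClusterSet


@dataclass
class StructureOverlap:
    name: str
    label_id: int
    n_voxels: int
    fraction: float


@dataclass
class AtlasOverlapTable:
    """Per-cluster overlap histogram over atlas structures."""

    rows: list[dict] = dc_field(default_factory=list)

    def majority(self, cluster_index: int) -> StructureOverlap | None:
        overlaps = [r for r in self.rows if r["cluster"] == cluster_index]
        if not overlaps:
            return None
        best = max(overlaps, key=lambda r: r["fraction"])
        return StructureOverlap(best["structure"], best["label_id"], best["n_voxels"], best["fraction"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def load_naming_table(path: str | Path) -> dict[int, str]:
    """CSV with columns label_id, name (area_group optional) -> {id: name}."""
    df = pd.read_csv(path)
    if "label_id" not in df.columns or "name" not in df.columns:
        raise ValueError("naming table needs columns label_id and name")
    return {int(r.label_id): str(r.name) for r in df.itertuples()}


def register_atlas(
    atlas_labels: Volume,
    atlas_ref: Volume,
    template: Volume,
    kind: str = "rigid",
    levels: tuple[int, ...] = (4, 2, 1),
) -> tuple[Volume, AffineTransform]:
    """Rigidly map the atlas into template space (labels via nearest neighbour)."""
    transform = register_affine(atlas_ref, template, kind=kind, levels=levels)
    # pull-back of the labels into the template grid: labels(T(x))
    warped = resample_affine(atlas_labels, template, transform, order=0)
    warped.units = "label"
    warped.data = np.rint(np.asarray(warped.data)).astype(np.int32)
    return warped, transform


def clusters_to_structures(
    clusters: ClusterSet,
    labels: Volume,
    naming: dict[int, str],
) -> AtlasOverlapTable:
    """Overlap tally of each cluster against the atlas labels.

    Fractions are relative to the cluster size; unlabeled (background)
    voxels make the fractions sum to < 1. Labels missing from the naming
    table are reported as ``unnamed:<id>``.
    """
    lab = np.asarray(labels.data).astype(int)
    table = AtlasOverlapTable()
    for ci, cluster in enumerate(clusters.clusters):
        vox = cluster.voxels
        ids = lab[vox[:, 0], vox[:, 1], vox[:, 2]]
        counts = np.bincount(ids)
        order = np.argsort(counts)[::-1]
        for label_id in order:
            n = int(counts[label_id])
            if n == 0 or label_id == 0:
                continue
            name = naming.get(int(label_id), f"unnamed:{int(label_id)}")
            table.rows.append(
                {
                    "cluster": ci,
                    "sign": cluster.sign,
                    "structure": name,
                    "label_id": int(label_id),
                    "n_voxels": n,
                    "fraction": n / cluster.n_voxels,
                }
            )
    return table
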