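"""Single-subject z-score deviation maps and cluster-extent correction.

A subject's standardized deviation from the normative atlas at voxel r is

    z(r) = (R1(r) - E{R1}(r; age)) / RMSE(r)

inside the analysis mask (NaN outside). Because Mn deposition raises R1,
abnormality detection is one-sided positive by default: voxels with
z strictly above the threshold are kept, grouped into connected components
(26-neighbor by default; 6 and 18 selectable), and components smaller than
the minimum extent are discarded — the classic cluster-extent guard against
isolated false positives. Surviving clusters are labeled 1..k by decreasing
size, ties broken by smallest linear (C-order) voxel index, so reports are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, GridMismatchError
from .normative_atlas import NormativeAtlas, predict
from .volume_io import VolumeGrid, assert_shared_grid

__all__ = ["ZMap", "ClusterSet", "compute_zmap", "cluster_correct", "summarize_clusters"]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ZMap:
    """Standardized deviation map of one subject against an atlas."""

    z: VolumeGrid
    subject_id: str = ""
    age_used: int = 0
    atlas_id: str = ""


@dataclass
class ClusterSet:
    """Retained supra-threshold clusters: label volume + per-cluster sizes."""

    labels: VolumeGrid
    sizes: np.ndarray  # sizes[i] is the voxel count of cluster label i+1
    threshold: float
    min_extent: int
    connectivity: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def total_voxels(self) -> int:
        return int(self.sizes.sum())


def compute_zmap(
    subject_r1: VolumeGrid,
    age: int,
    atlas: NormativeAtlas,
    subject_id: str = "",
    atlas_id: str = "",
) -> ZMap:
    """z = (observed - expected) / RMSE inside the atlas mask, NaN outside."""
    try:
        assert_shared_grid([subject_r1, atlas.beta0])
    except GridMismatchError as exc:
        raise GridMismatchError(f"subject volume not on the atlas grid: {exc}") from exc
    expected = predict(atlas, age)
    mask = atlas.mask.mask.data
    rmse = atlas.rmse.data
    if np.any(mask & ~(rmse > 0)):
        raise RuntimeError("atlas invariant violated: non-positive RMSE inside mask")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (subject_r1.data - expected.data) / rmse
    z = np.where(mask, z, np.nan)
    return ZMap(z=subject_r1.like(z), subject_id=subject_id, age_used=int(age), atlas_id=atlas_id)


def cluster_correct(
    zmap: ZMap | VolumeGrid,
    threshold: float = 6.0,
    min_extent: int = 100,
    connectivity: int = 26,
    two_sided: bool = False,
) -> ClusterSet:
    """Threshold, label connected components, drop those below ``min_extent``.

    ``min_extent`` semantics: a cluster is retained iff its size >= min_extent.
    NaN voxels (outside the mask) never exceed the threshold. Components
    touching the volume border are ordinary clusters.
    """
    if not np.isfinite(threshold):
        raise ConfigurationError("threshold must be finite")
    if min_extent < 1:
        raise ConfigurationError("min_extent must be >= 1")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ConfigurationError("connectivity must be 6, 18 or 26")
    vol = zmap.z if isinstance(zmap, ZMap) else zmap
    with np.errstate(invalid="ignore"):
        field = np.abs(vol.data) if two_sided else vol.data
        binary = field > threshold  # strict; NaN compares False
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw_labels, n_raw = ndimage.label(binary, structure=structure)

    out = np.zeros(vol.shape, dtype=np.int32)
    kept: list[tuple[int, int, int]] = []  # (size, first_flat_index, raw_label)
    if n_raw:
        sizes = np.bincount(raw_labels.ravel())[1:]
        flat = raw_labels.ravel()
        # first C-order occurrence per raw label = smallest linear voxel index
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        first_pos = np.searchsorted(sorted_labels, np.arange(1, n_raw + 1))
        first_index = order[first_pos]
        for raw in range(1, n_raw + 1):
            if sizes[raw - 1] >= min_extent:
                kept.append((int(sizes[raw - 1]), int(first_index[raw - 1]), raw))
        kept.sort(key=lambda t: (-t[0], t[1]))
        for new_label, (_, _, raw) in enumerate(kept, start=1):
            out[raw_labels == raw] = new_label
    return ClusterSet(
        labels=vol.like(out),
        sizes=np.array([s for s, _, _ in kept], dtype=np.int64),
        threshold=threshold,
        min_extent=min_extent,
        connectivity=connectivity,
    )


def summarize_clusters(clusters: ClusterSet, zmap: ZMap | VolumeGrid) -> pd.DataFrame:
    """Per-cluster report: size, peak z, peak voxel, centroid (voxel coords)."""
    vol = zmap.z if isinstance(zmap, ZMap) else zmap
    rows = []
    lab = clusters.labels.data
    for label in range(1, clusters.n_clusters + 1):
        inside = lab == label
        zvals = vol.data[inside]
        coords = np.argwhere(inside)
        peak_local = int(np.nanargmax(zvals))
        peak = coords[peak_local]
        rows.append(
            {
                "cluster": label,
                "size": int(inside.sum()),
                "peak_z": float(zvals[peak_local]),
                "peak_i": int(peak[0]),
                "peak_j": int(peak[1]),
                "peak_k": int(peak[2]),
                "centroid_i": float(coords[:, 0].mean()),
                "centroid_j": float(coords[:, 1].mean()),
                "centroid_k": float(coords[:, 2].mean()),
            }
        )
    columns = [
        "cluster",
        "size",
        "peak_z",
        "peak_i",
        "peak_j",
        "peak_k",
        "centroid_i",
        "centroid_j",
        "centroid_k",
    ]
    return pd.DataFrame(rows, columns=columns)
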