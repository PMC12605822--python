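"""Image-domain utilities: depth-limited SWM extraction and resection overlap.

Superficial white matter (SWM) is defined as WM voxels within a fixed
Euclidean distance (default 5 mm, anisotropy-aware) of the gray-white
boundary; each such voxel is assigned to the parcellation label of its
nearest GM voxel.  Resection overlap is exact voxel counting of a binary
mask against a label volume; a region counts as resected when strictly
more than 10% of its voxels fall inside the mask.

Synthetic label volumes and resection masks with controllable coverage
are provided as fixtures for the tabular pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ParcellationVolume",
    "generate_parcellation_volume",
    "generate_resection_mask",
    "extract_swm_values",
    "region_overlap",
    "resected_region_set",
]


@dataclass
class ParcellationVolume:
    """Integer label volume (0 = background) with voxel spacing in mm and
    optional GM/WM masks on the same grid."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gm_mask: np.ndarray | None = None
    wm_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        for m in (self.gm_mask, self.wm_mask):
            if m is not None and m.shape != self.labels.shape:
                raise ValueError("mask shape does not match the label volume")

    @property
    def region_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs != 0]


def generate_parcellation_volume(n_regions: int, grid_shape=(32, 32, 32),
                                 voxel_size_mm=(1.0, 1.0, 1.0), seed: int = 0
                                 ) -> ParcellationVolume:
    """Pack n_regions GM blocks (each wrapped by a WM shell) into a grid.

    Blocks are axis-aligned and deterministic given the seed (the seed
    perturbs block sizes only).  Every label occupies at least 8 voxels,
    and each GM block abuts WM so a gray-white boundary exists.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(grid_shape)
    labels = np.zeros(shape, dtype=np.int32)
    gm = np.zeros(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool)

    # cells of (block + 1-voxel WM shell + 1 gap), laid on a 3D lattice
    block = max(2, int(rng.integers(2, 4)))
    cell = block + 3
    per_axis = [max(1, s // cell) for s in shape]
    capacity = per_axis[0] * per_axis[1] * per_axis[2]
    if capacity < n_regions:
        raise ValueError(
            f"grid {shape} cannot host {n_regions} regions "
            f"(capacity {capacity} at block size {block})")

    lab = 0
    for ix in range(per_axis[0]):
        for iy in range(per_axis[1]):
            for iz in range(per_axis[2]):
                if lab >= n_regions:
                    break
                lab += 1
                o = (ix * cell + 1, iy * cell + 1, iz * cell + 1)
                sl = tuple(slice(o[d], o[d] + block) for d in range(3))
                labels[sl] = lab
                gm[sl] = True
                shell = tuple(slice(max(0, o[d] - 1),
                                    min(shape[d], o[d] + block + 1))
                              for d in range(3))
                wm[shell] = True
    wm &= ~gm
    return ParcellationVolume(labels, tuple(float(v) for v in voxel_size_mm), gm, wm)


def generate_resection_mask(parc: ParcellationVolume, coverage: dict[int, float],
                            seed: int = 0) -> np.ndarray:
    """Binary mask covering the requested fraction of each target region.

    Voxels of each target are taken in a deterministic raster order after
    a seeded shuffle; the realized fraction is exact to within one voxel.
    Non-target regions are untouched.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros(parc.labels.shape, dtype=np.uint8)
    present = set(int(x) for x in parc.region_labels)
    for lab, frac in sorted(coverage.items()):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("coverage fractions must lie in [0, 1]")
        if int(lab) not in present:
            raise ValueError(f"region {lab} absent from the parcellation")
        vox = np.argwhere(parc.labels == int(lab))
        k = int(round(frac * len(vox)))
        order = rng.permutation(len(vox))
        chosen = vox[order[:k]]
        mask[tuple(chosen.T)] = 1
    return mask


def extract_swm_values(md_volume: np.ndarray, parc: ParcellationVolume,
                       depth_mm: float = 5.0) -> pd.Series:
    """Per-region mean MD over WM voxels within depth_mm of the GM boundary.

    Distances are Euclidean with physical voxel spacing.  Each selected WM
    voxel is assigned to the label of its nearest GM voxel; equidistant
    voxels go to the lower label ID.  Regions with no assigned voxels are
    returned as NaN.
    """
    if depth_mm <= 0:
        raise ValueError("depth_mm must be > 0")
    if parc.gm_mask is None or parc.wm_mask is None:
        raise ValueError("parcellation must carry GM and WM masks")
    md = np.asarray(md_volume, dtype=float)
    if md.shape != parc.labels.shape:
        raise ValueError("MD volume shape does not match the parcellation")

    labels = parc.region_labels
    best_dist = np.full(md.shape, np.inf)
    best_lab = np.zeros(md.shape, dtype=parc.labels.dtype)
    # iterate labels in ascending order; strict '<' keeps the lower label
    # on exact distance ties
    for lab in labels:
        src = (parc.labels == lab) & parc.gm_mask
        if not src.any():
            continue
        dist = ndimage.distance_transform_edt(~src, sampling=parc.spacing)
        closer = dist < best_dist
        best_dist[closer] = dist[closer]
        best_lab[closer] = lab

    selected = parc.wm_mask & (best_dist <= depth_mm) & (best_lab > 0)
    out = {}
    for lab in labels:
        sel = selected & (best_lab == lab)
        out[int(lab)] = float(md[sel].mean()) if sel.any() else np.nan
    return pd.Series(out, name="swm_md")


def region_overlap(parc: ParcellationVolume, mask: np.ndarray) -> pd.DataFrame:
    """Exact per-region voxel counts against a binary resection mask."""
    mask = np.asarray(mask)
    if mask.shape != parc.labels.shape:
        raise ValueError("mask shape does not match the parcellation")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("resection mask must be binary")
    labs = parc.region_labels
    total = ndimage.sum_labels(np.ones_like(mask, dtype=np.int64),
                               parc.labels, labs).astype(int)
    resected = ndimage.sum_labels(mask.astype(np.int64), parc.labels,
                                  labs).astype(int)
    return pd.DataFrame({
        "voxels": total,
        "resected_voxels": resected,
        "fraction": resected / total,
    }, index=pd.Index(labs.astype(int), name="region"))


def resected_region_set(overlap: pd.DataFrame, threshold: float = 0.10) -> set:
    """Regions whose resected fraction strictly exceeds the threshold."""
    return set(overlap.index[overlap["fraction"] > threshold])
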