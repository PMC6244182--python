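"""Tissue segmentation of the masked breast.

Stage two of the modelling pipeline: the breast region is partitioned into
a geometric skin shell, a single fat cluster, and one or more
fibroglandular (FGT) clusters.  Fat/FGT separation and FGT sub-clustering
are 1-D k-means on voxel intensity — under the fat-suppressed contrast the
fibroglandular class is the brighter one.  Sub-clustering into K clusters
adds reconfigurable model complexity without changing the anatomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .masking import BreastMask
from .mri_io import MRIVolume

__all__ = [
    "BACKGROUND",
    "SKIN",
    "FAT",
    "FGT_FIRST",
    "TissueLabelMap",
    "ClusterStats",
    "extract_skin_layer",
    "segment_tissues",
    "subcluster_fgt",
    "cluster_statistics",
]

BACKGROUND = 0
SKIN = 1
FAT = 2
#: first fibroglandular label; fgt_k occupies FGT_FIRST + k - 1
FGT_FIRST = 3


@dataclass
class TissueLabelMap:
    """Integer voxel labels plus a legend mapping label -> tissue role.

    Roles are ``background``, ``skin``, ``fat``, ``fgt_1`` ... ``fgt_K``
    (contiguous labels, legend ordered by increasing cluster mean
    intensity) and optionally ``tumour``.
    """

    labels: np.ndarray
    legend: dict[int, str]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)  # type: ignore[assignment]
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} absent from legend")

    @property
    def fgt_labels(self) -> list[int]:
        """Fibroglandular labels in legend order (ascending mean intensity)."""
        return sorted(l for l, role in self.legend.items() if role.startswith("fgt_"))

    @property
    def tumour_label(self) -> int | None:
        for l, role in self.legend.items():
            if role == "tumour":
                return l
        return None

    def copy(self) -> "TissueLabelMap":
        return TissueLabelMap(self.labels.copy(), dict(self.legend), self.spacing_mm)


@dataclass
class ClusterStats:
    """Per-label voxel count and mean intensity.

    ``mean_intensity`` is NaN for legend labels absent from the grid.
    """

    voxel_count: dict[int, int]
    mean_intensity: dict[int, float]


def extract_skin_layer(
    mask: BreastMask, thickness_mm: float = 1.5
) -> np.ndarray:
    """Mask voxels within ``thickness_mm`` of the exterior surface.

    Distance is Euclidean and spacing-aware, measured to the nearest
    non-mask voxel centre.  The grid boundary itself is not exterior: a
    breast resting on the chest-wall face grows no skin there.
    """
    if thickness_mm <= 0:
        raise ValueError("thickness_mm must be positive")
    m = mask.mask
    if not m.any():
        raise ValueError("mask is empty")
    if thickness_mm < min(mask.spacing_mm):
        warnings.warn(
            "skin thickness below the voxel spacing; the shell may be "
            "empty on some faces",
            stacklevel=2,
        )
    if m.all():
        # no exterior anywhere: the whole region is deeper than any shell
        return np.zeros_like(m, dtype=bool)
    dist = ndimage.distance_transform_edt(m, sampling=mask.spacing_mm)
    return m & (dist <= thickness_mm)


def _weighted_kmeans_1d(
    values: np.ndarray, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """K-means on scalar intensities; returns (assignments, sorted centres).

    Clustering runs on the unique values weighted by multiplicity, which is
    exact for 1-D k-means and independent of the number of voxels.
    Centres come back ascending and assignments use them.
    """
    uniq, counts = np.unique(values, return_counts=True)
    if len(uniq) < k:
        raise ValueError(
            f"K too large: {k} clusters requested but only {len(uniq)} "
            "distinct intensities"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(uniq.reshape(-1, 1), sample_weight=counts)
    centres = np.sort(km.cluster_centers_.ravel())
    # nearest-centre assignment; ties go to the lower-mean cluster
    assign = np.argmin(np.abs(values[:, None] - centres[None, :]), axis=1)
    return assign, centres


def segment_tissues(
    volume: MRIVolume,
    mask: BreastMask,
    skin_thickness_mm: float = 1.5,
    seed: int = 0,
) -> TissueLabelMap:
    """Partition the masked breast into skin, fat and fibroglandular tissue.

    Skin is the geometric shell of :func:`extract_skin_layer`; the interior
    is split by 2-class intensity k-means with the brighter class labelled
    fibroglandular.  A degenerate single-intensity interior is assigned
    entirely to fat with a warning.
    """
    if volume.shape != mask.mask.shape:
        raise ValueError("volume and mask grids are not congruent")
    skin = extract_skin_layer(mask, skin_thickness_mm)
    interior = mask.mask & ~skin
    if not interior.any():
        raise ValueError("no interior: nothing remains after skin removal")

    labels = np.zeros(volume.shape, dtype=np.int32)
    labels[skin] = SKIN
    vals = volume.intensities[interior]
    legend = {BACKGROUND: "background", SKIN: "skin", FAT: "fat"}
    if np.ptp(vals) == 0:
        warnings.warn(
            "interior intensities are degenerate (single value); "
            "assigning all interior tissue to fat",
            stacklevel=2,
        )
        labels[interior] = FAT
        return TissueLabelMap(labels, legend, volume.spacing_mm)

    assign, _ = _weighted_kmeans_1d(vals, 2, seed)
    interior_labels = np.where(assign == 0, FAT, FGT_FIRST)
    labels[interior] = interior_labels
    legend[FGT_FIRST] = "fgt_1"
    return TissueLabelMap(labels, legend, volume.spacing_mm)


def subcluster_fgt(
    volume: MRIVolume, labelmap: TissueLabelMap, K: int, seed: int = 0
) -> TissueLabelMap:
    """Split the fibroglandular class into K intensity clusters.

    Labels are renumbered contiguously from the first fibroglandular label
    in increasing order of cluster mean intensity.  ``K=1`` returns a copy
    with the class untouched.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    fgt = labelmap.fgt_labels
    if not fgt:
        raise ValueError("labelmap contains no fibroglandular class")
    out = labelmap.copy()
    fgt_mask = np.isin(out.labels, fgt)
    for l in fgt:
        del out.legend[l]
    if K == 1:
        out.labels[fgt_mask] = FGT_FIRST
        out.legend[FGT_FIRST] = "fgt_1"
        return out
    vals = volume.intensities[fgt_mask]
    assign, _ = _weighted_kmeans_1d(vals, K, seed)
    out.labels[fgt_mask] = FGT_FIRST + assign
    for k in range(K):
        out.legend[FGT_FIRST + k] = f"fgt_{k + 1}"
    return out


def cluster_statistics(
    volume: MRIVolume, labelmap: TissueLabelMap
) -> ClusterStats:
    """Voxel count and mean scan intensity per legend label."""
    if volume.shape != labelmap.labels.shape:
        raise ValueError("volume and labelmap grids are not congruent")
    lab = labelmap.labels.ravel()
    vals = volume.intensities.ravel()
    nmax = max(labelmap.legend) + 1
    counts = np.bincount(lab, minlength=nmax)
    sums = np.bincount(lab, weights=vals, minlength=nmax)
    voxel_count = {l: int(counts[l]) for l in labelmap.legend}
    mean_intensity = {
        l: (float(sums[l] / counts[l]) if counts[l] > 0 else float("nan"))
        for l in labelmap.legend
    }
    return ClusterStats(voxel_count=voxel_count, mean_intensity=mean_intensity)
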