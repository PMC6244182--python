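"""Breast-region masking by orthogonal surface scanning.

Stage one of the modelling pipeline.  A background intensity threshold is
estimated from the corner margins of the grid; the scan is then traversed
along each of the three orthogonal axes, marking everything between the
first and last above-threshold run on each ray; the breast mask is the
voxelwise intersection of the three directional masks, cleaned up to its
largest connected component(s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mri_io import MRIVolume

__all__ = [
    "BreastMask",
    "estimate_background_threshold",
    "detect_surface_along_axis",
    "build_breast_mask",
]

_AXES = {"row": 0, "column": 1, "slice": 2}


@dataclass
class BreastMask:
    """Binary breast-region mask congruent with its source volume."""

    mask: np.ndarray
    threshold_used: float
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if self.threshold_used < 0:
            raise ValueError("threshold must be non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)  # type: ignore[assignment]


def _margin_voxels(intensities: np.ndarray, margin_fraction: float) -> np.ndarray:
    """Intensities of the eight corner-margin blocks of the grid."""
    widths = [max(1, int(round(margin_fraction * n))) for n in intensities.shape]
    sel = np.zeros(intensities.shape, dtype=bool)
    for ax, w in enumerate(widths):
        edge = np.zeros(intensities.shape[ax], dtype=bool)
        edge[:w] = True
        edge[-w:] = True
        shape = [1, 1, 1]
        shape[ax] = -1
        if ax == 0:
            sel = edge.reshape(shape) & np.ones_like(sel)
        else:
            sel &= edge.reshape(shape)
    return intensities[sel]


def estimate_background_threshold(
    volume: MRIVolume,
    k: float = 3.0,
    margin_fraction: float = 0.05,
    warn_fraction: float = 0.2,
) -> float:
    """Background threshold: mean + k*sd of the corner-margin intensities.

    The corner margins (width ``margin_fraction`` of each dimension) are
    assumed to contain air/background only.  When the object reaches into
    the corners the estimate is biased high; as a heuristic flag, a warning
    is emitted when more than ``warn_fraction`` of all voxels fall below
    ``threshold + sd`` — on a field of view that is mostly air this fires
    routinely and is informational only.
    """
    margins = _margin_voxels(volume.intensities, margin_fraction)
    if margins.size == 0:
        raise ValueError("cannot estimate background: margin region is empty")
    mean = float(margins.mean())
    sd = float(margins.std())
    if mean == 0.0 and sd == 0.0:
        warnings.warn("margins are identically zero; threshold 0", stacklevel=2)
        return 0.0
    threshold = mean + k * sd
    below = float(np.mean(volume.intensities < threshold + sd))
    if below > warn_fraction:
        warnings.warn(
            f"{100 * below:.1f}% of voxels fall below threshold+sd "
            f"({threshold + sd:.3g}); the corner margins may not be pure "
            "background",
            stacklevel=2,
        )
    return threshold


def detect_surface_along_axis(
    volume: MRIVolume | np.ndarray,
    axis: str | int,
    threshold: float,
    min_run: int = 3,
) -> np.ndarray:
    """Per-ray interior fill along one axis.

    Each 1-D ray along ``axis`` is scanned for runs of at least ``min_run``
    consecutive above-threshold voxels; everything from the start of the
    first such run to the end of the last is marked breast (interior holes
    along the ray are filled).  Rays without a qualifying run stay
    background.
    """
    data = volume.intensities if isinstance(volume, MRIVolume) else np.asarray(volume)
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    if ax not in (0, 1, 2):
        raise ValueError("axis must be 'row', 'column' or 'slice'")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    above = np.moveaxis(data > threshold, ax, -1)
    n = above.shape[-1]
    if n < min_run:
        return np.zeros(data.shape, dtype=bool)

    # window[i] == True iff voxels i .. i+min_run-1 are all above threshold
    cs = np.cumsum(above, axis=-1, dtype=np.int32)
    pad = np.zeros(above.shape[:-1] + (1,), dtype=np.int32)
    cs = np.concatenate([pad, cs], axis=-1)
    window = (cs[..., min_run:] - cs[..., :-min_run]) == min_run

    any_run = window.any(axis=-1)
    first = np.argmax(window, axis=-1)
    # the latest qualifying window start; its window necessarily ends at the
    # end of the last qualifying run
    last = window.shape[-1] - 1 - np.argmax(window[..., ::-1], axis=-1)
    idx = np.arange(n)
    filled = (
        any_run[..., None]
        & (idx >= first[..., None])
        & (idx <= (last + min_run - 1)[..., None])
    )
    return np.moveaxis(filled, -1, ax)


def build_breast_mask(
    volume: MRIVolume,
    threshold: float | None = None,
    min_run: int = 3,
    n_components: int = 1,
) -> BreastMask:
    """Intersect the three directional surface masks into a breast mask.

    The threshold defaults to :func:`estimate_background_threshold`.  After
    intersection only the ``n_components`` largest connected components are
    retained (1 for a single breast, 2 for bilateral scans).
    """
    if threshold is None:
        threshold = estimate_background_threshold(volume)
    combined = np.ones(volume.shape, dtype=bool)
    for ax in range(3):
        combined &= detect_surface_along_axis(volume, ax, threshold, min_run)
    if not combined.any():
        raise ValueError("no breast region found")
    labelled, n = ndimage.label(combined)
    if n > n_components:
        sizes = np.bincount(labelled.ravel())[1:]
        keep = np.argsort(sizes)[::-1][:n_components] + 1
        combined = np.isin(labelled, keep)
    return BreastMask(combined, float(max(threshold, 0.0)), volume.spacing_mm)
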