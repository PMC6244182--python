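"""Breast density and radiological density-class assignment.

Breast density is the percentage of the soft interior tissue (fat +
fibroglandular) occupied by fibroglandular voxels; the four radiological
classes cut that percentage at 25, 50 and 75.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import FAT, TissueLabelMap

__all__ = [
    "BREAST_CLASSES",
    "ClassificationResult",
    "compute_density",
    "classify_breast",
    "classify_labelmap",
]

BREAST_CLASSES = ("fatty", "scattered", "heterogeneously dense", "dense")


@dataclass(frozen=True)
class ClassificationResult:
    density_percent: float
    breast_class: str


def compute_density(
    labelmap: TissueLabelMap, include_skin_in_denominator: bool = False
) -> float:
    """Percent fibroglandular tissue of the breast interior.

    ``100 * n_fgt / (n_fat + n_fgt)``; skin, tumour and background are
    excluded from both numerator and denominator unless
    ``include_skin_in_denominator`` adds skin to the denominator.
    """
    labels = labelmap.labels
    n_fgt = int(np.isin(labels, labelmap.fgt_labels).sum())
    n_fat = int((labels == FAT).sum())
    denom = n_fat + n_fgt
    if include_skin_in_denominator:
        skin_label = next(
            (l for l, r in labelmap.legend.items() if r == "skin"), None
        )
        if skin_label is not None:
            denom += int((labels == skin_label).sum())
    if denom == 0:
        raise ValueError("no interior tissue: fat + fibroglandular count is zero")
    return 100.0 * n_fgt / denom


def classify_breast(density_percent: float) -> str:
    """Map a density percentage to its radiological class.

    fatty < 25 <= scattered < 50 <= heterogeneously dense < 75 <= dense;
    a boundary value belongs to the upper class.
    """
    if not 0 <= density_percent <= 100:
        raise ValueError("invalid density: must lie in [0, 100]")
    if density_percent < 25:
        return "fatty"
    if density_percent < 50:
        return "scattered"
    if density_percent < 75:
        return "heterogeneously dense"
    return "dense"


def classify_labelmap(labelmap: TissueLabelMap) -> ClassificationResult:
    """Density plus class for one label map."""
    density = compute_density(labelmap)
    return ClassificationResult(density, classify_breast(density))
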