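"""The assembled breast model: labels, per-cluster Debye properties, metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dielectrics import DebyeParameters
from .segmentation import BACKGROUND, TissueLabelMap

__all__ = ["BreastModel", "element_name", "CLASS_FOLDER_NAMES"]

#: breast class -> repository naming-convention token (BM_Class_ID)
CLASS_FOLDER_NAMES = {
    "fatty": "Fatty",
    "scattered": "Scattered",
    "heterogeneously dense": "Hetero",
    "dense": "Dense",
}


def element_name(role: str) -> str:
    """Container element name for a tissue role (e.g. fgt_1 -> FGT_Cluster_1)."""
    if role == "skin":
        return "Skin_Layer"
    if role == "fat":
        return "Fat_Cluster"
    if role == "tumour":
        return "Tumour"
    if role.startswith("fgt_"):
        return f"FGT_Cluster_{role[4:]}"
    raise ValueError(f"no element name for role {role!r}")


@dataclass
class BreastModel:
    """A complete numerical breast model.

    ``properties`` maps every non-background label to its single-pole Debye
    parameter set; ``attributes`` carries the descriptive metadata mirrored
    into the HDF5/XML containers (breast_health, breast_class,
    density_percent, model_name, n_fgt_clusters, property_level,
    voxel_size_mm).
    """

    labelmap: TissueLabelMap
    properties: dict[int, DebyeParameters]
    attributes: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(np.unique(self.labelmap.labels).tolist()) - {BACKGROUND}
        missing = present - set(self.properties)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no dielectric properties")
        n_fgt = len(self.labelmap.fgt_labels)
        stored = self.attributes.get("n_fgt_clusters")
        if stored is not None and int(stored) != n_fgt:
            raise ValueError(
                f"attribute n_fgt_clusters={stored} disagrees with the "
                f"label map ({n_fgt} fgt labels)"
            )
        self.attributes.setdefault("n_fgt_clusters", n_fgt)

    def element_names(self) -> dict[int, str]:
        """Label -> container element name for labels carrying properties."""
        return {
            l: element_name(role)
            for l, role in self.labelmap.legend.items()
            if role != "background" and l in self.properties
        }
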