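"""End-to-end model assembly.

Drives the default pipeline — PCA denoising, breast masking, tissue
segmentation, fibroglandular sub-clustering, dielectric property
assignment, density classification — and handles tumour embedding and the
human-readable model report.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .classification import classify_breast, compute_density
from .denoise import pca_denoise
from .dielectrics import (
    PROPERTY_LEVELS,
    DebyeParameters,
    PropertyLevel,
    ReferencePropertyTable,
    apply_property_level,
    debye_permittivity,
    effective_conductivity,
    assign_properties,
)
from .masking import build_breast_mask
from .model import BreastModel
from .mri_io import MRIVolume
from .segmentation import (
    BACKGROUND,
    SKIN,
    TissueLabelMap,
    cluster_statistics,
    segment_tissues,
    subcluster_fgt,
)
from .synthetic import TumourModel

__all__ = ["build_model", "embed_tumour", "generate_model_report"]

#: frequencies tabulated in the model report, GHz
_REPORT_FREQS_GHZ = (1.0, 3.0, 6.0, 10.0)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except ValueError as exc:
        raise ValueError(f"[{name}] {exc}") from exc


def build_model(
    volume: MRIVolume,
    K: int = 1,
    level: PropertyLevel | str = "high",
    table: ReferencePropertyTable | None = None,
    *,
    variance_fraction: float = 0.99,
    skin_thickness_mm: float = 1.5,
    mask_threshold: float | None = None,
    seed: int = 0,
    model_name: str | None = None,
) -> BreastModel:
    """Run the full MRI-to-model pipeline.

    Stages: PCA denoise -> breast mask -> skin/fat/fibroglandular
    segmentation -> sub-cluster the fibroglandular class into ``K``
    clusters -> per-cluster statistics -> Debye property assignment at the
    chosen contrast level -> density and class attributes.  Errors carry a
    stage tag.
    """
    if table is None:
        table = ReferencePropertyTable.default()
    denoised = _stage("denoise", pca_denoise, volume, variance_fraction)
    mask = _stage("mask", build_breast_mask, denoised, mask_threshold)
    labelmap = _stage(
        "segment", segment_tissues, denoised, mask, skin_thickness_mm, seed
    )
    labelmap = _stage("subcluster", subcluster_fgt, denoised, labelmap, K, seed)
    stats = _stage("statistics", cluster_statistics, denoised, labelmap)
    model = _stage(
        "properties",
        assign_properties,
        labelmap,
        stats,
        table,
        level,
        model_name,
    )
    model.attributes["cluster_mean_intensity"] = {
        l: stats.mean_intensity[l] for l in labelmap.legend
    }
    return model


def embed_tumour(
    model: BreastModel,
    tumour: TumourModel,
    centre_mm: tuple[float, float, float],
    properties: DebyeParameters | None = None,
) -> BreastModel:
    """Embed a tumour inclusion into a breast model.

    The tumour mask is resampled to the host grid if spacings differ and
    placed with its centre at ``centre_mm`` (millimetres from the host
    origin).  Tumour voxels overwrite fat and fibroglandular labels only;
    skin is never replaced.  The centre must fall inside the breast and at
    most 10% of the tumour may land on skin or background.
    """
    host = model.labelmap
    spacing = np.asarray(host.spacing_mm)
    tmask = tumour.mask
    if tuple(tumour.spacing_mm) != tuple(host.spacing_mm):
        zoom = np.asarray(tumour.spacing_mm) / spacing
        tmask = ndimage.zoom(tmask.astype(float), zoom, order=1) > 0.5
        if not tmask.any():
            raise ValueError("invalid placement: tumour vanishes on the host grid")

    centre_idx = np.round(np.asarray(centre_mm) / spacing).astype(int)
    if np.any(centre_idx < 0) or np.any(centre_idx >= host.labels.shape):
        raise ValueError("tumour outside breast: centre beyond the grid")
    if host.labels[tuple(centre_idx)] == BACKGROUND:
        raise ValueError("tumour outside breast: centre is in the background")

    # centre the tumour bounding box on centre_idx
    offset = centre_idx - np.asarray(tmask.shape) // 2
    target = np.zeros(host.labels.shape, dtype=bool)
    src_lo = np.maximum(0, -offset)
    src_hi = np.minimum(tmask.shape, np.asarray(host.labels.shape) - offset)
    if np.any(src_lo >= src_hi):
        raise ValueError("tumour outside breast: no overlap with the grid")
    dst_lo = offset + src_lo
    dst_hi = offset + src_hi
    target[
        dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]
    ] = tmask[src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]]

    clipped = int(tmask.sum() - target.sum())
    host_labels = host.labels[target]
    invalid = int(((host_labels == BACKGROUND) | (host_labels == SKIN)).sum()) + clipped
    if invalid > 0.10 * tmask.sum():
        raise ValueError(
            "invalid placement: tumour overlaps skin/background by more than 10%"
        )

    out = host.copy()
    new_label = max(out.legend) + 1
    replace = target & (out.labels != SKIN) & (out.labels != BACKGROUND)
    out.labels[replace] = new_label
    out.legend[new_label] = "tumour"

    props = dict(model.properties)
    props[new_label] = properties if properties is not None else tumour.properties
    attrs = dict(model.attributes)
    attrs["breast_health"] = "diseased"
    attrs["density_percent"] = compute_density(out)
    attrs["breast_class"] = classify_breast(attrs["density_percent"])
    return BreastModel(labelmap=out, properties=props, attributes=attrs)


def _intensity_summary(model: BreastModel) -> str:
    means = model.attributes.get("cluster_mean_intensity")
    if not means:
        return "cluster mean intensities unavailable"
    parts = [
        f"{model.labelmap.legend[l]}: {m:.1f}"
        for l, m in sorted(means.items())
        if model.labelmap.legend.get(l) != "background" and np.isfinite(m)
    ]
    return "mean scan intensity per cluster — " + ", ".join(parts)


def generate_model_report(
    model: BreastModel, output_dir: str | Path | None = None
) -> str:
    """Render the model's four-section markdown report.

    Sections: general information, model elements, dielectric properties
    (eps' and effective conductivity at 1/3/6/10 GHz per cluster, with the
    three contrast levels for fibroglandular clusters), and visualization.
    When ``output_dir`` is given, a central-slice label image is saved
    alongside and referenced from the last section.
    """
    attrs = model.attributes
    lm = model.labelmap
    lines: list[str] = []
    lines.append(f"# Model report: {attrs.get('model_name', 'unnamed')}")
    lines.append("")
    lines.append("## General information")
    lines.append("")
    lines.append(f"- Breast health: {attrs.get('breast_health', 'unknown')}")
    lines.append(f"- Breast class: {attrs.get('breast_class', 'unknown')}")
    density = attrs.get("density_percent")
    if density is not None:
        lines.append(f"- Breast density: {density:.1f}%")
    lines.append(f"- Fibroglandular clusters: {attrs.get('n_fgt_clusters')}")
    lines.append(f"- Property level: {attrs.get('property_level', 'high')}")
    lines.append(f"- {_intensity_summary(model)}")
    lines.append("")
    lines.append("## Model elements")
    lines.append("")
    lines.append(
        f"- Grid size: {lm.labels.shape[0]} x {lm.labels.shape[1]} x "
        f"{lm.labels.shape[2]} voxels at "
        f"{' x '.join(f'{s:g}' for s in lm.spacing_mm)} mm"
    )
    lines.append("")
    lines.append("| Element | Label | Voxels |")
    lines.append("|---|---|---|")
    counts = np.bincount(lm.labels.ravel(), minlength=max(lm.legend) + 1)
    names = model.element_names()
    for label in sorted(names):
        lines.append(f"| {names[label]} | {label} | {int(counts[label])} |")
    lines.append("")
    lines.append("## Dielectric properties")
    lines.append("")
    header = "| Element | Level | " + " | ".join(
        f"eps' @ {f:g} GHz | sigma @ {f:g} GHz (S/m)" for f in _REPORT_FREQS_GHZ
    ) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (2 + 2 * len(_REPORT_FREQS_GHZ)))
    for label in sorted(names):
        role = lm.legend[label]
        base = model.properties[label]
        levels = (
            [PROPERTY_LEVELS[n] for n in ("high", "med", "low")]
            if role.startswith("fgt_")
            else [PROPERTY_LEVELS["high"]]
        )
        for lvl in levels:
            p = apply_property_level(base, lvl)
            cells = []
            for f in _REPORT_FREQS_GHZ:
                eps = debye_permittivity(p, f * 1e9)
                sig = effective_conductivity(p, f * 1e9)
                cells.append(f"{eps.real:.2f} | {sig:.3f}")
            lines.append(f"| {names[label]} | {lvl.name} | " + " | ".join(cells) + " |")
    lines.append("")
    lines.append("## Visualization")
    lines.append("")
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        image_path = output_dir / f"{attrs.get('model_name', 'model')}_central_slice.png"
        _save_central_slice(lm, image_path)
        lines.append(f"![central slice]({image_path.name})")
    else:
        lines.append(
            "Central-slice label image not rendered (no output directory given)."
        )
    lines.append("")
    return "\n".join(lines)


def _save_central_slice(lm: TissueLabelMap, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = lm.labels.shape[2] // 2
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(lm.labels[:, :, k], interpolation="nearest", cmap="viridis")
    ax.set_title(f"labels, slice {k}")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
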