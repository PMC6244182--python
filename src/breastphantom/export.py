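"""Model containers: RAW voxel grids, HDF5, XML property files, STL, NPZ.

Layouts follow the breast-model repository conventions: the HDF5 file
carries one 3D dataset per model element under ``modelData`` plus Debye
parameter sets under ``modelProps`` with descriptive root attributes
(breastHealth, breastClass, density, ...); the XML property file has a
``modelProps`` root with one node per tissue, each holding the four Debye
parameter tags.  STL meshes are binary, in millimetres, one watertight
surface per cluster.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import h5py
import numpy as np
import trimesh
from skimage import measure

from .dielectrics import DebyeParameters
from .model import BreastModel
from .segmentation import TissueLabelMap

__all__ = [
    "write_raw",
    "read_raw",
    "write_hdf5",
    "read_hdf5",
    "write_xml_properties",
    "read_xml_properties",
    "write_stl",
    "write_voxel_container",
    "read_voxel_container",
]

_DEBYE_TAGS = ("eps_inf", "del_eps", "tau", "sigma_s")


# ---------------------------------------------------------------- RAW


def write_raw(labelmap: TissueLabelMap, path: str | Path) -> Path:
    """Write the label grid as one unsigned byte per voxel.

    The row index varies fastest, then columns, then slices.  A JSON
    sidecar (``<path>.json``) records dimensions, spacing, axis order and
    the label legend, making the RAW file self-describing; its path is
    returned.
    """
    path = Path(path)
    if labelmap.labels.max(initial=0) > 255 or labelmap.labels.min(initial=0) < 0:
        raise ValueError("label overflow: RAW export supports labels 0..255")
    data = labelmap.labels.astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(data.flatten(order="F").tobytes())
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "dimensions": list(labelmap.labels.shape),
        "spacing_mm": list(labelmap.spacing_mm),
        "axis_order": "row-fastest (Fortran): row, column, slice",
        "dtype": "uint8",
        "legend": {str(k): v for k, v in sorted(labelmap.legend.items())},
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return sidecar


def read_raw(path: str | Path) -> TissueLabelMap:
    """Read a RAW label grid via its JSON sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    shape = tuple(meta["dimensions"])
    raw = np.fromfile(path, dtype=np.uint8)
    if raw.size != int(np.prod(shape)):
        raise ValueError("malformed model file: RAW size does not match sidecar")
    labels = raw.reshape(shape, order="F").astype(np.int32)
    legend = {int(k): v for k, v in meta["legend"].items()}
    return TissueLabelMap(labels, legend, tuple(meta["spacing_mm"]))


# ---------------------------------------------------------------- HDF5


def write_hdf5(model: BreastModel, path: str | Path) -> None:
    """Write a model to the HDF5 layout.

    ``modelData/<element>`` holds each element's binary occupancy grid
    (uint8) with its integer label as a dataset attribute;
    ``modelProps/<element>`` holds the four Debye parameters; descriptive
    attributes live at the root.
    """
    attrs = model.attributes
    names = model.element_names()
    with h5py.File(path, "w") as fh:
        data = fh.create_group("modelData")
        props = fh.create_group("modelProps")
        for label in sorted(names):
            element = names[label]
            ds = data.create_dataset(
                element,
                data=(model.labelmap.labels == label).astype(np.uint8),
                compression="gzip",
                track_times=False,
            )
            ds.attrs["label"] = int(label)
            ds.attrs["role"] = model.labelmap.legend[label]
            p = model.properties[label]
            props.create_dataset(
                element,
                data=np.array([p.eps_inf, p.delta_eps, p.tau_s, p.sigma_s]),
                track_times=False,
            )
        fh.attrs["breastHealth"] = str(attrs.get("breast_health", "healthy"))
        fh.attrs["breastClass"] = str(attrs.get("breast_class", ""))
        fh.attrs["density"] = float(attrs.get("density_percent", float("nan")))
        fh.attrs["modelName"] = str(attrs.get("model_name", ""))
        fh.attrs["nClusters"] = int(attrs.get("n_fgt_clusters", 0))
        fh.attrs["voxelSize"] = np.asarray(model.labelmap.spacing_mm)


def read_hdf5(path: str | Path) -> BreastModel:
    """Exact inverse of :func:`write_hdf5`."""
    with h5py.File(path, "r") as fh:
        if "modelData" not in fh or "modelProps" not in fh:
            raise ValueError("malformed model file: missing modelData/modelProps")
        for required in ("breastHealth", "breastClass", "modelName", "voxelSize"):
            if required not in fh.attrs:
                raise ValueError(f"malformed model file: missing attribute {required}")
        spacing = tuple(float(s) for s in fh.attrs["voxelSize"])
        labels = None
        legend = {0: "background"}
        properties: dict[int, DebyeParameters] = {}
        for element, ds in fh["modelData"].items():
            label = int(ds.attrs["label"])
            role = str(ds.attrs["role"])
            occupancy = ds[()].astype(bool)
            if labels is None:
                labels = np.zeros(occupancy.shape, dtype=np.int32)
            labels[occupancy] = label
            legend[label] = role
            vals = fh["modelProps"][element][()]
            properties[label] = DebyeParameters(*[float(v) for v in vals])
        if labels is None:
            raise ValueError("malformed model file: no model elements")
        attributes = {
            "breast_health": str(fh.attrs["breastHealth"]),
            "breast_class": str(fh.attrs["breastClass"]),
            "density_percent": float(fh.attrs["density"]),
            "model_name": str(fh.attrs["modelName"]),
            "n_fgt_clusters": int(fh.attrs["nClusters"]),
            "voxel_size_mm": spacing,
        }
    labelmap = TissueLabelMap(labels, legend, spacing)
    return BreastModel(labelmap=labelmap, properties=properties, attributes=attributes)


# ---------------------------------------------------------------- XML


def write_xml_properties(model: BreastModel, path: str | Path) -> None:
    """Write the per-tissue Debye parameters as a modelProps XML document.

    One node per tissue element, each with the four Debye parameter child
    tags serialized at 17 significant digits (lossless for doubles);
    descriptive model attributes sit on the root.
    """
    attrs = model.attributes
    root = ET.Element("modelProps")
    root.set("breastHealth", str(attrs.get("breast_health", "healthy")))
    root.set("breastClass", str(attrs.get("breast_class", "")))
    density = attrs.get("density_percent")
    if density is not None:
        root.set("density", repr(float(density)))
    root.set("modelName", str(attrs.get("model_name", "")))
    root.set("nClusters", str(int(attrs.get("n_fgt_clusters", 0))))
    names = model.element_names()
    for label in sorted(names):
        node = ET.SubElement(root, names[label])
        node.set("label", str(label))
        p = model.properties[label]
        for tag, value in zip(
            _DEBYE_TAGS, (p.eps_inf, p.delta_eps, p.tau_s, p.sigma_s)
        ):
            ET.SubElement(node, tag).text = f"{value:.17g}"
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_xml_properties(path: str | Path) -> dict[str, DebyeParameters]:
    """Parse a modelProps XML file into element-name -> Debye parameters."""
    root = ET.parse(path).getroot()
    if root.tag != "modelProps":
        raise ValueError("malformed model file: root node is not modelProps")
    out: dict[str, DebyeParameters] = {}
    for node in root:
        values = []
        for tag in _DEBYE_TAGS:
            child = node.find(tag)
            if child is None or child.text is None:
                raise ValueError(
                    f"incomplete property entry: {node.tag} lacks <{tag}>"
                )
            values.append(float(child.text))
        out[node.tag] = DebyeParameters(*values)
    return out


# ---------------------------------------------------------------- STL


def write_stl(
    labelmap: TissueLabelMap, label: int, path: str | Path
) -> dict[str, float]:
    """Triangulate one cluster's 0.5-level isosurface to binary STL.

    Coordinates are millimetres (index * spacing per axis); the mask is
    zero-padded so the surface closes at the grid boundary, and normals
    point outward.  Returns triangle count and enclosed volume in mm^3.
    """
    mask = labelmap.labels == label
    if not mask.any():
        raise ValueError(f"empty cluster: label {label} has no voxels")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=labelmap.spacing_mm
    )
    verts -= np.asarray(labelmap.spacing_mm)  # undo the pad offset
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    mesh.export(path, file_type="stl")
    return {
        "n_triangles": float(len(mesh.faces)),
        "volume_mm3": float(abs(mesh.volume)),
    }


# ---------------------------------------------------------------- NPZ


def write_voxel_container(model: BreastModel, path: str | Path) -> None:
    """Write the voxelized model to a single NPZ array container.

    Stores the label grid, spacing, legend, per-label Debye parameters and
    attributes; :func:`read_voxel_container` is its lossless inverse.
    """
    labels_sorted = sorted(model.properties)
    params = np.array(
        [
            [
                model.properties[l].eps_inf,
                model.properties[l].delta_eps,
                model.properties[l].tau_s,
                model.properties[l].sigma_s,
            ]
            for l in labels_sorted
        ]
    ).reshape(-1, 4)
    attrs = {
        k: v
        for k, v in model.attributes.items()
        if isinstance(v, (str, int, float, bool, tuple, list))
    }
    np.savez_compressed(
        path,
        labels=model.labelmap.labels,
        spacing_mm=np.asarray(model.labelmap.spacing_mm),
        legend=json.dumps(
            {str(k): v for k, v in model.labelmap.legend.items()}, sort_keys=True
        ),
        property_labels=np.asarray(labels_sorted, dtype=np.int64),
        property_values=params,
        attributes=json.dumps(attrs, sort_keys=True),
    )


def read_voxel_container(path: str | Path) -> BreastModel:
    """Inverse of :func:`write_voxel_container`."""
    with np.load(path, allow_pickle=False) as data:
        legend = {int(k): v for k, v in json.loads(str(data["legend"])).items()}
        labelmap = TissueLabelMap(
            data["labels"].astype(np.int32),
            legend,
            tuple(float(s) for s in data["spacing_mm"]),
        )
        properties = {
            int(l): DebyeParameters(*[float(v) for v in row])
            for l, row in zip(data["property_labels"], data["property_values"])
        }
        attributes = json.loads(str(data["attributes"]))
    if "voxel_size_mm" in attributes:
        attributes["voxel_size_mm"] = tuple(attributes["voxel_size_mm"])
    return BreastModel(labelmap=labelmap, properties=properties, attributes=attributes)
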