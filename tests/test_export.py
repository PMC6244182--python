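"""Container writers/readers: RAW, HDF5, XML, STL, NPZ."""

from __future__ import annotations

import numpy as np
import pytest

import breastphantom as bp
from breastphantom.export import (
    read_hdf5,
    read_raw,
    read_voxel_container,
    read_xml_properties,
    write_hdf5,
    write_raw,
    write_stl,
    write_voxel_container,
    write_xml_properties,
)
from breastphantom.segmentation import TissueLabelMap


def _tiny_labelmap():
    labels = np.zeros((16, 16, 10), dtype=np.int32)
    labels[4:12, 4:12, 2:8] = 2
    labels[6:10, 6:10, 4:6] = 3
    legend = {0: "background", 2: "fat", 3: "fgt_1"}
    return TissueLabelMap(labels, legend, (1.0, 1.0, 1.1))


class TestRaw:
    def test_file_size_is_voxel_count(self, tmp_path):
        lm = _tiny_labelmap()
        path = tmp_path / "m.raw"
        write_raw(lm, path)
        assert path.stat().st_size == 16 * 16 * 10

    def test_roundtrip_identity(self, tmp_path):
        lm = _tiny_labelmap()
        write_raw(lm, tmp_path / "m.raw")
        back = read_raw(tmp_path / "m.raw")
        np.testing.assert_array_equal(back.labels, lm.labels)
        assert back.legend == lm.legend
        assert back.spacing_mm == lm.spacing_mm

    def test_all_zero_map(self, tmp_path):
        lm = TissueLabelMap(
            np.zeros((4, 4, 4), dtype=np.int32), {0: "background"}, (1, 1, 1)
        )
        path = tmp_path / "z.raw"
        write_raw(lm, path)
        assert path.read_bytes() == b"\x00" * 64

    def test_label_overflow_rejected(self, tmp_path):
        labels = np.full((2, 2, 2), 300, dtype=np.int32)
        lm = TissueLabelMap(labels, {300: "fgt_1"}, (1, 1, 1))
        with pytest.raises(ValueError, match="label overflow"):
            write_raw(lm, tmp_path / "m.raw")

    def test_writes_are_byte_identical(self, tmp_path):
        lm = _tiny_labelmap()
        write_raw(lm, tmp_path / "a.raw")
        write_raw(lm, tmp_path / "b.raw")
        assert (tmp_path / "a.raw").read_bytes() == (tmp_path / "b.raw").read_bytes()
        assert (tmp_path / "a.raw.json").read_bytes() == (
            tmp_path / "b.raw.json"
        ).read_bytes()


class TestHdf5:
    def test_roundtrip_of_k8_model(self, k8_model, tmp_path):
        path = tmp_path / "m.h5"
        write_hdf5(k8_model, path)
        back = read_hdf5(path)
        np.testing.assert_array_equal(back.labelmap.labels, k8_model.labelmap.labels)
        assert back.labelmap.legend == k8_model.labelmap.legend
        assert back.properties == k8_model.properties
        assert back.attributes["breast_health"] == k8_model.attributes["breast_health"]
        assert back.attributes["density_percent"] == pytest.approx(
            k8_model.attributes["density_percent"]
        )

    def test_layout_attributes_and_dataset_count(self, k8_model, tmp_path):
        import h5py

        path = tmp_path / "m.h5"
        write_hdf5(k8_model, path)
        with h5py.File(path) as fh:
            assert "breastHealth" in fh.attrs
            assert set(fh) == {"modelData", "modelProps"}
            # skin + fat + 8 fibroglandular clusters
            assert len(fh["modelData"]) == 10

    def test_malformed_file_rejected(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as fh:
            fh.create_group("modelData")
        with pytest.raises(ValueError, match="malformed model file"):
            read_hdf5(path)


class TestXml:
    def test_root_node_and_debye_children(self, k8_model, tmp_path):
        import xml.etree.ElementTree as ET

        path = tmp_path / "m.xml"
        write_xml_properties(k8_model, path)
        root = ET.parse(path).getroot()
        assert root.tag == "modelProps"
        assert root.get("breastHealth") == "healthy"
        for node in root:
            assert [c.tag for c in node] == ["eps_inf", "del_eps", "tau", "sigma_s"]

    def test_roundtrip_to_parsing_precision(self, k8_model, tmp_path):
        path = tmp_path / "m.xml"
        write_xml_properties(k8_model, path)
        props = read_xml_properties(path)
        names = k8_model.element_names()
        for label, element in names.items():
            want = k8_model.properties[label]
            got = props[element]
            for attr in ("eps_inf", "delta_eps", "tau_s", "sigma_s"):
                assert getattr(got, attr) == pytest.approx(
                    getattr(want, attr), rel=1e-10
                )

    def test_incomplete_entry_rejected(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            "<modelProps><Skin_Layer><eps_inf>2.0</eps_inf></Skin_Layer></modelProps>"
        )
        with pytest.raises(ValueError, match="incomplete property entry"):
            read_xml_properties(path)

    def test_writes_are_byte_identical(self, k8_model, tmp_path):
        write_xml_properties(k8_model, tmp_path / "a.xml")
        write_xml_properties(k8_model, tmp_path / "b.xml")
        assert (tmp_path / "a.xml").read_bytes() == (tmp_path / "b.xml").read_bytes()


class TestStl:
    def test_cube_volume_within_five_percent(self, tmp_path):
        labels = np.zeros((14, 14, 14), dtype=np.int32)
        labels[2:12, 2:12, 2:12] = 2  # 10 mm cube at 1 mm spacing
        lm = TissueLabelMap(labels, {0: "background", 2: "fat"}, (1, 1, 1))
        stats = write_stl(lm, 2, tmp_path / "cube.stl")
        assert stats["volume_mm3"] == pytest.approx(1000.0, rel=0.05)

    def test_sphere_volume_within_three_percent(self, tmp_path):
        t = bp.generate_tumour(10.0, (0.25, 0.25, 0.25))
        labels = t.mask.astype(np.int32)
        lm = TissueLabelMap(labels, {0: "background", 1: "skin"}, t.spacing_mm)
        stats = write_stl(lm, 1, tmp_path / "sphere.stl")
        assert stats["volume_mm3"] == pytest.approx(np.pi * 1000 / 6, rel=0.03)

    def test_mesh_volume_converges_to_voxel_volume(self, tmp_path):
        # refinement halves the surface-voxelization bias
        errors = []
        for spacing in (0.5, 0.25):
            t = bp.generate_tumour(10.0, (spacing,) * 3)
            lm = TissueLabelMap(
                t.mask.astype(np.int32), {0: "background", 1: "skin"}, t.spacing_mm
            )
            stats = write_stl(lm, 1, tmp_path / f"s{spacing}.stl")
            voxel_volume = t.mask.sum() * spacing**3
            errors.append(abs(stats["volume_mm3"] - voxel_volume) / voxel_volume)
        assert errors[1] < errors[0]

    def test_single_voxel_is_closed_with_positive_volume(self, tmp_path):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = 2
        lm = TissueLabelMap(labels, {0: "background", 2: "fat"}, (1, 1, 1))
        stats = write_stl(lm, 2, tmp_path / "v.stl")
        assert stats["volume_mm3"] > 0

    def test_empty_label_rejected(self, tmp_path):
        lm = _tiny_labelmap()
        with pytest.raises(ValueError, match="empty cluster"):
            write_stl(lm, 99, tmp_path / "e.stl")

    def test_writes_are_byte_identical(self, tmp_path):
        lm = _tiny_labelmap()
        write_stl(lm, 2, tmp_path / "a.stl")
        write_stl(lm, 2, tmp_path / "b.stl")
        assert (tmp_path / "a.stl").read_bytes() == (tmp_path / "b.stl").read_bytes()


class TestVoxelContainer:
    def test_roundtrip_equality(self, k8_model, tmp_path):
        path = tmp_path / "m.npz"
        write_voxel_container(k8_model, path)
        back = read_voxel_container(path)
        np.testing.assert_array_equal(back.labelmap.labels, k8_model.labelmap.labels)
        assert back.labelmap.legend == k8_model.labelmap.legend
        assert back.labelmap.spacing_mm == k8_model.labelmap.spacing_mm
        assert back.properties == k8_model.properties

    def test_legend_preserved_under_label_permutation(self, tmp_path):
        lm = _tiny_labelmap()
        # permute 2<->3 and keep legend consistent
        permuted = lm.labels.copy()
        permuted[lm.labels == 2] = 3
        permuted[lm.labels == 3] = 2
        lm2 = TissueLabelMap(
            permuted, {0: "background", 3: "fat", 2: "fgt_1"}, lm.spacing_mm
        )
        table = bp.ReferencePropertyTable.default()
        model = bp.BreastModel(
            labelmap=lm2,
            properties={3: table.debye["fat"], 2: table.debye["fgt_lower"]},
            attributes={"model_name": "perm"},
        )
        path = tmp_path / "p.npz"
        write_voxel_container(model, path)
        back = read_voxel_container(path)
        assert back.labelmap.legend == lm2.legend
        np.testing.assert_array_equal(back.labelmap.labels, lm2.labels)
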