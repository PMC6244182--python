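"""Parametric synthetic breast MRI volumes with ground-truth labels.

The generator emulates the statistical structure of a fat-suppressed 3 T
breast acquisition — a 256 x 256 x 240 grid at 0.9375 x 0.9375 x 1.1 mm —
without simulating MR physics: a half-ellipsoid breast rests on the
chest-wall face of the grid, wrapped in a geometric skin shell, its
interior filled with fat and with bright fibroglandular structures grown
from thresholded correlated noise until a target volume fraction is hit.
Optional k-space truncation adds Gibbs ringing.  Every volume comes with a
ground-truth label map, making each pipeline stage testable without
patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid
from scipy import ndimage

from .dielectrics import DebyeParameters
from .mri_io import MRIVolume
from .segmentation import BACKGROUND, FAT, FGT_FIRST, SKIN, TissueLabelMap

__all__ = [
    "SyntheticParams",
    "SyntheticGroundTruth",
    "TumourModel",
    "generate_breast_volume",
    "add_gibbs_ringing",
    "generate_tumour",
    "write_dicom_series",
]


@dataclass
class SyntheticParams:
    """Configuration of the synthetic acquisition.

    Geometry defaults match the emulated protocol (matrix 256 x 256, 240
    slices, voxel 0.9375 x 0.9375 x 1.1 mm).  Intensity means are arbitrary
    scanner units; the fat-suppressed contrast only requires the
    fibroglandular mean to exceed the fat mean.
    """

    grid: tuple[int, int, int] = (256, 256, 240)
    spacing_mm: tuple[float, float, float] = (0.9375, 0.9375, 1.1)
    breast_semi_axes_mm: tuple[float, float, float] = (90.0, 80.0, 90.0)
    skin_thickness_mm: float = 1.5
    target_fgt_fraction: float = 0.3
    fat_intensity_mean: float = 60.0
    fat_intensity_sd: float = 8.0
    fgt_intensity_mean: float = 200.0
    fgt_intensity_sd: float = 20.0
    skin_intensity_mean: float = 120.0
    skin_intensity_sd: float = 10.0
    background_noise_sd: float = 5.0
    texture_scale_mm: float = 6.0
    ringing: bool = False
    ringing_truncation: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = tuple(int(n) for n in self.grid)  # type: ignore[assignment]
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)  # type: ignore[assignment]
        self.breast_semi_axes_mm = tuple(  # type: ignore[assignment]
            float(a) for a in self.breast_semi_axes_mm
        )
        if any(n < 1 for n in self.grid):
            raise ValueError("grid dimensions must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")
        if any(a <= 0 for a in self.breast_semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if not 0 <= self.target_fgt_fraction <= 1:
            raise ValueError("target_fgt_fraction must lie in [0, 1]")
        if self.fgt_intensity_mean <= self.fat_intensity_mean:
            raise ValueError(
                "fat-suppressed contrast requires fgt_intensity_mean > "
                "fat_intensity_mean"
            )
        if not 0 < self.ringing_truncation <= 1:
            raise ValueError("ringing_truncation must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticGroundTruth:
    """True labels and true fibroglandular fraction of a generated volume."""

    labels: TissueLabelMap
    true_fgt_fraction: float


@dataclass
class TumourModel:
    """A voxelized spherical tumour inclusion with dielectric properties."""

    mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    properties: DebyeParameters
    nominal_diameter_mm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("tumour mask is empty")

    @property
    def spherical_equivalent_diameter_mm(self) -> float:
        """Diameter of the sphere with the mask's voxel volume, (6V/pi)^(1/3)."""
        voxel = float(np.prod(self.spacing_mm))
        volume = self.mask.sum() * voxel
        return float((6.0 * volume / np.pi) ** (1.0 / 3.0))


def _half_ellipsoid(params: SyntheticParams) -> np.ndarray:
    """Breast support: half-ellipsoid resting on the last row face."""
    nr, nc, ns = params.grid
    sr, sc, ss = params.spacing_mm
    a, b, c = params.breast_semi_axes_mm
    r = np.arange(nr)[:, None, None] * sr
    col = np.arange(nc)[None, :, None] * sc
    s = np.arange(ns)[None, None, :] * ss
    r0 = (nr - 1) * sr
    c0 = (nc - 1) * sc / 2.0
    s0 = (ns - 1) * ss / 2.0
    return ((r - r0) / a) ** 2 + ((col - c0) / b) ** 2 + ((s - s0) / c) ** 2 <= 1.0


def generate_breast_volume(
    params: SyntheticParams,
) -> tuple[MRIVolume, SyntheticGroundTruth]:
    """Generate one synthetic volume plus its ground truth.

    Deterministic under a fixed seed.  The achieved fibroglandular fraction
    of the interior is within +/-0.02 of ``target_fgt_fraction`` or an
    ``"infeasible density"`` error is raised.
    """
    rng = np.random.default_rng(params.seed)
    breast = _half_ellipsoid(params)
    if not breast.any():
        raise ValueError("infeasible density: breast geometry is empty")

    exterior = ~breast
    dist = ndimage.distance_transform_edt(breast, sampling=params.spacing_mm)
    skin = breast & (dist <= params.skin_thickness_mm)
    interior = breast & ~skin
    n_interior = int(interior.sum())
    if n_interior == 0 and params.target_fgt_fraction > 0:
        raise ValueError("infeasible density: no interior voxels for tissue")

    labels = np.zeros(params.grid, dtype=np.int32)
    labels[skin] = SKIN
    labels[interior] = FAT
    legend = {BACKGROUND: "background", SKIN: "skin", FAT: "fat", FGT_FIRST: "fgt_1"}

    if params.target_fgt_fraction > 0 and n_interior > 0:
        # correlated noise field, thresholded at the quantile that delivers
        # the target interior fraction
        sigma_vox = [params.texture_scale_mm / s for s in params.spacing_mm]
        noise = rng.standard_normal(params.grid)
        texture = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        tvals = texture[interior]
        thr = np.quantile(tvals, 1.0 - params.target_fgt_fraction)
        fgt = interior & (texture > thr)
        achieved = fgt.sum() / n_interior
        if abs(achieved - params.target_fgt_fraction) > 0.02:
            raise ValueError(
                "infeasible density: achieved fibroglandular fraction "
                f"{achieved:.3f} misses target {params.target_fgt_fraction:.3f}"
            )
        labels[fgt] = FGT_FIRST

    n_fgt = int((labels == FGT_FIRST).sum())
    true_fraction = n_fgt / n_interior if n_interior else 0.0

    intens = np.abs(rng.normal(0.0, params.background_noise_sd, params.grid))
    for lab, mean, sd in (
        (SKIN, params.skin_intensity_mean, params.skin_intensity_sd),
        (FAT, params.fat_intensity_mean, params.fat_intensity_sd),
        (FGT_FIRST, params.fgt_intensity_mean, params.fgt_intensity_sd),
    ):
        sel = labels == lab
        intens[sel] = rng.normal(mean, sd, int(sel.sum()))
    intens = np.clip(intens, 0.0, None)

    volume = MRIVolume(intens, params.spacing_mm)
    if params.ringing:
        volume = add_gibbs_ringing(volume, params.ringing_truncation)

    labelmap = TissueLabelMap(labels, legend, params.spacing_mm)
    return volume, SyntheticGroundTruth(labelmap, float(true_fraction))


def add_gibbs_ringing(volume: MRIVolume, truncation_fraction: float) -> MRIVolume:
    """Introduce Gibbs ringing by in-plane k-space truncation.

    Each slice is Fourier transformed, the spectrum cropped to the central
    ``truncation_fraction`` of frequencies per in-plane axis, and the
    magnitude of the inverse transform taken — reproducing the edge
    oscillation of a band-limited MR reconstruction.
    """
    if not 0 < truncation_fraction <= 1:
        raise ValueError("truncation_fraction must lie in (0, 1]")
    if truncation_fraction == 1.0:
        return MRIVolume(volume.intensities.copy(), volume.spacing_mm, volume.meta)
    data = volume.intensities
    nr, nc = data.shape[:2]
    kr, kc = max(1, int(round(truncation_fraction * nr))), max(
        1, int(round(truncation_fraction * nc))
    )
    spec = np.fft.fftshift(np.fft.fft2(data, axes=(0, 1)), axes=(0, 1))
    keep = np.zeros((nr, nc, 1), dtype=bool)
    r0, c0 = (nr - kr) // 2, (nc - kc) // 2
    keep[r0 : r0 + kr, c0 : c0 + kc] = True
    spec = np.where(keep, spec, 0.0)
    out = np.abs(
        np.fft.ifft2(np.fft.ifftshift(spec, axes=(0, 1)), axes=(0, 1))
    )
    return MRIVolume(out, volume.spacing_mm, volume.meta)


def generate_tumour(
    diameter_mm: float = 10.0,
    spacing_mm: tuple[float, float, float] = (0.25, 0.25, 0.25),
    properties: DebyeParameters | None = None,
) -> TumourModel:
    """Voxelize a spherical tumour of the given diameter.

    A voxel belongs to the tumour when its centre lies within the sphere.
    Defaults model the repository's 10 mm malignant inclusion.
    """
    spacing = tuple(float(s) for s in spacing_mm)
    if diameter_mm < 2.0 * max(spacing):
        raise ValueError("diameter too small for grid")
    if properties is None:
        from .dielectrics import ReferencePropertyTable

        properties = ReferencePropertyTable.default().debye["tumour"]
    radius = diameter_mm / 2.0
    shape = [int(np.ceil(diameter_mm / s)) + 3 for s in spacing]
    centre = [(n - 1) * s / 2.0 for n, s in zip(shape, spacing)]
    axes = [
        (np.arange(n) * s - c) ** 2
        for n, s, c in zip(shape, spacing, centre)
    ]
    d2 = (
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    )
    mask = d2 <= radius**2
    return TumourModel(mask, spacing, properties, float(diameter_mm))


def write_dicom_series(
    volume: MRIVolume, directory: str | Path, series_description: str = "synthetic"
) -> list[Path]:
    """Write a volume as a minimal single-frame DICOM slice series.

    One file per slice with matrix size, pixel spacing, slice position and
    orientation tags — enough for the series reader to reassemble the
    volume.  Intensities are rounded to uint16.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(volume.intensities), 0, 65535).astype(np.uint16)
    study_uid = generate_uid()
    series_uid = generate_uid()
    paths: list[Path] = []
    for k in range(data.shape[2]):
        ds = Dataset()
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.SeriesDescription = series_description
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = data.shape[0], data.shape[1]
        ds.PixelSpacing = [volume.spacing_mm[0], volume.spacing_mm[1]]
        ds.SliceThickness = volume.spacing_mm[2]
        ds.ImagePositionPatient = [0.0, 0.0, k * volume.spacing_mm[2]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(data[:, :, k]).tobytes()
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.file_meta = meta
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
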