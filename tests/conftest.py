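"""Shared fixtures: small synthetic phantoms sized for fast test runs."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import breastphantom as bp


@pytest.fixture(scope="session")
def small_params() -> bp.SyntheticParams:
    """A coarse phantom: 48x48x32 grid, 2 x 2 x 2.5 mm voxels."""
    return bp.SyntheticParams(
        grid=(48, 48, 32),
        spacing_mm=(2.0, 2.0, 2.5),
        breast_semi_axes_mm=(60.0, 55.0, 50.0),
        skin_thickness_mm=3.0,
        target_fgt_fraction=0.4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_params):
    """(volume, ground truth) for the coarse phantom."""
    return bp.generate_breast_volume(small_params)


@pytest.fixture(scope="session")
def native_params() -> bp.SyntheticParams:
    """A small breast at native acquisition resolution (128x128x96 grid)."""
    return bp.SyntheticParams(
        grid=(128, 128, 96),
        spacing_mm=(0.9375, 0.9375, 1.1),
        breast_semi_axes_mm=(50.0, 45.0, 45.0),
        skin_thickness_mm=1.5,
        target_fgt_fraction=0.3,
        seed=21,
    )


@pytest.fixture(scope="session")
def native_phantom(native_params):
    return bp.generate_breast_volume(native_params)


@pytest.fixture(scope="session")
def k8_model(native_phantom) -> bp.BreastModel:
    """Full-pipeline model with 8 fibroglandular clusters."""
    volume, _ = native_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bp.build_model(volume, K=8, seed=3)


def make_phantom(target_fraction: float, seed: int):
    """Native-resolution phantom at a requested fibroglandular fraction."""
    params = bp.SyntheticParams(
        grid=(128, 128, 96),
        spacing_mm=(0.9375, 0.9375, 1.1),
        breast_semi_axes_mm=(50.0, 45.0, 45.0),
        skin_thickness_mm=1.5,
        target_fgt_fraction=target_fraction,
        seed=seed,
    )
    return bp.generate_breast_volume(params)
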