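"""Single-pole Debye dielectric properties and the intensity-to-property map.

Tissues are described by the four-parameter single-pole Debye model

    eps*(w) = eps_inf + delta_eps / (1 + j w tau) + sigma_s / (j w eps0)

with ``w = 2 pi f``.  The sign convention is ``eps* = eps' - j eps''``
with ``eps'' >= 0`` (negative imaginary part encodes loss).

Fibroglandular clusters receive properties by linear mapping: the cluster's
mean scan intensity is located within the fibroglandular intensity range to
give a weight in [0, 1], which convexly combines a lower- and an
upper-bound Debye curve.  Three contrast levels (high / med / low) scale
the resulting complex permittivity curve by 1.0 / 0.85 / 0.75 at every
frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "VACUUM_PERMITTIVITY",
    "DebyeParameters",
    "DielectricSpectrum",
    "PropertyLevel",
    "PROPERTY_LEVELS",
    "ReferencePropertyTable",
    "debye_permittivity",
    "debye_spectrum",
    "effective_conductivity",
    "map_intensity_to_weight",
    "combine_property_curves",
    "apply_property_level",
]

#: vacuum permittivity, F/m
VACUUM_PERMITTIVITY = 8.8541878128e-12


@dataclass(frozen=True)
class DebyeParameters:
    """One tissue's single-pole Debye parameter set.

    ``eps_inf`` — high-frequency relative permittivity (>= 1);
    ``delta_eps`` — static minus high-frequency permittivity (>= 0);
    ``tau_s`` — relaxation time in seconds (> 0);
    ``sigma_s`` — static conductivity in S/m (>= 0).
    """

    eps_inf: float
    delta_eps: float
    tau_s: float
    sigma_s: float

    def __post_init__(self) -> None:
        vals = (self.eps_inf, self.delta_eps, self.tau_s, self.sigma_s)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("Debye parameters must be finite")
        if self.eps_inf < 1:
            warnings.warn(
                f"eps_inf = {self.eps_inf:.4g} < 1 is unphysical", stacklevel=3
            )
        if self.delta_eps < 0:
            raise ValueError("delta_eps must be >= 0")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be >= 0")

    @property
    def eps_static(self) -> float:
        """Static (low-frequency) relative permittivity eps_s."""
        return self.eps_inf + self.delta_eps


@dataclass(frozen=True)
class DielectricSpectrum:
    """Complex relative permittivity sampled on an ascending frequency grid."""

    frequencies_Hz: np.ndarray
    complex_relative_permittivity: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_Hz, dtype=float)
        e = np.asarray(self.complex_relative_permittivity, dtype=complex)
        if f.shape != e.shape:
            raise ValueError("frequency and permittivity arrays must match")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and ascending")
        object.__setattr__(self, "frequencies_Hz", f)
        object.__setattr__(self, "complex_relative_permittivity", e)


@dataclass(frozen=True)
class PropertyLevel:
    """A fibroglandular contrast level: a uniform scale on the property curve."""

    name: str
    scale: float

    def __post_init__(self) -> None:
        if not 0 < self.scale <= 1:
            raise ValueError("scale must lie in (0, 1]")


#: the three shipped contrast levels
PROPERTY_LEVELS: dict[str, PropertyLevel] = {
    "high": PropertyLevel("high", 1.0),
    "med": PropertyLevel("med", 0.85),
    "low": PropertyLevel("low", 0.75),
}


def debye_permittivity(params: DebyeParameters, frequency_Hz: float) -> complex:
    """Evaluate the single-pole Debye model at one frequency.

    Returns the complex relative permittivity
    ``eps_inf + delta_eps/(1 + j w tau) + sigma_s/(j w eps0)``; loss appears
    as a negative imaginary part.
    """
    if frequency_Hz <= 0:
        raise ValueError("invalid frequency: must be positive")
    w = 2.0 * np.pi * frequency_Hz
    return complex(
        params.eps_inf
        + params.delta_eps / (1.0 + 1j * w * params.tau_s)
        + params.sigma_s / (1j * w * VACUUM_PERMITTIVITY)
    )


def debye_spectrum(
    params: DebyeParameters, frequencies_Hz: np.ndarray
) -> DielectricSpectrum:
    """Evaluate the Debye model over an ascending frequency grid."""
    f = np.asarray(frequencies_Hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("invalid frequency: must be positive")
    w = 2.0 * np.pi * f
    eps = (
        params.eps_inf
        + params.delta_eps / (1.0 + 1j * w * params.tau_s)
        + params.sigma_s / (1j * w * VACUUM_PERMITTIVITY)
    )
    return DielectricSpectrum(f, eps)


def effective_conductivity(params: DebyeParameters, frequency_Hz: float) -> float:
    """Total conductivity sigma(w) = -w eps0 Im(eps*), in S/m."""
    eps = debye_permittivity(params, frequency_Hz)
    return -2.0 * np.pi * frequency_Hz * VACUUM_PERMITTIVITY * eps.imag


def map_intensity_to_weight(
    mean_intensity: float, intensity_range: tuple[float, float]
) -> float:
    """Locate a cluster mean within an intensity range, clamped to [0, 1]."""
    lower, upper = intensity_range
    if not lower < upper:
        raise ValueError("intensity range must satisfy lower < upper")
    return float(np.clip((mean_intensity - lower) / (upper - lower), 0.0, 1.0))


def combine_property_curves(
    w: float, lower: DebyeParameters, upper: DebyeParameters
) -> DebyeParameters:
    """Convex combination of two Debye parameter sets.

    Each parameter (including tau) is mixed as ``(1-w)*lower + w*upper``,
    which keeps the result a valid single-pole Debye model.
    """
    if not 0 <= w <= 1:
        raise ValueError("weight must lie in [0, 1]")
    return DebyeParameters(
        eps_inf=(1 - w) * lower.eps_inf + w * upper.eps_inf,
        delta_eps=(1 - w) * lower.delta_eps + w * upper.delta_eps,
        tau_s=(1 - w) * lower.tau_s + w * upper.tau_s,
        sigma_s=(1 - w) * lower.sigma_s + w * upper.sigma_s,
    )


def apply_property_level(
    params: DebyeParameters, level: PropertyLevel
) -> DebyeParameters:
    """Scale a property curve by a contrast level.

    ``eps_inf``, ``delta_eps`` and ``sigma_s`` are multiplied by the level's
    scale while ``tau_s`` is untouched, so the complex permittivity curve is
    scaled uniformly at every frequency.
    """
    if level.scale == 1.0:
        return params
    return DebyeParameters(
        eps_inf=params.eps_inf * level.scale,
        delta_eps=params.delta_eps * level.scale,
        tau_s=params.tau_s,
        sigma_s=params.sigma_s * level.scale,
    )


# Representative single-pole Debye parameter defaults for breast tissues in
# the microwave band (0.5-10 GHz), of the kind used throughout the microwave
# breast imaging literature.  These are editable placeholders: absolute
# values are a free configuration of the pipeline, only their structure
# (lower <= upper for the fibroglandular bounds) is relied upon.
_DEFAULT_TABLE: dict[str, dict] = {
    "skin": {
        "debye": {"eps_inf": 15.93, "delta_eps": 23.83, "tau_s": 13.0e-12, "sigma_s": 0.831},
        "intensity_range": [80.0, 160.0],
    },
    "fat": {
        "debye": {"eps_inf": 3.14, "delta_eps": 1.61, "tau_s": 14.65e-12, "sigma_s": 0.036},
        "intensity_range": [0.0, 100.0],
    },
    "fgt_lower": {
        "debye": {"eps_inf": 12.99, "delta_eps": 24.40, "tau_s": 13.0e-12, "sigma_s": 0.397},
        "intensity_range": [100.0, 300.0],
    },
    "fgt_upper": {
        "debye": {"eps_inf": 23.20, "delta_eps": 46.05, "tau_s": 13.0e-12, "sigma_s": 0.808},
        "intensity_range": [100.0, 300.0],
    },
    "tumour": {
        "debye": {"eps_inf": 23.20, "delta_eps": 48.38, "tau_s": 13.0e-12, "sigma_s": 0.827},
        "intensity_range": [200.0, 400.0],
    },
}

_REQUIRED_ROLES = ("skin", "fat", "fgt_lower", "fgt_upper", "tumour")


@dataclass
class ReferencePropertyTable:
    """Per-tissue Debye parameters and scan-intensity ranges.

    ``fgt_lower`` / ``fgt_upper`` are the bounding fibroglandular property
    curves of the linear mapping; both share the fibroglandular intensity
    range.  The table round-trips through a human-editable YAML config.
    """

    debye: dict[str, DebyeParameters]
    intensity_range: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for role in _REQUIRED_ROLES:
            if role not in self.debye:
                raise ValueError(f"incomplete property table: missing role {role!r}")
        for role, (lo, hi) in self.intensity_range.items():
            if not lo < hi:
                raise ValueError(
                    f"intensity range for {role!r} must satisfy lower < upper"
                )

    @classmethod
    def default(cls) -> "ReferencePropertyTable":
        return cls.from_dict(_DEFAULT_TABLE)

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping]) -> "ReferencePropertyTable":
        debye = {
            role: DebyeParameters(**entry["debye"]) for role, entry in data.items()
        }
        ranges = {
            role: (float(entry["intensity_range"][0]), float(entry["intensity_range"][1]))
            for role, entry in data.items()
            if "intensity_range" in entry
        }
        return cls(debye=debye, intensity_range=ranges)

    def to_dict(self) -> dict:
        out: dict[str, dict] = {}
        for role, p in self.debye.items():
            out[role] = {
                "debye": {
                    "eps_inf": p.eps_inf,
                    "delta_eps": p.delta_eps,
                    "tau_s": p.tau_s,
                    "sigma_s": p.sigma_s,
                }
            }
            if role in self.intensity_range:
                out[role]["intensity_range"] = list(self.intensity_range[role])
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferencePropertyTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def assign_properties(
    labelmap,
    stats,
    table: ReferencePropertyTable,
    level: PropertyLevel | str = "high",
    model_name: str | None = None,
):
    """Assign per-cluster Debye parameters via the linear mapping strategy.

    Skin, fat and tumour take their reference-table parameters directly.
    Each fibroglandular cluster's mean intensity is located within the
    fibroglandular intensity range to give a weight, which convexly mixes
    the lower- and upper-bound fibroglandular curves; the chosen contrast
    level then scales the result.  Returns a fully attributed
    :class:`~breastphantom.model.BreastModel`.
    """
    from .classification import classify_breast, compute_density
    from .model import CLASS_FOLDER_NAMES, BreastModel

    if isinstance(level, str):
        level = PROPERTY_LEVELS[level]
    role_to_table = {"skin": "skin", "fat": "fat", "tumour": "tumour"}
    fgt_range = table.intensity_range.get("fgt_lower") or table.intensity_range.get(
        "fgt_upper"
    )
    if fgt_range is None:
        raise ValueError("incomplete property table: no fibroglandular intensity range")

    properties: dict[int, DebyeParameters] = {}
    for label, role in labelmap.legend.items():
        if role == "background":
            continue
        if stats.voxel_count.get(label, 0) == 0:
            continue
        if role.startswith("fgt_"):
            w = map_intensity_to_weight(stats.mean_intensity[label], fgt_range)
            params = combine_property_curves(
                w, table.debye["fgt_lower"], table.debye["fgt_upper"]
            )
            properties[label] = apply_property_level(params, level)
        else:
            key = role_to_table.get(role)
            if key is None or key not in table.debye:
                raise ValueError(f"incomplete property table: missing role {role!r}")
            properties[label] = table.debye[key]

    density = compute_density(labelmap)
    breast_class = classify_breast(density)
    health = "diseased" if labelmap.tumour_label is not None else "healthy"
    if model_name is None:
        model_name = f"BM_{CLASS_FOLDER_NAMES[breast_class]}_001"
    attributes = {
        "breast_health": health,
        "breast_class": breast_class,
        "density_percent": density,
        "model_name": model_name,
        "n_fgt_clusters": len(labelmap.fgt_labels),
        "property_level": level.name,
        "voxel_size_mm": tuple(labelmap.spacing_mm),
    }
    return BreastModel(labelmap=labelmap, properties=properties, attributes=attributes)
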