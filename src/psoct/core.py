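"""Domain types for layered birefringent samples and PS-OCT imaging geometry.

The central objects are :class:`SampleModel` — an ordered stack of
:class:`LayerSpec` describing thickness (μm), attenuation coefficient
(mm⁻¹) and birefringence Δn per layer — and :class:`ImagingConfig`, the
scan geometry of a 1300-nm polarization-sensitive OCT system.  Uniaxial
stretch of a clamped elastomer slab is described by :class:`StretchState`
(the length ratio, elongated/original) and applied with
:func:`apply_stretch`: layer thicknesses thin as 1/ratio (incompressible
material, clamp width held fixed) and photoelastic layers acquire
stretch-induced birefringence from a :class:`StretchCalibration` curve.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MaterialSpec",
    "LayerSpec",
    "SampleModel",
    "ImagingConfig",
    "StretchState",
    "StretchCalibration",
    "CalibrationError",
    "PDMS",
    "DRAGON_SKIN",
    "apply_stretch",
    "evaluate_stretch_calibration",
    "default_stretch_calibration",
]

#: Largest |Δn| a layer may declare; an order of magnitude above the
#: strongest stretch-induced value ever reached in PDMS (2.1e-4).
MAX_ABS_BIREFRINGENCE = 5e-3


class CalibrationError(KeyError):
    """No calibration anchors available for a requested curing ratio."""


@dataclass(frozen=True)
class MaterialSpec:
    """An elastomer recipe.

    Parameters
    ----------
    name : str
        Label, e.g. ``"PDMS"`` or ``"DragonSkin"``.
    photoelastic : bool
        Whether stretch induces birefringence.  PDMS is photoelastic;
        Dragon Skin shows no stretch-induced birefringence and every
        stretch leaves its Δn at zero.
    curing_ratio : float
        Base:curing-agent weight ratio (15 means 15:1).  Controls
        crosslink density, stiffness and the photoelastic response.
    scatterer_weight_fraction : float
        TiO2 weight percent mixed in to set scattering (attenuation);
        decoupled from the photoelastic response.
    """

    name: str
    photoelastic: bool
    curing_ratio: float = 10.0
    scatterer_weight_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.curing_ratio <= 0:
            raise ValueError(f"curing_ratio must be > 0, got {self.curing_ratio}")
        if self.scatterer_weight_fraction < 0:
            raise ValueError("scatterer_weight_fraction must be >= 0")


def PDMS(curing_ratio: float, scatterer_weight_fraction: float = 0.0) -> MaterialSpec:
    """Photoelastic polydimethylsiloxane at the given curing ratio."""
    return MaterialSpec("PDMS", True, curing_ratio, scatterer_weight_fraction)


def DRAGON_SKIN(scatterer_weight_fraction: float = 0.0) -> MaterialSpec:
    """Dragon Skin silicone: elastic but with no stretch-induced birefringence."""
    return MaterialSpec("DragonSkin", False, 1.0, scatterer_weight_fraction)


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a sample: geometry plus optical properties.

    ``thickness_um`` is the physical thickness in the current stretch
    state; ``attenuation_mm`` is the one-way exponential intensity decay
    coefficient in mm⁻¹; ``birefringence`` is the dimensionless Δn
    (0 for isotropic layers, negative values allowed for completeness).
    """

    name: str
    thickness_um: float
    attenuation_mm: float
    birefringence: float = 0.0
    material: MaterialSpec = field(default_factory=lambda: DRAGON_SKIN())

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if self.attenuation_mm < 0:
            raise ValueError(f"layer {self.name!r}: attenuation must be >= 0")
        if abs(self.birefringence) > MAX_ABS_BIREFRINGENCE:
            raise ValueError(
                f"layer {self.name!r}: |birefringence| exceeds {MAX_ABS_BIREFRINGENCE}"
            )


@dataclass
class SampleModel:
    """A layered sample: top layer first, plus bulk geometry.

    ``surface_profile`` holds per-lateral-column surface height offsets in
    μm of air path above the nominal zero depth (all zero = flat,
    untilted surface).  ``width_L1_mm`` is the clamp-contact width and
    ``relaxed_thickness_L2_0_mm`` the relaxed total thickness; together
    they define the cross-sectional area used for stress (σ = P / (L1·L2,0)).
    """

    layers: list[LayerSpec]
    refractive_index: float = 1.4
    surface_profile: np.ndarray | None = None
    width_L1_mm: float = 10.0
    relaxed_thickness_L2_0_mm: float = 1.5

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("SampleModel needs at least one layer")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.surface_profile is not None:
            self.surface_profile = np.asarray(self.surface_profile, dtype=float)
            if self.surface_profile.ndim != 1:
                raise ValueError("surface_profile must be 1-D (per lateral column)")

    @property
    def total_thickness_um(self) -> float:
        """Total physical thickness: the sum of the layer thicknesses."""
        return float(sum(l.thickness_um for l in self.layers))

    def layer_boundaries_um(self) -> np.ndarray:
        """Cumulative physical depths of layer interfaces, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([l.thickness_um for l in self.layers])])

    def surface_offsets_um(self, n_columns: int) -> np.ndarray:
        """Per-column surface offsets, broadcast to ``n_columns``."""
        if self.surface_profile is None:
            return np.zeros(n_columns)
        if self.surface_profile.size == n_columns:
            return self.surface_profile
        if self.surface_profile.size == 1:
            return np.full(n_columns, float(self.surface_profile[0]))
        raise ValueError(
            f"surface_profile has {self.surface_profile.size} columns, image has {n_columns}"
        )


@dataclass(frozen=True)
class ImagingConfig:
    """Scan geometry of the PS-OCT system.

    The depth axis is sampled in optical path length: one pixel spans
    ``axial_pixel_spacing_air_um`` of optical path, so a physical depth z
    inside a medium of index n falls on pixel round(n·z / spacing).  The
    default spacing, 2.75 μm, is half the 5.5-μm axial resolution of the
    emulated 1300-nm system; lateral spacing defaults to the 7.8-μm
    lateral resolution.
    """

    wavelength_nm: float = 1300.0
    axial_pixel_spacing_air_um: float = 2.75
    lateral_pixel_spacing_um: float = 7.8
    depth_pixels: int = 1200
    lateral_pixels: int = 320
    max_imaging_depth_um: float | None = None
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be > 0")
        if self.axial_pixel_spacing_air_um <= 0 or self.lateral_pixel_spacing_um <= 0:
            raise ValueError("pixel spacings must be > 0")
        if self.depth_pixels < 1 or self.lateral_pixels < 1:
            raise ValueError("image dimensions must be >= 1 pixel")
        window = self.depth_pixels * self.axial_pixel_spacing_air_um
        if self.max_imaging_depth_um is None:
            object.__setattr__(self, "max_imaging_depth_um", window)
        elif window < self.max_imaging_depth_um:
            raise ValueError(
                "depth_pixels x axial_pixel_spacing_air_um must cover max_imaging_depth_um"
            )


@dataclass(frozen=True)
class StretchState:
    """Uniaxial clamp stretch: elongated vs original clamp separation."""

    elongated_length_mm: float
    original_length_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.original_length_mm <= 0:
            raise ValueError("original_length must be > 0")
        if self.elongated_length_mm < self.original_length_mm:
            raise ValueError("length_ratio must be >= 1 (no compression)")

    @property
    def length_ratio(self) -> float:
        return self.elongated_length_mm / self.original_length_mm

    @classmethod
    def from_ratio(cls, length_ratio: float, original_length_mm: float = 6.0) -> "StretchState":
        return cls(length_ratio * original_length_mm, original_length_mm)


class StretchCalibration:
    """Piecewise-linear Δn vs length-ratio anchors, one curve per curing ratio.

    Anchors are (length_ratio, Δn) pairs.  Each curve must contain the
    relaxed point (1, 0) and is interpolated linearly between anchors;
    queries outside the anchored range raise (clamp slipping limits the
    reachable stretch differently per curing ratio, so extrapolation is
    refused rather than guessed).
    """

    def __init__(self, anchors: dict[float, Sequence[tuple[float, float]]]):
        self._anchors: dict[float, np.ndarray] = {}
        for ratio, pts in anchors.items():
            arr = np.asarray(sorted(pts), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"curing ratio {ratio}: need >= 2 (length_ratio, dn) anchors")
            if not np.any((arr[:, 0] == 1.0) & (arr[:, 1] == 0.0)):
                raise ValueError(f"curing ratio {ratio}: anchors must include (1, 0)")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"curing ratio {ratio}: duplicate length-ratio anchors")
            self._anchors[float(ratio)] = arr

    @property
    def curing_ratios(self) -> list[float]:
        return sorted(self._anchors)

    def anchors(self, curing_ratio: float) -> np.ndarray:
        try:
            return self._anchors[float(curing_ratio)].copy()
        except KeyError:
            raise CalibrationError(
                f"no stretch calibration for curing ratio {curing_ratio}:1"
            ) from None

    def delta_n(self, curing_ratio: float, length_ratio: float) -> float:
        """Interpolated induced Δn; exact at anchors, 0 at length ratio 1."""
        arr = self.anchors(curing_ratio)
        lo, hi = arr[0, 0], arr[-1, 0]
        if not (lo <= length_ratio <= hi):
            raise ValueError(
                f"length ratio {length_ratio} outside calibrated range "
                f"[{lo}, {hi}] for curing ratio {curing_ratio}:1 (no extrapolation)"
            )
        return float(np.interp(length_ratio, arr[:, 0], arr[:, 1]))

    def to_dict(self) -> dict[float, list[list[float]]]:
        return {cr: arr.tolist() for cr, arr in self._anchors.items()}


#: Default stretch-calibration anchors.  Only two facts are measured:
#: every curve passes through (1, 0), and the 20:1 recipe reaches
#: Δn = 2.1e-4 at a length ratio of ~5 (the largest induced value
#: observed).  All other anchor points are SYNTHETIC placeholders that
#: reproduce the qualitative trends — lower curing ratios stiffen, gain
#: birefringence faster with stretch, and slip out of the clamps sooner —
#: and should be replaced with user measurements for quantitative work.
_DEFAULT_ANCHORS: dict[float, list[tuple[float, float]]] = {
    10.0: [(1.0, 0.0), (1.4, 0.8e-4), (1.8, 1.5e-4)],
    15.0: [(1.0, 0.0), (1.5, 0.7e-4), (2.0, 1.01e-4), (2.5, 1.4e-4)],
    20.0: [(1.0, 0.0), (2.0, 0.5e-4), (3.0, 1.0e-4), (4.0, 1.6e-4), (5.0, 2.1e-4)],
    25.0: [(1.0, 0.0), (2.0, 0.4e-4), (3.0, 0.8e-4), (4.0, 1.2e-4), (5.0, 1.7e-4)],
}


def default_stretch_calibration() -> StretchCalibration:
    """Default anchor table (synthetic except (1,0) and the 20:1 maximum)."""
    return StretchCalibration(_DEFAULT_ANCHORS)


def evaluate_stretch_calibration(
    calibration: StretchCalibration, curing_ratio: float, length_ratio: float
) -> float:
    """Induced Δn for a curing ratio at a length ratio (interpolated)."""
    return calibration.delta_n(curing_ratio, length_ratio)


def apply_stretch(
    model: SampleModel,
    stretch: StretchState,
    calibration: StretchCalibration | None = None,
) -> SampleModel:
    """Return the sample as it appears under uniaxial stretch.

    The clamps hold the width fixed and the material is incompressible,
    so all thinning goes into the thickness: every layer's thickness is
    divided by the length ratio.  Photoelastic layers take their Δn from
    the calibration curve at (curing_ratio, length_ratio);
    non-photoelastic layers stay at Δn = 0.  Attenuation coefficients are
    unchanged.  A length ratio of exactly 1 is the identity.
    """
    ratio = stretch.length_ratio
    if ratio < 1:
        raise ValueError("length_ratio must be >= 1")
    if ratio == 1.0:
        return copy.deepcopy(model)

    new_layers = []
    for layer in model.layers:
        if layer.material.photoelastic:
            if calibration is None:
                raise CalibrationError(
                    f"layer {layer.name!r} is photoelastic but no calibration was given"
                )
            dn = calibration.delta_n(layer.material.curing_ratio, ratio)
        else:
            dn = 0.0
        new_layers.append(
            replace(layer, thickness_um=layer.thickness_um / ratio, birefringence=dn)
        )
    stretched = copy.deepcopy(model)
    stretched.layers = new_layers
    return stretched
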