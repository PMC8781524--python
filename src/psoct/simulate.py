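"""Forward PS-OCT B-scan simulator for layered birefringent samples.

Produces co-registered intensity and cumulative-retardation images from a
:class:`~psoct.core.SampleModel`.  The intensity channel follows one-way
Beer–Lambert decay with per-layer attenuation coefficients and optional
unit-mean exponential speckle; the retardation channel accumulates phase
as delta = 2*pi*dn*z/lambda per layer (z = one-way physical path in the
layer), is expressed in degrees, given additive Gaussian noise, and
folded into [0, 90] deg by triangle-wave reflection — the standard
display convention for PS-OCT retardation maps.

The depth axis is sampled in optical path: a physical depth z inside a
medium of refractive index n lands on pixel round(n*z / axial spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import (
    DRAGON_SKIN,
    PDMS,
    ImagingConfig,
    LayerSpec,
    SampleModel,
)

__all__ = [
    "NoiseModel",
    "BScanPair",
    "fold_retardation",
    "simulate_bscan",
    "make_bladder_model",
    "make_slab_model",
    "simulate_manipulation_scene",
    "BLADDER_DELTA_N",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise configuration for the simulator.

    speckle_enabled multiplies the in-sample linear intensity by
    unit-mean exponential deviates (fully developed speckle);
    retardation_noise_sd_deg is the s.d. of additive Gaussian noise on
    the retardation in degrees (applied before folding);
    background_level is the intensity of pixels outside the sample.
    """

    speckle_enabled: bool = True
    retardation_noise_sd_deg: float = 2.0
    background_level: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.retardation_noise_sd_deg < 0:
            raise ValueError("retardation_noise_sd_deg must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")

    @classmethod
    def off(cls, background_level: float = 0.0) -> "NoiseModel":
        """Noise-free configuration (for deterministic round-trip checks)."""
        return cls(False, 0.0, background_level, 0)


@dataclass
class BScanPair:
    """Co-registered intensity and retardation B-scans.

    intensity: linear arbitrary units, >= 0; retardation: degrees in
    [0, 90]; both (depth_pixels x lateral_pixels).
    """

    intensity: np.ndarray
    retardation: np.ndarray
    config: ImagingConfig
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.retardation = np.asarray(self.retardation, dtype=np.float64)
        if self.intensity.shape != self.retardation.shape:
            raise ValueError("intensity and retardation must share shape")
        if self.intensity.ndim != 2:
            raise ValueError("B-scans must be 2-D (depth x lateral)")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be >= 0 everywhere")
        if np.any((self.retardation < 0) | (self.retardation > 90)):
            raise ValueError("retardation must lie in [0, 90] degrees")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


def fold_retardation(delta_deg: np.ndarray) -> np.ndarray:
    """Fold unbounded phase (degrees) into [0, 90] by triangle reflection.

    The map has period 180 deg and reflects at 0 and 90, matching how
    PS-OCT systems display cumulative retardation.
    """
    y = np.mod(np.asarray(delta_deg, dtype=float), 180.0)
    return np.where(y > 90.0, 180.0 - y, y)


def _column_depth_tables(model: SampleModel, wavelength_nm: float):
    """Piecewise-linear knots for cumulative attenuation and phase vs physical depth.

    Returns (z_knots_um, cum_atten_ln, cum_phase_deg) where cum_atten_ln
    is the accumulated mu*path (natural-log units, path in mm) and
    cum_phase_deg the accumulated 2*pi*dn*z/lambda expressed in degrees.
    Both are exactly linear within a layer, so np.interp evaluates them
    exactly at any depth.
    """
    thicknesses = np.array([l.thickness_um for l in model.layers])
    z_knots = np.concatenate([[0.0], np.cumsum(thicknesses)])
    mus = np.array([l.attenuation_mm for l in model.layers])
    dns = np.array([l.birefringence for l in model.layers])
    cum_atten = np.concatenate([[0.0], np.cumsum(mus * thicknesses * 1e-3)])
    # degrees per um of path in layer i: 360 * dn_i / lambda_um
    deg_per_um = 360.0 * dns / (wavelength_nm * 1e-3)
    cum_phase = np.concatenate([[0.0], np.cumsum(deg_per_um * thicknesses)])
    return z_knots, cum_atten, cum_phase


def _noise_free_column(
    model: SampleModel, config: ImagingConfig, surface_row: int, i0: float
):
    """Noise-free intensity / phase profile of one A-scan, plus in-sample mask."""
    rows = np.arange(config.depth_pixels)
    optical_below_um = (rows - surface_row) * config.axial_pixel_spacing_air_um
    z_phys = optical_below_um / model.refractive_index
    z_knots, cum_atten, cum_phase = _column_depth_tables(model, config.wavelength_nm)
    in_sample = (z_phys >= 0.0) & (z_phys <= z_knots[-1])
    zc = np.clip(z_phys, 0.0, z_knots[-1])
    intensity = i0 * np.exp(-np.interp(zc, z_knots, cum_atten))
    phase = np.interp(zc, z_knots, cum_phase)
    return intensity, phase, in_sample


def simulate_bscan(
    model: SampleModel | Sequence[SampleModel],
    config: ImagingConfig,
    noise: NoiseModel | None = None,
    i0: float = 1.0,
) -> BScanPair:
    """Simulate a co-registered intensity/retardation B-scan pair.

    ``model`` is either a single :class:`SampleModel` applied to every
    lateral column or a sequence of per-column models (laterally varying
    scenes, e.g. a manipulation site).  Pixels above the surface, or
    below the bottom of the layer stack, carry the background intensity
    and retardation noise only.  With identical seed and inputs the
    output is bit-identical.
    """
    if noise is None:
        noise = NoiseModel()

    if isinstance(model, SampleModel):
        models: Sequence[SampleModel] = [model]
        per_column = False
    else:
        models = list(model)
        per_column = True
        if len(models) != config.lateral_pixels:
            raise ValueError(
                f"need one model per lateral column ({config.lateral_pixels}), got {len(models)}"
            )

    ref = models[0]
    optical_depth_um = ref.total_thickness_um * ref.refractive_index
    offsets = ref.surface_offsets_um(config.lateral_pixels)
    max_offset_px = int(np.max(np.round(offsets / config.axial_pixel_spacing_air_um)))
    if optical_depth_um > config.max_imaging_depth_um - max_offset_px * config.axial_pixel_spacing_air_um:
        raise ValueError(
            f"layer stack ({optical_depth_um:.0f} um optical + surface offset) "
            f"exceeds the imaging window ({config.max_imaging_depth_um:.0f} um)"
        )

    shape = (config.depth_pixels, config.lateral_pixels)
    intensity = np.empty(shape)
    phase = np.empty(shape)
    in_sample = np.empty(shape, dtype=bool)

    surface_rows = np.round(offsets / config.axial_pixel_spacing_air_um).astype(int)
    if per_column:
        for c in range(config.lateral_pixels):
            icol, pcol, mcol = _noise_free_column(models[c], config, surface_rows[c], i0)
            intensity[:, c], phase[:, c], in_sample[:, c] = icol, pcol, mcol
    else:
        # group columns sharing a surface row; profile identical within a group
        for row in np.unique(surface_rows):
            cols = np.nonzero(surface_rows == row)[0]
            icol, pcol, mcol = _noise_free_column(ref, config, int(row), i0)
            intensity[:, cols] = icol[:, None]
            phase[:, cols] = pcol[:, None]
            in_sample[:, cols] = mcol[:, None]

    rng = np.random.default_rng(noise.seed)
    if noise.speckle_enabled:
        intensity = intensity * rng.exponential(1.0, size=shape)
    intensity = np.where(in_sample, intensity, noise.background_level)

    phase = np.where(in_sample, phase, 0.0)
    if noise.retardation_noise_sd_deg > 0:
        phase = phase + rng.normal(0.0, noise.retardation_noise_sd_deg, size=shape)
    retardation = fold_retardation(phase)

    return BScanPair(intensity, retardation, config, provenance="simulated")


# ---------------------------------------------------------------------------
# Bladder-wall design models
# ---------------------------------------------------------------------------

#: Default per-layer birefringence of the bladder design models.  The
#: normal-LP and CIS fused-layer values are measured ex vivo tissue means;
#: the urothelium is a non-birefringent cell layer; the MP default is the
#: achieved normal-phantom MP value (tissue MP sits beyond reliable
#: imaging depth, and CIS does not invade the muscle, so both conditions
#: share it).
BLADDER_DELTA_N = {
    "urothelium": 0.0,
    "LP": 1.18e-4,
    "fused": 3.21e-5,
    "MP": 4.50e-5,
}

#: Length ratio at which the design models are imaged (the final phantoms
#: were imaged stretched to a length ratio of roughly four).
DESIGN_LENGTH_RATIO = 4.0

#: Per-layer birefringence actually achieved in the fabricated reference
#: phantoms (as opposed to the tissue-mean design defaults above); used
#: by the demo workflow so the simulated phantom matches what a built
#: phantom measures.
ACHIEVED_PHANTOM_DELTA_N = {
    "normal": {"urothelium": 3.11e-7, "LP": 1.05e-4, "MP": 4.50e-5},
    "diseased": {"fused": 4.61e-6, "MP": 3.59e-5},
}


def make_bladder_model(
    condition: str,
    stretched: bool = True,
    delta_n: dict[str, float] | None = None,
    surface_profile: np.ndarray | None = None,
) -> SampleModel:
    """Bladder-wall phantom design model, normal or diseased.

    Normal: urothelium 50 μm (AC 0.8 mm⁻¹, Δn 0, Dragon Skin), lamina
    propria 400 μm (AC 3.5, Δn 1.18e-4, 15:1 PDMS), muscularis propria
    1600 μm (AC 1.5, 25:1 PDMS).  Diseased (CIS): the urothelium and LP
    lose their stratification and appear as a single 450-μm fused layer
    with near-zero birefringence and graded attenuation (2.2 mm⁻¹ at the
    top to 1.8 near the MP, modelled as two sublayers); the MP is
    unchanged.  ``delta_n`` overrides the per-layer defaults by name
    (``"fused"`` covers both sublayers).  With ``stretched=False`` the
    relaxed fabrication geometry is returned: thicknesses multiplied by
    the design length ratio and photoelastic Δn reset to zero.
    """
    dn = dict(BLADDER_DELTA_N)
    if delta_n:
        unknown = set(delta_n) - set(dn)
        if unknown:
            raise ValueError(f"unknown layer names in delta_n override: {sorted(unknown)}")
        dn.update(delta_n)

    if condition == "normal":
        layers = [
            LayerSpec("urothelium", 50.0, 0.8, dn["urothelium"], DRAGON_SKIN(0.04)),
            LayerSpec("LP", 400.0, 3.5, dn["LP"], PDMS(15.0, 0.3)),
            LayerSpec("MP", 1600.0, 1.5, dn["MP"], PDMS(25.0, 0.15)),
        ]
    elif condition == "diseased":
        layers = [
            LayerSpec("fused_upper", 225.0, 2.2, dn["fused"], DRAGON_SKIN(0.2)),
            LayerSpec("fused_lower", 225.0, 1.8, dn["fused"], DRAGON_SKIN(0.15)),
            LayerSpec("MP", 1600.0, 1.5, dn["MP"], PDMS(25.0, 0.15)),
        ]
    else:
        raise ValueError(f"condition must be 'normal' or 'diseased', got {condition!r}")

    if not stretched:
        layers = [
            replace(
                l,
                thickness_um=l.thickness_um * DESIGN_LENGTH_RATIO,
                birefringence=0.0 if l.material.photoelastic else l.birefringence,
            )
            for l in layers
        ]

    return SampleModel(layers=layers, surface_profile=surface_profile)


def make_slab_model(
    thickness_um: float,
    attenuation_mm: float = 2.0,
    birefringence: float = 0.0,
    curing_ratio: float = 15.0,
    surface_profile: np.ndarray | None = None,
    refractive_index: float = 1.4,
) -> SampleModel:
    """Single-layer PDMS slab, the workhorse of stretch characterization."""
    layer = LayerSpec(
        "slab", thickness_um, attenuation_mm, birefringence, PDMS(curing_ratio, 0.3)
    )
    return SampleModel(
        layers=[layer],
        refractive_index=refractive_index,
        surface_profile=surface_profile,
        relaxed_thickness_L2_0_mm=thickness_um * 1e-3,
    )


def simulate_manipulation_scene(
    base: SampleModel,
    site_column: int,
    affected_halfwidth: int,
    delta_n_factor: float,
    n_columns: int,
) -> list[SampleModel]:
    """Per-column models for a tool-manipulation scene.

    Columns within ±affected_halfwidth of ``site_column`` carry every
    layer's birefringence multiplied by ``delta_n_factor`` (pressing on a
    stretched photoelastic slab locally raises the retardation growth
    along the manipulation axis); all other columns are the base model.
    """
    if delta_n_factor < 1:
        raise ValueError("delta_n_factor must be >= 1")
    if not (0 <= site_column < n_columns):
        raise ValueError(f"site_column {site_column} outside image (0..{n_columns - 1})")

    affected = replace_birefringence(base, delta_n_factor)
    return [
        affected if abs(c - site_column) <= affected_halfwidth else base
        for c in range(n_columns)
    ]


def replace_birefringence(model: SampleModel, factor: float) -> SampleModel:
    """Copy of ``model`` with every layer's Δn multiplied by ``factor``."""
    import copy as _copy

    out = _copy.deepcopy(model)
    out.layers = [
        replace(l, birefringence=l.birefringence * factor) for l in model.layers
    ]
    return out
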