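"""Reading and writing the package's on-disk formats.

Sample models, imaging configs, noise settings and stretch calibrations
share one YAML dialect (round-trippable, JSON-compatible mapping
structure).  B-scan pairs are stored as two-page 32-bit-float TIFF
stacks (page 1 intensity, page 2 retardation in degrees) with a YAML
sidecar carrying the imaging config and provenance.  Tables (segmentation,
profiles, per-layer estimates, campaigns) are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    ImagingConfig,
    LayerSpec,
    MaterialSpec,
    SampleModel,
    StretchCalibration,
)
from .fitting import BirefringenceEstimate, RetardationProfile
from .mechanics import CharacterizationCurve, StretchExperiment
from .segmentation import SurfaceSegmentation
from .simulate import BScanPair, NoiseModel

__all__ = [
    "sample_to_dict",
    "sample_from_dict",
    "save_config",
    "load_config",
    "write_bscan_pair",
    "read_bscan_pair",
    "segmentation_to_frame",
    "profile_to_frame",
    "estimates_to_frame",
    "experiments_to_frame",
]


# ---------------------------------------------------------------------------
# YAML configuration dialect
# ---------------------------------------------------------------------------

def _material_to_dict(m: MaterialSpec) -> dict:
    return {
        "name": m.name,
        "photoelastic": m.photoelastic,
        "curing_ratio": m.curing_ratio,
        "scatterer_weight_fraction": m.scatterer_weight_fraction,
    }


def sample_to_dict(model: SampleModel) -> dict:
    d = {
        "refractive_index": model.refractive_index,
        "width_L1_mm": model.width_L1_mm,
        "relaxed_thickness_L2_0_mm": model.relaxed_thickness_L2_0_mm,
        "layers": [
            {
                "name": l.name,
                "thickness_um": l.thickness_um,
                "attenuation_mm": l.attenuation_mm,
                "birefringence": l.birefringence,
                "material": _material_to_dict(l.material),
            }
            for l in model.layers
        ],
    }
    if model.surface_profile is not None:
        d["surface_profile_um"] = [float(v) for v in model.surface_profile]
    return d


def sample_from_dict(d: dict) -> SampleModel:
    layers = [
        LayerSpec(
            name=l["name"],
            thickness_um=float(l["thickness_um"]),
            attenuation_mm=float(l["attenuation_mm"]),
            birefringence=float(l.get("birefringence", 0.0)),
            material=MaterialSpec(**l["material"]),
        )
        for l in d["layers"]
    ]
    profile = d.get("surface_profile_um")
    return SampleModel(
        layers=layers,
        refractive_index=float(d.get("refractive_index", 1.4)),
        surface_profile=np.asarray(profile, float) if profile is not None else None,
        width_L1_mm=float(d.get("width_L1_mm", 10.0)),
        relaxed_thickness_L2_0_mm=float(d.get("relaxed_thickness_L2_0_mm", 1.5)),
    )


def _imaging_to_dict(c: ImagingConfig) -> dict:
    return {
        "wavelength_nm": c.wavelength_nm,
        "axial_pixel_spacing_air_um": c.axial_pixel_spacing_air_um,
        "lateral_pixel_spacing_um": c.lateral_pixel_spacing_um,
        "depth_pixels": c.depth_pixels,
        "lateral_pixels": c.lateral_pixels,
        "max_imaging_depth_um": c.max_imaging_depth_um,
        "noise_seed": c.noise_seed,
    }


def save_config(
    path: str | Path,
    sample: SampleModel | None = None,
    imaging: ImagingConfig | None = None,
    noise: NoiseModel | None = None,
    calibration: StretchCalibration | None = None,
) -> None:
    """Write any subset of sample / imaging / noise / calibration to one YAML file."""
    doc: dict = {}
    if sample is not None:
        doc["sample"] = sample_to_dict(sample)
    if imaging is not None:
        doc["imaging"] = _imaging_to_dict(imaging)
    if noise is not None:
        doc["noise"] = {
            "speckle_enabled": noise.speckle_enabled,
            "retardation_noise_sd_deg": noise.retardation_noise_sd_deg,
            "background_level": noise.background_level,
            "seed": noise.seed,
        }
    if calibration is not None:
        doc["calibration"] = {
            str(cr): [[float(a), float(b)] for a, b in pts]
            for cr, pts in calibration.to_dict().items()
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> dict:
    """Read a YAML config; returns a dict with any of the keys
    ``sample`` (SampleModel), ``imaging`` (ImagingConfig), ``noise``
    (NoiseModel), ``calibration`` (StretchCalibration)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    if "sample" in doc:
        out["sample"] = sample_from_dict(doc["sample"])
    if "imaging" in doc:
        out["imaging"] = ImagingConfig(**doc["imaging"])
    if "noise" in doc:
        out["noise"] = NoiseModel(**doc["noise"])
    if "calibration" in doc:
        out["calibration"] = StretchCalibration(
            {float(cr): [tuple(p) for p in pts] for cr, pts in doc["calibration"].items()}
        )
    return out


# ---------------------------------------------------------------------------
# B-scan image stacks
# ---------------------------------------------------------------------------

def write_bscan_pair(path: str | Path, pair: BScanPair) -> None:
    """Two-page float32 TIFF (intensity, retardation) + YAML sidecar."""
    path = Path(path)
    stack = np.stack(
        [pair.intensity.astype(np.float32), pair.retardation.astype(np.float32)]
    )
    tifffile.imwrite(path, stack)
    sidecar = {
        "imaging": _imaging_to_dict(pair.config),
        "provenance": pair.provenance,
        "pages": ["intensity_linear_au", "retardation_deg"],
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_bscan_pair(path: str | Path) -> BScanPair:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a two-page (intensity, retardation) stack")
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    config = ImagingConfig(**sidecar["imaging"])
    return BScanPair(
        stack[0].astype(np.float64),
        stack[1].astype(np.float64),
        config,
        provenance=sidecar.get("provenance", "imported"),
    )


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

def segmentation_to_frame(seg: SurfaceSegmentation) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "column": np.arange(seg.top_index.size),
            "top": seg.top_index,
            "bottom": seg.bottom_index,
            "max_depth": seg.max_detection_depth,
            "valid": seg.valid,
        }
    )


def profile_to_frame(profile: RetardationProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {"depth_um": profile.depth_um, "retardation_deg": profile.mean_retardation_deg}
    )


def estimates_to_frame(
    estimates: dict[str, BirefringenceEstimate | None], sample_id: str = "sample"
) -> pd.DataFrame:
    rows = []
    for layer, est in estimates.items():
        if est is None:
            rows.append(
                {"sample_id": sample_id, "layer": layer, "delta_n": np.nan,
                 "delta_n_se": np.nan, "slope_deg_per_um": np.nan,
                 "r_squared": np.nan, "n_points": 0,
                 "window_lo_um": np.nan, "window_hi_um": np.nan}
            )
        else:
            rows.append(
                {"sample_id": sample_id, "layer": layer, "delta_n": est.delta_n,
                 "delta_n_se": np.nan if est.delta_n_se is None else est.delta_n_se,
                 "slope_deg_per_um": est.slope_deg_per_um, "r_squared": est.r_squared,
                 "n_points": est.n_points, "window_lo_um": est.fit_window_um[0],
                 "window_hi_um": est.fit_window_um[1]}
            )
    return pd.DataFrame(rows)


def experiments_to_frame(experiments: list[StretchExperiment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "curing_ratio": [e.curing_ratio for e in experiments],
            "length_ratio": [e.length_ratio for e in experiments],
            "replicate": [e.replicate_id for e in experiments],
            "delta_n": [e.measured_delta_n for e in experiments],
            "stress_Pa": [e.stress_Pa for e in experiments],
        }
    )
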