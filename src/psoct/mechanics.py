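"""Stress computation and stretch-characterization campaigns.

Engineering stress is force over the relaxed cross-section,
sigma = P / (L1 * L2_0), with L1 the clamp-contact width (held fixed by
the clamps throughout a stretch series) and L2_0 the relaxed thickness.
A characterization campaign images a slab at a ladder of length ratios
(clamp separation advanced in 2.5-mm increments from a 6-mm original
length, in the reference protocol), extracts the birefringence at each
stretch through the full segmentation + slope-fit pipeline, and
aggregates replicate statistics into a Δn-vs-length-ratio curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ImagingConfig, SampleModel, StretchCalibration, StretchState, apply_stretch
from .fitting import estimate_retardation_noise, fit_birefringence, lateral_average
from .segmentation import detect_surfaces, flatten
from .simulate import NoiseModel, simulate_bscan

__all__ = [
    "StretchExperiment",
    "CharacterizationCurve",
    "compute_stress",
    "build_characterization_curve",
    "run_stretch_campaign",
]


def compute_stress(force_N: float, width_L1_mm: float, initial_thickness_mm: float) -> float:
    """Engineering stress sigma = P / (L1 * L2_0) in Pa (area in mm² → m²)."""
    if force_N < 0:
        raise ValueError("force must be >= 0")
    if width_L1_mm <= 0 or initial_thickness_mm <= 0:
        raise ValueError("clamp width and relaxed thickness must be > 0")
    area_m2 = width_L1_mm * initial_thickness_mm * 1e-6
    return force_N / area_m2


@dataclass(frozen=True)
class StretchExperiment:
    """One imaging of a stretched slab: geometry, force and measured Δn."""

    stretch: StretchState
    force_N: float
    width_L1_mm: float
    initial_thickness_L2_0_mm: float
    measured_delta_n: float
    replicate_id: int
    curing_ratio: float

    @property
    def stress_Pa(self) -> float:
        return compute_stress(self.force_N, self.width_L1_mm, self.initial_thickness_L2_0_mm)

    @property
    def length_ratio(self) -> float:
        return self.stretch.length_ratio


@dataclass
class CharacterizationCurve:
    """Replicate-aggregated induced birefringence vs length ratio."""

    curing_ratio: float
    points: pd.DataFrame  # columns: length_ratio, mean_delta_n, sd_delta_n, n, mean_stress_Pa


def build_characterization_curve(
    experiments: list[StretchExperiment], curing_ratio: float
) -> CharacterizationCurve:
    """Group replicates by length ratio; mean and sample s.d. of Δn per point.

    All experiments must share the stated curing ratio (mixing curves
    from different recipes is an error, not an average).
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    ratios = {e.curing_ratio for e in experiments}
    if ratios != {curing_ratio}:
        raise ValueError(f"mixed or mismatched curing ratios in input: {sorted(ratios)}")

    df = pd.DataFrame(
        {
            "length_ratio": [e.length_ratio for e in experiments],
            "delta_n": [e.measured_delta_n for e in experiments],
            "stress_Pa": [e.stress_Pa for e in experiments],
        }
    )
    g = df.groupby("length_ratio", sort=True)
    points = pd.DataFrame(
        {
            "length_ratio": g.size().index,
            "mean_delta_n": g["delta_n"].mean().values,
            # sample (n-1) s.d.; a single replicate has no spread
            "sd_delta_n": g["delta_n"].std(ddof=1).fillna(0.0).values,
            "n": g.size().values,
            "mean_stress_Pa": g["stress_Pa"].mean().values,
        }
    ).reset_index(drop=True)
    return CharacterizationCurve(curing_ratio, points)


def _synthetic_force(
    length_ratio: float, width_mm: float, thickness_mm: float, modulus_Pa: float
) -> float:
    """SYNTHETIC linear stress–stretch toy law: sigma = E * (ratio - 1).

    No constitutive law is measured for the phantoms; force enters the
    analysis only as the x-axis of Δn-vs-stress plots, so a linear
    placeholder with a configurable effective modulus is used.
    """
    sigma = modulus_Pa * (length_ratio - 1.0)
    return sigma * width_mm * thickness_mm * 1e-6


def run_stretch_campaign(
    model: SampleModel,
    calibration: StretchCalibration,
    ratios: list[float],
    repeats: int,
    config: ImagingConfig,
    noise: NoiseModel,
    original_length_mm: float = 6.0,
    modulus_Pa: float = 5e4,
    surface_skip_um: float = 10.0,
) -> list[StretchExperiment]:
    """Simulate a full stretch-characterization campaign on one slab.

    For every length ratio and replicate: stretch the model, simulate a
    B-scan with a fresh replicate seed, segment, flatten, laterally
    average, fit the retardation slope over the visible slab, and record
    a :class:`StretchExperiment`.  Seeds derive deterministically from
    ``noise.seed`` so the campaign is reproducible.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    curing = model.layers[0].material.curing_ratio
    width = model.width_L1_mm
    thickness0 = model.relaxed_thickness_L2_0_mm

    ss = np.random.SeedSequence(noise.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(ratios) * repeats)]

    experiments = []
    k = 0
    for ratio in ratios:
        stretch = StretchState.from_ratio(ratio, original_length_mm)
        stretched = apply_stretch(model, stretch, calibration)
        force = _synthetic_force(ratio, width, thickness0, modulus_Pa)
        for rep in range(repeats):
            nm = NoiseModel(
                noise.speckle_enabled,
                noise.retardation_noise_sd_deg,
                noise.background_level,
                seeds[k],
            )
            k += 1
            pair = simulate_bscan(stretched, config, nm)
            seg = detect_surfaces(pair)
            flat = flatten(pair, seg)
            sd = (
                estimate_retardation_noise(pair.retardation, seg.top_index, seg.valid)
                if nm.retardation_noise_sd_deg > 0
                else 0.0
            )
            extents = seg.depth_extent()
            max_px = int(np.median(extents[seg.valid]))
            profile = lateral_average(
                flat, refractive_index=stretched.refractive_index, max_depth_px=max_px
            )
            window = (surface_skip_um, float(profile.depth_um[-1]) + 1.0)
            est = fit_birefringence(profile, config, window, noise_sd_deg=sd)
            experiments.append(
                StretchExperiment(
                    stretch=stretch,
                    force_N=force,
                    width_L1_mm=width,
                    initial_thickness_L2_0_mm=thickness0,
                    measured_delta_n=est.delta_n,
                    replicate_id=rep,
                    curing_ratio=curing,
                )
            )
    return experiments
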