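"""Birefringence extraction from flattened retardation B-scans.

Cumulative retardation grows linearly with depth at constant
birefringence, delta = 2*pi*dn*z/lambda, so dn is recovered from the
slope of a straight line fitted to the laterally averaged retardation
profile: slope (deg/um of physical depth) is converted to rad/m and
dn = slope_rad_per_m * lambda / (2*pi).  Negative slopes yield negative
dn estimates (reported, not clipped — thin near-zero layers routinely
fit slightly negative).

Because the displayed retardation is folded into [0, 90] deg, additive
measurement noise biases the mean upward wherever the true value sits
within about two noise s.d. of the 0 deg fold (E[fold(mu+eps)] > mu).
When the noise level sigma is known or estimated, the averaged profile
is therefore de-biased pointwise by inverting

    g(mu) = E[fold(mu + sigma*Z)] = mu + 2*[sigma*phi(mu/sigma)
            - mu*Phi(-mu/sigma)],   Z ~ N(0,1)

before the ordinary least-squares fit; with sigma = 0 this reduces to a
plain OLS fit on the raw profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ImagingConfig
from .segmentation import FlattenedBScan, pixels_to_physical_thickness

__all__ = [
    "RetardationProfile",
    "BirefringenceEstimate",
    "LayerWindows",
    "DEFAULT_TISSUE_WINDOWS",
    "bladder_windows",
    "lateral_average",
    "columns_for_extent",
    "fit_birefringence",
    "layer_birefringence",
    "percent_change",
    "fold_bias_mean",
    "fold_bias_correct",
    "estimate_retardation_noise",
]


@dataclass
class RetardationProfile:
    """Laterally averaged retardation vs physical depth below the surface."""

    depth_um: np.ndarray
    mean_retardation_deg: np.ndarray
    n_columns: int
    column_range_um: float

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.mean_retardation_deg = np.asarray(self.mean_retardation_deg, dtype=float)
        if self.depth_um.shape != self.mean_retardation_deg.shape:
            raise ValueError("depth and retardation arrays must share shape")
        if self.depth_um.size and np.any(np.diff(self.depth_um) <= 0):
            raise ValueError("depth axis must be strictly increasing")
        if self.n_columns < 1:
            raise ValueError("profile must average >= 1 column")


@dataclass
class BirefringenceEstimate:
    """Result of a retardation-slope fit over one depth window.

    ``delta_n_se`` is the standard error of ``delta_n`` propagated from
    the residual scatter of the fit (None when unavailable, e.g. for
    externally supplied point values).
    """

    delta_n: float
    slope_deg_per_um: float
    intercept_deg: float
    fit_window_um: tuple[float, float]
    r_squared: float
    n_points: int
    delta_n_se: float | None = None


@dataclass
class LayerWindows:
    """Named, ordered, non-overlapping depth windows below the surface (μm)."""

    windows: list[tuple[str, tuple[float, float]]]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("need at least one layer window")
        prev_end = -np.inf
        for name, (z0, z1) in self.windows:
            if z1 <= z0:
                raise ValueError(f"window {name!r} is empty: [{z0}, {z1})")
            if z0 < prev_end:
                raise ValueError(f"window {name!r} overlaps the previous one")
            prev_end = z1

    def __iter__(self):
        return iter(self.windows)


def DEFAULT_TISSUE_WINDOWS() -> LayerWindows:
    """Bladder-tissue analysis windows: urothelium 0–50 μm below the
    surface, lamina propria the next 200 μm."""
    return LayerWindows([("urothelium", (0.0, 50.0)), ("LP", (50.0, 250.0))])


def bladder_windows(condition: str) -> LayerWindows:
    """Per-condition analysis windows for the bladder phantom designs.

    Normal keeps the tissue convention (urothelium 0–50, LP 50–250 μm)
    and adds the MP below the 450-μm LP bottom; diseased treats the
    fused urothelium+LP as one 450-μm window atop the MP.
    """
    if condition == "normal":
        return LayerWindows(
            [("urothelium", (0.0, 50.0)), ("LP", (50.0, 250.0)), ("MP", (450.0, 2050.0))]
        )
    if condition == "diseased":
        return LayerWindows([("fused", (0.0, 450.0)), ("MP", (450.0, 2050.0))])
    raise ValueError(f"condition must be 'normal' or 'diseased', got {condition!r}")


def columns_for_extent(extent_um: float, config: ImagingConfig) -> int:
    """Number of lateral columns spanning a physical extent (e.g. 2 mm)."""
    return int(round(extent_um / config.lateral_pixel_spacing_um))


def lateral_average(
    flat: FlattenedBScan,
    column_range: tuple[int, int] | None = None,
    refractive_index: float = 1.4,
    max_depth_px: int | None = None,
) -> RetardationProfile:
    """Average the flattened retardation laterally over valid columns.

    ``column_range`` is a half-open (start, stop) column slice; None uses
    the full width.  The depth axis is converted to physical μm below the
    surface (optical path / refractive index).  Depths where fewer than
    half the selected valid columns still have support (ragged bottoms
    after flattening) are dropped; ``max_depth_px`` truncates further,
    e.g. at the maximum detection depth.
    """
    c0, c1 = column_range if column_range is not None else (0, flat.shape[1])
    sel = np.zeros(flat.shape[1], dtype=bool)
    sel[c0:c1] = True
    sel &= flat.valid
    ncols = int(sel.sum())
    if ncols == 0:
        raise ValueError("no valid columns in the requested range")

    block = flat.retardation[:, sel]
    if max_depth_px is not None:
        block = block[: max_depth_px + 1]
    counts = np.sum(~np.isnan(block), axis=1)
    keep = counts >= max(1, int(np.ceil(ncols / 2)))
    # support is contiguous from the surface; cut at the first dropout
    last = np.nonzero(keep)[0]
    if last.size == 0:
        raise ValueError("no depth with enough valid columns")
    depth_stop = int(last.max()) + 1

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(block[:depth_stop], axis=1)
    rows = np.arange(depth_stop)
    depth_um = pixels_to_physical_thickness(1.0, flat.config, refractive_index) * rows
    good = ~np.isnan(mean)
    extent = (c1 - c0) * flat.config.lateral_pixel_spacing_um
    return RetardationProfile(depth_um[good], mean[good], ncols, extent)


# ---------------------------------------------------------------------------
# Fold-bias correction
# ---------------------------------------------------------------------------

def fold_bias_mean(mu_deg: np.ndarray, sigma_deg: float) -> np.ndarray:
    """E[fold(mu + sigma*Z)] for the 0-deg fold, Z standard normal.

    Valid while mu stays well below the 90-deg fold (the two folds are
    > 40 sigma apart for any realistic noise level).
    """
    mu = np.asarray(mu_deg, dtype=float)
    if sigma_deg == 0:
        return mu.copy()
    m = mu / sigma_deg
    return mu + 2.0 * (sigma_deg * stats.norm.pdf(m) - mu * stats.norm.cdf(-m))


def fold_bias_correct(mean_deg: np.ndarray, sigma_deg: float) -> np.ndarray:
    """Invert the folded-noise mean: recover mu from E[fold(mu + noise)].

    g(mu) is strictly increasing with g(0) = sigma*sqrt(2/pi); observed
    means at or below g(0) map to 0.  Values above 45 deg are corrected
    by the mirrored relation at the 90-deg fold.  Inversion uses a dense
    monotone grid and linear interpolation (grid step 0.01 deg keeps the
    inversion error orders of magnitude below the noise floor).
    """
    y = np.asarray(mean_deg, dtype=float)
    if sigma_deg == 0:
        return y.copy()
    grid_mu = np.arange(0.0, 45.0 + 10 * sigma_deg, 0.01)
    grid_g = fold_bias_mean(grid_mu, sigma_deg)
    lower = np.clip(y, grid_g[0], grid_g[-1])
    inv = np.interp(lower, grid_g, grid_mu)
    mirrored = 90.0 - np.interp(np.clip(90.0 - y, grid_g[0], grid_g[-1]), grid_g, grid_mu)
    return np.where(y <= 45.0, inv, mirrored)


def estimate_retardation_noise(
    retardation: np.ndarray, top_index: np.ndarray, valid: np.ndarray
) -> float:
    """Estimate the retardation noise s.d. from above-surface pixels.

    Above the surface the retardation channel holds folded pure noise,
    |N(0, sigma)| in expectation sigma*sqrt(2/pi); the mean of those
    pixels therefore yields sigma.  Returns 0.0 when no above-surface
    pixels exist (surface at row 0).
    """
    vals = []
    for c in np.nonzero(valid)[0]:
        t = int(top_index[c])
        if t > 0:
            vals.append(retardation[:t, c])
    if not vals:
        return 0.0
    flat = np.concatenate(vals)
    return float(np.mean(flat) * np.sqrt(np.pi / 2.0))


# ---------------------------------------------------------------------------
# Slope fitting
# ---------------------------------------------------------------------------

def _slope_to_delta_n(slope_deg_per_um: float, wavelength_nm: float) -> float:
    # deg/um -> rad/m: * pi/180 * 1e6 ; dn = slope_rad_per_m * lambda_m / (2 pi)
    slope_rad_per_m = slope_deg_per_um * np.pi / 180.0 * 1e6
    return slope_rad_per_m * wavelength_nm * 1e-9 / (2.0 * np.pi)


def fit_birefringence(
    profile: RetardationProfile,
    config: ImagingConfig,
    fit_window_um: tuple[float, float],
    noise_sd_deg: float = 0.0,
    fold_limit_deg: float = 80.0,
) -> BirefringenceEstimate:
    """OLS line through (depth, retardation) inside a window; Δn from the slope.

    The window is additionally truncated at the first depth where the
    mean retardation exceeds ``fold_limit_deg`` so only the monotone
    pre-fold region is fitted.  With ``noise_sd_deg`` > 0 the profile is
    fold-bias corrected before fitting (see module docstring).
    """
    z0, z1 = fit_window_um
    if z1 <= z0:
        raise ValueError("empty fit window")
    mask = (profile.depth_um >= z0) & (profile.depth_um < z1)
    over = np.nonzero(mask & (profile.mean_retardation_deg > fold_limit_deg))[0]
    if over.size:
        mask &= np.arange(profile.depth_um.size) < over[0]
    z = profile.depth_um[mask]
    y = profile.mean_retardation_deg[mask]
    if z.size < 3:
        raise ValueError(
            f"fewer than 3 profile points inside fit window [{z0}, {z1}) um"
        )
    if np.ptp(z) == 0:
        raise ValueError("zero depth spread inside fit window")

    if noise_sd_deg > 0:
        y = fold_bias_correct(y, noise_sd_deg)

    slope, intercept = np.polyfit(z, y, 1)
    resid = y - (slope * z + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    # OLS slope standard error from residual scatter (which already
    # carries any fold-correction noise amplification)
    sigma2 = ss_res / (z.size - 2)
    slope_se = float(np.sqrt(sigma2 / np.sum((z - z.mean()) ** 2)))

    return BirefringenceEstimate(
        delta_n=_slope_to_delta_n(float(slope), config.wavelength_nm),
        slope_deg_per_um=float(slope),
        intercept_deg=float(intercept),
        fit_window_um=(float(z.min()), float(z.max())),
        r_squared=float(r2),
        n_points=int(z.size),
        delta_n_se=_slope_to_delta_n(slope_se, config.wavelength_nm),
    )


def layer_birefringence(
    flat: FlattenedBScan,
    windows: LayerWindows,
    config: ImagingConfig,
    column_range: tuple[int, int] | None = None,
    refractive_index: float = 1.4,
    noise_sd_deg: float = 0.0,
    surface_skip_um: float = 10.0,
    max_depth_px: int | None = None,
) -> dict[str, BirefringenceEstimate | None]:
    """One slope fit per layer window over the laterally averaged profile.

    Windows starting at the surface skip the first ``surface_skip_um``
    (specular surface pixels); windows whose start lies beyond the
    profile support (max detection depth) are reported as None rather
    than fitted.
    """
    profile = lateral_average(flat, column_range, refractive_index, max_depth_px)
    support_end = float(profile.depth_um[-1]) if profile.depth_um.size else 0.0
    out: dict[str, BirefringenceEstimate | None] = {}
    for name, (z0, z1) in windows:
        start = z0 + surface_skip_um if z0 == 0.0 else z0
        end = min(z1, support_end)
        n_inside = int(np.sum((profile.depth_um >= start) & (profile.depth_um < end)))
        if start >= support_end or n_inside < 3:
            out[name] = None
            continue
        out[name] = fit_birefringence(profile, config, (start, end), noise_sd_deg)
    return out


def percent_change(delta_n_test: float, delta_n_reference: float) -> float:
    """Signed percent change of a test Δn relative to a reference Δn."""
    if delta_n_reference == 0:
        raise ValueError("reference delta_n must be nonzero")
    return 100.0 * (delta_n_test - delta_n_reference) / delta_n_reference
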