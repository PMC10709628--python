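"""Spectral preprocessing: the exact feature chain of the chemometric model,
plus soil background subtraction for particle spectra.

The model chain is, in order: linear interpolation onto a common grid,
rubber-band baseline correction (lower convex hull), Savitzky-Golay second
derivative (window 23, polynomial degree 3), and vector (L2) normalization.
The chain makes features invariant to additive linear baselines and global
positive scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import ROIBand, Spectrum, WavenumberGrid

__all__ = [
    "PreprocessConfig",
    "resample",
    "rubberband_baseline",
    "sg_derivative",
    "vector_normalize",
    "preprocess_features",
    "subtract_background",
    "synthetic_vapor_reference",
    "subtract_water_vapor",
]

DEFAULT_AUTO_BAND = ROIBand("soil-silicate", 950.0, 1150.0)


@dataclass
class PreprocessConfig:
    """Configuration of the model feature chain.

    The default feature range is 1800-900 cm^-1 at 2 cm^-1 spacing: the
    window where principal-component loadings are most diagnostic of starch.
    Savitzky-Golay defaults: 23-point window, 3rd-degree polynomial, 2nd
    derivative.
    """

    range_lo: float = 900.0
    range_hi: float = 1800.0
    step: float = 2.0
    sg_window: int = 23
    sg_poly: int = 3
    sg_deriv: int = 2
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_poly:
            raise ValueError("sg_window must be odd and > sg_poly")
        if self.sg_deriv > self.sg_poly:
            raise ValueError("sg_deriv must be <= sg_poly")
        if not self.range_lo < self.range_hi:
            raise ValueError("range_lo must be < range_hi")

    @property
    def target_grid(self) -> WavenumberGrid:
        return WavenumberGrid.regular(self.range_lo, self.range_hi, self.step)


def resample(spectrum: Spectrum, grid: WavenumberGrid) -> Spectrum:
    """Linear interpolation onto a target grid. No extrapolation: the target
    must lie within the source range."""
    src = spectrum.wavenumbers
    tgt = grid.values
    if tgt[0] < src[0] or tgt[-1] > src[-1]:
        raise ValueError(
            f"target grid [{tgt[0]}, {tgt[-1]}] extends beyond source "
            f"[{src[0]}, {src[-1]}]; refusing to extrapolate"
        )
    return Spectrum(grid, np.interp(tgt, src, spectrum.absorbance), dict(spectrum.meta))


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull vertices (Andrew's monotone chain).

    Points are scaled to the unit square first so hull arithmetic is well
    conditioned regardless of the relative scale of cm^-1 vs absorbance
    (the hull itself is invariant under positive axis scaling).
    """
    xs = (x - x[0]) / (x[-1] - x[0])
    yr = y.max() - y.min()
    ys = (y - y.min()) / yr if yr > 0 else np.zeros_like(y)
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on/above the segment j->i (not a lower vertex)
            cross = (xs[k] - xs[j]) * (ys[i] - ys[j]) - (ys[k] - ys[j]) * (xs[i] - xs[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def rubberband_baseline(spectrum: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Rubber-band baseline correction.

    The baseline is the lower convex hull of the (wavenumber, absorbance)
    points, linearly interpolated between hull vertices; the corrected
    spectrum is input minus baseline: non-negative everywhere and exactly
    zero at every hull vertex.
    """
    x = spectrum.wavenumbers
    y = spectrum.absorbance
    if x.size < 3:
        raise ValueError("rubber-band baseline needs at least 3 points")
    idx = _lower_hull_indices(x, y)
    baseline = np.interp(x, x[idx], y[idx])
    corrected = np.maximum(y - baseline, 0.0)
    return (
        spectrum.copy(absorbance=corrected),
        spectrum.copy(absorbance=baseline),
    )


def sg_derivative(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Savitzky-Golay derivative with respect to wavenumber.

    Requires a uniform grid. Edge values come from asymmetric windows: the
    polynomial fitted to the first/last window is evaluated at the boundary
    points rather than padding with invented data.
    """
    if config is None:
        config = PreprocessConfig()
    if not spectrum.grid.is_uniform:
        raise ValueError("sg_derivative needs a uniform grid; resample first")
    if len(spectrum.grid) < config.sg_window:
        raise ValueError(
            f"spectrum length {len(spectrum.grid)} < sg_window {config.sg_window}"
        )
    d = savgol_filter(
        spectrum.absorbance,
        window_length=config.sg_window,
        polyorder=config.sg_poly,
        deriv=config.sg_deriv,
        delta=spectrum.grid.spacing,
        mode="interp",
    )
    return spectrum.copy(absorbance=d)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale the absorbance vector to unit Euclidean norm."""
    norm = float(np.linalg.norm(spectrum.absorbance))
    if norm == 0.0:
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return spectrum.copy(absorbance=spectrum.absorbance / norm)


def preprocess_features(spectrum: Spectrum, config: PreprocessConfig | None = None) -> np.ndarray:
    """The full model feature chain: resample -> rubber band -> SG second
    derivative -> vector normalization; returns the feature vector on the
    configured target grid."""
    if config is None:
        config = PreprocessConfig()
    s = resample(spectrum, config.target_grid)
    s, _ = rubberband_baseline(s)
    s = sg_derivative(s, config)
    if config.normalize:
        s = vector_normalize(s)
    return s.absorbance


def subtract_background(
    target: Spectrum,
    background: Spectrum,
    scale: float | str = "auto",
    auto_band: ROIBand = DEFAULT_AUTO_BAND,
) -> Spectrum:
    """Subtract a (scaled) background spectrum, e.g. the soil surrounding a
    particle.

    With ``scale="auto"`` the coefficient is the non-negative least-squares
    fit of the background to the target over ``auto_band`` (default the
    silicate-dominated 1150-950 cm^-1 window), clipped to [0, 2] to prevent
    pathological over-subtraction.
    """
    if target.grid != background.grid:
        raise ValueError("target and background must share a grid")
    if scale == "auto":
        x = target.wavenumbers
        sel = (x >= auto_band.lo) & (x <= auto_band.hi)
        if not sel.any():
            raise ValueError("auto_band does not overlap the grid")
        b = background.absorbance[sel]
        t = target.absorbance[sel]
        denom = float(b @ b)
        coef = float(t @ b) / denom if denom > 0 else 0.0
        # absorbance cannot go negative: never subtract more background than
        # the target actually contains anywhere in the fit band
        pos = b > 1e-12
        if pos.any():
            coef = min(coef, float(np.min(np.maximum(t[pos], 0.0) / b[pos])))
        scale_val = float(np.clip(coef, 0.0, 2.0))
    else:
        scale_val = float(scale)
    out = target.absorbance - scale_val * background.absorbance
    result = target.copy(absorbance=out)
    result.meta["background_scale"] = scale_val
    return result


# ---------------------------------------------------------------------------
# Water-vapor compensation (simplified, off by default)
# ---------------------------------------------------------------------------

# Rotational-vibrational water vapor lines in the 1900-1300 cm^-1 bending
# region (positions rounded to the nearest cm^-1; relative strengths coarse).
_VAPOR_LINES = (
    (1918.0, 0.30), (1870.0, 0.45), (1845.0, 0.40), (1792.0, 0.55),
    (1772.0, 0.50), (1734.0, 0.60), (1717.0, 0.70), (1684.0, 0.65),
    (1653.0, 0.90), (1635.0, 0.75), (1617.0, 1.00), (1576.0, 0.80),
    (1560.0, 0.85), (1540.0, 0.70), (1522.0, 0.60), (1507.0, 0.75),
    (1457.0, 0.55), (1437.0, 0.45), (1419.0, 0.40), (1395.0, 0.35),
    (1362.0, 0.30), (1340.0, 0.25),
)


def synthetic_vapor_reference(grid: WavenumberGrid, fwhm: float = 6.0) -> Spectrum:
    """A synthetic water-vapor line spectrum (narrow Lorentzian lines in the
    1900-1300 cm^-1 region) used for the simplified vapor compensation.

    This is a documented simplification standing in for instrument-side
    atmospheric compensation; it is synthetic, not a measured reference.
    """
    x = grid.values
    y = np.zeros_like(x)
    for center, strength in _VAPOR_LINES:
        y += strength / (1.0 + 4.0 * ((x - center) / fwhm) ** 2)
    return Spectrum(grid, y, {"id": "synthetic-water-vapor", "provenance": "synthetic"})


def subtract_water_vapor(spectrum: Spectrum, fit_lo: float = 1300.0, fit_hi: float = 1900.0) -> Spectrum:
    """Least-squares removal of the synthetic vapor reference over the
    1900-1300 cm^-1 window. Optional; off by default in every pipeline."""
    vapor = synthetic_vapor_reference(spectrum.grid)
    x = spectrum.wavenumbers
    sel = (x >= fit_lo) & (x <= fit_hi)
    v = vapor.absorbance[sel]
    # fit vapor jointly with a linear baseline so offsets do not bias the
    # vapor coefficient; only the vapor term is subtracted
    t = (x[sel] - fit_lo) / (fit_hi - fit_lo)
    design = np.column_stack([v, np.ones_like(t), t])
    coef = float(np.linalg.lstsq(design, spectrum.absorbance[sel], rcond=None)[0][0])
    coef = max(coef, 0.0)
    return spectrum.copy(absorbance=spectrum.absorbance - coef * vapor.absorbance)
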