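"""Mineralization-marker scoring and the authentication verdict.

Ancient starch grains differ from modern ones by diagenetic mineral
deposition: calcium carbonate (broad ~1430 cm^-1 band, C=O stretch at 1790,
overtone at 2520), clay/kaolinite ordered-water absorptions (sharp peaks in
3750-3580 cm^-1), calcium oxalate (~1322 cm^-1 shoulder) and silicates
(broad ~1030 cm^-1). This module scores each marker on a scale-free
signal-to-noise ratio, checks the carbohydrate profile (O-H and C-H
stretching, fingerprint band pattern), and combines them into one of three
verdicts: ``modern_like``, ``ancient_candidate``, or ``non_carbohydrate``.

All scores are ratio-based, so the verdict is invariant to global positive
scaling of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import find_peaks

from .preprocess import rubberband_baseline
from .spectra import DiagnosticBand, ROIBand, Spectrum, default_roi_panel

__all__ = [
    "MarkerPanel",
    "MineralizationReport",
    "CarbohydrateProfile",
    "default_marker_panel",
    "band_presence",
    "carbohydrate_profile",
    "assess",
]

# Flank half-widths (cm^-1) for the local baseline/noise estimate, by shape.
_FLANK = {"sharp": 25.0, "broad": 80.0, "shoulder": 40.0}
_FLANK_SEG = 14.0  # width of each outer flank segment used for the fit

# Starch fingerprint pattern windows: ring/backbone bands expected in at
# least two of these for a spectrum to count as carbohydrate.
FINGERPRINT_WINDOWS = ((1150.0, 1160.0), (1060.0, 1080.0), (980.0, 1040.0))
WINDOW_MARGIN = 10.0  # cm^-1 slack for overlapping-band apex shifts


@dataclass
class MarkerPanel:
    """The diagnostic band set, composite weights and decision thresholds."""

    bands: dict[str, DiagnosticBand]
    weights: dict[str, float]
    kappa: float = 3.0            # SNR scale in score = h / (h + kappa * sigma)
    theta_low: float = 0.2        # composite threshold: modern vs ancient
    saturation_clip: float = 2.5  # absorbance above this flags saturation
    rois: tuple[ROIBand, ...] = field(default_factory=lambda: tuple(default_roi_panel()))


def default_marker_panel() -> MarkerPanel:
    """Markers and defaults for the authentication decision.

    Composite weights are equal over the six mineral deposition markers
    (carbonate triplet, clay, kaolinite, oxalate). The silicate band is
    scored and reported but enters the composite with weight 0: at ~1030
    cm^-1 it overlaps the starch C-OH stretching band and is the soil
    interferent the imaging workflow explicitly distrusts, so treating it
    as mineralization evidence would mark every intact starch as aged.
    """
    bands = {
        "carbonate_main": DiagnosticBand("carbonate_main", 1430.0, 25.0, "broad"),
        "carbonate_CO": DiagnosticBand("carbonate_CO", 1790.0, 15.0, "sharp"),
        "carbonate_overtone": DiagnosticBand("carbonate_overtone", 2520.0, 20.0, "sharp"),
        "clay_sharp": DiagnosticBand("clay_sharp", 3613.0, 10.0, "sharp"),
        "kaolinite_range": DiagnosticBand("kaolinite_range", 3665.0, 85.0, "sharp"),
        "oxalate_shoulder": DiagnosticBand("oxalate_shoulder", 1322.0, 12.0, "shoulder"),
        "silicate_broad": DiagnosticBand("silicate_broad", 1030.0, 40.0, "broad"),
    }
    weights = {
        "carbonate_main": 1.0,
        "carbonate_CO": 1.0,
        "carbonate_overtone": 1.0,
        "clay_sharp": 1.0,
        "kaolinite_range": 1.0,
        "oxalate_shoulder": 1.0,
        "silicate_broad": 0.0,
    }
    return MarkerPanel(bands=bands, weights=weights)


def _robust_sigma(residuals: np.ndarray) -> float:
    """MAD-based noise scale (consistent for a Gaussian)."""
    if residuals.size == 0:
        return 0.0
    med = np.median(residuals)
    return float(1.4826 * np.median(np.abs(residuals - med)))


NOISE_MAX_Z = 3.0  # expected-maximum offset for noise inside the peak window
QUIET_WINDOW = (2050.0, 2300.0)  # signal-free region used as a noise floor


def _smooth(y: np.ndarray) -> np.ndarray:
    """Mild Savitzky-Golay smoothing so the peak statistic measures the
    underlying band, not the maximum of the noise."""
    from scipy.signal import savgol_filter

    if y.size < 7:
        return y
    return savgol_filter(y, 7, 2)


def band_presence(
    spectrum: Spectrum,
    band: DiagnosticBand,
    kappa: float = 3.0,
    saturation_clip: float | None = None,
) -> float:
    """Presence score in [0, 1] for one diagnostic band.

    A local straight baseline is fitted through the medians of two flanking
    segments. The peak height h is measured on a mildly smoothed,
    baseline-corrected trace: the window maximum for sharp/shoulder bands,
    the window median for broad bands (so a narrow interloper inside a
    broad marker's window under-counts), minus an expected-noise-maximum
    offset ``NOISE_MAX_Z * sigma`` so that pure noise scores ~0. The score
    is h / (h + kappa * sigma) with sigma a robust (MAD) noise scale from
    the detrended flanks: 0 with no excursion above noise, approaching 1
    for strong peaks. If ``saturation_clip`` is given and the raw
    absorbance exceeds it, the band is saturated and scores 1.0 (a band too
    intense to quantify is unambiguous evidence of presence).
    """
    x = spectrum.wavenumbers
    y = spectrum.absorbance
    flank = _FLANK[band.shape_class]
    span = band.tolerance + flank
    lo, hi = band.center - span, band.center + span
    if lo < x[0] or hi > x[-1]:
        raise ValueError(
            f"band {band.name} window [{lo:.0f}, {hi:.0f}] outside grid "
            f"[{x[0]:.0f}, {x[-1]:.0f}]"
        )
    left = (x >= lo) & (x <= lo + _FLANK_SEG)
    right = (x >= hi - _FLANK_SEG) & (x <= hi)
    if not (left.any() and right.any()):
        raise ValueError(f"band {band.name}: flank segments empty; grid too coarse")
    xl, xr = float(x[left].mean()), float(x[right].mean())
    yl, yr = float(np.median(y[left])), float(np.median(y[right]))
    slope = (yr - yl) / (xr - xl)
    baseline = yl + slope * (x - xl)
    window = (x >= lo) & (x <= hi)
    corrected = np.zeros_like(y)
    corrected[window] = (y - baseline)[window]
    corrected[window] = _smooth(corrected[window])
    peak_win = (x >= band.center - band.tolerance) & (x <= band.center + band.tolerance)
    if not peak_win.any():
        raise ValueError(f"band {band.name}: no grid points within tolerance")
    if saturation_clip is not None and float(y[peak_win].max()) > saturation_clip:
        return 1.0
    if band.shape_class == "broad":
        m = float(np.median(corrected[peak_win]))
    else:
        m = float(corrected[peak_win].max())
    # The few flank points underestimate noise; bound sigma from below by a
    # smoothed-scale estimate from the signal-free quiet window when covered.
    sigma = _robust_sigma(np.concatenate([corrected[left], corrected[right]]))
    quiet = (x >= QUIET_WINDOW[0]) & (x <= QUIET_WINDOW[1])
    if quiet.sum() >= 9:
        seg = _smooth(y[quiet])
        trend = np.polyval(np.polyfit(x[quiet], seg, 1), x[quiet])
        sigma = max(sigma, _robust_sigma(seg - trend))
    h = max(m - NOISE_MAX_Z * sigma, 0.0)
    if h == 0.0:
        return 0.0
    return h / (h + kappa * sigma) if sigma > 0 else 1.0


@dataclass
class CarbohydrateProfile:
    """Flags for the three carbohydrate spectral regions."""

    oh_present: bool
    ch_present: bool
    ch_apex: float | None        # cm^-1 position of the strongest C-H peak
    fingerprint_present: bool
    fingerprint_windows_hit: int


def _quiet_sigma(x: np.ndarray, corrected: np.ndarray) -> float:
    """Noise scale from the signal-free 2300-2050 cm^-1 window."""
    quiet = (x >= 2050.0) & (x <= 2300.0)
    if quiet.sum() >= 5:
        seg = corrected[quiet]
        t = np.polyval(np.polyfit(x[quiet], seg, 1), x[quiet])
        return _robust_sigma(seg - t)
    return _robust_sigma(corrected)


def carbohydrate_profile(
    spectrum: Spectrum, kappa: float = 3.0, rois: tuple[ROIBand, ...] | None = None
) -> CarbohydrateProfile:
    """Check the three carbohydrate regions on a rubber-band-corrected
    spectrum.

    O-H: maximum corrected absorbance in 3600-3100 cm^-1 above kappa*sigma.
    C-H: strongest peak in 3000-2800 cm^-1 above kappa*sigma, with its apex
    position. Fingerprint: the 1200-900 cm^-1 region must show a starch-like
    band *pattern* — peaks in at least two of the ring/backbone windows
    (1150-1160, 1060-1080, 980-1040 cm^-1, +/- 10 cm^-1 margin). A single
    broad silicate band fails the pattern test even though it is intense.
    """
    if rois is None:
        rois = tuple(default_roi_panel())
    roi1, roi2, roi3 = rois
    x = spectrum.wavenumbers
    if x[0] > 900.0 or x[-1] < 3620.0:
        raise ValueError(
            "carbohydrate profiling needs coverage of at least 900-3620 cm^-1"
        )
    corrected, _ = rubberband_baseline(spectrum)
    # smooth so peak finding responds to bands, not to noise maxima
    yc = _smooth(corrected.absorbance)
    sigma = _quiet_sigma(x, yc)
    # flags must clear both the noise-maximum excursion and the SNR scale
    thresh = (kappa + NOISE_MAX_Z) * sigma

    sel1 = (x >= roi1.lo) & (x <= roi1.hi)
    oh = float(yc[sel1].max()) > thresh and float(yc[sel1].max()) > 0.0

    sel2 = (x >= roi2.lo) & (x <= roi2.hi)
    y2 = yc[sel2]
    x2 = x[sel2]
    peaks, props = find_peaks(y2, height=max(thresh, 0.0) or None)
    ch_present = False
    ch_apex: float | None = None
    if peaks.size:
        best = peaks[np.argmax(props["peak_heights"])]
        ch_apex = float(x2[best])
        ch_present = True
    elif y2.size and float(y2.max()) > thresh > 0:
        # monotone edge of a band whose apex sits at the ROI boundary
        ch_apex = float(x2[np.argmax(y2)])
        ch_present = True

    fsel = (x >= 900.0) & (x <= 1250.0)
    yf, xf = yc[fsel], x[fsel]
    fpeaks, fprops = find_peaks(yf, prominence=max(thresh, 0.0) or None)
    hit = 0
    for wlo, whi in FINGERPRINT_WINDOWS:
        in_win = [
            p
            for p in fpeaks
            if wlo - WINDOW_MARGIN <= xf[p] <= whi + WINDOW_MARGIN
        ]
        if in_win:
            hit += 1
    fingerprint = hit >= 2
    return CarbohydrateProfile(
        oh_present=bool(oh),
        ch_present=bool(ch_present),
        ch_apex=ch_apex,
        fingerprint_present=bool(fingerprint),
        fingerprint_windows_hit=hit,
    )


@dataclass
class MineralizationReport:
    """Marker scores, carbohydrate flags and the authentication verdict."""

    marker_scores: dict[str, float]
    composite: float
    profile: CarbohydrateProfile
    verdict: str                  # modern_like | ancient_candidate | non_carbohydrate
    theta_low: float
    kappa: float
    saturated: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            **{f"score[{k}]": v for k, v in self.marker_scores.items()},
            "composite": self.composite,
            "oh_present": self.profile.oh_present,
            "ch_present": self.profile.ch_present,
            "ch_apex": self.profile.ch_apex,
            "fingerprint_present": self.profile.fingerprint_present,
            "verdict": self.verdict,
            "theta_low": self.theta_low,
        }


def assess(spectrum: Spectrum, panel: MarkerPanel | None = None) -> MineralizationReport:
    """Score all markers and emit the authentication verdict.

    Decision rule: no carbohydrate fingerprint pattern -> non_carbohydrate;
    fingerprint present and composite mineralization < theta_low ->
    modern_like; fingerprint present and composite >= theta_low ->
    ancient_candidate. Thresholds are reported in the output; they are
    configuration, not measured facts.
    """
    if panel is None:
        panel = default_marker_panel()
    scores: dict[str, float] = {}
    saturated: list[str] = []
    x = spectrum.wavenumbers
    for name, band in panel.bands.items():
        raw_max_win = (x >= band.center - band.tolerance) & (x <= band.center + band.tolerance)
        scores[name] = band_presence(
            spectrum, band, kappa=panel.kappa, saturation_clip=panel.saturation_clip
        )
        if raw_max_win.any() and float(spectrum.absorbance[raw_max_win].max()) > panel.saturation_clip:
            saturated.append(name)
    total_w = sum(panel.weights.get(k, 0.0) for k in scores)
    composite = (
        sum(scores[k] * panel.weights.get(k, 0.0) for k in scores) / total_w
        if total_w > 0
        else 0.0
    )
    profile = carbohydrate_profile(spectrum, kappa=panel.kappa, rois=panel.rois)
    if not profile.fingerprint_present:
        verdict = "non_carbohydrate"
    elif composite < panel.theta_low:
        verdict = "modern_like"
    else:
        verdict = "ancient_candidate"
    return MineralizationReport(
        marker_scores=scores,
        composite=float(composite),
        profile=profile,
        verdict=verdict,
        theta_low=panel.theta_low,
        kappa=panel.kappa,
        saturated=saturated,
    )
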