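"""Hyperspectral chemical imaging: ROI integration maps, co-localized
hotspot detection, hotspot spectrum extraction and adjacent-pixel soil
background estimation.

A focal-plane-array tile is a 64 x 64 pixel grid with one full FTIR spectrum
per pixel (~2.6 um pixels). Chemical maps integrate each pixel's absorbance
over a region of interest; a starch particle shows up as a pixel region where
the O-H, C-H and carbohydrate-fingerprint maps all have co-localized local
maxima — soil minerals light up the fingerprint map alone, so requiring the
three maps to agree rejects those "false hotspots".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .spectra import ROIBand, Spectrum, WavenumberGrid, default_roi_panel

__all__ = [
    "HyperspectralCube",
    "ChemicalMap",
    "Hotspot",
    "HotspotSet",
    "HotspotConfig",
    "integrate_roi",
    "colocalized_hotspots",
    "hotspot_mean_spectrum",
    "annulus_background",
    "extract_asc_spectra",
    "concat_mosaic",
    "read_envi",
    "write_envi",
]

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class HyperspectralCube:
    """A pixel grid of spectra: ``data[row, col, wavenumber]``."""

    data: np.ndarray
    grid: WavenumberGrid
    pixel_size: float = 2.6
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != len(self.grid):
            raise ValueError(
                f"cube shape {d.shape} inconsistent with grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(d)):
            raise ValueError("cube contains non-finite values")
        self.data = d

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.grid, self.data[row, col].copy(), {"pixel": (row, col)})


@dataclass
class ChemicalMap:
    """Integrated absorbance per pixel over one ROI (absorbance * cm^-1)."""

    values: np.ndarray
    roi: ROIBand

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


def integrate_roi(cube: HyperspectralCube, roi: ROIBand, local_baseline: bool = True) -> ChemicalMap:
    """Trapezoidal integral of each pixel spectrum over [roi.lo, roi.hi].

    With ``local_baseline`` the straight line joining the spectrum values at
    the ROI edges is subtracted before integration and the map is clipped at
    zero (so background pixels map to zero, not to their offset).
    """
    x = cube.grid.values
    sel = (x >= roi.lo) & (x <= roi.hi)
    if not sel.any():
        raise ValueError(f"ROI {roi.name} [{roi.lo}, {roi.hi}] outside cube grid")
    xs = x[sel]
    y = cube.data[:, :, sel]
    if local_baseline:
        t = (xs - xs[0]) / (xs[-1] - xs[0]) if xs.size > 1 else np.zeros_like(xs)
        base = y[:, :, :1] + (y[:, :, -1:] - y[:, :, :1]) * t[None, None, :]
        y = y - base
    vals = np.trapezoid(y, xs, axis=2)
    if local_baseline:
        vals = np.clip(vals, 0.0, None)
    return ChemicalMap(vals, roi)


@dataclass
class Hotspot:
    """One detected particle candidate."""

    mask: np.ndarray            # boolean (n_rows, n_cols)
    area: int
    centroid: tuple[float, float]
    mean_roi3: float
    mean_spectrum: Spectrum | None = None
    background_spectrum: Spectrum | None = None


@dataclass
class HotspotSet:
    """Disjoint hotspot masks ranked by mean fingerprint intensity."""

    hotspots: list[Hotspot]
    label_image: np.ndarray     # int (n_rows, n_cols); 0 = background

    def __len__(self) -> int:
        return len(self.hotspots)


@dataclass
class HotspotConfig:
    """Detection parameters for co-localized hotspots."""

    percentile: float = 90.0
    min_area: int = 4
    mode: str = "and"           # "and" (all three ROIs) | "two_of_three" | "or"
    annulus_width: int = 2
    local_baseline: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must be in (0, 100)")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.mode not in ("and", "two_of_three", "or"):
            raise ValueError(f"unknown mode {self.mode!r}")


def colocalized_hotspots(
    maps: Sequence[ChemicalMap],
    percentile: float = 90.0,
    min_area: int = 4,
    mode: str = "and",
) -> HotspotSet:
    """Detect pixel regions bright in all three ROI maps.

    Each map is thresholded at its own percentile (scale-free criterion),
    the binary masks are intersected (default AND over all maps; a
    two-of-three and an OR mode are selectable for sensitivity analysis),
    8-connected components smaller than ``min_area`` pixels are discarded,
    and hotspots are ranked by mean intensity in the last map given
    (conventionally ROI3, the carbohydrate fingerprint).
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps to co-localize")
    shape = maps[0].values.shape
    for m in maps:
        if m.values.shape != shape:
            raise ValueError("all maps must share dimensions")
    binary = np.stack([m.values > np.percentile(m.values, percentile) for m in maps])
    if mode == "and":
        combined = binary.all(axis=0)
    elif mode == "or":
        combined = binary.any(axis=0)
    else:  # two_of_three
        combined = binary.sum(axis=0) >= 2
    labeled, n = ndimage.label(combined, structure=EIGHT_CONNECTED)
    roi3 = maps[-1].values
    hotspots: list[Hotspot] = []
    label_image = np.zeros(shape, dtype=int)
    for comp in range(1, n + 1):
        mask = labeled == comp
        area = int(mask.sum())
        if area < min_area:
            continue
        rr, cc = np.nonzero(mask)
        hotspots.append(
            Hotspot(
                mask=mask,
                area=area,
                centroid=(float(rr.mean()), float(cc.mean())),
                mean_roi3=float(roi3[mask].mean()),
            )
        )
    hotspots.sort(key=lambda h: -h.mean_roi3)
    for i, h in enumerate(hotspots, start=1):
        label_image[h.mask] = i
    return HotspotSet(hotspots, label_image)


def hotspot_mean_spectrum(cube: HyperspectralCube, mask: np.ndarray) -> Spectrum:
    """Arithmetic mean spectrum over the mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty hotspot mask")
    mean = cube.data[mask].mean(axis=0)
    return Spectrum(cube.grid, mean, {"n_pixels": int(mask.sum())})


def annulus_background(
    cube: HyperspectralCube,
    mask: np.ndarray,
    width: int = 2,
    exclude: np.ndarray | None = None,
) -> Spectrum:
    """Mean spectrum of the pixels adjacent to a particle.

    The annulus is the 8-connected morphological dilation of the mask by
    ``width`` pixels, minus the mask itself and minus any ``exclude`` pixels
    (e.g. other hotspots), so one particle's halo never contaminates
    another's background estimate.
    """
    mask = np.asarray(mask, dtype=bool)
    if width < 1:
        raise ValueError("width must be >= 1")
    dilated = ndimage.binary_dilation(mask, structure=EIGHT_CONNECTED, iterations=width)
    annulus = dilated & ~mask
    if exclude is not None:
        annulus &= ~np.asarray(exclude, dtype=bool)
    if not annulus.any():
        raise ValueError("annulus is empty; widen it or check mask placement")
    mean = cube.data[annulus].mean(axis=0)
    return Spectrum(cube.grid, mean, {"n_pixels": int(annulus.sum()), "role": "background"})


def extract_asc_spectra(
    cube: HyperspectralCube,
    config: HotspotConfig | None = None,
    rois: Sequence[ROIBand] | None = None,
) -> tuple[HotspotSet, list[Spectrum]]:
    """The full imaging path: ROI maps -> co-localized hotspots -> mean
    hotspot spectra -> adjacent-pixel background subtraction.

    Returns the hotspot set (with mean and background spectra attached) and
    the list of background-subtracted candidate spectra, ready for
    mineralization scoring and classification.
    """
    from .preprocess import subtract_background  # local import avoids a cycle

    if config is None:
        config = HotspotConfig()
    if rois is None:
        rois = default_roi_panel()
    maps = [integrate_roi(cube, roi, local_baseline=config.local_baseline) for roi in rois]
    hs = colocalized_hotspots(
        maps, percentile=config.percentile, min_area=config.min_area, mode=config.mode
    )
    others = hs.label_image > 0
    extracted: list[Spectrum] = []
    for i, h in enumerate(hs.hotspots, start=1):
        # partial-volume pixels at the particle rim are mostly soil; average
        # over the eroded core when it survives erosion
        core = ndimage.binary_erosion(h.mask, structure=EIGHT_CONNECTED)
        h.mean_spectrum = hotspot_mean_spectrum(cube, core if core.any() else h.mask)
        exclude = others & (hs.label_image != i)
        h.background_spectrum = annulus_background(
            cube, h.mask, width=config.annulus_width, exclude=exclude
        )
        sub = subtract_background(h.mean_spectrum, h.background_spectrum, scale="auto")
        sub.meta.update(
            hotspot=i,
            area=h.area,
            centroid=h.centroid,
            provenance="ASC",
        )
        extracted.append(sub)
    return hs, extracted


def concat_mosaic(tiles: Sequence[Sequence[HyperspectralCube]]) -> HyperspectralCube:
    """Concatenate tiles on a row/col offset grid (plain concatenation, no
    stitching correction). ``tiles[i][j]`` sits at tile-row i, tile-col j;
    coordinates are 0-based with row 0 at top."""
    rows = []
    grid = tiles[0][0].grid
    for tile_row in tiles:
        for t in tile_row:
            if t.grid != grid:
                raise ValueError("all mosaic tiles must share a wavenumber grid")
        rows.append(np.concatenate([t.data for t in tile_row], axis=1))
    data = np.concatenate(rows, axis=0)
    first = tiles[0][0]
    return HyperspectralCube(data, grid, first.pixel_size, {**first.meta, "mosaic": True})


# ---------------------------------------------------------------------------
# ENVI-style cube I/O (text header + raw float32 band-sequential body)
# ---------------------------------------------------------------------------

def write_envi(cube: HyperspectralCube, path_base: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.hdr`` (text header) and ``<base>.raw`` (float32 BSQ).

    The wavelength list holds wavenumbers in cm^-1. Little-endian
    (byte order = 0).
    """
    base = Path(path_base)
    hdr = base.with_suffix(".hdr")
    raw = base.with_suffix(".raw")
    wl = ", ".join(f"{v:.6g}" for v in cube.grid.values)
    hdr.write_text(
        "ENVI\n"
        f"samples = {cube.n_cols}\n"
        f"lines = {cube.n_rows}\n"
        f"bands = {len(cube.grid)}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"pixel size = {{{cube.pixel_size}, {cube.pixel_size}}}\n"
        "wavelength units = cm-1\n"
        f"wavelength = {{{wl}}}\n"
    )
    # BSQ: band-sequential, i.e. (band, line, sample)
    bsq = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0), dtype="<f4")
    bsq.tofile(raw)
    return hdr, raw


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # collapse brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            fields[k.strip().lower()] = v.strip()
    return fields


def read_envi(path_base: str | Path) -> HyperspectralCube:
    """Read an ENVI pair written by :func:`write_envi` (bsq, float32 only)."""
    base = Path(path_base)
    hdr = base.with_suffix(".hdr")
    raw = base.with_suffix(".raw")
    fields = _parse_envi_header(hdr.read_text())
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only bsq interleave is supported")
    if fields.get("data type", "4") != "4":
        raise ValueError("only float32 (data type 4) is supported")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    wl_text = fields["wavelength"].strip("{} ")
    wavenumbers = np.array([float(v) for v in wl_text.split(",")])
    data = np.fromfile(raw, dtype="<f4").reshape(bands, rows, cols)
    pixel_size = 2.6
    m = re.search(r"pixel size\s*=\s*\{([^,}]+)", hdr.read_text())
    if m:
        pixel_size = float(m.group(1))
    return HyperspectralCube(
        np.moveaxis(data.astype(float), 0, 2),
        WavenumberGrid(wavenumbers),
        pixel_size,
        {"source": str(base)},
    )
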