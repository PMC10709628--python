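"""Core data model for mid-infrared spectra and labeled spectral libraries.

The atomic object of the whole pipeline is a :class:`Spectrum`: an absorbance
trace on a strictly increasing wavenumber grid (cm^-1). FTIR instruments
conventionally write spectra from 4000 down to 800 cm^-1; everything in this
package is canonicalised to ascending wavenumber on read, and every band is
expressed as a closed interval ``[lo, hi]`` with ``lo < hi``. That single
orientation convention removes a whole class of off-by-direction bugs.

Also defined here: class labels for reference starches (species + storage
organ type), the labeled :class:`SpectralLibrary` used to train the
chemometric model, region-of-interest bands (:class:`ROIBand`) used for
chemical imaging, and diagnostic marker bands (:class:`DiagnosticBand`) used
for mineralization scoring.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "ClassLabel",
    "SpectralLibrary",
    "ROIBand",
    "DiagnosticBand",
    "ORGAN_TYPES",
    "SpectrumParseError",
    "EmptyRangeError",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcamp",
    "read_library_manifest",
    "band_slice",
    "default_roi_panel",
]

ORGAN_TYPES = ("USO", "ASO", "contaminant")


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed; names the offending line."""


class EmptyRangeError(ValueError):
    """Raised when a band does not overlap a spectrum's grid."""


@dataclass(frozen=True)
class WavenumberGrid:
    """A strictly increasing wavenumber axis in cm^-1.

    ``spacing`` is the nominal step; resampled grids are uniform to within
    1e-6 relative tolerance, raw instrument grids need not be.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two wavenumbers")
        if not np.all(np.isfinite(v)):
            raise ValueError("grid contains non-finite wavenumbers")
        if np.any(v <= 0):
            raise ValueError("wavenumbers must be positive")
        if np.any(np.diff(v) <= 0):
            raise ValueError("grid must be strictly increasing without duplicates")

    @classmethod
    def regular(cls, lo: float, hi: float, step: float) -> "WavenumberGrid":
        """Uniform grid from ``lo`` to ``hi`` inclusive with the given step."""
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.values)))

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.values)
        return bool(np.all(np.abs(d - d.mean()) <= 1e-6 * abs(d.mean())))

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


@dataclass
class Spectrum:
    """Absorbance trace on a wavenumber grid plus provenance metadata.

    ``meta`` carries free-form provenance: an identifier, a provenance tag
    (``MSR`` modern reference | ``ASC`` ancient candidate | ``soil`` |
    ``synthetic``) and optional site/tool labels.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (len(self.grid),):
            raise ValueError(
                f"absorbance length {a.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        self.absorbance = a

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.values

    def copy(self, absorbance: np.ndarray | None = None, **meta) -> "Spectrum":
        a = self.absorbance if absorbance is None else absorbance
        return Spectrum(self.grid, np.array(a, dtype=float), {**self.meta, **meta})


@dataclass(frozen=True)
class ClassLabel:
    """Botanical class of a reference starch: species, organ type, organ.

    ``organ_type`` is the closed three-value set: USO (underground storage
    organ), ASO (above-ground storage organ) or contaminant (a modern
    non-Eurasian taxon used as a contamination reference).
    """

    species: str
    organ_type: str
    organ: str = ""

    def __post_init__(self) -> None:
        if self.organ_type not in ORGAN_TYPES:
            raise ValueError(
                f"organ_type {self.organ_type!r} not in {ORGAN_TYPES}"
            )

    @property
    def key(self) -> str:
        """Stable string identity used as the classification target."""
        return f"{self.species}|{self.organ}" if self.organ else self.species


class SpectralLibrary:
    """A labeled collection of spectra used to train/evaluate the model."""

    def __init__(self, entries: Iterable[tuple[Spectrum, ClassLabel]], name: str = ""):
        self.entries: list[tuple[Spectrum, ClassLabel]] = list(entries)
        self.name = name

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[Spectrum, ClassLabel]]:
        return iter(self.entries)

    @property
    def spectra(self) -> list[Spectrum]:
        return [s for s, _ in self.entries]

    @property
    def labels(self) -> list[ClassLabel]:
        return [l for _, l in self.entries]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, lab in self.entries:
            counts[lab.key] = counts.get(lab.key, 0) + 1
        return counts

    def validate_for_cv(self, min_per_class: int = 2) -> None:
        """Stratified CV needs at least ``min_per_class`` spectra per class."""
        for key, n in self.class_counts().items():
            if n < min_per_class:
                raise ValueError(
                    f"class {key!r} has {n} spectra; "
                    f"stratification needs >= {min_per_class}"
                )


@dataclass(frozen=True)
class ROIBand:
    """A closed wavenumber interval [lo, hi] whose integral forms a map channel."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"ROIBand {self.name}: lo must be < hi, got ({self.lo}, {self.hi})")

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class DiagnosticBand:
    """A marker band: center +/- tolerance, with a qualitative shape class.

    Bands quoted as ranges (e.g. the kaolinite window) are stored with
    ``center`` at the midpoint and ``tolerance`` at the half-width.
    """

    name: str
    center: float
    tolerance: float
    shape_class: str = "sharp"  # sharp | broad | shoulder

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not (800.0 <= self.center <= 4000.0):
            raise ValueError("band center outside the mid-IR range 800-4000 cm^-1")
        if self.shape_class not in ("sharp", "broad", "shoulder"):
            raise ValueError(f"unknown shape_class {self.shape_class!r}")


def default_roi_panel() -> list[ROIBand]:
    """The three carbohydrate ROIs used for chemical imaging.

    ROI1 3600-3100 cm^-1 (O-H stretching, water content), ROI2 3000-2800
    cm^-1 (C-H stretching of methyl/methylene), ROI3 1200-900 cm^-1 (the
    carbohydrate-backbone fingerprint, most diagnostic of starch).
    """
    return [
        ROIBand("ROI1", 3100.0, 3600.0),
        ROIBand("ROI2", 2800.0, 3000.0),
        ROIBand("ROI3", 900.0, 1200.0),
    ]


def band_slice(spectrum: Spectrum, band: ROIBand) -> Spectrum:
    """Restrict a spectrum to the closed interval [band.lo, band.hi]."""
    v = spectrum.wavenumbers
    mask = (v >= band.lo) & (v <= band.hi)
    if not mask.any():
        raise EmptyRangeError(
            f"band {band.name} [{band.lo}, {band.hi}] does not overlap grid "
            f"[{v[0]}, {v[-1]}]"
        )
    return Spectrum(
        WavenumberGrid(v[mask]), spectrum.absorbance[mask], dict(spectrum.meta)
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

CSV_HEADER = "wavenumber_cm-1,absorbance"


def _canonicalise(wn: np.ndarray, ab: np.ndarray, source: str) -> Spectrum:
    order = np.argsort(wn)
    wn, ab = wn[order], ab[order]
    dup = np.flatnonzero(np.diff(wn) == 0)
    if dup.size:
        raise SpectrumParseError(
            f"{source}: duplicate wavenumber {wn[dup[0]]:g}"
        )
    return Spectrum(WavenumberGrid(wn), ab)


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a two-column (wavenumber, absorbance) CSV with one header line.

    Files written in descending instrument order are reordered to ascending.
    Leading ``#`` comment lines are parsed as ``key: value`` metadata.
    """
    path = Path(path)
    meta: dict = {}
    wns: list[float] = []
    abs_: list[float] = []
    with path.open(newline="") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    k, _, v = line.lstrip("# ").partition(":")
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                header_seen = True  # first non-comment line is the header
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumParseError(f"{path.name}: line {lineno}: expected 2 columns")
            try:
                wns.append(float(parts[0]))
                abs_.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path.name}: line {lineno}: non-numeric value"
                ) from exc
    if len(wns) < 2:
        raise SpectrumParseError(f"{path.name}: fewer than 2 data points")
    spec = _canonicalise(np.array(wns), np.array(abs_), path.name)
    spec.meta.update(meta)
    spec.meta.setdefault("id", path.stem)
    return spec


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV (metadata as ``#`` comments, then the header)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        for k, v in spectrum.meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write(CSV_HEADER + "\n")
        for wn, ab in zip(spectrum.wavenumbers, spectrum.absorbance):
            fh.write(f"{float(wn)!r},{float(ab)!r}\n")


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def read_jcamp(path_or_text: str | Path) -> Spectrum:
    """Read a single-block JCAMP-DX spectrum in the (X++(Y..Y)) dialect.

    Covers spectra exported from Bruker/OPUS: AFFN-encoded XYDATA lines, with
    XFACTOR/YFACTOR scaling. Compressed (SQZ/DIF/DUP) encodings are out of
    scope. Descending X order is canonicalised to ascending.
    """
    if isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str) and "\n" not in path_or_text
    ):
        text = Path(path_or_text).read_text()
        source = Path(path_or_text).name
    else:
        text = str(path_or_text)
        source = "<jcamp>"
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in io.StringIO(text):
        line = raw.strip()
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_data = "(X++(Y..Y))" in value.replace(" ", "")
                if not in_data:
                    raise SpectrumParseError(
                        f"{source}: unsupported XYDATA dialect {value.strip()!r}"
                    )
                continue
            if key == "END":
                in_data = False
                continue
            fields[key] = value.strip()
        elif in_data and line:
            data_lines.append(line)
    if not data_lines:
        raise SpectrumParseError(f"{source}: no (X++(Y..Y)) data block found")
    xfactor = float(fields.get("XFACTOR", "1"))
    yfactor = float(fields.get("YFACTOR", "1"))
    first = float(fields["FIRSTX"])
    last = float(fields["LASTX"])
    npoints = int(fields["NPOINTS"])
    ys: list[float] = []
    for line in data_lines:
        nums = _JCAMP_NUM.findall(line)
        if not nums:
            raise SpectrumParseError(f"{source}: malformed data line {line!r}")
        ys.extend(float(v) * yfactor for v in nums[1:])  # nums[0] is the X value
    if len(ys) != npoints:
        raise SpectrumParseError(
            f"{source}: NPOINTS={npoints} but {len(ys)} Y values read"
        )
    wn = np.linspace(first * xfactor, last * xfactor, npoints)
    spec = _canonicalise(wn, np.array(ys), source)
    spec.meta["id"] = fields.get("TITLE", source)
    return spec


def read_library_manifest(path: str | Path, base_dir: str | Path | None = None) -> SpectralLibrary:
    """Read a library manifest: columns ``id, species, organ_type, organ, path``."""
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    entries: list[tuple[Spectrum, ClassLabel]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "species", "organ_type", "organ", "path"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SpectrumParseError(
                f"{path.name}: manifest must have columns {sorted(required)}"
            )
        for row in reader:
            spec = read_spectrum_csv(base / row["path"])
            spec.meta["id"] = row["id"]
            label = ClassLabel(row["species"], row["organ_type"], row["organ"])
            entries.append((spec, label))
    return SpectralLibrary(entries, name=path.stem)
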