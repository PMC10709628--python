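"""Synthetic mid-IR spectra: modern starch references, aged/mineralized
starch candidates, soil matrices, and hyperspectral imaging scenes.

No reference dataset ships with this package; every downstream stage is
exercised on spectra generated here. A class signature is a set of
pseudo-Voigt bands at the positions the starch literature assigns to
amylose/amylopectin, water, protein and lipid vibrations; botanical classes
differ by reproducible multiplicative amplitude profiles and small band-center
offsets, emulating the observation that within-plant spectral variability is
lower than between-plant variability. Aging is modelled as a signature
transformation: dehydration attenuates the O-H stretching band, diagenesis
attenuates the carbohydrate fingerprint, and biomineralization appends
carbonate/clay/silicate/oxalate marker bands.

All generation is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .imaging import HyperspectralCube
from .spectra import ClassLabel, Spectrum, SpectralLibrary, WavenumberGrid

__all__ = [
    "BandComponent",
    "ClassSignature",
    "AgingModel",
    "Particle",
    "SceneSpec",
    "SceneTruth",
    "pseudo_voigt",
    "default_starch_band_library",
    "default_mineral_band_library",
    "default_soil_signature",
    "default_class_roster",
    "generate_class_signatures",
    "synthesize_spectrum",
    "apply_aging",
    "generate_reference_library",
    "generate_hypercube",
    "default_grid",
    "signature_band_sum",
    "roi_contrast",
]

# Frozen generator defaults: the study conditions every seeded test runs under.
DEFAULT_NOISE_SD = 0.005      # absorbance units, i.i.d. per channel
DEFAULT_AMP_CV = 0.15         # within-class relative amplitude variability
DEFAULT_CENTER_JITTER_SD = 0.8  # cm^-1, within-class band-center jitter
CLASS_AMP_SIGMA = 0.45        # log-sd of between-class amplitude profiles
CLASS_CENTER_SD = 2.0         # cm^-1, between-class band-center offsets
DEFAULT_DRIFT_SCALE = 0.02    # absorbance units, low-order baseline drift
DEFAULT_GAUSS_FRACTION = 0.7  # pseudo-Voigt Gaussian weight


def default_grid(lo: float = 800.0, hi: float = 4000.0, step: float = 4.0) -> WavenumberGrid:
    """The default full-MIR acquisition grid (4 cm^-1 spacing)."""
    return WavenumberGrid.regular(lo, hi, step)


@dataclass(frozen=True)
class BandComponent:
    """One absorption band: pseudo-Voigt with peak height ``amplitude``."""

    center: float
    amplitude: float
    fwhm: float
    gauss_fraction: float = DEFAULT_GAUSS_FRACTION

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if not 0.0 <= self.gauss_fraction <= 1.0:
            raise ValueError("gauss_fraction must be in [0, 1]")


def pseudo_voigt(x: np.ndarray, band: BandComponent) -> np.ndarray:
    """Pseudo-Voigt profile: eta * Gaussian + (1 - eta) * Lorentzian.

    Both components share the band FWHM and are normalised to peak height 1,
    so ``band.amplitude`` is the absorbance at the band center.
    """
    d = np.asarray(x, dtype=float) - band.center
    g = np.exp(-4.0 * np.log(2.0) * (d / band.fwhm) ** 2)
    l = 1.0 / (1.0 + 4.0 * (d / band.fwhm) ** 2)
    return band.amplitude * (band.gauss_fraction * g + (1.0 - band.gauss_fraction) * l)


@dataclass(frozen=True)
class ClassSignature:
    """A botanical class: its band set plus within-class variability knobs."""

    label: ClassLabel
    bands: tuple[BandComponent, ...]
    amp_cv: float = DEFAULT_AMP_CV
    center_jitter_sd: float = DEFAULT_CENTER_JITTER_SD

    def __post_init__(self) -> None:
        if self.amp_cv < 0 or self.center_jitter_sd < 0:
            raise ValueError("variability parameters must be >= 0")
        object.__setattr__(self, "bands", tuple(self.bands))

    def scaled(self, factor: float) -> "ClassSignature":
        """All band amplitudes multiplied by ``factor``."""
        return replace(
            self,
            bands=tuple(replace(b, amplitude=b.amplitude * factor) for b in self.bands),
        )


@dataclass(frozen=True)
class AgingModel:
    """Diagenetic transformation of a starch signature.

    mineral_fraction: total appended mineral band amplitude as a fraction of
    the signature's summed band amplitudes. dehydration: attenuation of the
    3600-3100 cm^-1 O-H stretching band. fingerprint_attenuation: attenuation
    of the 1200-900 cm^-1 carbohydrate backbone. mineral_mix: weights over
    the four mineral families, summing to 1.
    """

    mineral_fraction: float = 0.0
    dehydration: float = 0.0
    fingerprint_attenuation: float = 0.0
    mineral_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "carbonate": 0.4,
            "clay_kaolinite": 0.3,
            "silicate": 0.2,
            "oxalate": 0.1,
        }
    )

    def __post_init__(self) -> None:
        for name, v in (
            ("mineral_fraction", self.mineral_fraction),
            ("dehydration", self.dehydration),
            ("fingerprint_attenuation", self.fingerprint_attenuation),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        mix = dict(self.mineral_mix)
        if any(w < 0 for w in mix.values()):
            raise ValueError("mineral_mix weights must be >= 0")
        total = sum(mix.values())
        if total > 0:
            mix = {k: w / total for k, w in mix.items()}
        object.__setattr__(self, "mineral_mix", mix)

    @classmethod
    def from_severity(cls, severity: float, mineral_mix: Mapping[str, float] | None = None) -> "AgingModel":
        """One-knob aging: mineral deposition with proportionate dehydration
        (0.6 x severity) and fingerprint loss (0.5 x severity)."""
        kwargs = {} if mineral_mix is None else {"mineral_mix": mineral_mix}
        return cls(
            mineral_fraction=severity,
            dehydration=0.6 * severity,
            fingerprint_attenuation=0.5 * severity,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Band libraries
# ---------------------------------------------------------------------------

def default_starch_band_library() -> list[BandComponent]:
    """Band set of a generic starch grain.

    Centers: broad O-H stretch (3300), methylene C-H stretches (2925/2850),
    C=O of aldehyde/galacturonans (1740), protein amide signals (1658, 1622),
    water bending (1640), beta-glucans (1428), ring breathing and C-O-C /
    C-OH modes of the glucose backbone (1174, 1163, 1135, 1065, 1060, 1033,
    985, 950). Widths are qualitative: the O-H stretch is very broad,
    fingerprint bands are 15-40 cm^-1.
    """
    spec = [
        # (center, amplitude, fwhm)
        (3300.0, 0.55, 300.0),
        (2925.0, 0.18, 30.0),
        (2850.0, 0.10, 26.0),
        (1740.0, 0.06, 24.0),
        (1658.0, 0.08, 28.0),
        (1640.0, 0.12, 40.0),
        (1622.0, 0.07, 24.0),
        (1428.0, 0.10, 30.0),
        (1174.0, 0.14, 18.0),
        (1163.0, 0.12, 16.0),
        (1135.0, 0.16, 18.0),
        (1065.0, 0.22, 22.0),
        (1060.0, 0.20, 20.0),
        (1033.0, 0.28, 22.0),
        (985.0, 0.16, 26.0),
        (950.0, 0.10, 20.0),
    ]
    return [BandComponent(c, a, w) for c, a, w in spec]


def default_mineral_band_library() -> dict[str, list[BandComponent]]:
    """Marker bands of the four mineral families seen on aged starches.

    carbonate: broad intense ~1430, C=O stretch 1790, overtone 2520.
    clay_kaolinite: sharp ordered-water absorptions at 3614 and 3695
    (inside the 3750-3580 window). silicate: very broad ~1030. oxalate:
    shoulder-width band at ~1322.
    """
    return {
        "carbonate": [
            BandComponent(1430.0, 1.00, 90.0),
            BandComponent(1790.0, 0.12, 20.0),
            BandComponent(2520.0, 0.08, 35.0),
        ],
        "clay_kaolinite": [
            BandComponent(3614.0, 0.55, 12.0),
            BandComponent(3695.0, 0.45, 14.0),
        ],
        "silicate": [
            BandComponent(1030.0, 1.00, 150.0),
        ],
        "oxalate": [
            BandComponent(1322.0, 0.35, 22.0),
        ],
    }


def default_soil_signature() -> ClassSignature:
    """A soil matrix: broad silicate band, sharp clay peaks, weak carbonate,
    adsorbed water, and a trace of organic C-H.

    Amplitudes emulate the thin scattered sediment layer left around
    particles after aqueous extraction — optically much thinner than a
    solid starch grain, whose fingerprint bands must therefore out-absorb
    the soil at the particle center.
    """
    bands = (
        BandComponent(1030.0, 0.30, 160.0),   # silicate
        BandComponent(3620.0, 0.10, 12.0),    # clay OH
        BandComponent(3695.0, 0.08, 14.0),    # kaolinite OH
        BandComponent(1430.0, 0.08, 80.0),    # weak carbonate
        BandComponent(3420.0, 0.12, 350.0),   # adsorbed water, broad
        BandComponent(2920.0, 0.022, 30.0),   # trace soil organic matter C-H
        BandComponent(2850.0, 0.014, 26.0),
        BandComponent(1640.0, 0.05, 45.0),    # water bending
    )
    label = ClassLabel("soil matrix", "contaminant", "sediment")
    return ClassSignature(label, bands, amp_cv=0.10, center_jitter_sd=0.5)


def default_class_roster() -> list[ClassLabel]:
    """The 16-class modern reference roster: 9 ASO species, 5 USO species,
    and 2 non-Eurasian USO taxa included as modern-contamination references."""
    aso = [
        ("Aesculus hippocastanum", "seed"),
        ("Brassica oleracea", "stem"),
        ("Carex sp.", "seed"),
        ("Gingko biloba", "kernel"),
        ("Juniperus sp.", "fruit"),
        ("Linum usitatissimum", "seed"),
        ("Panicum miliaceum", "seed"),
        ("Quercus ilex", "kernel"),
        ("Trapa natans", "seed"),
    ]
    uso = [
        ("Cyperus esculentus", "rhizome"),
        ("Erythronium dens-canis", "rhizome"),
        ("Pueraria lobata", "root"),
        ("Sagittaria sagittifolia", "rhizome"),
        ("Typha latifolia", "rhizome"),
    ]
    contaminant = [
        ("Ipomoea batatas", "tuber"),
        ("Manihot esculenta", "tuber"),
    ]
    return (
        [ClassLabel(s, "ASO", o) for s, o in aso]
        + [ClassLabel(s, "USO", o) for s, o in uso]
        + [ClassLabel(s, "contaminant", o) for s, o in contaminant]
    )


# ---------------------------------------------------------------------------
# Signature and spectrum generation
# ---------------------------------------------------------------------------

def _lognormal_cv(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def generate_class_signatures(
    n_classes: int = 16,
    seed: int = 0,
    roster: Sequence[ClassLabel] | None = None,
    base_bands: Sequence[BandComponent] | None = None,
    class_amp_sigma: float = CLASS_AMP_SIGMA,
    class_center_sd: float = CLASS_CENTER_SD,
    amp_cv: float = DEFAULT_AMP_CV,
    center_jitter_sd: float = DEFAULT_CENTER_JITTER_SD,
) -> list[ClassSignature]:
    """Reproducible class signatures: shared starch band set, class-specific
    amplitude profiles (lognormal, log-sd ``class_amp_sigma``) and band-center
    offsets (normal, sd ``class_center_sd``).

    Defaults mirror the 16-species reference roster; other ``n_classes`` get
    generic labels beyond (or truncating) the roster.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if roster is None:
        roster = default_class_roster()
    base = list(base_bands) if base_bands is not None else default_starch_band_library()
    rng = np.random.default_rng(seed)
    signatures: list[ClassSignature] = []
    for i in range(n_classes):
        if i < len(roster):
            label = roster[i]
        else:
            label = ClassLabel(f"taxon-{i + 1}", "USO", "tuber")
        mult = rng.lognormal(0.0, class_amp_sigma, len(base)) if class_amp_sigma > 0 else np.ones(len(base))
        offs = rng.normal(0.0, class_center_sd, len(base)) if class_center_sd > 0 else np.zeros(len(base))
        # the two methylene stretches co-vary (same CH2 population); keep the
        # asymmetric 2925 band dominant as it is in every real starch
        centers = [b.center for b in base]
        if 2925.0 in centers and 2850.0 in centers:
            mult[centers.index(2850.0)] = mult[centers.index(2925.0)]
        bands = tuple(
            replace(b, amplitude=b.amplitude * m, center=b.center + o)
            for b, m, o in zip(base, mult, offs)
        )
        signatures.append(
            ClassSignature(label, bands, amp_cv=amp_cv, center_jitter_sd=center_jitter_sd)
        )
    return signatures


def _signature_trace(bands: Sequence[BandComponent], x: np.ndarray) -> np.ndarray:
    y = np.zeros_like(x)
    for b in bands:
        y += pseudo_voigt(x, b)
    return y


def synthesize_spectrum(
    signature: ClassSignature,
    grid: WavenumberGrid,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    drift_scale: float = DEFAULT_DRIFT_SCALE,
) -> Spectrum:
    """One noisy realisation of a class signature on a wavenumber grid.

    Band amplitudes are jittered by the signature's ``amp_cv`` (unit-mean
    lognormal), centers by ``center_jitter_sd``; a random non-negative
    quadratic baseline drift of scale ``drift_scale`` and i.i.d. Gaussian
    noise are added. With all variability at zero the output equals the
    analytic band sum at every grid point.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = grid.values
    n = len(signature.bands)
    mult = _lognormal_cv(rng, signature.amp_cv, n)
    offs = (
        rng.normal(0.0, signature.center_jitter_sd, n)
        if signature.center_jitter_sd > 0
        else np.zeros(n)
    )
    y = np.zeros_like(x)
    for b, m, o in zip(signature.bands, mult, offs):
        y += pseudo_voigt(x, replace(b, amplitude=b.amplitude * m, center=b.center + o))
    if drift_scale > 0:
        t = (x - x[0]) / (x[-1] - x[0])
        c = rng.uniform(0.0, drift_scale, 3)
        y += c[0] + c[1] * t + c[2] * t**2
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, x.size)
    return Spectrum(
        grid,
        y,
        {
            "id": f"{signature.label.key}",
            "provenance": "synthetic",
            "class": signature.label.key,
        },
    )


OH_REGION = (3100.0, 3600.0)
FINGERPRINT_REGION = (900.0, 1200.0)


def signature_band_sum(signature: ClassSignature) -> float:
    """Summed peak amplitudes; the reference scale for mineral deposition."""
    return float(sum(b.amplitude for b in signature.bands))


def apply_aging(signature: ClassSignature, aging: AgingModel) -> ClassSignature:
    """Transform a modern signature into an aged/mineralized one.

    O-H stretching amplitudes are scaled by (1 - dehydration), carbohydrate
    fingerprint amplitudes by (1 - fingerprint_attenuation), and mineral
    family bands are appended with total amplitude
    ``mineral_fraction * sum(original amplitudes)`` partitioned by
    ``mineral_mix``.
    """
    total = signature_band_sum(signature)
    out: list[BandComponent] = []
    for b in signature.bands:
        a = b.amplitude
        if OH_REGION[0] <= b.center <= OH_REGION[1]:
            a *= 1.0 - aging.dehydration
        if FINGERPRINT_REGION[0] <= b.center <= FINGERPRINT_REGION[1]:
            a *= 1.0 - aging.fingerprint_attenuation
        out.append(replace(b, amplitude=a))
    if aging.mineral_fraction > 0:
        library = default_mineral_band_library()
        for mineral, weight in aging.mineral_mix.items():
            if weight == 0:
                continue
            fam = library[mineral]
            fam_sum = sum(b.amplitude for b in fam)
            scale = aging.mineral_fraction * total * weight / fam_sum
            out.extend(replace(b, amplitude=b.amplitude * scale) for b in fam)
    return replace(signature, bands=tuple(out))


def generate_reference_library(
    signatures: Sequence[ClassSignature],
    reps_per_class: int = 20,
    grid: WavenumberGrid | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    drift_scale: float = DEFAULT_DRIFT_SCALE,
    name: str = "synthetic MSR library",
) -> SpectralLibrary:
    """A labeled library with ``reps_per_class`` replicates per signature.

    Each spectrum draws from an independent substream keyed by (seed, class
    index, replicate index), so regeneration is byte-identical per seed.
    """
    if reps_per_class < 2:
        raise ValueError("reps_per_class must be >= 2 for stratified use")
    if grid is None:
        grid = default_grid()
    entries: list[tuple[Spectrum, ClassLabel]] = []
    for ci, sig in enumerate(signatures):
        for rep in range(reps_per_class):
            rng = np.random.default_rng([seed, ci, rep])
            spec = synthesize_spectrum(
                sig, grid, noise_sd=noise_sd, rng=rng, drift_scale=drift_scale
            )
            spec.meta["id"] = f"{sig.label.key}#{rep:02d}"
            spec.meta["provenance"] = "MSR"
            entries.append((spec, sig.label))
    return SpectralLibrary(entries, name=name)


# ---------------------------------------------------------------------------
# Hyperspectral scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Particle:
    """A starch particle planted in a scene (center in pixel coordinates).

    ``thickness`` is the grain's optical thickness relative to the reference
    single-grain deposition: a solid starch grain in transmission absorbs
    severalfold more than the thin scattered sediment layer around it, which
    is what makes particles stand out in the fingerprint map at all.
    """

    row: float
    col: float
    radius_px: float
    signature: ClassSignature
    aging: AgingModel | None = None
    thickness: float = 3.5

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("particle radius must be >= 1 px")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")


@dataclass
class SceneSpec:
    """An imaging scene: soil matrix with embedded starch particles.

    Defaults mirror one focal-plane-array tile: 64 x 64 pixels at 2.6 um.
    ``soil_texture_sd`` is the log-sd of per-pixel soil density variation,
    emulating an unevenly packed sediment deposit.
    """

    n_rows: int = 64
    n_cols: int = 64
    pixel_size: float = 2.6
    particles: tuple[Particle, ...] = ()
    soil_signature: ClassSignature = field(default_factory=default_soil_signature)
    noise_sd: float = DEFAULT_NOISE_SD
    baseline_drift: tuple[float, ...] = (0.0, 0.0, 0.0)
    soil_texture_sd: float = 0.10

    def __post_init__(self) -> None:
        self.particles = tuple(self.particles)
        for p in self.particles:
            if not (0 <= p.row < self.n_rows and 0 <= p.col < self.n_cols):
                raise ValueError(
                    f"particle center ({p.row}, {p.col}) outside "
                    f"{self.n_rows} x {self.n_cols} scene"
                )


@dataclass
class SceneTruth:
    """Ground truth returned alongside a generated cube."""

    masks: list[np.ndarray]          # boolean (n_rows, n_cols) per particle
    labels: list[ClassLabel]

    @property
    def any_mask(self) -> np.ndarray:
        if not self.masks:
            raise ValueError("no particles in truth")
        return np.logical_or.reduce(self.masks)


def _cosine_taper(dist: np.ndarray, radius: float) -> np.ndarray:
    """Blend weight: 1 at the particle center, 0 at the radius (cosine)."""
    w = 0.5 * (1.0 + np.cos(np.pi * np.clip(dist / radius, 0.0, 1.0)))
    w[dist > radius] = 0.0
    return w


def generate_hypercube(
    scene: SceneSpec,
    grid: WavenumberGrid | None = None,
    seed: int = 0,
) -> tuple[HyperspectralCube, SceneTruth]:
    """Generate a hyperspectral cube for a scene plus ground-truth masks.

    Every pixel starts as the soil spectrum scaled by a per-pixel texture
    factor; pixels inside a particle disc blend the (aged) particle spectrum
    with soil using a cosine taper from 1 at the center to 0 at the radius
    (partial-volume pixels at the disc edge). I.i.d. Gaussian noise is added
    per pixel and channel. Ground truth masks are the full discs
    (distance <= radius).
    """
    if grid is None:
        grid = default_grid(step=8.0)  # imaging resolution is coarser
    rng = np.random.default_rng(seed)
    x = grid.values
    soil = synthesize_spectrum(
        scene.soil_signature, grid, noise_sd=0.0, rng=rng, drift_scale=0.0
    ).absorbance
    texture = (
        rng.lognormal(0.0, scene.soil_texture_sd, (scene.n_rows, scene.n_cols))
        if scene.soil_texture_sd > 0
        else np.ones((scene.n_rows, scene.n_cols))
    )
    data = texture[:, :, None] * soil[None, None, :]

    rr, cc = np.mgrid[0 : scene.n_rows, 0 : scene.n_cols]
    masks: list[np.ndarray] = []
    labels: list[ClassLabel] = []
    for p in scene.particles:
        sig = apply_aging(p.signature, p.aging) if p.aging is not None else p.signature
        sig = sig.scaled(p.thickness)
        part = synthesize_spectrum(sig, grid, noise_sd=0.0, rng=rng, drift_scale=0.0).absorbance
        dist = np.hypot(rr - p.row, cc - p.col)
        w = _cosine_taper(dist, p.radius_px)
        data = (1.0 - w[:, :, None]) * data + w[:, :, None] * part[None, None, :]
        masks.append(dist <= p.radius_px)
        labels.append(sig.label)

    if any(scene.baseline_drift):
        t = (x - x[0]) / (x[-1] - x[0])
        drift = sum(c * t**k for k, c in enumerate(scene.baseline_drift))
        data = data + drift[None, None, :]
    if scene.noise_sd > 0:
        data = data + rng.normal(0.0, scene.noise_sd, data.shape)

    cube = HyperspectralCube(
        data=data,
        grid=grid,
        pixel_size=scene.pixel_size,
        meta={"provenance": "synthetic", "n_particles": len(scene.particles)},
    )
    return cube, SceneTruth(masks, labels)


def roi_contrast(
    particle_signature: ClassSignature,
    soil_signature: ClassSignature,
    lo: float,
    hi: float,
    grid: WavenumberGrid | None = None,
) -> float:
    """Noiseless band-integral ratio particle/soil over [lo, hi]; the knob
    scene builders use to set e.g. a 3x C-H stretching contrast."""
    if grid is None:
        grid = default_grid(step=8.0)
    x = grid.values
    sel = (x >= lo) & (x <= hi)
    p = _signature_trace(particle_signature.bands, x)[sel]
    s = _signature_trace(soil_signature.bands, x)[sel]
    return float(np.trapezoid(p, x[sel]) / np.trapezoid(s, x[sel]))
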