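"""Run configuration, deterministic seeding and pipeline orchestration.

A single YAML file holds every stage's parameters plus one master seed; all
randomness flows from that seed through named per-stage substreams, so a
partial re-run of any stage is reproducible on its own. Every output table
carries the hash of the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chemometrics, imaging, mineralization, synth
from .preprocess import PreprocessConfig
from .spectra import write_spectrum_csv

__all__ = [
    "RunConfig",
    "GeneratorConfig",
    "CVConfig",
    "ImagingConfig",
    "stage_seed",
    "stage_rng",
    "config_hash",
    "run_pipeline",
]

log = logging.getLogger("starchir")


@dataclass
class GeneratorConfig:
    n_classes: int = 16
    reps_per_class: int = 20
    grid_lo: float = 800.0
    grid_hi: float = 4000.0
    grid_step: float = 4.0
    noise_sd: float = synth.DEFAULT_NOISE_SD
    amp_cv: float = synth.DEFAULT_AMP_CV
    center_jitter_sd: float = synth.DEFAULT_CENTER_JITTER_SD
    class_amp_sigma: float = synth.CLASS_AMP_SIGMA
    class_center_sd: float = synth.CLASS_CENTER_SD
    drift_scale: float = synth.DEFAULT_DRIFT_SCALE


@dataclass
class CVConfig:
    folds: int = 10
    repeats: int = 6
    variance_target: float = 0.95
    max_components: int = 16
    knn_k: int = 4
    knn_weighting: str = "inverse_distance"


@dataclass
class ImagingConfig:
    percentile: float = 90.0
    min_area: int = 4
    mode: str = "and"
    annulus_width: int = 2
    local_baseline: bool = True
    scene_step: float = 8.0


@dataclass
class RunConfig:
    """All module parameters plus the master seed and a version tag."""

    seed: int = 42
    version: str = "0.1.0"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(dc_type, sub: dict):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(sub) - names
            if unknown:
                raise ValueError(f"unknown {dc_type.__name__} fields: {sorted(unknown)}")
            return dc_type(**sub)

        required = {"seed"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"config missing required field(s): {sorted(missing)}")
        kwargs = dict(d)
        for name, typ in (
            ("generator", GeneratorConfig),
            ("preprocess", PreprocessConfig),
            ("cv", CVConfig),
            ("imaging", ImagingConfig),
        ):
            if name in kwargs:
                kwargs[name] = build(typ, kwargs[name])
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - names
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the resolved configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the master seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(master: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master, stage))


def _library_from_config(config: RunConfig):
    g = config.generator
    grid = synth.WavenumberGrid.regular(g.grid_lo, g.grid_hi, g.grid_step)
    signatures = synth.generate_class_signatures(
        n_classes=g.n_classes,
        seed=stage_seed(config.seed, "signatures"),
        class_amp_sigma=g.class_amp_sigma,
        class_center_sd=g.class_center_sd,
        amp_cv=g.amp_cv,
        center_jitter_sd=g.center_jitter_sd,
    )
    library = synth.generate_reference_library(
        signatures,
        reps_per_class=g.reps_per_class,
        grid=grid,
        noise_sd=g.noise_sd,
        seed=stage_seed(config.seed, "library"),
        drift_scale=g.drift_scale,
    )
    return signatures, grid, library


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute the demo pipeline end to end: simulate a reference library
    and an imaging scene, cross-validate the model, extract and classify
    candidate spectra, and score mineralization. Returns the written paths.

    Each stage aborts with its name on failure; every tabular output carries
    the configuration hash in a header comment.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    written: dict[str, Path] = {}

    def save_table(df, name: str) -> Path:
        path = outdir / name
        with path.open("w") as fh:
            fh.write(f"# config_hash: {chash}\n# seed: {config.seed}\n")
            df.to_csv(fh, index=False)
        written[name] = path
        return path

    stage = "simulate"
    try:
        signatures, grid, library = _library_from_config(config)
        import pandas as pd

        manifest = pd.DataFrame(
            [
                {
                    "id": s.meta["id"],
                    "species": lab.species,
                    "organ_type": lab.organ_type,
                    "organ": lab.organ,
                }
                for s, lab in library
            ]
        )
        save_table(manifest, "library_manifest.csv")

        stage = "crossval"
        report = chemometrics.repeated_stratified_cv(
            library,
            preprocess_config=config.preprocess,
            variance_target=config.cv.variance_target,
            max_components=config.cv.max_components,
            knn_config=chemometrics.KNNConfig(config.cv.knn_k, config.cv.knn_weighting),
            folds=config.cv.folds,
            repeats=config.cv.repeats,
            seed=stage_seed(config.seed, "cv"),
        )
        save_table(
            pd.DataFrame([report.summary()]),
            "cv_summary.csv",
        )
        save_table(report.per_repeat, "cv_per_repeat.csv")

        stage = "train"
        model = chemometrics.train_model(
            library,
            preprocess_config=config.preprocess,
            variance_target=config.cv.variance_target,
            max_components=config.cv.max_components,
            knn_config=chemometrics.KNNConfig(config.cv.knn_k, config.cv.knn_weighting),
        )

        stage = "imaging"
        scene_grid = synth.default_grid(step=config.imaging.scene_step)
        soil = synth.default_soil_signature()
        rng = stage_rng(config.seed, "scene")
        particles = []
        for _ in range(3):
            sig = signatures[int(rng.integers(len(signatures)))]
            aging = synth.AgingModel.from_severity(float(rng.uniform(0.0, 0.4)))
            particles.append(
                synth.Particle(
                    row=float(rng.uniform(10, 54)),
                    col=float(rng.uniform(10, 54)),
                    radius_px=float(rng.uniform(3, 5)),
                    signature=sig,
                    aging=aging,
                )
            )
        scene = synth.SceneSpec(particles=tuple(particles), soil_signature=soil)
        cube, truth = synth.generate_hypercube(
            scene, scene_grid, seed=stage_seed(config.seed, "cube")
        )
        hs_config = imaging.HotspotConfig(
            percentile=config.imaging.percentile,
            min_area=config.imaging.min_area,
            mode=config.imaging.mode,
            annulus_width=config.imaging.annulus_width,
            local_baseline=config.imaging.local_baseline,
        )
        hotspots, asc_spectra = imaging.extract_asc_spectra(cube, hs_config)
        for i, spec in enumerate(asc_spectra):
            p = outdir / f"asc_{i:02d}.csv"
            write_spectrum_csv(spec, p)
            written[p.name] = p

        stage = "classify"
        if asc_spectra:
            _, detail = chemometrics.classify_unknowns(model, asc_spectra)
            save_table(detail, "asc_classification.csv")
            save_table(detail.attrs["summary"], "asc_classification_summary.csv")

        stage = "minerals"
        panel = mineralization.default_marker_panel()
        rows = []
        for i, spec in enumerate(asc_spectra):
            rep = mineralization.assess(spec, panel)
            rows.append({"spectrum": spec.meta.get("id", f"ASC-{i}"), **rep.to_row()})
        if rows:
            save_table(pd.DataFrame(rows), "asc_minerals.csv")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log.info("pipeline complete: %d artifacts in %s (config %s)", len(written), outdir, chash)
    return written
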