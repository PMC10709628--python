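"""Chemical maps, hotspot detection, background annuli, cube I/O."""

import numpy as np
import pytest
from scipy import ndimage

from starchir import synth
from starchir.imaging import (
    HotspotConfig,
    HyperspectralCube,
    annulus_background,
    colocalized_hotspots,
    concat_mosaic,
    extract_asc_spectra,
    hotspot_mean_spectrum,
    integrate_roi,
    read_envi,
    write_envi,
)
from starchir.mineralization import band_presence, default_marker_panel
from starchir.spectra import ROIBand, WavenumberGrid, default_roi_panel


@pytest.fixture(scope="module")
def scene_grid():
    return synth.default_grid(step=8.0)


@pytest.fixture(scope="module")
def soil_sig():
    return synth.default_soil_signature()


def _uniform_cube(grid, trace, rows=8, cols=8):
    data = np.broadcast_to(trace, (rows, cols, trace.size)).copy()
    return HyperspectralCube(data, grid)


class TestIntegrateROI:
    def test_identical_spectra_give_constant_map(self, scene_grid):
        trace = np.exp(-0.5 * ((scene_grid.values - 1030) / 80) ** 2)
        cube = _uniform_cube(scene_grid, trace)
        m = integrate_roi(cube, ROIBand("ROI3", 900, 1200), local_baseline=False)
        assert np.ptp(m.values) < 1e-9

    def test_rectangular_band_integral_is_area(self):
        grid = WavenumberGrid.regular(1000, 1060, 2)
        trace = np.where((grid.values >= 1020) & (grid.values <= 1030), 1.0, 0.0)
        cube = _uniform_cube(grid, trace, rows=1, cols=1)
        m = integrate_roi(cube, ROIBand("r", 1020, 1030), local_baseline=False)
        assert m.values[0, 0] == pytest.approx(10.0)

    def test_additive_over_partition(self, scene_grid, rng):
        data = rng.uniform(0, 1, (4, 4, len(scene_grid)))
        cube = HyperspectralCube(data, scene_grid)
        whole = integrate_roi(cube, ROIBand("w", 900, 1200), local_baseline=False)
        a = integrate_roi(cube, ROIBand("a", 900, 1048), local_baseline=False)
        b = integrate_roi(cube, ROIBand("b", 1048, 1200), local_baseline=False)
        np.testing.assert_allclose(whole.values, a.values + b.values, rtol=1e-9)

    def test_fingerprint_map_peaks_inside_planted_particle(self, scene_grid, soil_sig, signatures16):
        p = synth.Particle(30, 30, 4.0, signatures16[0])
        scene = synth.SceneSpec(particles=(p,), soil_signature=soil_sig)
        cube, truth = synth.generate_hypercube(scene, scene_grid, seed=8)
        m = integrate_roi(cube, ROIBand("ROI3", 900, 1200))
        peak = np.unravel_index(np.argmax(m.values), m.values.shape)
        assert truth.masks[0][peak]

    def test_roi_outside_grid_rejected(self, scene_grid):
        cube = _uniform_cube(scene_grid, np.zeros(len(scene_grid)))
        with pytest.raises(ValueError):
            integrate_roi(cube, ROIBand("x", 4200, 4300))


class TestColocalizedHotspots:
    def test_empty_scene_has_no_hotspots(self, scene_grid, soil_sig):
        for seed in range(3):
            scene = synth.SceneSpec(particles=(), soil_signature=soil_sig)
            cube, _ = synth.generate_hypercube(scene, scene_grid, seed=seed)
            maps = [integrate_roi(cube, roi) for roi in default_roi_panel()]
            assert len(colocalized_hotspots(maps)) == 0

    def test_two_disjoint_particles_found(self, scene_grid, soil_sig, signatures16):
        ps = (
            synth.Particle(16, 16, 4.0, signatures16[0]),
            synth.Particle(48, 48, 4.0, signatures16[3]),
        )
        scene = synth.SceneSpec(particles=ps, soil_signature=soil_sig)
        cube, truth = synth.generate_hypercube(scene, scene_grid, seed=21)
        maps = [integrate_roi(cube, roi) for roi in default_roi_panel()]
        hs = colocalized_hotspots(maps)
        assert len(hs) == 2
        hit = sum(
            any((h.mask & m).any() for h in hs.hotspots) for m in truth.masks
        )
        assert hit == 2

    def test_mineral_blob_rejected_starch_kept(self, scene_grid, soil_sig, signatures16):
        """A silicate-only blob lights up the fingerprint map but lacks the
        O-H/C-H co-localization, mimicking the 'false hotspots' soil causes."""
        silicate_label = synth.ClassLabel("quartz blob", "contaminant", "mineral")
        silicate_sig = synth.ClassSignature(
            silicate_label,
            tuple(synth.BandComponent(1030.0, 1.2, 150.0) for _ in range(1)),
            amp_cv=0.0,
            center_jitter_sd=0.0,
        )
        ps = (
            synth.Particle(16, 16, 4.0, signatures16[0]),
            synth.Particle(48, 48, 4.0, silicate_sig),
        )
        scene = synth.SceneSpec(particles=ps, soil_signature=soil_sig)
        cube, truth = synth.generate_hypercube(scene, scene_grid, seed=31)
        maps = [integrate_roi(cube, roi) for roi in default_roi_panel()]
        hs = colocalized_hotspots(maps)
        assert len(hs) == 1
        assert (hs.hotspots[0].mask & truth.masks[0]).any()
        assert not (hs.hotspots[0].mask & truth.masks[1]).any()

    def test_dimension_mismatch_rejected(self, scene_grid):
        from starchir.imaging import ChemicalMap

        a = ChemicalMap(np.zeros((8, 8)), ROIBand("a", 900, 1200))
        b = ChemicalMap(np.zeros((8, 9)), ROIBand("b", 2800, 3000))
        with pytest.raises(ValueError):
            colocalized_hotspots([a, b, a])

    def test_min_area_filters_single_pixels(self, rng):
        from starchir.imaging import ChemicalMap

        maps = []
        for b in default_roi_panel():
            vals = rng.normal(0, 1, (32, 32))
            vals[5, 5] = 50.0  # a single bright pixel co-localized in all maps
            maps.append(ChemicalMap(vals, b))
        assert len(colocalized_hotspots(maps, min_area=4)) == 0
        assert len(colocalized_hotspots(maps, min_area=1)) >= 1


class TestHotspotSpectra:
    def test_single_pixel_mask_returns_that_pixel(self, scene_grid, rng):
        data = rng.uniform(0, 1, (6, 6, len(scene_grid)))
        cube = HyperspectralCube(data, scene_grid)
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 3] = True
        np.testing.assert_array_equal(
            hotspot_mean_spectrum(cube, mask).absorbance, data[2, 3]
        )

    def test_mean_of_identical_spectra_is_unchanged(self, scene_grid):
        trace = np.linspace(0, 1, len(scene_grid))
        cube = _uniform_cube(scene_grid, trace)
        mask = np.zeros((8, 8), dtype=bool)
        mask[1:3, 1:3] = True
        np.testing.assert_allclose(hotspot_mean_spectrum(cube, mask).absorbance, trace)

    def test_empty_mask_rejected(self, scene_grid):
        cube = _uniform_cube(scene_grid, np.zeros(len(scene_grid)))
        with pytest.raises(ValueError):
            hotspot_mean_spectrum(cube, np.zeros((8, 8), dtype=bool))

    def test_blended_edge_bounded_by_endmembers(self, scene_grid, soil_sig, signatures16):
        p = synth.Particle(32, 32, 5.0, signatures16[0])
        scene = synth.SceneSpec(
            particles=(p,), soil_signature=soil_sig, noise_sd=0.0, soil_texture_sd=0.0
        )
        cube, truth = synth.generate_hypercube(scene, scene_grid, seed=2)
        soil_px = cube.data[0, 0]
        center_px = cube.data[32, 32]
        edge = truth.masks[0] & ~ndimage.binary_erosion(truth.masks[0])
        mean_edge = cube.data[edge].mean(axis=0)
        lo = np.minimum(soil_px, center_px) - 1e-9
        hi = np.maximum(soil_px, center_px) + 1e-9
        assert np.all(mean_edge >= lo) and np.all(mean_edge <= hi)


class TestAnnulus:
    def test_width_one_interior_pixel_has_eight_neighbors(self, scene_grid):
        cube = _uniform_cube(scene_grid, np.ones(len(scene_grid)))
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        bg = annulus_background(cube, mask, width=1)
        assert bg.meta["n_pixels"] == 8

    def test_matches_chebyshev_bruteforce(self, scene_grid, rng):
        data = rng.uniform(0, 1, (10, 10, len(scene_grid)))
        cube = HyperspectralCube(data, scene_grid)
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:5, 4:7] = True
        width = 2
        expected = np.zeros_like(mask)
        for r in range(10):
            for c in range(10):
                if mask[r, c]:
                    continue
                rr, cc = np.nonzero(mask)
                if np.min(np.maximum(np.abs(rr - r), np.abs(cc - c))) <= width:
                    expected[r, c] = True
        bg = annulus_background(cube, mask, width=width)
        np.testing.assert_allclose(bg.absorbance, data[expected].mean(axis=0))

    def test_excludes_other_hotspots(self, scene_grid):
        cube = _uniform_cube(scene_grid, np.ones(len(scene_grid)))
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        other = np.zeros((8, 8), dtype=bool)
        other[4, 5] = True
        bg = annulus_background(cube, mask, width=1, exclude=other)
        assert bg.meta["n_pixels"] == 7

    def test_empty_annulus_rejected(self, scene_grid):
        cube = _uniform_cube(scene_grid, np.ones(len(scene_grid)), rows=3, cols=3)
        mask = np.ones((3, 3), dtype=bool)
        with pytest.raises(ValueError):
            annulus_background(cube, mask, width=1)

    def test_annulus_recovers_soil_signature(self, scene_grid, soil_sig, signatures16):
        p = synth.Particle(32, 32, 4.0, signatures16[0])
        scene = synth.SceneSpec(particles=(p,), soil_signature=soil_sig, noise_sd=0.001)
        cube, truth = synth.generate_hypercube(scene, scene_grid, seed=3)
        soil_pure = synth.synthesize_spectrum(
            soil_sig, scene_grid, noise_sd=0.0,
            rng=np.random.default_rng(0), drift_scale=0.0
        )
        bg = annulus_background(cube, truth.masks[0], width=3)
        r = np.corrcoef(bg.absorbance, soil_pure.absorbance)[0, 1]
        assert r > 0.99


class TestExtraction:
    def test_planted_particles_recovered_with_correlated_spectra(
        self, scene_grid, soil_sig, signatures16
    ):
        chosen = [signatures16[i] for i in (0, 5, 10)]
        ps = tuple(
            synth.Particle(r, c, 4.0, sig)
            for (r, c), sig in zip(((14, 14), (32, 48), (50, 16)), chosen)
        )
        scene = synth.SceneSpec(particles=ps, soil_signature=soil_sig)
        cube, truth = synth.generate_hypercube(scene, scene_grid, seed=13)
        hs, specs = extract_asc_spectra(cube)
        assert len(specs) == 3
        sel = (scene_grid.values >= 900) & (scene_grid.values <= 1800)
        for h, spec in zip(hs.hotspots, specs):
            which = next(
                i for i, m in enumerate(truth.masks) if (h.mask & m).sum() > 0
            )
            pure = synth.synthesize_spectrum(
                chosen[which].scaled(ps[which].thickness), scene_grid, noise_sd=0.0,
                rng=np.random.default_rng(0), drift_scale=0.0,
            )
            r = np.corrcoef(spec.absorbance[sel], pure.absorbance[sel])[0, 1]
            assert r > 0.9

    def test_empty_scene_yields_empty_list(self, scene_grid, soil_sig):
        scene = synth.SceneSpec(particles=(), soil_signature=soil_sig)
        cube, _ = synth.generate_hypercube(scene, scene_grid, seed=17)
        hs, specs = extract_asc_spectra(cube)
        assert specs == []

    def test_mineralized_particle_keeps_carbonate_markers(
        self, scene_grid, soil_sig, signatures16
    ):
        aging = synth.AgingModel(mineral_fraction=0.5, mineral_mix={"carbonate": 1.0})
        p = synth.Particle(32, 32, 5.0, signatures16[2], aging=aging)
        scene = synth.SceneSpec(particles=(p,), soil_signature=soil_sig)
        cube, _ = synth.generate_hypercube(scene, scene_grid, seed=19)
        _, specs = extract_asc_spectra(cube)
        assert len(specs) >= 1
        panel = default_marker_panel()
        score = band_presence(specs[0], panel.bands["carbonate_main"], kappa=panel.kappa)
        assert score > 0.5


class TestCubeIO:
    def test_envi_round_trip(self, tmp_path, scene_grid, rng):
        data = rng.uniform(0, 1, (6, 7, len(scene_grid)))
        cube = HyperspectralCube(data, scene_grid, pixel_size=2.6, meta={})
        write_envi(cube, tmp_path / "cube")
        back = read_envi(tmp_path / "cube")
        assert back.n_rows == 6 and back.n_cols == 7
        np.testing.assert_allclose(back.grid.values, scene_grid.values, rtol=1e-6)
        np.testing.assert_allclose(back.data, data, atol=1e-6)
        assert back.pixel_size == pytest.approx(2.6)

    def test_mosaic_concatenation(self, scene_grid):
        t = _uniform_cube(scene_grid, np.ones(len(scene_grid)), rows=4, cols=4)
        mosaic = concat_mosaic([[t, t], [t, t]])
        assert mosaic.n_rows == 8 and mosaic.n_cols == 8

    def test_hotspot_config_validation(self):
        with pytest.raises(ValueError):
            HotspotConfig(percentile=120)
        with pytest.raises(ValueError):
            HotspotConfig(mode="three_of_two")
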