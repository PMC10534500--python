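"""CLS unmixing: operator identities, recovery oracles, mean features."""

import numpy as np
import pytest

from dissomap.cube import PureComponentLibrary
from dissomap.synth import generate_particle_map, render_cube
from dissomap.preprocess import preprocess_nir, preprocess_raman
from dissomap.unmix import (
    RankDeficientLibraryError,
    concentration_map,
    fit_cls,
    mean_concentration,
    mean_shift_correction,
    unmix_pixel,
    ConcentrationMap,
)


def library_from(matrix, modality="nir"):
    names = tuple(f"C{i}" for i in range(matrix.shape[0]))
    return PureComponentLibrary(names, matrix, np.arange(matrix.shape[1], dtype=float), modality)


class TestFitCls:
    def test_orthonormal_rows_give_library_back(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(40, 3)))
        lib = library_from(q.T)
        op = fit_cls(lib)
        assert np.allclose(op.matrix, q.T, atol=1e-12)

    def test_operator_times_library_is_identity(self, rng):
        lib = library_from(rng.normal(size=(5, 60)))
        op = fit_cls(lib)
        assert np.allclose(op.matrix @ lib.spectra.T, np.eye(5), atol=1e-8)

    def test_duplicate_component_raises(self, rng):
        row = rng.normal(size=60)
        lib = library_from(np.stack([row, row, rng.normal(size=60)]))
        with pytest.raises(RankDeficientLibraryError):
            fit_cls(lib)

    def test_more_components_than_bands_rejected(self, rng):
        with pytest.raises(ValueError, match="bands"):
            fit_cls(library_from(rng.normal(size=(5, 4))))


class TestUnmixPixel:
    @pytest.fixture(scope="class")
    def op(self):
        rng = np.random.default_rng(3)
        self_lib = library_from(rng.normal(size=(5, 80)))
        return self_lib, fit_cls(self_lib)

    def test_pure_component_recovery(self, op):
        lib, operator = op
        a = unmix_pixel(operator, lib.spectra[1])
        expected = np.zeros(5)
        expected[1] = 1.0
        assert np.allclose(a, expected, atol=1e-9)

    def test_two_component_mixture_oracle(self, op):
        lib, operator = op
        mix = 0.3 * lib.spectra[1] + 0.7 * lib.spectra[2]
        a = unmix_pixel(operator, mix)
        oracle, *_ = np.linalg.lstsq(lib.spectra.T, mix, rcond=None)
        assert np.allclose(a, np.clip(oracle, 0, None), atol=1e-9)
        assert a[1] == pytest.approx(0.3, abs=1e-9)
        assert a[2] == pytest.approx(0.7, abs=1e-9)

    def test_negative_abundance_clamped(self, op):
        lib, operator = op
        a = unmix_pixel(operator, -lib.spectra[1])
        assert a[1] == 0.0
        raw = unmix_pixel(operator, -lib.spectra[1], clamp=False)
        assert raw[1] == pytest.approx(-1.0, abs=1e-9)

    def test_length_mismatch(self, op):
        _, operator = op
        with pytest.raises(ValueError, match="length"):
            unmix_pixel(operator, np.zeros(7))


class TestConcentrationMap:
    def test_noiseless_nir_recovers_ground_truth(self, nir_library, particle_map_nir):
        cube = render_cube(particle_map_nir, nir_library, noise_sd=0.0)
        op = fit_cls(preprocess_nir(nir_library))
        cmap = concentration_map(op, preprocess_nir(cube), "HPMC")
        truth = 100.0 * particle_map_nir.component_fraction("HPMC")
        assert cmap.shape == (48, 48)
        assert np.max(np.abs(cmap.values - truth)) < 1e-6

    def test_raman_map_shape(self, raman_library, particle_map_raman):
        cube = render_cube(particle_map_raman, raman_library, noise_sd=0.0)
        op = fit_cls(preprocess_raman(raman_library))
        cmap = concentration_map(op, preprocess_raman(cube), "HPMC")
        assert cmap.shape == (31, 31)

    def test_absent_component_maps_to_zero(self, nir_library, design_20pct):
        no_hpmc = design_20pct.with_hpmc_frac(0.0)
        pm = generate_particle_map(no_hpmc, (20, 20), 25.0, seed=1)
        cube = render_cube(pm, nir_library, noise_sd=0.0)
        op = fit_cls(preprocess_nir(nir_library))
        cmap = concentration_map(op, preprocess_nir(cube), "HPMC")
        assert np.allclose(cmap.values, 0.0, atol=1e-6)

    def test_raman_recipe_proportional_recovery(self, raman_library, particle_map_raman):
        """Area normalization leaves abundances proportional to fractions."""
        cube = render_cube(particle_map_raman, raman_library, noise_sd=0.0)
        op = fit_cls(preprocess_raman(raman_library))
        cmap = concentration_map(op, preprocess_raman(cube), "HPMC")
        truth = 100.0 * particle_map_raman.component_fraction("HPMC")
        a, b = cmap.values.ravel(), truth.ravel()
        slope = np.polyfit(b / b.mean(), a / a.mean(), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_noise_increases_recovery_error_monotonically(self, nir_library, particle_map_nir):
        op = fit_cls(preprocess_nir(nir_library))
        truth = particle_map_nir.component_fraction("HPMC")
        errors = []
        for noise in (0.0, 0.02, 0.1):
            rmses = []
            for seed in (1, 2, 3):
                cube = render_cube(particle_map_nir, nir_library, noise, seed=seed)
                cmap = concentration_map(op, preprocess_nir(cube), "HPMC")
                rmses.append(np.sqrt(np.mean((cmap.values / 100 - truth) ** 2)))
            errors.append(np.mean(rmses))
        assert errors[0] < errors[1] < errors[2]

    def test_higher_similarity_inflates_error_spread(self, particle_map_nir, design_20pct):
        from dissomap.synth import generate_pure_spectra

        spreads = []
        for target in (0.6, 0.97):
            devs = []
            for seed in (1, 2, 3):
                lib = generate_pure_spectra("nir", 240, target, seed=seed)
                op = fit_cls(preprocess_nir(lib))
                cube = render_cube(particle_map_nir, lib, noise_sd=0.02, seed=seed)
                cmap = concentration_map(op, preprocess_nir(cube), "HPMC")
                truth = 100.0 * particle_map_nir.component_fraction("HPMC")
                devs.append(np.std(cmap.values - truth))
            spreads.append(np.mean(devs))
        assert spreads[1] > spreads[0]


class TestMeanFeatures:
    def test_mean_of_uniform_map(self):
        cmap = ConcentrationMap(np.full((10, 10), 20.0), "HPMC", 25.0)
        assert mean_concentration(cmap) == 20.0

    def test_mean_half_and_half(self):
        values = np.concatenate([np.zeros((5, 10)), np.full((5, 10), 40.0)])
        assert mean_concentration(ConcentrationMap(values, "HPMC", 25.0)) == 20.0

    def test_mean_matches_loop_oracle(self, rng):
        values = rng.uniform(0, 40, size=(13, 17))
        total = 0.0
        for row in values:
            for v in row:
                total += v
        cmap = ConcentrationMap(values, "HPMC", 25.0)
        assert mean_concentration(cmap) == pytest.approx(total / values.size, abs=1e-12)

    def test_mean_shift_correction(self):
        pred = np.array([10.0, 15.0, 20.0])
        ref = pred + 6.85
        shifted = mean_shift_correction(pred, ref)
        assert np.allclose(shifted, pred + 6.85)
        assert shifted.mean() == pytest.approx(ref.mean())
        assert np.std(shifted) == pytest.approx(np.std(pred))

    def test_mean_shift_zero_when_equal(self, rng):
        pred = rng.uniform(0, 30, 8)
        assert np.allclose(mean_shift_correction(pred, pred), pred)

    def test_mean_shift_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_shift_correction(np.array([]), np.array([]))
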