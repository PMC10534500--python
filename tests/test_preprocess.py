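"""Savitzky-Golay, AsLS Whittaker baseline, normalization and the recipes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dissomap.preprocess as pp
from dissomap.preprocess import (
    DegenerateSpectrumError,
    PreprocessConfig,
    normalize,
    preprocess_nir,
    preprocess_raman,
    savitzky_golay,
    whittaker_baseline,
    whittaker_smooth,
)


class TestSavitzkyGolay:
    def test_reproduces_quadratic_exactly(self):
        x = np.arange(120.0)
        quad = 3.0 + 0.5 * x - 0.01 * x**2
        assert np.allclose(savitzky_golay(quad, 15, 2), quad, atol=1e-9)

    def test_derivative_of_line_is_slope(self):
        x = np.arange(100.0)
        out = savitzky_golay(0.5 * x + 3.0, 15, 2, deriv=1)
        assert np.allclose(out, 0.5, atol=1e-10)

    def test_matches_sliding_polyfit_oracle(self, rng):
        spec = rng.normal(size=200)
        out = savitzky_golay(spec, 15, 2)
        for i in rng.integers(7, 193, size=5):
            w = spec[i - 7 : i + 8]
            coeffs = np.polyfit(np.arange(-7, 8), w, 2)
            assert out[i] == pytest.approx(np.polyval(coeffs, 0.0), abs=1e-10)

    def test_derivative_kills_offsets(self, rng):
        spec = rng.normal(size=150)
        assert np.allclose(
            savitzky_golay(spec, 15, 2, deriv=1),
            savitzky_golay(spec + 42.0, 15, 2, deriv=1),
            atol=1e-10,
        )

    def test_window_validation(self):
        with pytest.raises(ValueError, match="odd"):
            savitzky_golay(np.zeros(50), window=14)
        with pytest.raises(ValueError, match="window"):
            savitzky_golay(np.zeros(10), window=15)


class TestWhittakerBaseline:
    def test_flat_spectrum_is_fixed_point(self):
        flat = np.full(200, 3.7)
        assert np.allclose(whittaker_baseline(flat), 3.7, atol=1e-6)

    @staticmethod
    def asls_oracle(y, lam=10_000.0, p=0.001, n_iter=50):
        """Independent IRLS implementation on sparse matrices."""
        from scipy import sparse
        from scipy.sparse.linalg import spsolve

        n = y.size
        d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
        penalty = lam * (d.T @ d)
        w = np.ones(n)
        z = y
        for _ in range(n_iter):
            z = spsolve((sparse.diags(w) + penalty).tocsc(), w * y)
            w = np.where(y > z, p, 1.0 - p)
        return z

    def test_baseline_under_peak_matches_irls_oracle(self):
        x = np.arange(300.0)
        level = 2.0
        spec = level + 5.0 * np.exp(-0.5 * ((x - 150) / 6) ** 2)
        base = whittaker_baseline(spec)
        oracle = self.asls_oracle(spec)
        assert np.allclose(base, oracle, atol=1e-8)
        # at peak-free bands the baseline tracks the flat level closely
        assert np.allclose(base[:100], level, atol=0.03 * level)
        assert base[150] < spec[150]

    def test_symmetric_limit_matches_uniform_weight_solve(self, rng):
        y = rng.normal(size=150)
        base = whittaker_baseline(y, lam=100.0, p=0.499999, max_iter=1)
        smooth = whittaker_smooth(y, lam=100.0)
        # with p ~ 0.5 the first IRLS iterate is the symmetric smooth / 2 weights
        assert np.allclose(base, smooth, atol=1e-3)

    def test_additive_constant_shifts_baseline(self, rng):
        y = np.abs(rng.normal(size=200)) + np.sin(np.linspace(0, 3, 200))
        b0 = whittaker_baseline(y)
        b1 = whittaker_baseline(y + 5.0)
        assert np.allclose(b1 - b0, 5.0, atol=1e-6)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="short"):
            whittaker_baseline(np.zeros(5))


class TestNormalize:
    def test_uniform_area_case(self):
        assert np.allclose(normalize(np.array([2.0, 2.0, 2.0, 2.0])), 0.25)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_area_norm_identity_and_homogeneity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=50)
        out = normalize(x, "area")
        assert np.sum(np.abs(out)) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(normalize(3.7 * x, "area"), out)

    def test_vector_mode(self, rng):
        x = rng.normal(size=30)
        assert np.linalg.norm(normalize(x, "vector")) == pytest.approx(1.0)

    def test_zero_spectrum_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            normalize(np.zeros(20))


class TestRecipes:
    def test_raman_output_has_unit_area_per_pixel(self, raman_library, particle_map_raman):
        from dissomap.synth import render_cube

        cube = render_cube(particle_map_raman, raman_library, 0.01, 0.5, seed=1)
        out = preprocess_raman(cube)
        areas = np.sum(np.abs(out.data), axis=-1)
        assert np.allclose(areas, 1.0, atol=1e-9)

    def test_raman_stage_order(self, monkeypatch, raman_library):
        calls = []
        orig = {
            "savitzky_golay": pp.savitzky_golay,
            "whittaker_baseline": pp.whittaker_baseline,
            "normalize": pp.normalize,
        }
        for name, fn in orig.items():
            monkeypatch.setattr(
                pp, name,
                (lambda f, n: lambda *a, **k: (calls.append(n), f(*a, **k))[1])(fn, name),
            )
        pp.preprocess_raman(raman_library)
        assert calls == ["savitzky_golay", "whittaker_baseline", "normalize"]

    def test_flat_spectrum_becomes_degenerate_after_baseline(self):
        flat = np.full((1, 200), 2.0)
        with pytest.raises(DegenerateSpectrumError):
            preprocess_raman(flat)

    def test_nir_constant_maps_to_zero(self):
        out = preprocess_nir(np.full((2, 100), 7.0))
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_nir_is_linear_operator(self, rng):
        x = rng.normal(size=120)
        y = rng.normal(size=120)
        lhs = preprocess_nir(2.5 * x - 1.5 * y)
        rhs = 2.5 * preprocess_nir(x) - 1.5 * preprocess_nir(y)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_nir_ramp_derivative(self):
        ramp = 0.5 * np.arange(100.0)
        assert np.allclose(preprocess_nir(ramp), 0.5, atol=1e-10)

    def test_recipe_guards_deriv_order(self):
        with pytest.raises(ValueError, match="deriv"):
            preprocess_raman(np.zeros((1, 50)), PreprocessConfig(deriv_order=1))
        with pytest.raises(ValueError, match="deriv"):
            preprocess_nir(np.zeros((1, 50)), PreprocessConfig(deriv_order=0))

    def test_library_and_pure_pixel_cube_match(self, nir_library):
        """CLS consistency: identical treatment of cube pixels and library."""
        from dissomap.cube import HyperspectralCube

        k = 1  # HPMC
        data = np.tile(nir_library.spectrum("HPMC"), (2, 2, 1))
        cube = HyperspectralCube(data, nir_library.band_axis, 25.0, "nir")
        pre_cube = preprocess_nir(cube)
        pre_lib = preprocess_nir(nir_library)
        assert np.allclose(pre_cube.data[0, 0], pre_lib.spectra[k], atol=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(sg_window=14)
    with pytest.raises(ValueError):
        PreprocessConfig(whittaker_p=0.0)
    with pytest.raises(ValueError):
        PreprocessConfig(normalization="max")
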