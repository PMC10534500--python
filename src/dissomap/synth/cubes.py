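"""Rendering of hyperspectral cubes from composition maps.

Each pixel spectrum is the fraction-weighted sum of the pure-component
spectra (the linear mixing model CLS assumes) plus a smooth additive
baseline scaled by the local MCC fraction and i.i.d. Gaussian noise.  The
baseline emulates the dominant nuisance of each modality: for Raman a broad
fluorescence-like hump (MCC is the main fluorophore in this formulation),
modelled as a 4th-order polynomial in band index; for NIR a gentle additive
scatter slope.
"""

from __future__ import annotations

import numpy as np

from ..cube import HyperspectralCube, PureComponentLibrary
from .particles import ParticleMap

__all__ = ["scatter_baseline", "render_cube"]


def _baseline_shape(modality: str, n_bands: int) -> np.ndarray:
    """Unit-peak smooth baseline shape per modality."""
    x = np.linspace(0.0, 1.0, n_bands)
    if modality == "raman":
        # degree-4 polynomial fit to a broad fluorescence-like hump; the fit
        # stays positive on [0, 1] and is exactly polynomial in band index
        hump = np.exp(-0.5 * ((x - 0.4) / 0.45) ** 2)
        coeffs = np.polynomial.polynomial.polyfit(x, hump, 4)
        shape = np.polynomial.polynomial.polyval(x, coeffs)
    else:
        shape = x.copy()
    peak = np.abs(shape).max()
    return shape / peak if peak > 0 else shape


def scatter_baseline(
    pmap: ParticleMap, library: PureComponentLibrary, amplitude: float
) -> np.ndarray:
    """The (H, W, B) additive baseline term of a rendered cube.

    Scaled per pixel by the local MCC fraction times ``amplitude``.  Exposed
    separately so callers (and tests) can subtract the exact baseline from a
    rendered cube.
    """
    shape = _baseline_shape(library.modality, library.n_bands)
    mcc = pmap.component_fraction("MCC")
    return amplitude * mcc[:, :, None] * shape[None, None, :]


def render_cube(
    pmap: ParticleMap,
    library: PureComponentLibrary,
    noise_sd: float = 0.0,
    baseline_amplitude: float = 0.0,
    seed: int = 0,
) -> HyperspectralCube:
    """Render the chemical image of one composition map.

    cube[i, j, :] = sum_k grid[i, j, k] * S_k + baseline + N(0, noise_sd).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if pmap.grid.shape[2] != library.n_components:
        raise ValueError(
            f"map has {pmap.grid.shape[2]} components, library {library.n_components}"
        )
    data = pmap.grid @ library.spectra  # (H, W, K) @ (K, B) -> (H, W, B)
    if baseline_amplitude != 0.0:
        data = data + scatter_baseline(pmap, library, baseline_amplitude)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return HyperspectralCube(data, library.band_axis, pmap.pixel_pitch_um, library.modality)
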