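"""Spectral preprocessing ahead of CLS unmixing.

Two fixed recipes are used, applied identically to image pixels and to the
pure-component library (a requirement for CLS consistency):

* Raman: Savitzky-Golay smoothing (window 15, 2nd-order polynomial), then
  subtraction of an asymmetric-least-squares Whittaker baseline
  (lambda = 10,000, p = 0.001) to strip the fluorescence background, then
  total-area normalization.
* NIR: Savitzky-Golay first derivative (window 15, 2nd-order polynomial),
  which removes additive offsets and enhances the broad overlapping bands.

The Whittaker baseline is the Eilers asymmetric-least-squares smoother: a
penalized regression with a second-difference roughness penalty, iteratively
reweighted so points above the current baseline (peaks) get weight p and
points below get 1 - p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .cube import HyperspectralCube, PureComponentLibrary

__all__ = [
    "PreprocessConfig",
    "DegenerateSpectrumError",
    "savitzky_golay",
    "whittaker_baseline",
    "whittaker_smooth",
    "normalize",
    "preprocess_raman",
    "preprocess_nir",
    "preprocess",
]

logger = logging.getLogger(__name__)


class DegenerateSpectrumError(ValueError):
    """Spectrum with (near-)zero norm cannot be normalized."""


@dataclass(frozen=True)
class PreprocessConfig:
    sg_window: int = 15
    sg_polyorder: int = 2
    deriv_order: int = 0
    whittaker_lambda: float = 10_000.0
    whittaker_p: float = 0.001
    normalization: str = "area"  # area | vector | none

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.deriv_order not in (0, 1):
            raise ValueError("deriv_order must be 0 or 1")
        if not 0.0 < self.whittaker_p < 1.0:
            raise ValueError("whittaker_p must be in (0, 1)")
        if self.whittaker_lambda <= 0:
            raise ValueError("whittaker_lambda must be > 0")
        if self.normalization not in ("area", "vector", "none"):
            raise ValueError("normalization must be area|vector|none")


def savitzky_golay(
    spectrum: np.ndarray, window: int = 15, polyorder: int = 2, deriv: int = 0
) -> np.ndarray:
    """Savitzky-Golay filter along the band axis (last axis).

    The derivative is taken with respect to the band index (unit spacing);
    edges are handled by a least-squares polynomial fit over the edge window
    rather than padding, so no intensity is fabricated beyond the spectrum.
    """
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if x.shape[-1] < window:
        raise ValueError(f"spectrum length {x.shape[-1]} < window {window}")
    return savgol_filter(x, window, polyorder, deriv=deriv, delta=1.0, axis=-1, mode="interp")


@lru_cache(maxsize=8)
def _penalty_bands(n: int, lam: float) -> np.ndarray:
    """Upper banded form of lam * D2'D2 (second-difference penalty)."""
    d2 = np.zeros((3, n))
    # stencil of D'D for D the (n-2) x n second-difference operator
    diag = np.full(n, 6.0)
    diag[[0, -1]] = 1.0
    diag[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.full(n - 2, 1.0)
    d2[0, 2:] = lam * off2
    d2[1, 1:] = lam * off1
    d2[2, :] = lam * diag
    return d2


def _weighted_whittaker_solve(y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    n = y.size
    ab = _penalty_bands(n, lam).copy()
    ab[2, :] += w
    return solveh_banded(ab, w * y)


def whittaker_smooth(spectrum: np.ndarray, lam: float) -> np.ndarray:
    """Symmetric Whittaker smooth (uniform weights)."""
    y = np.asarray(spectrum, dtype=float)
    return _weighted_whittaker_solve(y, np.ones(y.size), lam)


def whittaker_baseline(
    spectrum: np.ndarray,
    lam: float = 10_000.0,
    p: float = 0.001,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate of one or more spectra.

    Returns the baseline (same shape as the input); subtract it from the
    input to baseline-correct.  Non-convergence after ``max_iter``
    iterations is logged and the last iterate returned.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.shape[-1] < 10:
        raise ValueError("spectrum too short for baseline estimation (need >= 10 bands)")
    if y.ndim == 1:
        return _asls_single(y, lam, p, max_iter, tol)
    flat = y.reshape(-1, y.shape[-1])
    out = np.empty_like(flat)
    for i, row in enumerate(flat):
        out[i] = _asls_single(row, lam, p, max_iter, tol)
    return out.reshape(y.shape)


def _asls_single(y: np.ndarray, lam: float, p: float, max_iter: int, tol: float) -> np.ndarray:
    w = np.ones(y.size)
    z_prev = None
    scale = max(float(np.max(np.abs(y))), 1.0)
    for _ in range(max_iter):
        z = _weighted_whittaker_solve(y, w, lam)
        w_new = np.where(y > z, p, 1.0 - p)
        # converged when the weight pattern is stable, or when the baseline
        # itself stops moving (weights can keep flipping on numerical noise)
        if np.max(np.abs(w_new - w)) < tol:
            return z
        if z_prev is not None and np.max(np.abs(z - z_prev)) < 1e-10 * scale:
            return z
        w, z_prev = w_new, z
    logger.warning("AsLS baseline did not converge in %d iterations", max_iter)
    return z


def normalize(spectrum: np.ndarray, mode: str = "area", atol: float = 1e-6) -> np.ndarray:
    """Normalize spectra (last axis) to unit area (sum |x|) or unit vector norm."""
    x = np.asarray(spectrum, dtype=float)
    if mode == "area":
        norms = np.sum(np.abs(x), axis=-1, keepdims=True)
    elif mode == "vector":
        norms = np.sqrt(np.sum(x**2, axis=-1, keepdims=True))
    elif mode == "none":
        return x.copy()
    else:
        raise ValueError("mode must be area|vector|none")
    if np.any(norms < atol):
        raise DegenerateSpectrumError(
            f"{int(np.sum(norms < atol))} spectrum/spectra with norm < {atol}"
        )
    return x / norms


def _as_matrix(spectra) -> tuple[np.ndarray, callable]:
    """View cube/library/array input as a 2-D (n_spectra, B) matrix plus a
    rebuilder mapping a processed matrix back onto the input's type."""
    if isinstance(spectra, HyperspectralCube):
        h, w, b = spectra.shape
        return spectra.data.reshape(-1, b), lambda m: spectra.with_data(m.reshape(h, w, b))
    if isinstance(spectra, PureComponentLibrary):
        return spectra.spectra, lambda m: spectra.with_spectra(m)
    arr = np.asarray(spectra, dtype=float)
    shape = arr.shape
    return arr.reshape(-1, shape[-1]), lambda m: m.reshape(shape)


def preprocess_raman(spectra, cfg: PreprocessConfig | None = None):
    """Raman recipe: SG smoothing -> Whittaker baseline subtraction ->
    normalization, per spectrum.  Accepts a cube, a library or an array."""
    cfg = cfg or PreprocessConfig(deriv_order=0)
    if cfg.deriv_order != 0:
        raise ValueError("Raman recipe requires deriv_order = 0")
    matrix, rebuild = _as_matrix(spectra)
    smoothed = savitzky_golay(matrix, cfg.sg_window, cfg.sg_polyorder, deriv=0)
    baseline = whittaker_baseline(smoothed, cfg.whittaker_lambda, cfg.whittaker_p)
    corrected = smoothed - baseline
    if cfg.normalization != "none":
        corrected = normalize(corrected, cfg.normalization)
    return rebuild(corrected)


def preprocess_nir(spectra, cfg: PreprocessConfig | None = None):
    """NIR recipe: SG first derivative per spectrum; no baseline step, no
    normalization (the derivative already removes additive offsets)."""
    cfg = cfg or PreprocessConfig(deriv_order=1)
    if cfg.deriv_order != 1:
        raise ValueError("NIR recipe requires deriv_order = 1")
    matrix, rebuild = _as_matrix(spectra)
    return rebuild(savitzky_golay(matrix, cfg.sg_window, cfg.sg_polyorder, deriv=1))


def preprocess(spectra, modality: str, cfg: PreprocessConfig | None = None):
    """Dispatch to the modality's recipe."""
    if modality == "raman":
        return preprocess_raman(spectra, cfg)
    if modality == "nir":
        return preprocess_nir(spectra, cfg)
    raise ValueError("modality must be 'raman' or 'nir'")
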