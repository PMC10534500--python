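"""Classical least squares (CLS) unmixing of chemical images.

CLS assumes each preprocessed pixel spectrum is a linear combination of the
preprocessed pure-component spectra, s = L^T a, and estimates the abundance
vector a per pixel by unconstrained least squares, a = (L L^T)^-1 L s.
Negative abundances are clamped to zero afterwards; no sum-to-one closure is
imposed, so systematic over/under-estimation of a component remains visible
(and is handled, for reporting only, by the mean-shift correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cube import HyperspectralCube, PureComponentLibrary

__all__ = [
    "RankDeficientLibraryError",
    "UnmixingOperator",
    "ConcentrationMap",
    "fit_cls",
    "unmix_pixel",
    "unmix_cube",
    "concentration_map",
    "mean_concentration",
    "mean_shift_correction",
]

logger = logging.getLogger(__name__)

#: condition numbers above this are logged as ill-conditioned
CONDITION_WARN_THRESHOLD = 1e6


class RankDeficientLibraryError(ValueError):
    """The pure-component library is numerically rank deficient."""


@dataclass(frozen=True)
class UnmixingOperator:
    """K x B operator mapping a preprocessed spectrum to K abundances."""

    component_names: tuple[str, ...]
    matrix: np.ndarray
    condition_number: float

    @property
    def n_components(self) -> int:
        return len(self.component_names)

    @property
    def n_bands(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ConcentrationMap:
    """H x W abundance map of one component, in w/w %."""

    values: np.ndarray
    component: str
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("concentration map must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("concentration map contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def fit_cls(library: PureComponentLibrary, rcond: float = 1e-10) -> UnmixingOperator:
    """Build the CLS operator (pseudo-inverse of the preprocessed library).

    Raises :class:`RankDeficientLibraryError` when the library's numerical
    rank is below its component count (e.g. duplicated spectra).
    """
    spectra = library.spectra
    k, b = spectra.shape
    if k < 2:
        raise ValueError("need at least 2 components")
    if k > b:
        raise ValueError(f"more components ({k}) than bands ({b})")
    sv = np.linalg.svd(spectra, compute_uv=False)
    if sv[-1] <= rcond * sv[0]:
        raise RankDeficientLibraryError(
            f"library rank < {k} (singular values {sv.round(6).tolist()})"
        )
    cond = float(sv[0] / sv[-1])
    if cond > CONDITION_WARN_THRESHOLD:
        logger.warning("ill-conditioned CLS library: condition number %.3g", cond)
    operator = np.linalg.solve(spectra @ spectra.T, spectra)
    return UnmixingOperator(library.names, operator, cond)


def unmix_pixel(op: UnmixingOperator, spectrum: np.ndarray, clamp: bool = True) -> np.ndarray:
    """Abundances of one preprocessed pixel spectrum (negatives clamped to 0)."""
    s = np.asarray(spectrum, dtype=float)
    if s.shape != (op.n_bands,):
        raise ValueError(f"spectrum length {s.shape} != operator bands {op.n_bands}")
    a = op.matrix @ s
    return np.clip(a, 0.0, None) if clamp else a


def unmix_cube(op: UnmixingOperator, cube: HyperspectralCube, clamp: bool = True) -> np.ndarray:
    """(H, W, K) abundances of a whole preprocessed cube."""
    if cube.n_bands != op.n_bands:
        raise ValueError(f"cube bands {cube.n_bands} != operator bands {op.n_bands}")
    a = cube.data @ op.matrix.T
    return np.clip(a, 0.0, None) if clamp else a


def concentration_map(
    op: UnmixingOperator, cube: HyperspectralCube, component: str = "HPMC"
) -> ConcentrationMap:
    """Per-pixel abundance of one component, scaled to w/w %."""
    if component not in op.component_names:
        raise ValueError(f"unknown component {component!r}")
    abundances = unmix_cube(op, cube)
    idx = op.component_names.index(component)
    return ConcentrationMap(100.0 * abundances[:, :, idx], component, cube.pixel_pitch_um)


def mean_concentration(cmap: ConcentrationMap) -> float:
    """Arithmetic mean over all map pixels, in w/w %."""
    if cmap.values.size == 0:
        raise ValueError("empty concentration map")
    return float(cmap.values.mean())


def mean_shift_correction(
    predicted_means: np.ndarray, reference_means: np.ndarray
) -> np.ndarray:
    """Add the mean bias (reference mean - predicted mean) to every prediction.

    A reporting-only correction of the systematic CLS bias: after the shift
    the predictions' mean equals the reference mean, while their spread is
    untouched.
    """
    pred = np.asarray(predicted_means, dtype=float)
    ref = np.asarray(reference_means, dtype=float)
    if pred.size == 0 or ref.size == 0:
        raise ValueError("empty input to mean_shift_correction")
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference lists must have equal length")
    return pred + (ref.mean() - pred.mean())
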