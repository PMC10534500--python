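"""Synthetic pure-component spectra.

Raman spectra are modelled as sums of narrow Gaussian peaks on a flat offset
(every component shows several sharp characteristic bands), NIR spectra as
sums of broad, strongly overlapping Gaussians, mimicking combination and
overtone bands.  Because the ability to tell HPMC from MCC is the crux of
the unmixing problem, the MCC spectrum is constructed to have an exactly
controlled Pearson correlation with the HPMC spectrum (``similarity_target``):
the MCC shape is a rho-weighted mixture of the standardized HPMC spectrum and
an orthogonalized independent peak spectrum, then shifted to stay positive
(an affine map, so the correlation is preserved exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..cube import COMPONENTS, PureComponentLibrary

__all__ = [
    "ComponentSpectrumModel",
    "generate_pure_spectra",
    "raman_band_axis",
    "nir_band_axis",
]

#: peak-count and width ranges (band-index units) per modality
_PEAK_COUNTS = {"raman": (4, 7), "nir": (3, 5)}
_WIDTH_RANGES = {"raman": (2.0, 5.0), "nir": (15.0, 45.0)}


def raman_band_axis(n_bands: int) -> np.ndarray:
    """Raman shift axis, 200-1800 cm^-1."""
    return np.linspace(200.0, 1800.0, n_bands)


def nir_band_axis(n_bands: int) -> np.ndarray:
    """NIR wavenumber axis, 4000-7800 cm^-1."""
    return np.linspace(4000.0, 7800.0, n_bands)


@dataclass(frozen=True)
class ComponentSpectrumModel:
    """Peak-list model of one pure-component spectrum.

    Peaks are (center, width, amplitude) in band-index units; the rendered
    spectrum is a sum of Gaussians plus a small positive offset.
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]
    modality: str
    n_bands: int
    offset: float = 0.02

    def __post_init__(self) -> None:
        if self.modality not in ("raman", "nir"):
            raise ValueError("modality must be 'raman' or 'nir'")
        for center, width, amp in self.peaks:
            if not 0 <= center < self.n_bands:
                raise ValueError(f"{self.name}: peak center {center} off the band axis")
            if width <= 0 or amp <= 0:
                raise ValueError(f"{self.name}: peak width/amplitude must be > 0")

    def render(self) -> np.ndarray:
        x = np.arange(self.n_bands, dtype=float)
        spectrum = np.full(self.n_bands, self.offset)
        for center, width, amp in self.peaks:
            spectrum += amp * np.exp(-0.5 * ((x - center) / width) ** 2)
        return spectrum


def _sample_model(
    name: str, modality: str, n_bands: int, rng: np.random.Generator
) -> ComponentSpectrumModel:
    lo, hi = _PEAK_COUNTS[modality]
    n_peaks = int(rng.integers(lo, hi + 1))
    wlo, whi = _WIDTH_RANGES[modality]
    # keep peak apexes away from the axis ends; broad NIR bands may still
    # run off the edge, as real overtone bands do
    margin = min(2.0 * whi, 0.15 * n_bands)
    if n_bands <= 2 * margin + 1:
        raise ValueError(
            f"n_bands={n_bands} too small to place {modality} peaks of width up to {whi}"
        )
    centers = rng.uniform(margin, n_bands - margin, size=n_peaks)
    widths = rng.uniform(wlo, whi, size=n_peaks)
    # the drug has a strong Raman response relative to the excipients
    scale = 2.0 if (name == "DR" and modality == "raman") else 1.0
    amps = scale * rng.uniform(0.3, 1.0, size=n_peaks)
    peaks = tuple(zip(centers.tolist(), widths.tolist(), amps.tolist()))
    return ComponentSpectrumModel(name, peaks, modality, n_bands)


def _standardized(x: np.ndarray) -> np.ndarray:
    centered = x - x.mean()
    return centered / np.linalg.norm(centered)


def generate_pure_spectra(
    modality: str,
    n_bands: int,
    similarity_target: float = 0.9,
    seed: int = 0,
) -> PureComponentLibrary:
    """Generate the 5-component pure-spectrum library for one modality.

    The Pearson correlation between the HPMC and MCC spectra equals
    ``similarity_target`` (to numerical precision) so that the difficulty of
    separating the two cellulose ethers is a controlled experimental knob.
    Deterministic for a fixed (modality, seed).
    """
    if n_bands < 50:
        raise ValueError("n_bands must be >= 50")
    if not 0.0 <= similarity_target < 1.0:
        raise ValueError("similarity_target must be in [0, 1)")
    modality = modality.lower()
    if modality not in ("raman", "nir"):
        raise ValueError("modality must be 'raman' or 'nir'")

    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 0 if modality == "raman" else 1])
    )
    models = {name: _sample_model(name, modality, n_bands, rng) for name in COMPONENTS}
    # equalize integrated peak area across components (intensity-calibrated
    # reference spectra): keeps signal abundance proportional to fraction
    areas = {
        name: sum(a * w for _, w, a in model.peaks) for name, model in models.items()
    }
    mean_area = float(np.mean(list(areas.values())))
    for name, model in models.items():
        factor = mean_area / areas[name]
        scaled = tuple((c, w, a * factor) for c, w, a in model.peaks)
        models[name] = ComponentSpectrumModel(name, scaled, modality, n_bands, model.offset)
    spectra = {name: model.render() for name, model in models.items()}

    # impose the HPMC-MCC correlation: MCC = t * (HPMC peak pattern) +
    # (1-t) * (its own peak pattern), t solved so that the Pearson
    # correlation with HPMC hits the target.  Both terms are sums of
    # positive Gaussians, so MCC stays a physically shaped spectrum.
    spectra["MCC"] = _correlated_mcc(
        spectra["HPMC"], spectra["MCC"], float(similarity_target)
    )

    axis = raman_band_axis(n_bands) if modality == "raman" else nir_band_axis(n_bands)
    matrix = np.stack([spectra[name] for name in COMPONENTS])
    if modality == "raman":
        matrix = _equalize_corrected_areas(matrix)
    return PureComponentLibrary(COMPONENTS, matrix, axis, modality)


def _correlated_mcc(hpmc: np.ndarray, own: np.ndarray, target: float) -> np.ndarray:
    """Mix shapes to give MCC the target Pearson correlation with HPMC.

    For u in [0, 1] the candidate is u*HPMC + (1-u)*own (correlation rises
    to 1); for u in [-1, 0) the HPMC term is replaced by the inverted HPMC
    spectrum max(HPMC) - HPMC (correlation exactly -1 with HPMC), pulling
    the mixture's correlation down toward -1.  Every candidate is a
    nonnegative combination of nonnegative spectra, and the correlation is
    continuous and monotone in u, so the target is solved by bisection."""
    from scipy.optimize import brentq

    inverted = hpmc.max() - hpmc + 0.02

    def mix(u: float) -> np.ndarray:
        if u >= 0:
            return u * hpmc + (1.0 - u) * own
        return (-u) * inverted + (1.0 + u) * own

    def corr(u: float) -> float:
        return float(np.corrcoef(mix(u), hpmc)[0, 1])

    if abs(corr(0.0) - target) < 1e-12:
        return own.copy()
    lo, hi = (0.0, 1.0) if corr(0.0) < target else (-1.0 + 1e-9, 0.0)
    u_star = brentq(lambda u: corr(u) - target, lo, hi, xtol=1e-12)
    return mix(u_star)


def _equalize_corrected_areas(matrix: np.ndarray) -> np.ndarray:
    """Scale each spectrum so all components carry equal signal area after
    smoothing and baseline subtraction (an intensity calibration).

    The asymmetric-least-squares baseline is positively homogeneous
    (baseline(c*y) = c*baseline(y) for c > 0), so a single rescaling
    equalizes the corrected areas exactly.  Scaling is per whole spectrum
    and therefore preserves all pairwise Pearson correlations.
    """
    from ..preprocess import savitzky_golay, whittaker_baseline

    smoothed = savitzky_golay(matrix)
    corrected = smoothed - whittaker_baseline(smoothed)
    areas = np.abs(corrected).sum(axis=1)
    return matrix * (areas.mean() / areas)[:, None]
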