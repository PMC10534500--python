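"""In-memory containers for chemical images and pure-component spectra."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["COMPONENTS", "HyperspectralCube", "PureComponentLibrary"]

#: Canonical component order used everywhere in the package.
COMPONENTS: tuple[str, ...] = ("DR", "HPMC", "MCC", "lactose", "MgSt")


@dataclass(frozen=True)
class HyperspectralCube:
    """An H x W grid of spectra over a tablet surface.

    ``data`` has shape (H, W, B) with B spectral bands; ``band_axis`` holds
    the band positions (Raman shift in cm^-1 or NIR wavenumber in cm^-1);
    ``pixel_pitch_um`` is the mapping step size in micrometres.
    """

    data: np.ndarray
    band_axis: np.ndarray
    pixel_pitch_um: float
    modality: str  # "raman" | "nir"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        b = np.asarray(self.band_axis, dtype=float)
        if d.ndim != 3:
            raise ValueError(f"cube data must be (H, W, B); got shape {d.shape}")
        if b.ndim != 1 or b.size != d.shape[2]:
            raise ValueError("band_axis length must match the cube's band dimension")
        if self.modality not in ("raman", "nir"):
            raise ValueError("modality must be 'raman' or 'nir'")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "band_axis", b)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray) -> "HyperspectralCube":
        return replace(self, data=data)


@dataclass(frozen=True)
class PureComponentLibrary:
    """K pure-component reference spectra on a shared band axis.

    ``spectra`` has shape (K, B), rows ordered as ``names``.
    """

    names: tuple[str, ...]
    spectra: np.ndarray
    band_axis: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        s = np.asarray(self.spectra, dtype=float)
        b = np.asarray(self.band_axis, dtype=float)
        if s.ndim != 2 or s.shape[0] != len(self.names):
            raise ValueError("spectra must be (K, B) matching names")
        if b.size != s.shape[1]:
            raise ValueError("band_axis length must match spectra")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "spectra", s)
        object.__setattr__(self, "band_axis", b)

    @property
    def n_components(self) -> int:
        return len(self.names)

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def spectrum(self, name: str) -> np.ndarray:
        return self.spectra[self.names.index(name)]

    def with_spectra(self, spectra: np.ndarray) -> "PureComponentLibrary":
        return replace(self, spectra=spectra)
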