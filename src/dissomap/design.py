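"""Tablet formulation design space.

The benchmark formulation is a 500 mg sustained-release matrix tablet:
drotaverine HCl (DR, the drug) at 8 w/w%, hydroxypropyl methylcellulose
(HPMC, the release-controlling matrix polymer) at 10-30 w/w% in one of four
sieve fractions, microcrystalline cellulose (MCC) at 20 w/w%, magnesium
stearate at 2 w/w% and lactose as filler balance.  36 compositions are used:
28 for calibration (7 HPMC levels x 4 sieve fractions) and 8 for validation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SIEVE_FRACTIONS",
    "SIEVE_BOUNDS_UM",
    "TabletDesign",
    "sieve_bounds",
    "sieve_midpoint",
    "sieve_label_um",
    "calibration_designs",
    "validation_designs",
    "full_design_table",
    "designs_to_frame",
    "designs_from_frame",
]

#: The four HPMC sieve fractions, keyed by label.  The "<45" fraction has no
#: lower sieve; 0 is used as its nominal lower bound.
SIEVE_BOUNDS_UM: dict[str, tuple[float, float]] = {
    "<45": (0.0, 45.0),
    "45-63": (45.0, 63.0),
    "63-100": (63.0, 100.0),
    "100-150": (100.0, 150.0),
}

SIEVE_FRACTIONS: tuple[str, ...] = tuple(SIEVE_BOUNDS_UM)

#: HPMC levels (w/w fraction) of the calibration grid.
_CAL_HPMC_LEVELS = (0.10, 0.1333, 0.1666, 0.20, 0.2333, 0.2666, 0.30)

#: (hpmc_frac, sieve fraction) of the 8 validation formulations.
_VAL_SETTINGS = (
    (0.12, "<45"),
    (0.12, "63-100"),
    (0.15, "45-63"),
    (0.15, "100-150"),
    (0.25, "<45"),
    (0.25, "100-150"),
    (0.28, "45-63"),
    (0.28, "63-100"),
)

_DR, _MCC, _MGST = 0.08, 0.20, 0.02


def sieve_bounds(fraction: str) -> tuple[float, float]:
    """Lower/upper sieve pore size in micrometres for a fraction label."""
    try:
        return SIEVE_BOUNDS_UM[fraction]
    except KeyError:
        raise ValueError(
            f"unknown sieve fraction {fraction!r}; expected one of {SIEVE_FRACTIONS}"
        ) from None


def sieve_midpoint(fraction: str) -> float:
    """Midpoint of the sieve interval in micrometres (22.5 for '<45')."""
    lo, hi = sieve_bounds(fraction)
    return 0.5 * (lo + hi)


def sieve_label_um(fraction: str) -> float:
    """Regression target for the particle-size model: the upper sieve pore
    size, i.e. the smallest pore the particles could pass through."""
    return sieve_bounds(fraction)[1]


@dataclass(frozen=True)
class TabletDesign:
    """One tablet composition: w/w fractions plus the HPMC sieve fraction."""

    name: str
    dr_frac: float
    hpmc_frac: float
    mcc_frac: float
    lactose_frac: float
    mgst_frac: float
    hpmc_size_fraction: str
    role: str = "calibration"  # calibration | validation

    def __post_init__(self) -> None:
        total = (
            self.dr_frac
            + self.hpmc_frac
            + self.mcc_frac
            + self.lactose_frac
            + self.mgst_frac
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: fractions sum to {total}, expected 1")
        if not 0.0 <= self.hpmc_frac <= 0.35:
            raise ValueError(f"{self.name}: hpmc_frac {self.hpmc_frac} out of range")
        sieve_bounds(self.hpmc_size_fraction)  # validates the label
        if self.role not in ("calibration", "validation"):
            raise ValueError(f"{self.name}: role must be calibration|validation")
        if min(self.dr_frac, self.mcc_frac, self.lactose_frac, self.mgst_frac) < 0:
            raise ValueError(f"{self.name}: negative component fraction")

    @property
    def fractions(self) -> np.ndarray:
        """Component fractions in canonical order (DR, HPMC, MCC, lactose, MgSt)."""
        return np.array(
            [
                self.dr_frac,
                self.hpmc_frac,
                self.mcc_frac,
                self.lactose_frac,
                self.mgst_frac,
            ]
        )

    def with_hpmc_frac(self, hpmc_frac: float) -> "TabletDesign":
        """Return a copy with a perturbed HPMC fraction, lactose rebalanced."""
        lactose = 1.0 - (self.dr_frac + hpmc_frac + self.mcc_frac + self.mgst_frac)
        return replace(self, hpmc_frac=hpmc_frac, lactose_frac=lactose)


def _make(name: str, hpmc: float, size: str, role: str) -> TabletDesign:
    lactose = 1.0 - (_DR + hpmc + _MCC + _MGST)
    return TabletDesign(name, _DR, hpmc, _MCC, lactose, _MGST, size, role)


def calibration_designs() -> list[TabletDesign]:
    """The 28 calibration compositions DR01..DR28."""
    out = []
    i = 1
    for hpmc in _CAL_HPMC_LEVELS:
        for size in SIEVE_FRACTIONS:
            out.append(_make(f"DR{i:02d}", hpmc, size, "calibration"))
            i += 1
    return out


def validation_designs() -> list[TabletDesign]:
    """The 8 validation compositions DRV01..DRV08."""
    return [
        _make(f"DRV{i + 1:02d}", hpmc, size, "validation")
        for i, (hpmc, size) in enumerate(_VAL_SETTINGS)
    ]


def full_design_table() -> list[TabletDesign]:
    """All 36 compositions (28 calibration + 8 validation)."""
    return calibration_designs() + validation_designs()


_CSV_COLUMNS = [
    "name",
    "dr_frac",
    "hpmc_frac",
    "mcc_frac",
    "lactose_frac",
    "mgst_frac",
    "hpmc_size_fraction",
    "role",
]


def designs_to_frame(designs: list[TabletDesign]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(d, c) for c in _CSV_COLUMNS} for d in designs])


def designs_from_frame(frame: pd.DataFrame) -> list[TabletDesign]:
    return [TabletDesign(**{c: row[c] for c in _CSV_COLUMNS}) for _, row in frame.iterrows()]


def write_design_csv(designs: list[TabletDesign], path) -> None:
    designs_to_frame(designs).to_csv(path, index=False)


def read_design_csv(path) -> list[TabletDesign]:
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        frame = pd.read_csv(path)
    else:  # file-like
        frame = pd.read_csv(io.TextIOWrapper(path) if isinstance(path, io.RawIOBase) else path)
    return designs_from_frame(frame)
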