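"""Ground-truth dissolution model for the synthetic benchmark.

Drug release from an HPMC matrix tablet follows a smooth sigmoidal-to-
first-order course; the benchmark uses a Weibull law

    F(t) = 100 * (1 - exp(-(t / tau)^beta)),    beta = 0.9,

with a characteristic time that grows with the HPMC level and shrinks with
the HPMC particle size,

    tau = 300 min * (c / 0.20)^1.2 * (45 / d_mid)^0.5,

where c is the HPMC w/w fraction and d_mid the sieve-interval midpoint in µm
(22.5 for the "<45" fraction).  More matrix polymer slows release; coarser
polymer hydrates into a less coherent gel layer and releases faster.  The
constants put the release half-time near 5 h for the centre of the design
grid so the profiles span the 16 h test window.
"""

from __future__ import annotations

import numpy as np

from ..design import TabletDesign, sieve_midpoint
from ..metrics import DissolutionProfile, dissolution_time_grid

__all__ = ["release_time_constant", "weibull_release", "simulate_dissolution"]

WEIBULL_BETA = 0.9
TAU_REF_MIN = 300.0
CONC_REF = 0.20
SIZE_REF_UM = 45.0
CONC_EXPONENT = 1.2
SIZE_EXPONENT = 0.5


def release_time_constant(hpmc_frac: float, size_fraction: str) -> float:
    """Weibull time constant tau (minutes) for one composition."""
    if hpmc_frac <= 0:
        raise ValueError("hpmc_frac must be > 0 for the release model")
    d_mid = sieve_midpoint(size_fraction)
    return (
        TAU_REF_MIN
        * (hpmc_frac / CONC_REF) ** CONC_EXPONENT
        * (SIZE_REF_UM / d_mid) ** SIZE_EXPONENT
    )


def weibull_release(times_min: np.ndarray, tau: float, beta: float = WEIBULL_BETA) -> np.ndarray:
    """Noise-free cumulative % released at the given times."""
    t = np.asarray(times_min, dtype=float)
    return 100.0 * (1.0 - np.exp(-((t / tau) ** beta)))


def simulate_dissolution(
    design: TabletDesign,
    time_grid: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> DissolutionProfile:
    """Simulate the measured dissolution profile of one tablet.

    Truncated Gaussian noise (clipped at ±3 sd, emulating the bounded error
    of the UV assay) is added to the Weibull curve; the result is clipped to
    [0, 100] and made non-decreasing, as a cumulative-release curve must be.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = dissolution_time_grid() if time_grid is None else np.asarray(time_grid, float)
    tau = release_time_constant(design.hpmc_frac, design.hpmc_size_fraction)
    released = weibull_release(times, tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = np.clip(rng.normal(0.0, noise_sd, size=times.shape), -3 * noise_sd, 3 * noise_sd)
        released = released + noise
    released = np.maximum.accumulate(np.clip(released, 0.0, 100.0))
    return DissolutionProfile(times, released)
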