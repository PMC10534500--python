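"""Spatial composition maps of the tablet surface.

HPMC is placed as non-overlapping disk-shaped particles whose diameters are
drawn uniformly from the sieve-fraction interval; all remaining surface is a
homogeneous mixture of the other four components.  Area fraction is used as
the proxy for w/w% (components assumed equally dense), so particles are
added until the rasterized HPMC area fraction reaches the design fraction
within tolerance.  Small sieve fractions therefore produce many small blobs
(homogeneous-looking maps) and large fractions a few large blobs separated
by HPMC-free background, which is exactly the texture the particle-size CNN
must learn to read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..cube import COMPONENTS
from ..design import TabletDesign, sieve_bounds

__all__ = ["ParticleMap", "ParticlePlacementError", "generate_particle_map"]

#: smallest particle diameter ever drawn, µm (the "<45" fraction has no lower
#: sieve; sub-15 µm fines are not resolvable at the 25-40 µm pixel pitch)
_MIN_DIAMETER_UM = 15.0


class ParticlePlacementError(RuntimeError):
    """Target HPMC area fraction unreachable within the attempt budget."""


@dataclass(frozen=True)
class ParticleMap:
    """Per-pixel component fractions plus the placed-particle list.

    ``grid`` has shape (H, W, K) in the canonical component order; fractions
    are nonnegative and sum to 1 in every pixel.  ``placed_particles`` holds
    (row_um, col_um, diameter_um) of each HPMC disk.
    """

    grid: np.ndarray
    pixel_pitch_um: float
    placed_particles: tuple[tuple[float, float, float], ...] = field(default=())
    design_name: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 3 or g.shape[2] != len(COMPONENTS):
            raise ValueError(f"grid must be (H, W, {len(COMPONENTS)})")
        if g.min() < -1e-12:
            raise ValueError("negative component fraction in grid")
        if not np.allclose(g.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("per-pixel fractions must sum to 1")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "placed_particles", tuple(self.placed_particles))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[:2]

    def component_fraction(self, name: str) -> np.ndarray:
        return self.grid[:, :, COMPONENTS.index(name)]

    @property
    def hpmc_area_fraction(self) -> float:
        """Realized HPMC area fraction of the map."""
        return float(self.component_fraction("HPMC").mean())


def _rasterize_disk(
    coverage: np.ndarray, row_um: float, col_um: float, radius_um: float,
    pitch: float, subsample: int,
) -> None:
    """Add the sub-pixel coverage of one disk to ``coverage`` in place."""
    h, w = coverage.shape
    r0 = max(int((row_um - radius_um) / pitch) - 1, 0)
    r1 = min(int((row_um + radius_um) / pitch) + 2, h)
    c0 = max(int((col_um - radius_um) / pitch) - 1, 0)
    c1 = min(int((col_um + radius_um) / pitch) + 2, w)
    # sub-pixel sample centers within the window, in µm
    offs = (np.arange(subsample) + 0.5) / subsample
    rows = (r0 + np.add.outer(np.arange(r1 - r0), offs).ravel()) * pitch
    cols = (c0 + np.add.outer(np.arange(c1 - c0), offs).ravel()) * pitch
    inside = ((rows - row_um) ** 2)[:, None] + ((cols - col_um) ** 2)[None, :] <= radius_um**2
    frac = inside.reshape(r1 - r0, subsample, c1 - c0, subsample).mean(axis=(1, 3))
    coverage[r0:r1, c0:c1] += frac


def generate_particle_map(
    design: TabletDesign,
    grid_shape: tuple[int, int],
    pixel_pitch_um: float,
    seed: int = 0,
    tolerance: float = 0.02,
    max_attempts: int = 10_000,
    subsample: int = 5,
) -> ParticleMap:
    """Place HPMC disks on a background of the remaining components.

    Disks are drawn with diameter ~ Uniform over the sieve interval and
    placed by rejection sampling (uniform centers, no overlap, fully inside
    the map) until the rasterized HPMC area fraction is within ``tolerance``
    of ``design.hpmc_frac``.
    """
    h, w = grid_shape
    lo, hi = sieve_bounds(design.hpmc_size_fraction)
    lo = max(lo, _MIN_DIAMETER_UM)
    extent_r, extent_c = h * pixel_pitch_um, w * pixel_pitch_um
    if min(extent_r, extent_c) < hi:
        raise ValueError(
            f"map extent {extent_r:.0f}x{extent_c:.0f} µm smaller than the "
            f"largest particle diameter {hi:.0f} µm"
        )
    target = design.hpmc_frac
    rng = np.random.default_rng(seed)

    coverage = np.zeros((h, w))
    particles: list[tuple[float, float, float]] = []
    centers: list[tuple[float, float, float]] = []  # (row, col, radius) µm
    realized = 0.0
    map_area = extent_r * extent_c
    attempts = 0
    while target > 0 and realized < target - tolerance:
        if attempts >= max_attempts:
            raise ParticlePlacementError(
                f"{design.name}: reached {realized:.3f} of target {target:.3f} "
                f"after {attempts} attempts ({len(particles)} particles placed)"
            )
        attempts += 1
        d = rng.uniform(lo, hi)
        radius = d / 2.0
        area_frac = np.pi * radius**2 / map_area
        if realized + area_frac > target + tolerance:
            continue  # would overshoot; redraw the diameter
        row = rng.uniform(radius, extent_r - radius)
        col = rng.uniform(radius, extent_c - radius)
        if any(
            (row - pr) ** 2 + (col - pc) ** 2 < (radius + prad) ** 2
            for pr, pc, prad in centers
        ):
            continue  # overlap; retry
        before = coverage.sum()
        _rasterize_disk(coverage, row, col, radius, pixel_pitch_um, subsample)
        realized += (coverage.sum() - before) / (h * w)
        centers.append((row, col, radius))
        particles.append((row, col, d))

    coverage = np.clip(coverage, 0.0, 1.0)
    others = [c for c in COMPONENTS if c != "HPMC"]
    bg_total = 1.0 - design.hpmc_frac
    bg = {
        name: (getattr(design, f"{name.lower()}_frac") / bg_total if bg_total > 0 else 0.0)
        for name in others
    }
    grid = np.empty((h, w, len(COMPONENTS)))
    grid[:, :, COMPONENTS.index("HPMC")] = coverage
    for name in others:
        grid[:, :, COMPONENTS.index(name)] = (1.0 - coverage) * bg[name]
    return ParticleMap(grid, pixel_pitch_um, tuple(particles), design.name)
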