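"""Full synthetic measurement campaign: cubes + profiles per tablet.

One :class:`GroundTruthRecord` stands for one physical tablet: its (jittered)
composition, its Raman and NIR chemical images, the underlying composition
maps (kept as ground truth for recovery tests) and its dissolution profile.
Seeds are derived from the master seed with numpy's SeedSequence spawning,
so records are statistically independent yet byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..cube import HyperspectralCube, PureComponentLibrary
from ..design import TabletDesign
from ..metrics import DissolutionProfile
from .cubes import render_cube
from .dissolution import simulate_dissolution
from .particles import ParticleMap, generate_particle_map
from .spectra import generate_pure_spectra

__all__ = ["SynthConfig", "GroundTruthRecord", "generate_record", "generate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    Map geometries follow the imaging campaign (31x31 points at 40 µm for
    Raman, 48x48 at 25 µm for NIR, both covering ~1200x1200 µm²); band
    counts, noise levels and the HPMC-MCC similarity are generator choices
    documented in the methods note.
    """

    raman_shape: tuple[int, int] = (31, 31)
    raman_pitch_um: float = 40.0
    raman_bands: int = 320
    nir_shape: tuple[int, int] = (48, 48)
    nir_pitch_um: float = 25.0
    nir_bands: int = 240
    similarity_target: float = 0.9
    noise_sd: float = 0.01
    baseline_amplitude_raman: float = 0.5
    baseline_amplitude_nir: float = 0.1
    dissolution_noise_sd: float = 1.0
    replicate_jitter_rel: float = 0.01
    placement_tolerance: float = 0.02

    def libraries(self, seed: int) -> tuple[PureComponentLibrary, PureComponentLibrary]:
        """The (raman, nir) pure-component libraries for this configuration."""
        return (
            generate_pure_spectra("raman", self.raman_bands, self.similarity_target, seed),
            generate_pure_spectra("nir", self.nir_bands, self.similarity_target, seed),
        )


@dataclass(frozen=True)
class GroundTruthRecord:
    """One synthetic tablet with everything the pipeline may consume."""

    record_id: str
    design: TabletDesign
    map_raman: ParticleMap
    map_nir: ParticleMap
    cube_raman: HyperspectralCube
    cube_nir: HyperspectralCube
    profile: DissolutionProfile
    seed: int
    replicate: int = 0


def _seed_ints(seq: np.random.SeedSequence, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(n)]


def generate_record(
    design: TabletDesign,
    libraries: tuple[PureComponentLibrary, PureComponentLibrary],
    cfg: SynthConfig,
    seed: int,
    record_id: str | None = None,
    replicate: int = 0,
) -> GroundTruthRecord:
    """Generate one tablet record (both modalities + dissolution profile)."""
    lib_raman, lib_nir = libraries
    seq = np.random.SeedSequence(seed)
    s_map_r, s_map_n, s_cube_r, s_cube_n, s_diss = _seed_ints(seq, 5)
    map_raman = generate_particle_map(
        design, cfg.raman_shape, cfg.raman_pitch_um, s_map_r, cfg.placement_tolerance
    )
    map_nir = generate_particle_map(
        design, cfg.nir_shape, cfg.nir_pitch_um, s_map_n, cfg.placement_tolerance
    )
    cube_raman = render_cube(
        map_raman, lib_raman, cfg.noise_sd, cfg.baseline_amplitude_raman, s_cube_r
    )
    cube_nir = render_cube(
        map_nir, lib_nir, cfg.noise_sd, cfg.baseline_amplitude_nir, s_cube_n
    )
    profile = simulate_dissolution(design, noise_sd=cfg.dissolution_noise_sd, seed=s_diss)
    return GroundTruthRecord(
        record_id or design.name,
        design,
        map_raman,
        map_nir,
        cube_raman,
        cube_nir,
        profile,
        seed,
        replicate,
    )


def jittered_design(
    design: TabletDesign, rel_sd: float, rng: np.random.Generator
) -> TabletDesign:
    """Tablet-to-tablet composition variation: multiplicative Gaussian jitter
    on the HPMC fraction (relative sd ``rel_sd``), filler rebalanced."""
    if rel_sd <= 0:
        return design
    factor = 1.0 + rel_sd * float(rng.standard_normal())
    return design.with_hpmc_frac(design.hpmc_frac * max(factor, 0.0))


def iter_dataset(
    designs: list[TabletDesign],
    replicates: int,
    master_seed: int,
    cfg: SynthConfig | None = None,
):
    """Lazily generate ``replicates`` tablets of every design.

    Deterministic in (designs, replicates, master_seed, cfg); per-record
    seeds are spawned from the master seed.  Raises on duplicate design
    names (records would be indistinguishable).  Yields one
    :class:`GroundTruthRecord` at a time so callers can extract features and
    drop the cubes, keeping memory flat.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    names = [d.name for d in designs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate design names: {dupes}")
    cfg = cfg or SynthConfig()
    root = np.random.SeedSequence(master_seed)
    lib_seed_seq, records_seq = root.spawn(2)
    lib_seed = int(lib_seed_seq.generate_state(1)[0] % (2**31))
    libraries = cfg.libraries(lib_seed)
    record_seqs = records_seq.spawn(len(designs) * replicates)

    i = 0
    for design in designs:
        for rep in range(replicates):
            seq = record_seqs[i]
            i += 1
            jitter_seed, rec_seed = _seed_ints(seq, 2)
            rng = np.random.default_rng(jitter_seed)
            actual = jittered_design(design, cfg.replicate_jitter_rel, rng)
            yield generate_record(
                actual,
                libraries,
                cfg,
                rec_seed,
                record_id=f"{design.name}_r{rep + 1}",
                replicate=rep + 1,
            )


def generate_dataset(
    designs: list[TabletDesign],
    replicates: int,
    master_seed: int,
    cfg: SynthConfig | None = None,
) -> list[GroundTruthRecord]:
    """Materialized form of :func:`iter_dataset`."""
    return list(iter_dataset(designs, replicates, master_seed, cfg))
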