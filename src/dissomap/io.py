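"""Persistence of synthetic datasets (HDF5) and experiment reports (JSON).

Dataset layout: ``/records/<id>/{cube_raman, cube_nir, band_axis_raman,
band_axis_nir, fractions_raman, fractions_nir, profile}`` with the design
and seeds stored as group attributes.  Dissolution profiles additionally
read/write as 2-column CSV via :class:`dissomap.metrics.DissolutionProfile`.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np

from .cube import HyperspectralCube
from .design import TabletDesign
from .metrics import DissolutionProfile
from .synth.dataset import GroundTruthRecord
from .synth.particles import ParticleMap

__all__ = [
    "DatasetIOError",
    "save_dataset",
    "load_dataset",
    "write_report",
    "read_report",
    "report_json",
    "config_hash",
]


class DatasetIOError(RuntimeError):
    """Corrupt or unreadable dataset container."""


_DESIGN_ATTRS = (
    "name",
    "dr_frac",
    "hpmc_frac",
    "mcc_frac",
    "lactose_frac",
    "mgst_frac",
    "hpmc_size_fraction",
    "role",
)


def save_dataset(records: list[GroundTruthRecord], path) -> None:
    with h5py.File(path, "w") as fh:
        root = fh.create_group("records")
        for rec in records:
            grp = root.create_group(rec.record_id)
            grp.create_dataset("cube_raman", data=rec.cube_raman.data)
            grp.create_dataset("cube_nir", data=rec.cube_nir.data)
            grp.create_dataset("band_axis_raman", data=rec.cube_raman.band_axis)
            grp.create_dataset("band_axis_nir", data=rec.cube_nir.band_axis)
            grp.create_dataset("fractions_raman", data=rec.map_raman.grid)
            grp.create_dataset("fractions_nir", data=rec.map_nir.grid)
            grp.create_dataset(
                "profile", data=np.stack([rec.profile.times, rec.profile.released])
            )
            grp.attrs["pitch_raman_um"] = rec.cube_raman.pixel_pitch_um
            grp.attrs["pitch_nir_um"] = rec.cube_nir.pixel_pitch_um
            grp.attrs["seed"] = rec.seed
            grp.attrs["replicate"] = rec.replicate
            for key in _DESIGN_ATTRS:
                grp.attrs[f"design_{key}"] = getattr(rec.design, key)


def load_dataset(path) -> list[GroundTruthRecord]:
    try:
        with h5py.File(path, "r") as fh:
            records = []
            for rec_id, grp in fh["records"].items():
                design = TabletDesign(
                    **{key: _np_to_py(grp.attrs[f"design_{key}"]) for key in _DESIGN_ATTRS}
                )
                pr, pn = float(grp.attrs["pitch_raman_um"]), float(grp.attrs["pitch_nir_um"])
                profile = grp["profile"][()]
                records.append(
                    GroundTruthRecord(
                        record_id=rec_id,
                        design=design,
                        map_raman=ParticleMap(grp["fractions_raman"][()], pr),
                        map_nir=ParticleMap(grp["fractions_nir"][()], pn),
                        cube_raman=HyperspectralCube(
                            grp["cube_raman"][()], grp["band_axis_raman"][()], pr, "raman"
                        ),
                        cube_nir=HyperspectralCube(
                            grp["cube_nir"][()], grp["band_axis_nir"][()], pn, "nir"
                        ),
                        profile=DissolutionProfile(profile[0], profile[1]),
                        seed=int(grp.attrs["seed"]),
                        replicate=int(grp.attrs["replicate"]),
                    )
                )
            return records
    except (OSError, KeyError) as exc:
        raise DatasetIOError(f"cannot read dataset {path}: {exc}") from exc


def _np_to_py(value):
    if isinstance(value, bytes):
        return value.decode()
    if isinstance(value, np.generic):
        return value.item()
    return value


# ---------------------------------------------------------------------------
# reports


def report_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, fixed separators) so that
    identical reports are byte-identical on disk."""
    return json.dumps(report, sort_keys=True, indent=1, separators=(",", ": "))


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write(report_json(report))


def read_report(path) -> dict:
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as exc:
            raise DatasetIOError(f"corrupt report {path}: {exc} (char {exc.pos})") from exc


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a config mapping, embedded in every artifact."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
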