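"""End-to-end experiment orchestration.

``run_experiment`` executes, for each requested modality: synthesize tablet
records (streamed, so cubes never accumulate in memory) -> preprocess ->
CLS concentration maps -> (mean HPMC concentration, CNN particle size) ->
restart-selected dissolution ANN -> predict the validation formulations'
profiles -> f2 / RMSE / R² metrics.  The result is a plain-dict report that
serializes to canonical JSON: the same config and master seed reproduce a
byte-identical report file.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .ann import train_ensemble
from .cnn import (
    CNNArchitecture,
    CNNTrainConfig,
    build_particle_cnn,
    split_train_val,
    train_particle_cnn,
)
from .design import (
    TabletDesign,
    full_design_table,
    read_design_csv,
    sieve_label_um,
)
from .io import config_hash, write_report
from .metrics import DissolutionProfile, ProfilePair, profile_metrics
from .preprocess import PreprocessConfig, preprocess
from .synth.dataset import SynthConfig, iter_dataset
from .unmix import concentration_map, fit_cls, mean_concentration, mean_shift_correction

__all__ = [
    "ExperimentConfig",
    "NotComparableError",
    "run_experiment",
    "compare_modalities",
]

logger = logging.getLogger(__name__)

MODALITIES = ("raman", "nir")


class NotComparableError(ValueError):
    """Modality comparison requested on a single-modality report."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything that determines one experiment run.

    The ANN restart count defaults to a desk-scale 10; ``paper_scale=True``
    raises it to the full 100-restart protocol.
    """

    modalities: tuple[str, ...] = MODALITIES
    replicates: int = 4
    design_table: str | None = None  # CSV path; None = built-in design grid
    synth: SynthConfig = field(default_factory=SynthConfig)
    raman_preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(deriv_order=0)
    )
    nir_preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(deriv_order=1)
    )
    cnn_arch: CNNArchitecture = field(default_factory=CNNArchitecture)
    cnn_max_epochs: int = 100
    cnn_batch_size: int = 16
    cnn_n_val: int = 16
    ann_runs: int = 10
    ann_hidden_min: int = 1
    ann_hidden_max: int = 10
    ann_max_epochs: int = 150
    master_seed: int = 0
    output_dir: str | None = None
    paper_scale: bool = False

    def __post_init__(self) -> None:
        if len(self.modalities) == 0:
            raise ValueError("at least one modality is required")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        if self.raman_preprocess.deriv_order != 0 or self.nir_preprocess.deriv_order != 1:
            raise ValueError("preprocess configs must match their modality's recipe")

    @property
    def effective_runs(self) -> int:
        return 100 if self.paper_scale else self.ann_runs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modalities"] = list(self.modalities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "modalities" in d:
            d["modalities"] = tuple(d["modalities"])
        for key, klass in (
            ("synth", SynthConfig),
            ("raman_preprocess", PreprocessConfig),
            ("nir_preprocess", PreprocessConfig),
            ("cnn_arch", CNNArchitecture),
        ):
            if key in d and isinstance(d[key], dict):
                sub = d[key]
                for tkey in ("n_filters", "kernel_size", "pool_size", "raman_shape", "nir_shape"):
                    if tkey in sub and isinstance(sub[tkey], list):
                        sub[tkey] = tuple(sub[tkey])
                d[key] = klass(**sub)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _extract_features(cfg: ExperimentConfig, designs: list[TabletDesign]) -> dict:
    """Stream the synthetic records once; per modality keep only the HPMC
    concentration map, its mean, and ground truth per record."""
    pre_cfgs = {"raman": cfg.raman_preprocess, "nir": cfg.nir_preprocess}
    operators = {}
    entries = []
    lib_pair = None
    for rec in iter_dataset(designs, cfg.replicates, cfg.master_seed, cfg.synth):
        if not operators:
            # preprocessed libraries and CLS operators, once per experiment
            root = np.random.SeedSequence(cfg.master_seed)
            lib_seed = int(root.spawn(2)[0].generate_state(1)[0] % (2**31))
            lib_raman, lib_nir = cfg.synth.libraries(lib_seed)
            lib_pair = {"raman": lib_raman, "nir": lib_nir}
            for mod in cfg.modalities:
                pre_lib = preprocess(lib_pair[mod], mod, pre_cfgs[mod])
                operators[mod] = fit_cls(pre_lib)
        entry = {
            "record_id": rec.record_id,
            "formulation": rec.design.name.split("_")[0],
            "role": rec.design.role,
            "replicate": rec.replicate,
            "true_hpmc_pct": 100.0 * rec.design.hpmc_frac,
            "size_label_um": sieve_label_um(rec.design.hpmc_size_fraction),
            "size_fraction": rec.design.hpmc_size_fraction,
            "profile": rec.profile,
            "design": rec.design,
        }
        for mod in cfg.modalities:
            cube = rec.cube_raman if mod == "raman" else rec.cube_nir
            pre = preprocess(cube, mod, pre_cfgs[mod])
            cmap = concentration_map(operators[mod], pre, "HPMC")
            entry[f"map_{mod}"] = cmap
            entry[f"conc_{mod}"] = mean_concentration(cmap)
        entries.append(entry)
    return {"entries": entries, "operators": operators, "libraries": lib_pair}


def _run_modality(cfg: ExperimentConfig, mod: str, entries: list[dict],
                  seed_root: np.random.SeedSequence) -> dict:
    t0 = time.time()
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_root.spawn(3)]
    split_seed, cnn_seed, ann_seed = seeds
    cal = [e for e in entries if e["role"] == "calibration"]
    val = [e for e in entries if e["role"] == "validation"]

    # --- particle-size CNN on the calibration maps ------------------------
    train_e, holdout_e = split_train_val(
        cal, cfg.cnn_n_val, split_seed, strata_key=lambda e: e["formulation"]
    )
    input_shape = cal[0][f"map_{mod}"].shape
    model = build_particle_cnn(input_shape, cfg.cnn_arch, seed=cnn_seed)
    train_cfg = CNNTrainConfig(
        max_epochs=cfg.cnn_max_epochs, batch_size=cfg.cnn_batch_size, seed=cnn_seed
    )
    history = train_particle_cnn(
        model,
        [e[f"map_{mod}"] for e in train_e],
        [e["size_label_um"] for e in train_e],
        [e[f"map_{mod}"] for e in holdout_e],
        [e["size_label_um"] for e in holdout_e],
        train_cfg,
    )
    maps_all = np.stack([e[f"map_{mod}"].values for e in entries])
    sizes_all = model.predict(maps_all)
    for e, size in zip(entries, sizes_all):
        e[f"size_{mod}"] = float(size)
    logger.info("[%s] CNN trained in %.1f s", mod, time.time() - t0)

    # --- dissolution ANN ensemble -----------------------------------------
    x_train = np.array([[e[f"conc_{mod}"], e[f"size_{mod}"]] for e in cal])
    y_train = np.stack([e["profile"].released for e in cal])
    x_val = np.array([[e[f"conc_{mod}"], e[f"size_{mod}"]] for e in val])
    val_profiles = [e["profile"] for e in val]
    selection = train_ensemble(
        x_train,
        y_train,
        x_val,
        val_profiles,
        runs=cfg.effective_runs,
        hidden_range=range(cfg.ann_hidden_min, cfg.ann_hidden_max + 1),
        master_seed=ann_seed,
        max_epochs=cfg.ann_max_epochs,
    )
    logger.info("[%s] ANN ensemble done at %.1f s", mod, time.time() - t0)

    # --- evaluate the validation tablets -----------------------------------
    preds = selection.best_model.predict(x_val)
    per_record = []
    for e, pred in zip(val, preds):
        pair = ProfilePair(e["profile"], DissolutionProfile(e["profile"].times, pred))
        m = profile_metrics(pair)
        per_record.append(
            {
                "record_id": e["record_id"],
                "formulation": e["formulation"],
                "replicate": e["replicate"],
                "true_hpmc_pct": float(e["true_hpmc_pct"]),
                "pred_hpmc_pct": float(e[f"conc_{mod}"]),
                "size_label_um": float(e["size_label_um"]),
                "pred_size_um": float(e[f"size_{mod}"]),
                "f2": float(m["f2"]),
                "rmse": float(m["rmse"]),
                "r_squared": float(m["r_squared"]),
                "true_profile": [float(v) for v in e["profile"].released],
                "predicted_profile": [float(v) for v in pred],
            }
        )

    # reporting-only bias correction of the CLS concentrations (all records)
    pred_concs = np.array([e[f"conc_{mod}"] for e in entries])
    true_concs = np.array([e["true_hpmc_pct"] for e in entries])
    shift = float(true_concs.mean() - pred_concs.mean())
    shifted = mean_shift_correction(pred_concs, true_concs)

    calibration_features = [
        {
            "record_id": e["record_id"],
            "formulation": e["formulation"],
            "true_hpmc_pct": float(e["true_hpmc_pct"]),
            "pred_hpmc_pct": float(e[f"conc_{mod}"]),
            "shifted_hpmc_pct": float(s),
            "size_label_um": float(e["size_label_um"]),
            "pred_size_um": float(e[f"size_{mod}"]),
        }
        for e, s in zip(entries, shifted)
        if e["role"] == "calibration"
    ]

    return {
        "mean_f2": float(np.mean([r["f2"] for r in per_record])),
        "mean_rmse": float(np.mean([r["rmse"] for r in per_record])),
        "mean_r_squared": float(np.mean([r["r_squared"] for r in per_record])),
        "concentration_shift": shift,
        "selected_n_hidden": int(selection.best_n_hidden),
        "selected_run": int(selection.best_run),
        "selection_score": float(selection.best_score),
        "cnn_final_train_loss": float(history.train_loss[-1]),
        "cnn_epochs": len(history.train_loss),
        "validation_records": per_record,
        "calibration_features": calibration_features,
        "score_table": {
            "n_hidden": [int(v) for v in selection.scores["n_hidden"]],
            "run": [int(v) for v in selection.scores["run"]],
            "seed": [int(v) for v in selection.scores["seed"]],
            "mean_f2": [
                float(v) if np.isfinite(v) else None for v in selection.scores["mean_f2"]
            ],
            "termination": [str(v) for v in selection.scores["termination"]],
        },
    }


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full experiment; returns the report dict (and persists it to
    ``cfg.output_dir`` when set).  Deterministic per (config, master_seed)."""
    designs = (
        read_design_csv(cfg.design_table) if cfg.design_table else full_design_table()
    )
    t0 = time.time()
    stage = "synthesis/feature extraction"
    try:
        features = _extract_features(cfg, designs)
        entries = features["entries"]
        logger.info("features extracted for %d records in %.1f s",
                    len(entries), time.time() - t0)
        report: dict = {
            "config_hash": config_hash(cfg.to_dict()),
            "master_seed": cfg.master_seed,
            "package_version": _pkg_version,
            "n_records": len(entries),
            "n_calibration": sum(e["role"] == "calibration" for e in entries),
            "n_validation": sum(e["role"] == "validation" for e in entries),
            "modalities": {},
        }
        seed_root = np.random.SeedSequence([cfg.master_seed, 7_654_321])
        mod_seeds = seed_root.spawn(len(MODALITIES))
        for i, mod in enumerate(MODALITIES):
            if mod not in cfg.modalities:
                continue
            stage = f"modality {mod}"
            report["modalities"][mod] = _run_modality(cfg, mod, entries, mod_seeds[i])
    except Exception as exc:
        raise RuntimeError(
            f"experiment failed at stage '{stage}' "
            f"(config {config_hash(cfg.to_dict())}, seed {cfg.master_seed}): {exc}"
        ) from exc

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        for mod, modrep in report["modalities"].items():
            pd.DataFrame(modrep["score_table"]).to_csv(
                out / f"ann_scores_{mod}.csv", index=False
            )
            pd.DataFrame(modrep["calibration_features"]).to_csv(
                out / f"features_{mod}.csv", index=False
            )
    return report


def compare_modalities(report: dict) -> pd.DataFrame:
    """Per-formulation side-by-side metric table plus win counts.

    Wins are counted per validation formulation on mean f2 (higher is
    better); ties contribute 0.5 to each side.  The winners and the means
    are appended as summary rows.
    """
    mods = sorted(report["modalities"])
    if len(mods) < 2:
        raise NotComparableError("need at least two modalities to compare")
    rows = {}
    for mod in mods:
        frame = pd.DataFrame(report["modalities"][mod]["validation_records"])
        agg = frame.groupby("formulation")[["f2", "rmse", "r_squared"]].mean()
        rows[mod] = agg
    table = pd.concat(rows, axis=1)  # columns: (modality, metric)
    wins = {mod: 0.0 for mod in mods}
    a, b = mods[0], mods[1]
    for formulation in table.index:
        fa, fb = table.loc[formulation, (a, "f2")], table.loc[formulation, (b, "f2")]
        if np.isclose(fa, fb):
            wins[a] += 0.5
            wins[b] += 0.5
        elif fa > fb:
            wins[a] += 1.0
        else:
            wins[b] += 1.0
    table.loc["mean"] = table.mean()
    table.attrs["wins"] = wins
    return table
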