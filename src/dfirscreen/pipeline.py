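"""End-to-end experiment templates: simulate -> QC -> extract -> analyse.

Three named experiments mirror the package's study designs:

* ``replicates`` — technical replicate spots from one pooled-serum model,
  acquired independently at the 199-, 14- and 9-frequency presets, QC'd and
  averaged; reports the reproducibility table (delta_abs, mean RSD per
  preset).
* ``full_vs_sparse`` — a handful of control and cancer samples imaged at
  the full 199-point axis; amide centroids computed at full resolution and
  after downsampling to the 14-frequency set, emitted as a centroid
  correlation table.
* ``cohort50`` — a 5 x 10 mosaic (controls + four cancer classes, 10
  patients each), full pipeline at the 14-frequency axis, then four
  one-vs-control triplicate SVM classifications with modal voting.

Every run is fully determined by (config, seed); artifacts carry the seed
and a config hash in their manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .classify import ClassificationResult, SVMConfig, accuracy_report, triplicate_modal
from .core import (
    FrequencyAxis,
    HyperCube,
    InstrumentPreset,
    PRESET_SIM,
    SpotLayout,
    build_axis,
    downsample_to_axis,
)
from .features import ReproStats, centroid_table, repro_stats
from .qc import QCParams, qc_pipeline
from .spots import extract_spot_spectra, min_max_scale
from .synth import (
    CANCER_EFFECT,
    ClassEffect,
    CohortConfig,
    SpotConfig,
    draw_patient_bands,
    simulate_mosaic,
    simulate_spot,
    spot_param_rng,
)

__all__ = [
    "RunConfig",
    "DEFAULT_COHORT50_EFFECTS",
    "run_replicates",
    "run_full_vs_sparse",
    "run_cohort50",
    "run_experiment",
    "write_manifest",
]

# Per-class amide effects for the 50-spot cohort; the four cancers share the
# qualitative direction (amide I down, amide II up) with skin the weakest.
DEFAULT_COHORT50_EFFECTS: dict[str, ClassEffect] = {
    "control": ClassEffect(),
    "brain": CANCER_EFFECT,
    "breast": ClassEffect(-3.5, 2.5, 1.05),
    "lung": ClassEffect(-4.5, 3.0, 1.04),
    "skin": ClassEffect(-2.5, 2.0, 1.03),
}


@dataclass(frozen=True)
class RunConfig:
    """One experiment run: which template, at what size, with which seed."""

    experiment: str = "cohort50"            # replicates | full_vs_sparse | cohort50
    seed: int = 0
    n_replicates: int = 40                  # replicates experiment
    n_per_class: int = 10                   # cohort50
    replicate_center_sd: float = 1.5        # cm^-1 band-centre jitter per replicate
    replicate_ratio_sd: float = 0.02        # lognormal sigma of amide I/II ratio jitter
    spot: SpotConfig = SpotConfig()
    instrument: InstrumentPreset = PRESET_SIM
    qc: QCParams = QCParams()
    svm: SVMConfig = SVMConfig()
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("replicates", "full_vs_sparse", "cohort50"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("experiment", "seed", "n_replicates", "n_per_class",
                    "replicate_center_sd", "replicate_ratio_sd", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "spot" in raw:
            kwargs["spot"] = SpotConfig(**raw["spot"])
        if "qc" in raw:
            qc = dict(raw["qc"])
            if "baseline_window" in qc:
                qc["baseline_window"] = tuple(qc["baseline_window"])
            kwargs["qc"] = QCParams(**qc)
        if "svm" in raw:
            svm = dict(raw["svm"])
            for g in ("c_grid", "gamma_rel_grid"):
                if g in svm:
                    svm[g] = tuple(svm[g])
            kwargs["svm"] = SVMConfig(**svm)
        if "instrument" in raw:
            kwargs["instrument"] = InstrumentPreset(**raw["instrument"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(cfg: RunConfig, outdir: str, extra: Mapping | None = None) -> str:
    os.makedirs(outdir, exist_ok=True)
    manifest = {"experiment": cfg.experiment, "seed": cfg.seed,
                "config_hash": cfg.config_hash()}
    if extra:
        manifest.update(extra)
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def _single_spot_layout(n_pixels: int, sample_id: str = "replicate",
                        label: str = "pooled_serum") -> SpotLayout:
    return SpotLayout(1, 1, np.array([0, n_pixels]), np.array([0, n_pixels]),
                      (sample_id,), (label,))


def _replicate_mean_spectrum(cube: HyperCube, qc_params: QCParams,
                             sample_id: str):
    layout = _single_spot_layout(cube.data.shape[0], sample_id)
    mask = qc_pipeline(cube, qc_params)
    kept, excluded = extract_spot_spectra(cube, mask, layout, scale=False)
    if not kept:
        raise RuntimeError(f"replicate {sample_id} lost all pixels to QC: {excluded}")
    return kept[0]


def run_replicates(cfg: RunConfig) -> pd.DataFrame:
    """Technical-replicate reproducibility at the three frequency presets.

    Each replicate spot gets its own band-centre jitter and thickness scale
    (pooled serum measured repeatedly), and each preset is acquired as an
    independent noisy measurement of that replicate.  Returns a
    reproducibility table with one row per preset.
    """
    presets = ["FULL_199", "DF_14", "DF_9"]
    axes = {name: build_axis(name) for name in presets}
    effect = ClassEffect(center_sd=cfg.replicate_center_sd,
                         ratio_sd=cfg.replicate_ratio_sd)
    per_preset: dict[str, list] = {name: [] for name in presets}
    for r in range(cfg.n_replicates):
        prng = spot_param_rng(cfg.seed, r)
        bands = draw_patient_bands(cfg.spot.bands, effect, prng)
        tscale = prng.lognormal(0.0, cfg.spot.thickness_scale_sd)
        spot_cfg = replace(cfg.spot, bands=bands,
                           center_thickness=cfg.spot.center_thickness * tscale,
                           ring_thickness=cfg.spot.ring_thickness * tscale)
        for a_idx, name in enumerate(presets):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, r, 10 + a_idx]))
            cube = simulate_spot(spot_cfg, axes[name], cfg.instrument, rng=rng)
            ss = _replicate_mean_spectrum(cube, cfg.qc, f"rep_{r:02d}")
            per_preset[name].append(ss.spectrum)
    rows = []
    for name in presets:
        stats = repro_stats(per_preset[name])
        rows.append({"preset": name, "n_frequencies": len(axes[name]),
                     "n_replicates": stats.n_replicates,
                     "delta_abs": stats.delta_abs, "mean_rsd": stats.mean_rsd})
    table = pd.DataFrame.from_records(rows)
    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        table.to_csv(os.path.join(cfg.outdir, "repro_table.csv"), index=False)
        write_manifest(cfg, cfg.outdir, {"n_replicates": cfg.n_replicates})
    return table


def run_full_vs_sparse(cfg: RunConfig, n_per_class: int = 2) -> pd.DataFrame:
    """Full-frequency vs discrete-frequency amide centroid comparison.

    Simulates control and cancer spots, images them at the full 199-point
    axis, and computes min-max scaled amide centroids both at full
    resolution and after downsampling to the 14-frequency preset.  Returns
    the centroid correlation table (one row per sample per mode).
    """
    full = build_axis("FULL_199")
    sparse = build_axis("DF_14")
    effects = {"control": ClassEffect(), "cancer": CANCER_EFFECT}
    rows = []
    idx = 0
    for label, effect in effects.items():
        for j in range(n_per_class):
            prng = spot_param_rng(cfg.seed, idx)
            bands = draw_patient_bands(cfg.spot.bands, effect, prng)
            spot_cfg = replace(cfg.spot, bands=bands)
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, idx, 1]))
            cube = simulate_spot(spot_cfg, full, cfg.instrument, rng=rng)
            ss = _replicate_mean_spectrum(cube, cfg.qc, f"{label}_{j + 1}")
            raw = ss.spectrum
            for mode, spec in (("full_199", raw),
                               ("df_14", downsample_to_axis(raw, sparse))):
                tab = centroid_table([min_max_scale(spec)], [label],
                                     [f"{label}_{j + 1}"], mode=mode)
                rows.append(tab)
            idx += 1
    table = pd.concat(rows, ignore_index=True)
    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        table.to_csv(os.path.join(cfg.outdir, "centroid_table.csv"), index=False)
        write_manifest(cfg, cfg.outdir, {"n_per_class": n_per_class})
    return table


def run_cohort50(cfg: RunConfig,
                 class_effects: Mapping[str, ClassEffect] | None = None,
                 ) -> dict:
    """The proof-of-concept mosaic: 5 classes x n patients, one-vs-control
    triplicate SVM per cancer class with modal voting.

    Returns a report dict with the accuracy table, per-patient decisions,
    extraction metadata and the truth table.
    """
    effects = dict(class_effects or DEFAULT_COHORT50_EFFECTS)
    if "control" not in effects:
        raise ValueError("class_effects must include a 'control' class")
    axis = build_axis("DF_14")
    cohort = CohortConfig(class_effects=effects, n_per_class=cfg.n_per_class,
                          axis=axis, spot=cfg.spot, instrument=cfg.instrument,
                          seed=cfg.seed)
    cube, layout, truth = simulate_mosaic(cohort)
    mask = qc_pipeline(cube, cfg.qc)
    kept, excluded = extract_spot_spectra(cube, mask, layout, scale=True)
    by_class: dict[str, list] = {}
    for ss in kept:
        by_class.setdefault(ss.class_label, []).append(ss)
    controls = by_class.get("control", [])
    if len(controls) < 2:
        raise RuntimeError("cohort degenerate: fewer than 2 control spectra survived QC")
    results: list[ClassificationResult] = []
    decision_rows = []
    for label in effects:
        if label == "control":
            continue
        cancer = by_class.get(label, [])
        if len(cancer) < 2:
            raise RuntimeError(f"cohort degenerate: class {label!r} has "
                               f"{len(cancer)} usable spectra")
        res = triplicate_modal(cancer, controls, cfg.svm, class_label=label)
        results.append(res)
        for i, ss in enumerate(cancer):
            decision_rows.append({
                "sample_id": ss.sample_id, "class_label": label,
                "run_1": bool(res.decisions[i, 0]),
                "run_2": bool(res.decisions[i, 1]),
                "run_3": bool(res.decisions[i, 2]),
                "modal_cancer": bool(res.modal[i]),
                "correct": bool(res.modal[i]),
            })
    report = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "qc_summary": mask.summary(),
        "n_spots_kept": len(kept),
        "excluded": excluded,
        "accuracy_table": accuracy_report(results),
        "decisions": pd.DataFrame.from_records(decision_rows),
        "unanimous_fraction": float(np.mean(
            [r.unanimous_fraction for r in results])),
        "truth": truth,
    }
    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        report["accuracy_table"].to_csv(
            os.path.join(cfg.outdir, "class_accuracy.csv"), index=False)
        report["decisions"].to_csv(
            os.path.join(cfg.outdir, "patient_decisions.csv"), index=False)
        truth.to_csv(os.path.join(cfg.outdir, "truth_table.csv"), index=False)
        with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
            json.dump({k: report[k] for k in
                       ("seed", "config_hash", "n_spots_kept",
                        "unanimous_fraction", "excluded", "qc_summary")},
                      fh, indent=2, sort_keys=True)
        write_manifest(cfg, cfg.outdir, {"n_per_class": cfg.n_per_class})
    return report


def run_experiment(cfg: RunConfig):
    """Dispatch on ``cfg.experiment``."""
    if cfg.experiment == "replicates":
        return run_replicates(cfg)
    if cfg.experiment == "full_vs_sparse":
        return run_full_vs_sparse(cfg)
    return run_cohort50(cfg)
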