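"""End-to-end pipeline orchestration behind a YAML config.

``run_pipeline`` chains: simulate (or load spectra) -> preprocess -> 7:3
split -> cascade training -> evaluation -> band selection (guided + SPA)
-> re-evaluation of an SVM on the selected band subset.  Every stage writes
its artifacts into the run directory and a manifest records file hashes,
the config hash and the seed, so identical configs produce identical
manifests for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from .baselines import split_dataset, svm_fit, svm_predict
from .cascade import TrainConfig, cascade_predict, save_classifier
from .evaluation import cross_variety_matrix, evaluate_predictions
from .experiments import train_cascade
from .preprocess import PreprocessConfig, preprocess_spectra
from .selection import GuidedConfig, guided_select, selection_overlap, spa_select
from .simulate import default_nir_design, default_thz_design, simulate_spectrum_set
from .spectra import SpectrumSet

log = logging.getLogger("seedcascade")

DEFAULT_CONFIG: dict = {
    "domain": "thz",
    "seed": 0,
    "simulate": {"samples_per_cell": 100, "noise_sd": 0.01},
    "spectra_csv": None,  # set to a path to skip simulation
    # simulated spectra carry no instrument drift, so airPLS is off here;
    # pass baseline: true when feeding drifting terahertz measurements
    "preprocess": {"ma_window": 5, "baseline": False},
    "train": {
        "variety_epochs": 60,
        "gm_epochs": 120,
        "learning_rate": 1e-3,
        "batch_size": 64,
        "width_scale": 8,
    },
    "protocol": {"split_ratio": 0.7},
    "selection": {
        "guided": {"learning_rate": 0.05, "iterations": 500, "sparsity_weight": 0.3},
        "spa_max_k": 6,
    },
}


def _merged(base: dict, override: dict | None) -> dict:
    out = {}
    for key, val in base.items():
        if isinstance(val, dict):
            out[key] = _merged(val, (override or {}).get(key))
        else:
            out[key] = (override or {}).get(key, val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        cfg = _merged(cfg, yaml.safe_load(Path(path).read_text()) or {})
    return _merged(cfg, overrides)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stages": {},
        "artifacts": {},
    }

    def record(stage: str, status: str, **info):
        manifest["stages"][stage] = {"status": status, **info}

    def add_artifact(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path.relative_to(out)), "sha256": _sha256(path)}

    try:
        # ---- stage 1: spectra in --------------------------------------
        t0 = time.time()
        if cfg.get("spectra_csv"):
            sset = SpectrumSet.from_csv(cfg["spectra_csv"])
        else:
            sim = cfg["simulate"]
            maker = default_thz_design if cfg["domain"] == "thz" else default_nir_design
            design = maker(
                class_sizes=int(sim["samples_per_cell"]),
                noise_sd=float(sim["noise_sd"]),
                rng_seed=seed,
            )
            sset = simulate_spectrum_set(design)
        raw_csv = out / "spectra_raw.csv"
        sset.to_csv(raw_csv)
        add_artifact("spectra_raw", raw_csv)
        record("simulate", "ok", n_samples=sset.n_samples, seconds=round(time.time() - t0, 2))

        # ---- stage 2: preprocess --------------------------------------
        t0 = time.time()
        pp = cfg["preprocess"]
        pcfg = PreprocessConfig(ma_window=int(pp["ma_window"]))
        clean = preprocess_spectra(sset, pcfg, baseline=pp.get("baseline"))
        clean_csv = out / "spectra_clean.csv"
        clean.to_csv(clean_csv)
        add_artifact("spectra_clean", clean_csv)
        record("preprocess", "ok", n_bands=clean.n_bands, seconds=round(time.time() - t0, 2))

        # ---- stage 3: split + cascade training ------------------------
        t0 = time.time()
        plan = split_dataset(clean, float(cfg["protocol"]["split_ratio"]), True, seed)
        train, test = clean.take(plan.train_indices), clean.take(plan.test_indices)
        tr = cfg["train"]
        cascade = train_cascade(
            train,
            TrainConfig(
                epochs=int(tr["variety_epochs"]),
                learning_rate=float(tr["learning_rate"]),
                batch_size=int(tr["batch_size"]),
                rng_seed=seed,
            ),
            TrainConfig(
                epochs=int(tr["gm_epochs"]),
                learning_rate=float(tr["learning_rate"]),
                batch_size=max(8, int(tr["batch_size"]) // 2),
                rng_seed=seed,
            ),
            scale=int(tr["width_scale"]),
        )
        for name, clf in [("variety_model", cascade.variety_model)] + [
            (f"gm_model_{v}", m) for v, m in cascade.gm_registry.items()
        ]:
            save_classifier(clf, out / name)
            add_artifact(name, (out / name).with_suffix(".npz"))
        record("train", "ok", seconds=round(time.time() - t0, 2))

        # ---- stage 4: evaluation --------------------------------------
        t0 = time.time()
        pred = cascade_predict(cascade, test)
        pred_csv = out / "predictions.csv"
        pred.to_csv(pred_csv, index=False)
        add_artifact("predictions", pred_csv)
        v_report = evaluate_predictions(test.variety_labels, pred["variety"].to_numpy())
        g_report = evaluate_predictions(test.gm_labels, pred["gm"].to_numpy())
        transfer, order = cross_variety_matrix(
            cascade.gm_registry,
            {v: test.filter_variety(v) for v in cascade.gm_registry},
        )
        report = {
            "variety": v_report.to_dict(),
            "gm": g_report.to_dict(),
            "cross_variety_accuracy": {"order": order, "matrix": transfer.tolist()},
        }
        report_json = out / "eval_report.json"
        report_json.write_text(json.dumps(report, indent=2))
        add_artifact("eval_report", report_json)
        record(
            "evaluate",
            "ok",
            variety_accuracy=v_report.accuracy,
            gm_accuracy=g_report.accuracy,
            seconds=round(time.time() - t0, 2),
        )

        # ---- stage 5: band selection ----------------------------------
        t0 = time.time()
        sel = cfg["selection"]
        gcfg = GuidedConfig(
            learning_rate=float(sel["guided"]["learning_rate"]),
            iterations=int(sel["guided"]["iterations"]),
            sparsity_weight=float(sel["guided"]["sparsity_weight"]),
            rng_seed=seed,
        )
        guided = guided_select(cascade, "variety", gcfg)
        spa = spa_select(train, train.variety_labels, max_k=int(sel["spa_max_k"]), rng_seed=seed)
        overlap = selection_overlap(spa, guided, tolerance_index=1)
        sel_json = out / "selection.json"
        sel_json.write_text(
            json.dumps(
                {"guided": guided.to_dict(), "spa": spa.to_dict(), "overlap": overlap}, indent=2
            )
        )
        add_artifact("selection", sel_json)
        record(
            "select_bands",
            "ok",
            n_guided=int(guided.band_indices.size),
            n_spa=int(spa.band_indices.size),
            seconds=round(time.time() - t0, 2),
        )

        # ---- stage 6: re-evaluate on the selected subset --------------
        t0 = time.time()
        subset = guided.band_indices
        svm = svm_fit(train.select_bands(subset), train.variety_labels)
        sub_pred = svm_predict(svm, test.select_bands(subset))
        sub_report = evaluate_predictions(test.variety_labels, sub_pred)
        sub_json = out / "selected_band_report.json"
        sub_json.write_text(
            json.dumps(
                {"n_bands": int(subset.size), "report": sub_report.to_dict()}, indent=2
            )
        )
        add_artifact("selected_band_report", sub_json)
        record(
            "reevaluate_selected",
            "ok",
            n_bands=int(subset.size),
            accuracy=sub_report.accuracy,
            seconds=round(time.time() - t0, 2),
        )
    except Exception as exc:  # record the failing stage, halt downstream work
        stage = "simulate"
        for name in (
            "simulate",
            "preprocess",
            "train",
            "evaluate",
            "select_bands",
            "reevaluate_selected",
        ):
            if name not in manifest["stages"]:
                stage = name
                break
        record(stage, "failed", error=f"{type(exc).__name__}: {exc}")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
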