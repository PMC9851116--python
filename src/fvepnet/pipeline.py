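"""End-to-end experiment orchestration.

:func:`run_experiment` wires the full pipeline from a YAML/JSON config:
simulate (or load CSV) -> optional EMD denoising -> feature extraction ->
patient-grouped split -> optional autoencoder pretraining -> training ->
classification metrics on the held-out patients -> OOD scoring and metrics.
Every artifact (resolved config, split manifest, per-epoch log, predictions,
metrics, model weights) lands in the run directory.

:func:`run_benchmark` is the package's standard synthetic benchmark — the
fixed study conditions used by the test suite and the acceptance script.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import emd, metrics, ood, records, synth
from .loss import LossConfig
from .model import ModelConfig
from .train import (
    TrainConfig,
    partition,
    predict,
    pretrain_autoencoder,
    split_by_patient,
    train,
)

log = logging.getLogger("fvepnet")


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG = {
    "seed": 0,
    "data": {
        "source": "synth",
        "path": None,
        "n_normal": 100,
        "n_rp": 100,
        "n_abnormal": 0,
        "n_unlabelled": 0,
        "rp_p2_attenuation": 0.5,
        "noise_std": 1.0,
    },
    "preprocess": {"denoise": False, "imfs": [3, 4, 5]},
    "split": {"train_fraction": 0.7, "abnormal_train_fraction": 0.3},
    "train": {
        "epochs": 50,
        "batch_size": 128,
        "lr_main": 0.01,
        "lr_local_pretrained": 0.001,
        "optimizer": "sgd",
        "pretrain": False,
        "pretrain_epochs": 5,
    },
    "loss": {"gamma": 2.0, "lam": 0.1, "hint_fraction": 0.5, "symmetric_gamma": False},
    "ood": {"method": "all"},
    "eval": {"positive_class": "normal"},
}


def _merge(default: dict, user: dict, path: str = "") -> dict:
    out = dict(default)
    bad = []
    for k, v in (user or {}).items():
        if k not in default:
            bad.append(f"{path}{k}")
        elif isinstance(default[k], dict) and isinstance(v, dict):
            out[k] = _merge(default[k], v, f"{path}{k}.")
        else:
            out[k] = v
    if bad:
        raise ConfigError(f"unknown config keys: {', '.join(bad)}")
    return out


def load_config(source) -> dict:
    """Resolve a config dict, YAML path, or None against the defaults."""
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        user = yaml.safe_load(Path(source).read_text()) or {}
    return _merge(DEFAULT_CONFIG, user)


def _dataset_from_config(cfg: dict):
    d = cfg["data"]
    if d["source"] == "csv":
        if not d["path"]:
            raise ConfigError("data.path required for csv source")
        return records.read_csv(d["path"])
    if d["source"] != "synth":
        raise ConfigError(f"unknown data.source {d['source']!r}")
    params = synth.WaveformParams(
        rp_p2_attenuation=d["rp_p2_attenuation"], noise_std=d["noise_std"]
    )
    counts = {
        "normal": d["n_normal"],
        "rp": d["n_rp"],
        "abnormal": d["n_abnormal"],
        "unlabelled": d["n_unlabelled"],
    }
    counts = {k: v for k, v in counts.items() if v > 0}
    return synth.generate_dataset(counts, params, rng_seed=cfg["seed"])


def _ood_metrics(score_tr_in, score_tr_out, score_te_in, score_te_out):
    """Freeze a training-side threshold, evaluate on test scores."""
    thr, f1_tr, _ = ood.choose_threshold(score_tr_in, score_tr_out)
    s = np.concatenate([score_te_in.scores, score_te_out.scores])
    y = np.concatenate(
        [np.zeros(score_te_in.scores.size, int), np.ones(score_te_out.scores.size, int)]
    )
    rep = metrics.confusion(y, (s > thr).astype(int))
    rep.auc = metrics.auc(s, y)
    out = rep.as_dict()
    out["threshold"] = thr
    return out


def evaluate_ood(result, train_recs, test_recs, methods=ood.METHODS, seed: int = 0) -> dict:
    """Score train/test records with each detector and compute test metrics.

    Training-side scores (in-distribution = labelled classes, OOD = abnormal)
    pick the threshold; test-side scores at that frozen threshold give the
    reported metrics.  Feature-space detectors are fitted on in-distribution
    training embeddings only.
    """
    tr_in = [r for r in train_recs if r.label in ("normal", "rp")]
    tr_out = [r for r in train_recs if r.label == "abnormal"]
    te_in = [r for r in test_recs if r.label in ("normal", "rp")]
    te_out = [r for r in test_recs if r.label == "abnormal"]
    if not (tr_out and te_out):
        raise ood.OodError("OOD evaluation requires abnormal records on both split sides")
    p_tri, c_tri, e_tri = predict(result.model, tr_in)
    p_tro, c_tro, e_tro = predict(result.model, tr_out)
    p_tei, c_tei, e_tei = predict(result.model, te_in)
    p_teo, c_teo, e_teo = predict(result.model, te_out)
    out = {}
    for method in methods:
        if method == "confidence":
            scores = [ood.confidence_score(c) for c in (c_tri, c_tro, c_tei, c_teo)]
        elif method == "entropy":
            scores = [ood.entropy_scores(p) for p in (p_tri, p_tro, p_tei, p_teo)]
        else:
            det = ood.fit_feature_detector(method, e_tri, seed=seed)
            scores = [det.score(e) for e in (e_tri, e_tro, e_tei, e_teo)]
        out[method] = _ood_metrics(*scores)
    return out


def run_experiment(config=None, out_dir=None) -> dict:
    """Run the full pipeline; returns (and optionally writes) the results."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    recs = _dataset_from_config(cfg)
    if cfg["preprocess"]["denoise"]:
        recs = emd.denoise_records(recs, cfg["preprocess"]["imfs"])
    split = split_by_patient(
        recs,
        train_fraction=cfg["split"]["train_fraction"],
        abnormal_train_fraction=cfg["split"]["abnormal_train_fraction"],
        seed=seed,
    )
    train_recs, test_recs = partition(recs, split)

    tcfg = TrainConfig(
        lr_main=cfg["train"]["lr_main"],
        lr_local_pretrained=cfg["train"]["lr_local_pretrained"],
        batch_size=cfg["train"]["batch_size"],
        epochs=cfg["train"]["epochs"],
        seed=seed,
        optimizer=cfg["train"]["optimizer"],
        loss=LossConfig(**cfg["loss"]),
        model=ModelConfig(),
    )
    pre = None
    if cfg["train"]["pretrain"]:
        pool = [r for r in train_recs] + [r for r in recs if r.label == "unlabelled"]
        pre = pretrain_autoencoder(
            records.signals_matrix(pool),
            tcfg.model,
            epochs=cfg["train"]["pretrain_epochs"],
            seed=seed,
        )
    abnormal_train = [r for r in train_recs if r.label == "abnormal"]
    result = train(recs, split, tcfg, pretrained=pre, abnormal_records=abnormal_train)

    # classification on held-out patients (normal vs RP)
    te_cls = [r for r in test_recs if r.label in ("normal", "rp")]
    positive = cfg["eval"]["positive_class"]
    p, c, _ = predict(result.model, te_cls)
    pred_label = [("normal", "rp")[i] for i in p.argmax(1)]
    y_true = records.labels_vector(te_cls, positive=positive)
    y_pred = np.array([1 if l == positive else 0 for l in pred_label])
    cls_report = metrics.confusion(y_true, y_pred)
    pos_idx = ("normal", "rp").index(positive)
    cls_report.auc = metrics.auc(p[:, pos_idx], y_true)

    results = {
        "seed": seed,
        "n_records": len(recs),
        "n_train_records": len(train_recs),
        "n_test_records": len(test_recs),
        "best_epoch": result.best_epoch,
        "classification": cls_report.as_dict(),
    }
    if cfg["ood"]["method"] != "none" and any(r.label == "abnormal" for r in recs):
        methods = ood.METHODS if cfg["ood"]["method"] == "all" else (cfg["ood"]["method"],)
        results["ood"] = evaluate_ood(result, train_recs, test_recs, methods, seed=seed)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
        (out / "metrics.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        (out / "split.json").write_text(
            json.dumps(
                {
                    "train_patients": sorted(split.train_patients),
                    "test_patients": sorted(split.test_patients),
                    "seed": seed,
                },
                indent=2,
            )
        )
        pd.DataFrame(result.log).to_csv(out / "train_log.csv", index=False)
        pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in te_cls],
                "eye": [r.eye for r in te_cls],
                "repeat": [r.repeat_index for r in te_cls],
                "label": [r.label for r in te_cls],
                "predicted": pred_label,
                "p_normal": p[:, 0],
                "p_rp": p[:, 1],
                "confidence": c,
            }
        ).to_csv(out / "predictions.csv", index=False)
        result.model.save(out / "model")
        log.info("run artifacts written to %s", out)
    return results


# ---------------------------------------------------------------------------
# the standard synthetic benchmark

BENCHMARK = {
    "n_normal": 60,
    "n_rp": 60,
    "n_abnormal": 40,
    "rp_p2_attenuation": 0.5,
    "noise_std": 1.0,
    "epochs": 50,
}


def run_benchmark(seed: int, pretrain: bool = False, ood_methods=ood.METHODS) -> dict:
    """Train and evaluate on the standard benchmark conditions."""
    cfg = {
        "seed": int(seed),
        "data": {
            "n_normal": BENCHMARK["n_normal"],
            "n_rp": BENCHMARK["n_rp"],
            "n_abnormal": BENCHMARK["n_abnormal"],
            "rp_p2_attenuation": BENCHMARK["rp_p2_attenuation"],
            "noise_std": BENCHMARK["noise_std"],
        },
        "train": {"epochs": BENCHMARK["epochs"], "pretrain": pretrain},
        "ood": {"method": "all" if ood_methods == ood.METHODS else ood_methods[0]},
    }
    return run_experiment(cfg)
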