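"""End-to-end orchestration: simulate/load -> train AE -> encode -> classify.

A run is configured by a single YAML file and writes a run directory
containing the trained autoencoder, encoded features, classifier,
metrics report, op-count report, and a machine-readable manifest with
seeds and SHA-256 hashes of every artifact. Runs are deterministic given
their seeds; every stage output can be re-loaded individually.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._core import LabeledEpochSet
from . import autoencoder as ae
from . import classifiers as clf_mod
from . import complexity
from .evaluation import confusion, format_metric, metrics
from .eeg_io import SplitSpec, make_split
from .synthetic import SynthConfig, generate_dataset

log = logging.getLogger("seizae")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    dataset: dict = field(default_factory=dict)
    ae: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(dataset=doc.get("dataset", {}), ae=doc.get("ae", {}),
                   classifier=doc.get("classifier", {}),
                   evaluation=doc.get("evaluation", {}),
                   out_dir=doc.get("out_dir", "run"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_dataset(cfg: PipelineConfig) -> LabeledEpochSet:
    ds = cfg.dataset
    fmt = ds.get("format", "synthetic")
    if fmt == "synthetic":
        synth_keys = {k: ds[k] for k in
                      ("fs", "epoch_len_s", "background_model", "background_sd",
                       "ictal_freq_hz", "ictal_amp", "ictal_duty", "seed")
                      if k in ds}
        scfg = SynthConfig(**synth_keys)
        return generate_dataset(scfg, int(ds.get("n_ictal", 400)),
                                int(ds.get("n_interictal", 600)),
                                seed=ds.get("seed"))
    if fmt == "csv":
        return LabeledEpochSet.load(ds["signals"], ds["labels"],
                                    fs=float(ds.get("fs", 256.0)))
    raise ValueError(f"unknown dataset format {fmt!r}")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seizae_version": __version__, "stages": {}, "artifacts": {}}
    t_all = time.time()

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"t_start": time.time() - t_all}
        return time.time()

    try:
        t = stage("dataset")
        epoch_set = _build_dataset(cfg)
        n = epoch_set.n_samples
        manifest["stages"]["dataset"].update(
            n_epochs=len(epoch_set), epoch_len=n,
            class_counts=epoch_set.class_counts(), dt=time.time() - t)

        ev = cfg.evaluation
        split = SplitSpec(
            train_fraction=float(ev.get("train_fraction", 0.7)),
            val_fraction=float(ev.get("val_fraction", 0.1)),
            test_fraction=float(ev.get("test_fraction", 0.2)),
            train_class_ratio=tuple(ev["train_class_ratio"])
            if ev.get("train_class_ratio") else None,
            seed=int(ev.get("seed", 0)))
        train_set, _val_set, test_set = make_split(epoch_set, split)

        t = stage("train_ae")
        m = int(cfg.ae.get("hidden_size", 16))
        if m >= n:
            raise ValueError(f"hidden_size {m} must be smaller than epoch length {n}")
        ae_cfg = ae.TrainConfig(
            l2_coeff=float(cfg.ae.get("l2", 1e-4)),
            max_iter=int(cfg.ae.get("max_iter", 1000)),
            seed=int(cfg.ae.get("seed", 0)))
        model, fold_mse = ae.fit_feature_extractor(
            train_set, m, ae_cfg, folds=int(cfg.ae.get("folds", 5)))
        model.save(out / "ae_model.json")
        manifest["stages"]["train_ae"].update(
            hidden_size=m, fold_mse=[float(v) for v in fold_mse],
            dt=time.time() - t)

        t = stage("encode")
        F_train = ae.encode(model, train_set.X)
        F_test = ae.encode(model, test_set.X)
        np.savetxt(out / "features_train.csv", F_train, delimiter=",")
        np.savetxt(out / "features_test.csv", F_test, delimiter=",")
        manifest["stages"]["encode"]["dt"] = time.time() - t

        t = stage("train_clf")
        family = cfg.classifier.get("family", "knn")
        clf = clf_mod.fit(family, F_train, train_set.labels)
        clf.save(out / "classifier.pkl")
        manifest["stages"]["train_clf"].update(family=family, dt=time.time() - t)

        t = stage("evaluate")
        preds = clf_mod.predict(clf, F_test)
        c = confusion(test_set.labels, preds)
        acc, sen, sp = metrics(c)
        report = {
            "family": family, "hidden_size": m,
            "tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp,
            "accuracy": format_metric(acc), "sensitivity": format_metric(sen),
            "specificity": format_metric(sp),
        }
        (out / "metrics.json").write_text(json.dumps(report, indent=2))
        manifest["stages"]["evaluate"].update(report=report, dt=time.time() - t)

        t = stage("opcount")
        if family in ("knn", "svm", "softmax"):
            ops = complexity.pipeline_op_count(
                n, m, family, n_train=len(train_set))
            op_doc = {"multiplications": ops.multiplications,
                      "additions": ops.additions, "total": ops.total,
                      "breakdown": {k: list(v) for k, v in ops.breakdown.items()}}
        else:
            op_doc = {"note": f"op counting not defined for family {family!r}"}
        (out / "opcount.json").write_text(json.dumps(op_doc, indent=2))
        manifest["stages"]["opcount"]["dt"] = time.time() - t
    except Exception as exc:
        failed = next((s for s, v in manifest["stages"].items()
                       if "dt" not in v), "unknown")
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["artifacts"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
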