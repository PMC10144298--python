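"""Channel-wise performance metrics and hidden-size x classifier sweeps.

The positive class is ictal throughout: sensitivity is the true-positive
rate on seizure epochs, specificity the true-negative rate on background
epochs. Metrics are percentages on [0, 100], reported to two decimals
with half-even rounding; a metric whose denominator class is absent is
undefined and rendered ``NA``, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import ICTAL, INTERICTAL, LabeledEpochSet
from . import autoencoder as ae
from . import classifiers as clf_mod


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(labels, predictions) -> ConfusionCounts:
    """Count the 2x2 confusion table with ictal as the positive class."""
    y = np.asarray(labels, dtype=object)
    p = np.asarray(predictions, dtype=object)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    bad = set(y.tolist()) - {ICTAL, INTERICTAL}
    if bad:
        raise ValueError(f"unknown labels {bad}")
    return ConfusionCounts(
        tp=int(np.sum((y == ICTAL) & (p == ICTAL))),
        fn=int(np.sum((y == ICTAL) & (p != ICTAL))),
        tn=int(np.sum((y == INTERICTAL) & (p == INTERICTAL))),
        fp=int(np.sum((y == INTERICTAL) & (p != INTERICTAL))),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy %, sensitivity %, specificity %); NaN marks undefined."""
    acc = 100.0 * (c.tp + c.tn) / c.total if c.total else math.nan
    sen = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else math.nan
    sp = 100.0 * c.tn / (c.tn + c.fp) if c.tn + c.fp else math.nan
    return acc, sen, sp


def format_metric(v: float) -> str:
    """Two-decimal half-even rendering; undefined metrics become 'NA'."""
    if math.isnan(v):
        return "NA"
    return f"{float(np.round(v, 2)):.2f}"


@dataclass
class ChannelMetrics:
    channel_id: str
    hidden_size: int
    family: str
    accuracy: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts | None = field(default=None, repr=False)


def evaluate_channel(train_set: LabeledEpochSet, test_set: LabeledEpochSet,
                     hidden_size: int, family: str,
                     ae_cfg: ae.TrainConfig | None = None,
                     clf_cfg=None, folds: int = 5) -> ChannelMetrics:
    """Full single-channel protocol: AE features + classifier + metrics.

    Fits the autoencoder (with k-fold reconstruction CV) on the training
    epochs, encodes both sets, fits the classifier on the encoded train
    set and scores the encoded test set. The classification path is
    encoder-only: the decoder is exercised only inside the AE's own
    cross-validated reconstruction estimate.
    """
    if train_set.n_samples != test_set.n_samples:
        raise ValueError("train/test epoch lengths differ")
    ae_cfg = ae_cfg or ae.TrainConfig()
    model, _ = ae.fit_feature_extractor(train_set, hidden_size, ae_cfg, folds=folds)
    decode_calls_before = model.decode_calls
    F_train = ae.encode(model, train_set.X)
    F_test = ae.encode(model, test_set.X)
    clf = clf_mod.fit(family, F_train, train_set.labels, clf_cfg)
    preds = clf_mod.predict(clf, F_test)
    assert model.decode_calls == decode_calls_before, \
        "classification path must be encoder-only"
    c = confusion(test_set.labels, preds)
    acc, sen, sp = metrics(c)
    return ChannelMetrics(train_set.channel_id or test_set.channel_id,
                          hidden_size, family, acc, sen, sp, c)


@dataclass
class SweepReport:
    """Grid of per-channel metrics plus aggregates.

    ``cells`` has one row per (channel, hidden_size, family);
    ``means`` averages metric columns over channels per grid cell;
    ``best_hidden`` gives, per channel and metric, the hidden size
    achieving the maximum (ties broken toward the larger hidden size).
    """

    cells: pd.DataFrame
    means: pd.DataFrame
    best_hidden: pd.DataFrame

    def to_text(self) -> str:
        cols = ["hidden_size", "family", "accuracy", "sensitivity", "specificity"]
        df = self.means.reset_index()[cols].copy()
        for c in ("accuracy", "sensitivity", "specificity"):
            df[c] = df[c].map(format_metric)
        return df.to_string(index=False)


def sweep(channel_datasets: dict[str, tuple[LabeledEpochSet, LabeledEpochSet]],
          hidden_sizes, families,
          ae_cfg: ae.TrainConfig | None = None,
          clf_cfgs: dict | None = None, folds: int = 5) -> SweepReport:
    """Evaluate the full (hidden size x classifier) grid per channel."""
    hidden_sizes = list(hidden_sizes)
    families = list(families)
    if not hidden_sizes or not families or not channel_datasets:
        raise ValueError("sweep grid must be non-empty")
    clf_cfgs = clf_cfgs or {}
    rows = []
    for chan, (train_set, test_set) in channel_datasets.items():
        for m in hidden_sizes:
            for fam in families:
                cm = evaluate_channel(train_set, test_set, m, fam,
                                      ae_cfg=ae_cfg,
                                      clf_cfg=clf_cfgs.get(fam), folds=folds)
                rows.append({"channel": chan, "hidden_size": m, "family": fam,
                             "accuracy": cm.accuracy,
                             "sensitivity": cm.sensitivity,
                             "specificity": cm.specificity})
    cells = pd.DataFrame(rows)
    means = cells.groupby(["hidden_size", "family"], sort=False)[
        ["accuracy", "sensitivity", "specificity"]].mean()

    best_rows = []
    for chan, grp in cells.groupby("channel", sort=False):
        per_size = grp.groupby("hidden_size")[
            ["accuracy", "sensitivity", "specificity"]].max()
        rec = {"channel": chan}
        for metric_name in ("accuracy", "sensitivity", "specificity"):
            col = per_size[metric_name]
            best = col[col == col.max()].index.max()  # tie -> larger m
            rec[f"best_m_{metric_name}"] = int(best)
        best_rows.append(rec)
    best_hidden = pd.DataFrame(best_rows)
    return SweepReport(cells=cells, means=means, best_hidden=best_hidden)
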