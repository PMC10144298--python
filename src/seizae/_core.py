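"""Shared domain containers: epochs and labeled epoch sets.

An *epoch* is a fixed-length single-channel EEG segment (1 s by default:
256 samples at 256 Hz) classified independently as ictal (seizure) or
interictal (background). Epoch sets are stored densely as an (N, n) float
matrix plus a parallel label vector, which is the shape every downstream
stage (autoencoder, classifiers, metrics) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ICTAL = "ictal"
INTERICTAL = "interictal"
UNLABELED = "unlabeled"

LABELS = (ICTAL, INTERICTAL)


@dataclass
class Epoch:
    """One fixed-length EEG segment with provenance.

    Parameters
    ----------
    samples : ndarray, shape (n,)
        Signal values (unitless amplitude; no physical calibration).
    channel_id : str
        Source channel tag, e.g. a bipolar montage name like ``'P8O2'``.
    t_start_s : float
        Offset of the first sample in the source recording, seconds.
    label : str
        ``'ictal'``, ``'interictal'`` or ``'unlabeled'``.
    """

    samples: np.ndarray
    channel_id: str = ""
    t_start_s: float = 0.0
    label: str = UNLABELED

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("epoch samples must be a 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch samples must be finite")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class LabeledEpochSet:
    """A dense collection of same-length labeled epochs.

    ``X`` has one epoch per row; ``labels`` holds ``'ictal'`` /
    ``'interictal'`` strings, one per row.
    """

    X: np.ndarray
    labels: np.ndarray
    fs: float = 256.0
    channel_id: str = ""
    t_start_s: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape[0] != self.X.shape[0]:
            raise ValueError(
                f"label count {self.labels.shape[0]} != epoch count {self.X.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.t_start_s is not None:
            self.t_start_s = np.asarray(self.t_start_s, dtype=float)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        """Epoch length n in samples."""
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}

    def subset(self, idx) -> "LabeledEpochSet":
        idx = np.asarray(idx)
        ts = None if self.t_start_s is None else self.t_start_s[idx]
        return LabeledEpochSet(self.X[idx], self.labels[idx], self.fs,
                               self.channel_id, ts)

    @classmethod
    def from_epochs(cls, epochs: list[Epoch], fs: float = 256.0,
                    channel_id: str = "") -> "LabeledEpochSet":
        if not epochs:
            raise ValueError("empty epoch list")
        lengths = {len(e) for e in epochs}
        if len(lengths) != 1:
            raise ValueError(f"epochs have mixed lengths {sorted(lengths)}")
        X = np.stack([e.samples for e in epochs])
        labels = np.array([e.label for e in epochs], dtype=object)
        ts = np.array([e.t_start_s for e in epochs])
        cid = channel_id or (epochs[0].channel_id if epochs[0].channel_id else "")
        return cls(X, labels, fs, cid, ts)

    # -- two-file CSV persistence: signal matrix + labels ------------------

    def save(self, signals_path, labels_path) -> None:
        """Write the epoch matrix (rows = epochs) and labels as CSV."""
        np.savetxt(signals_path, self.X, delimiter=",")
        pd.DataFrame({"label": self.labels}).to_csv(labels_path, index=False)

    @classmethod
    def load(cls, signals_path, labels_path, fs: float = 256.0,
             channel_id: str = "") -> "LabeledEpochSet":
        X = np.loadtxt(Path(signals_path), delimiter=",", ndmin=2)
        labels = pd.read_csv(labels_path)["label"].to_numpy(dtype=object)
        return cls(X, labels, fs, channel_id)
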