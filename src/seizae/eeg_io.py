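"""Reading real EEG, epoch segmentation, labeling, and dataset splits.

Supports the two public-data dialects the pipeline targets:

* EDF recordings (CHB-MIT style: 256 Hz, bipolar channel names), read
  through :mod:`mne`, with seizure intervals supplied in a companion CSV
  (columns ``record,start_s,end_s``; ``record`` may be blank or a file
  stem to filter on);
* Bonn-style plain-ASCII files — one numeric sample per line, 4097
  samples per record, segmented at 173 samples per epoch.

Signals are cut into fixed-length non-overlapping epochs (trailing
partial windows dropped — the autoencoder needs a fixed input length n),
labeled ictal when at least half the epoch overlaps an annotated seizure
interval, and split into train/validation/test sets, optionally forcing
a class ratio (e.g. 40% ictal / 60% interictal) in the training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._core import ICTAL, INTERICTAL, Epoch, LabeledEpochSet


@dataclass
class Recording:
    """A multi-channel recording with optional seizure annotations."""

    channels: list[str]
    data: np.ndarray  # (n_channels, n_times)
    fs: float
    annotations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel label count != data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        dur = self.data.shape[1] / self.fs
        for start, end in self.annotations:
            if not (0 <= start < end <= dur + 1e-9):
                raise ValueError(
                    f"annotation ({start}, {end}) outside record duration {dur:.3f}s")

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channels.index(channel_id)]


def read_seizure_csv(path, record: str | None = None) -> list[tuple[float, float]]:
    """Read a seizure-interval companion CSV (record, start_s, end_s)."""
    df = pd.read_csv(path)
    required = {"start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns start_s,end_s (got {list(df.columns)})")
    if record is not None and "record" in df.columns:
        df = df[df["record"].astype(str) == str(record)]
    return [(float(r.start_s), float(r.end_s)) for r in df.itertuples()]


def read_edf(path, seizure_csv=None) -> Recording:
    """Read an EDF file into a Recording.

    Channel values are returned in the file's physical units (microvolt
    channels come back as microvolt-scale numbers, not volts). Duplicate
    channel labels are disambiguated by acquisition index, e.g. a second
    ``T8P8`` becomes ``T8P8#1``.
    """
    import mne  # heavy import, deferred

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"{path}: malformed EDF ({exc})") from exc
    # mne stores EEG in volts; request microvolts to recover the physical
    # values written in the file (CHB-MIT records are microvolt-scaled).
    units = {"eeg": "uV"} if "eeg" in raw.get_channel_types() else None
    data = raw.get_data(units=units)
    labels: list[str] = []
    seen: dict[str, int] = {}
    for name in raw.ch_names:
        k = seen.get(name, 0)
        seen[name] = k + 1
        labels.append(name if k == 0 else f"{name}#{k}")
    ann = read_seizure_csv(seizure_csv, record=path.stem) if seizure_csv else []
    return Recording(labels, data, float(raw.info["sfreq"]), ann)


def read_bonn_ascii(path) -> np.ndarray:
    """Read a single-column ASCII signal file (one sample per line)."""
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                values.append(float(s))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {s!r}") from exc
    if not values:
        raise ValueError(f"{path}: empty signal file")
    return np.array(values)


def segment(signal, n: int, overlap: int = 0, fs: float = 256.0,
            channel_id: str = "") -> list[Epoch]:
    """Cut a 1-D signal into fixed-length windows with stride n - overlap.

    The trailing partial window is dropped. A signal shorter than n
    yields an empty list.
    """
    signal = np.asarray(signal, dtype=float)
    if n < 1:
        raise ValueError("epoch length n must be at least 1")
    if not 0 <= overlap < n:
        raise ValueError("require 0 <= overlap < n")
    stride = n - overlap
    epochs = []
    for start in range(0, signal.size - n + 1, stride):
        epochs.append(Epoch(signal[start:start + n], channel_id=channel_id,
                            t_start_s=start / fs))
    return epochs


def label_epochs(epochs: list[Epoch], annotations: list[tuple[float, float]],
                 fs: float = 256.0, min_overlap_frac: float = 0.5) -> list[Epoch]:
    """Label each epoch ictal iff it overlaps a seizure interval enough.

    An epoch covering [t, t + n/fs) is ictal when its overlap with any
    annotated interval is at least ``min_overlap_frac`` of the epoch
    duration (default 50%); otherwise interictal.
    """
    out = []
    for ep in epochs:
        dur = len(ep) / fs
        t0, t1 = ep.t_start_s, ep.t_start_s + dur
        ov = sum(max(0.0, min(t1, e) - max(t0, s)) for s, e in annotations)
        label = ICTAL if ov >= min_overlap_frac * dur - 1e-12 else INTERICTAL
        out.append(Epoch(ep.samples, ep.channel_id, ep.t_start_s, label))
    return out


@dataclass
class SplitSpec:
    """Train/validation/test proportions, optional train class ratio, seed."""

    train_fraction: float = 0.7
    val_fraction: float = 0.1
    test_fraction: float = 0.2
    train_class_ratio: tuple[float, float] | None = None  # (ictal, interictal)
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.train_fraction, self.val_fraction, self.test_fraction)
        if any(not 0 <= f <= 1 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr)}")
        if self.train_class_ratio is not None:
            ri, rn = self.train_class_ratio
            if abs(ri + rn - 1.0) > 1e-9:
                raise ValueError("train_class_ratio entries must sum to 1")


class InsufficientClassMembers(ValueError):
    """Raised when a requested train class ratio cannot be satisfied."""


def make_split(epoch_set: LabeledEpochSet, spec: SplitSpec
               ) -> tuple[LabeledEpochSet, LabeledEpochSet, LabeledEpochSet]:
    """Seeded random train/val/test split.

    Without a class ratio the shuffled input is cut at the requested
    fractions. When ``train_class_ratio`` is given, the train set is
    drawn per class — the first ``ratio * n_train`` shuffled ictal
    epochs and the complementary count of interictal epochs — so the
    train set hits the requested balance exactly; val/test keep the
    natural ratio of the remainder. The three parts always partition
    the input.
    """
    N = len(epoch_set)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(N)
    n_train = min(int(round(spec.train_fraction * N)), N)
    n_val = min(int(round(spec.val_fraction * N)), N - n_train)

    if spec.train_class_ratio is None:
        train_idx = order[:n_train]
        rest = order[n_train:]
    else:
        ri, _ = spec.train_class_ratio
        want_ict = int(round(ri * n_train))
        want_int = n_train - want_ict
        labels = epoch_set.labels[order]
        ict_all = order[labels == ICTAL]
        int_all = order[labels == INTERICTAL]
        if ict_all.size < want_ict or int_all.size < want_int:
            raise InsufficientClassMembers(
                f"input has {ict_all.size} ictal / {int_all.size} interictal "
                f"epochs, need {want_ict}/{want_int} for ratio "
                f"{spec.train_class_ratio}")
        train_idx = np.concatenate([ict_all[:want_ict], int_all[:want_int]])
        in_train = np.isin(order, train_idx)
        rest = order[~in_train]

    val_idx = rest[:n_val]
    test_idx = rest[n_val:]
    return (epoch_set.subset(train_idx), epoch_set.subset(val_idx),
            epoch_set.subset(test_idx))
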