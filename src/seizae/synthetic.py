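"""Synthetic single-channel EEG: interictal background and ictal spike-wave.

The generator produces labeled 1-s epochs with known statistical structure
so every downstream stage — autoencoder training, classification, the full
pipeline — is testable without access to clinical recordings.

Interictal background is an order-2 autoregressive process whose pole pair
gives an alpha-band (~10 Hz) spectral peak, rescaled to a target standard
deviation. Ictal epochs add a generalized spike-wave train: a fundamental
(3 Hz by default, the classic spike-and-wave rate) with two decaying
harmonics, sharpened by one narrow Gaussian transient per cycle — the
"spike" riding on the slow wave. Amplitudes are unitless; no microvolt
calibration is applied, matching a processing chain that consumes raw
epochs without normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from ._core import ICTAL, INTERICTAL, Epoch, LabeledEpochSet

# Harmonic weights of the spike-wave train (fundamental, 2f, 3f).
_HARMONIC_WEIGHTS = (1.0, 0.5, 0.25)
# Height of the per-cycle sharp transient relative to the sinusoid stack,
# and its Gaussian width in seconds (8 ms: spike-like, well under a cycle).
_SPIKE_HEIGHT = 1.5
_SPIKE_WIDTH_S = 0.008


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG generator.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz (default 256, the CHB-MIT rate).
    epoch_len_s : float
        Epoch duration in seconds (default 1).
    background_model : str
        ``"ar2"`` (default) or ``"pink"`` (1/f-shaped noise).
    ar_coeffs : tuple of float
        AR(2) coefficients (a1, a2) of the background recursion
        ``x[t] = a1 x[t-1] + a2 x[t-2] + e[t]``. The default places a
        pole pair at radius 0.95 and ~10 Hz, an EEG-like alpha peak.
    background_sd : float
        Standard deviation of the background, arbitrary amplitude units.
    ictal_freq_hz : float
        Spike-wave fundamental frequency (default 3.0 Hz).
    ictal_amp : float
        Peak amplitude of the spike-wave burst as a multiple of
        ``background_sd`` (default 5.0).
    ictal_duty : float
        Fraction of the epoch occupied by the burst, in (0, 1].
    seed : int
        RNG seed; identical configs + seeds give identical epochs.
    """

    fs: float = 256.0
    epoch_len_s: float = 1.0
    background_model: str = "ar2"
    ar_coeffs: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    background_sd: float = 0.25
    ictal_freq_hz: float = 3.0
    ictal_amp: float = 5.0
    ictal_duty: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be positive")
        if self.ictal_amp < 0:
            raise ValueError("ictal_amp must be non-negative")
        if not 0 < self.ictal_duty <= 1:
            raise ValueError("ictal_duty must lie in (0, 1]")
        if self.background_model not in ("ar2", "pink"):
            raise ValueError(f"unknown background_model {self.background_model!r}")
        if self.ar_coeffs is None:
            # pole radius 0.95 at 10 Hz: a1 = 2 r cos(theta), a2 = -r^2
            theta = 2 * np.pi * 10.0 / self.fs
            self.ar_coeffs = (2 * 0.95 * np.cos(theta), -0.95**2)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len_s))


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_samples
    burn = 256  # discard AR transient
    e = rng.standard_normal(n + burn)
    if cfg.background_model == "ar2":
        a1, a2 = cfg.ar_coeffs
        x = lfilter([1.0], [1.0, -a1, -a2], e)[burn:]
    else:  # pink: cumulative-sum + leak gives a ~1/f slope over the band
        x = lfilter([1.0], [1.0, -0.995], e)[burn:]
    sd = np.std(x)
    if sd > 0:
        x = x * (cfg.background_sd / sd)
    return x


def _spike_wave(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-peak spike-wave train over the whole epoch, random phase."""
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    phase = rng.uniform(0.0, 1.0) / cfg.ictal_freq_hz
    w = np.zeros(n)
    for h, g in enumerate(_HARMONIC_WEIGHTS, start=1):
        w += g * np.sin(2 * np.pi * h * cfg.ictal_freq_hz * (t + phase))
    period = 1.0 / cfg.ictal_freq_hz
    tt = np.mod(t + phase, period)
    w += _SPIKE_HEIGHT * np.exp(-0.5 * ((tt - period / 2) / _SPIKE_WIDTH_S) ** 2)
    peak = np.max(np.abs(w))
    return w / peak if peak > 0 else w


def generate_epoch(cfg: SynthConfig, cls: str,
                   rng: np.random.Generator | None = None) -> Epoch:
    """Generate one labeled epoch.

    ``cls`` is ``'ictal'`` or ``'interictal'``. Interictal epochs are the
    background process alone; ictal epochs add the amplitude-modulated
    spike-wave burst. The background is drawn before any burst parameter,
    so ``ictal_amp=0`` degenerates the ictal class to the interictal one
    exactly (same RNG state, same background).
    """
    if cls not in (ICTAL, INTERICTAL):
        raise ValueError(f"unknown class label {cls!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    x = _background(cfg, rng)
    if cls == ICTAL:
        burst = cfg.ictal_amp * cfg.background_sd * _spike_wave(cfg, rng)
        if cfg.ictal_duty < 1.0:
            n = cfg.n_samples
            width = max(1, int(round(cfg.ictal_duty * n)))
            start = int(rng.integers(0, n - width + 1))
            mask = np.zeros(n)
            mask[start:start + width] = 1.0
            burst = burst * mask
        x = x + burst
    return Epoch(x, channel_id="synthetic", label=cls)


def generate_dataset(cfg: SynthConfig, n_ictal: int, n_interictal: int,
                     seed: int | None = None) -> LabeledEpochSet:
    """Generate a labeled epoch set with exact per-class counts.

    Per-epoch RNG streams are spawned deterministically from the master
    seed (``seed`` argument, falling back to ``cfg.seed``), so the same
    call reproduces the same dataset bit for bit. Epochs are ordered
    ictal-first; shuffling is the splitter's job.
    """
    if n_ictal < 0 or n_interictal < 0:
        raise ValueError("epoch counts must be non-negative")
    if n_ictal == 0 and n_interictal == 0:
        raise ValueError("empty request: need at least one epoch")
    master = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    children = ss.spawn(n_ictal + n_interictal)
    epochs = []
    for i in range(n_ictal):
        epochs.append(generate_epoch(cfg, ICTAL, np.random.default_rng(children[i])))
    for j in range(n_interictal):
        epochs.append(generate_epoch(
            cfg, INTERICTAL, np.random.default_rng(children[n_ictal + j])))
    return LabeledEpochSet.from_epochs(epochs, fs=cfg.fs, channel_id="synthetic")


def line_length(X: np.ndarray) -> np.ndarray:
    """Per-epoch line length sum(|x[t] - x[t-1]|), a classic seizure feature."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.sum(np.abs(np.diff(X, axis=1)), axis=1)
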