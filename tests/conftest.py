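"""Shared fixtures: synthetic datasets and a programmatic EDF fixture writer."""

from pathlib import Path

import numpy as np
import pytest

from seizae import SynthConfig, TrainConfig, generate_dataset


@pytest.fixture(scope="session")
def default_cfg() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def small_train_test(default_cfg):
    """Small but learnable train/test pair for fast pipeline tests."""
    train = generate_dataset(default_cfg, 24, 36, seed=11)
    test = generate_dataset(default_cfg, 40, 40, seed=22)
    return train, test


@pytest.fixture(scope="session")
def fast_ae_cfg() -> TrainConfig:
    """Shorter SCG budget for tests that only need a usable encoder."""
    return TrainConfig(max_iter=200, seed=0)


def write_edf(path, channel_names, data, fs: int) -> None:
    """Write a minimal valid EDF file (synthetic fixture).

    int16 samples with physical range equal to the digital range and a
    microvolt dimension, so values round-trip exactly through an EDF
    reader. One-second data records; sample count must divide by fs.
    """
    data = np.atleast_2d(np.asarray(data))
    n_ch, n_samp = data.shape
    assert n_samp % fs == 0, "fixture length must be a whole number of records"
    n_rec = n_samp // fs

    def pad(s: str, w: int) -> bytes:
        return s.ljust(w)[:w].encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("synthetic patient", 80), pad("synthetic record", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    fields = []
    for getter, width in [
        (lambda i: channel_names[i], 16), (lambda i: "", 80),
        (lambda i: "uV", 8), (lambda i: "-32768", 8), (lambda i: "32767", 8),
        (lambda i: "-32768", 8), (lambda i: "32767", 8), (lambda i: "", 80),
        (lambda i: str(fs), 8), (lambda i: "", 32),
    ]:
        for i in range(n_ch):
            fields.append(pad(getter(i), width))
    body = bytearray()
    di = np.round(data).astype("<i2")
    for r in range(n_rec):
        for c in range(n_ch):
            body += di[c, r * fs:(r + 1) * fs].tobytes()
    Path(path).write_bytes(hdr + b"".join(fields) + bytes(body))
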