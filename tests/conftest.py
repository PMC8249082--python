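"""Shared fixtures: small simulated recordings and a minimal EDF writer."""

from __future__ import annotations

import numpy as np
import pytest

import physioconn as pc

# MVAR fits on deliberately short test windows trip the data-to-parameter
# margin warning; that is expected for fixtures.
pytestmark = []


def write_minimal_edf(path, signals, record_duration=1.0):
    """Write a minimal EDF file: ``signals`` is a list of (label, fs, data).

    Each channel's data length must be a whole number of records. Values
    are scaled into the int16 digital range, so read-back is exact only to
    16-bit quantization.
    """
    n_sig = len(signals)
    n_records = int(len(signals[0][2]) / (signals[0][1] * record_duration))
    header_bytes = 256 * (1 + n_sig)

    def pad(text, width):
        return text[:width].ljust(width).encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("synthetic test subject", 80),
            pad("synthetic test recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(header_bytes), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad(f"{record_duration:g}", 8),
            pad(str(n_sig), 4),
        ]
    )
    phys = []
    for label, fs, data in signals:
        pmin, pmax = float(np.min(data)), float(np.max(data))
        if pmax == pmin:
            pmax = pmin + 1.0
        phys.append((pmin, pmax))
    fields = []
    for sig in signals:
        fields.append(pad(sig[0], 16))
    for _ in signals:
        fields.append(pad("", 80))
    for _ in signals:
        fields.append(pad("uV", 8))
    for k in range(n_sig):
        fields.append(pad(f"{phys[k][0]:.6g}", 8))
    for k in range(n_sig):
        fields.append(pad(f"{phys[k][1]:.6g}", 8))
    for _ in signals:
        fields.append(pad("-32768", 8))
    for _ in signals:
        fields.append(pad("32767", 8))
    for _ in signals:
        fields.append(pad("", 80))
    for _, fs, _d in signals:
        fields.append(pad(str(int(fs * record_duration)), 8))
    for _ in signals:
        fields.append(pad("", 32))
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(b"".join(fields))
        for rec_i in range(n_records):
            for k, (label, fs, data) in enumerate(signals):
                spr = int(fs * record_duration)
                chunk = data[rec_i * spr : (rec_i + 1) * spr]
                pmin, pmax = phys[k]
                dig = np.round(
                    (chunk - pmin) / (pmax - pmin) * 65535.0 - 32768.0
                ).astype("<i2")
                fh.write(dig.tobytes())


@pytest.fixture(scope="session")
def six_channel_recording():
    """Short WT-like 6-channel recording (60 s at 500 Hz)."""
    return pc.make_testbed("WT_LIKE", duration_s=60, seed=7).recording


@pytest.fixture(scope="session")
def bivariate_var1():
    """Simulated bivariate VAR(1) with known coefficients and a fitted model."""
    A = np.array([[0.5, 0.0], [0.3, 0.4]])
    rng = np.random.default_rng(12345)
    n, burn = 5000, 200
    x = np.zeros((n + burn, 2))
    e = rng.standard_normal((n + burn, 2))
    for t in range(1, n + burn):
        x[t] = A @ x[t - 1] + e[t]
    return A, x[burn:]


@pytest.fixture(scope="session")
def default_grid():
    return pc.FrequencyGrid.default()


@pytest.fixture
def edf_writer(tmp_path):
    def _write(signals, record_duration=1.0, name="test.edf"):
        path = tmp_path / name
        write_minimal_edf(path, signals, record_duration)
        return path

    return _write
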