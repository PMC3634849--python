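"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from seizdyn.io_eeg import EventTimeline, Recording


def make_recording(
    data: np.ndarray,
    fs: float = 512.0,
    channels=None,
    events: tuple = (),
    **kwargs,
) -> Recording:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return Recording(
        data=data, fs=fs, channels=channels, events=EventTimeline(events), **kwargs
    )


@pytest.fixture
def sine_recording():
    def _make(freq=10.0, amp=100.0, fs=512.0, dur=30.0, channels=("a",)):
        t = np.arange(int(dur * fs)) / fs
        x = amp * np.sin(2 * np.pi * freq * t)
        data = np.tile(x, (len(channels), 1))
        return make_recording(data, fs=fs, channels=channels)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


# ---------------------------------------------------------------------------
# minimal EDF writer (synthetic fixture; enough of the format for readers)
# ---------------------------------------------------------------------------

def write_minimal_edf(path, data_uv: np.ndarray, fs: float, channels) -> None:
    """Write a bare-bones EDF file: 1 s data records, int16, physical µV."""
    data = np.atleast_2d(np.asarray(data_uv, dtype=float))
    nch, n = data.shape
    spr = int(fs)
    n_rec = n // spr
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32767, 32767

    def pad(s, width):
        return str(s)[:width].ljust(width).encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("synthetic subject", 80),
            pad("synthetic recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 * (1 + nch), 8),
            pad("", 44),
            pad(n_rec, 8),
            pad("1", 8),
            pad(nch, 4),
        ]
    )
    sig = b"".join(pad(c, 16) for c in channels)
    sig += b"".join(pad("", 80) for _ in channels)
    sig += b"".join(pad("uV", 8) for _ in channels)
    sig += b"".join(pad(int(phys_min), 8) for _ in channels)
    sig += b"".join(pad(int(phys_max), 8) for _ in channels)
    sig += b"".join(pad(dig_min, 8) for _ in channels)
    sig += b"".join(pad(dig_max, 8) for _ in channels)
    sig += b"".join(pad("", 80) for _ in channels)
    sig += b"".join(pad(spr, 8) for _ in channels)
    sig += b"".join(pad("", 32) for _ in channels)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            for c in range(nch):
                seg = data[c, r * spr : (r + 1) * spr]
                dig = np.clip(np.round(seg * scale), dig_min, dig_max).astype("<i2")
                fh.write(dig.tobytes())


# ---------------------------------------------------------------------------
# independent statistical oracles
# ---------------------------------------------------------------------------

def holm_sidak_oracle(pvalues) -> np.ndarray:
    """Hand-rolled step-down Sidak: independent of the implementation path."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj


def brute_force_max_cluster_masses(A, B, alpha=0.05):
    """Exhaustive max-cluster-mass null by explicit enumeration.

    Scans every label assignment with nested loops and a linear run scan;
    shares no code with the package implementation.
    """
    from itertools import combinations

    from scipy import stats as st

    X = np.vstack([A, B])
    n1, n = A.shape[0], X.shape[0]
    thr = st.t.ppf(1 - alpha / 2, n - 2)

    def max_mass(idx):
        a = X[list(idx)]
        b = X[[i for i in range(n) if i not in idx]]
        t = np.nan_to_num(st.ttest_ind(a, b, axis=0).statistic)
        best = 0.0
        cur = 0.0
        cursign = 0
        for v in t:
            s = 1 if v > thr else (-1 if v < -thr else 0)
            if s != 0 and s == cursign:
                cur += v
            elif s != 0:
                if cursign != 0:
                    best = max(best, abs(cur))
                cur, cursign = v, s
            else:
                if cursign != 0:
                    best = max(best, abs(cur))
                cur, cursign = 0.0, 0
        if cursign != 0:
            best = max(best, abs(cur))
        return best

    null = np.array([max_mass(c) for c in combinations(range(n), n1)])
    return null, max_mass(tuple(range(n1)))
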