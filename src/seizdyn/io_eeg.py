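"""Reading, writing and standardisation of multichannel EEG recordings.

A :class:`Recording` holds a block of equal-length channel traces in
microvolts together with its sampling rate, the channel labels/roles and an
:class:`EventTimeline` of experimental events (pilocarpine injection, light
epochs, pentobarbital).  All downstream feature extraction operates on
*standardized* recordings: resampled to a common rate (512 Hz by default)
and zero-phase band-limited to the acquisition bandwidth of 0.1-100 Hz.

Recordings are read from EDF files (via :mod:`mne`) or from plain CSV
(header row of channel labels, one column per channel, values in µV) with a
sidecar ``*.events.csv`` file carrying ``time_s,label`` rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import FormatError, ParameterError, PreconditionError

#: Channel roles expected by the cohort analyses.
CHANNEL_ROLES = (
    "cortical_left",
    "cortical_right",
    "hippocampal_1",
    "hippocampal_2",
)

#: Recognised event labels.
EVENT_LABELS = frozenset(
    {"pilocarpine", "light_on", "light_off", "pentobarbital", "seizure_onset"}
)

#: Common analysis sampling rate (Hz).
TARGET_FS = 512.0

#: Acquisition bandwidth (Hz); standardisation band-limits to this range.
ACQUISITION_BAND = (0.1, 100.0)


@dataclass(frozen=True)
class EventTimeline:
    """Timestamped experimental events, in seconds on the recording clock.

    ``events`` is a sequence of ``(time_s, label)`` pairs.  Times within a
    label must be nondecreasing and every ``light_on`` must be followed by a
    matching ``light_off``.
    """

    events: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        evs = tuple((float(t), str(lab)) for t, lab in self.events)
        object.__setattr__(self, "events", evs)
        for lab in {lab for _, lab in evs}:
            ts = [t for t, l in evs if l == lab]
            if any(b < a for a, b in zip(ts, ts[1:])):
                raise FormatError(f"event times for {lab!r} are not nondecreasing")
        # every light_on must have a later light_off
        ons = sorted(t for t, l in evs if l == "light_on")
        offs = sorted(t for t, l in evs if l == "light_off")
        if len(ons) != len(offs) or any(off <= on for on, off in zip(ons, offs)):
            raise FormatError("every light_on needs a matching later light_off")

    def times(self, label: str) -> np.ndarray:
        """Times (s) of all events with the given label, sorted."""
        return np.array(sorted(t for t, l in self.events if l == label))

    def light_epochs(self) -> list[tuple[float, float]]:
        """[light_on, light_off) intervals, time-ordered."""
        ons = self.times("light_on")
        offs = self.times("light_off")
        return list(zip(ons.tolist(), offs.tolist()))

    def shifted(self, dt: float) -> "EventTimeline":
        return EventTimeline(tuple((t + dt, l) for t, l in self.events))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.events), columns=["time_s", "label"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTimeline":
        if not {"time_s", "label"} <= set(df.columns):
            raise FormatError("events table needs columns time_s,label")
        return cls(tuple(zip(df["time_s"].astype(float), df["label"].astype(str))))


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    ``data`` has shape ``(n_channels, n_samples)``.  Sample ``i`` of every
    channel is at time ``start_time_s + i / fs`` on the same clock as
    ``events``; :func:`relative_time` moves that clock so the pilocarpine
    injection sits at time 0.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    events: EventTimeline = field(default_factory=EventTimeline)
    subject_id: str = ""
    group: str | None = None
    start_time_s: float = 0.0
    standardized: bool = False

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.channels = tuple(self.channels)
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.data.shape[0] != len(self.channels):
            raise FormatError(
                f"{self.data.shape[0]} signal rows for {len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("duplicate channel labels")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.fs

    def index_of(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"no channel {channel!r}; have {self.channels}") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.index_of(label)]

    def time_to_index(self, t: float) -> int:
        return int(round((t - self.start_time_s) * self.fs))

    def segment(self, channel: str, t0: float, t1: float) -> np.ndarray:
        """Samples of ``channel`` in ``[t0, t1)`` (recording clock)."""
        i0 = max(0, self.time_to_index(t0))
        i1 = min(self.n_samples, self.time_to_index(t1))
        return self.channel(channel)[i0:i1]

    def injection_time(self) -> float:
        t = self.events.times("pilocarpine")
        if len(t) != 1:
            raise PreconditionError(
                f"expected exactly one pilocarpine event, found {len(t)}"
            )
        return float(t[0])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _events_sidecar(path: Path) -> Path:
    return path.parent / (path.stem + ".events.csv")


def _read_events(path: Path | None) -> EventTimeline:
    if path is None or not Path(path).exists():
        return EventTimeline()
    df = pd.read_csv(path)
    return EventTimeline.from_frame(df)


def load_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    events_path: str | Path | None = None,
    subject_id: str | None = None,
    group: str | None = None,
) -> Recording:
    """Load a recording from EDF or CSV.

    For CSV the sampling rate must be supplied via ``fs`` (the format has no
    header field for it); for EDF it is read from the file header.  Events
    are read from ``events_path`` or, if absent, from the ``<stem>.events.csv``
    sidecar next to the recording.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    events = _read_events(Path(events_path) if events_path else _events_sidecar(path))

    if format == "csv":
        if fs is None:
            raise ParameterError("fs is required when loading CSV recordings")
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - normalise parser failures
            raise IOError(f"could not parse {path}: {exc}") from exc
        if df.shape[1] < 1 or df.shape[0] < 1:
            raise FormatError("CSV recording has no channels or no samples")
        if df.isna().any().any():
            raise FormatError("CSV recording has ragged columns (missing values)")
        data = df.to_numpy(dtype=np.float64).T
        channels = tuple(str(c) for c in df.columns)
        rec_fs = float(fs)
    elif format == "edf":
        import mne  # heavy import kept local

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        channels = tuple(raw.ch_names)
        rec_fs = float(raw.info["sfreq"])
    else:
        raise ParameterError(f"unknown format {format!r}")

    return Recording(
        data=data,
        fs=rec_fs,
        channels=channels,
        events=events,
        subject_id=subject_id or path.stem,
        group=group,
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV plus its ``*.events.csv`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channels))
    df.to_csv(path, index=False, float_format="%.3f")
    rec.events.to_frame().to_csv(_events_sidecar(path), index=False)
    return path


# ---------------------------------------------------------------------------
# Standardisation
# ---------------------------------------------------------------------------

def _band_limit(
    data: np.ndarray, fs: float, band: tuple[float, float] = ACQUISITION_BAND
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band limiting.

    The low-frequency corner has a period comparable to short test signals;
    the high-pass stage is applied only when the record spans at least three
    corner periods (any real recording does), with padding long enough for
    its slow transient.
    """
    lo, hi = band
    n = data.shape[-1]
    if hi < fs / 2.0 * 0.99:
        lp = signal.butter(4, hi, btype="lowpass", fs=fs, output="sos")
        data = signal.sosfiltfilt(lp, data, axis=-1)
    if n / fs >= 3.0 / lo:
        hp = signal.butter(4, lo, btype="highpass", fs=fs, output="sos")
        padlen = min(n - 1, int(30.0 / lo * fs))
        data = signal.sosfiltfilt(hp, data, axis=-1, padlen=padlen)
    else:
        data = data - data.mean(axis=-1, keepdims=True)
    return data


def standardize(rec: Recording, target_fs: float = TARGET_FS) -> Recording:
    """Resample to ``target_fs`` and band-limit to 0.1-100 Hz, zero-phase.

    Resampling is polyphase (exact rational factor), so window lengths used
    downstream are sample-exact.  Applying ``standardize`` to an already
    standardized recording at the same rate is the identity.
    """
    if target_fs <= 0:
        raise ParameterError("target_fs must be positive")
    if rec.standardized and math.isclose(rec.fs, target_fs):
        return replace(rec, data=rec.data.copy())

    data = rec.data
    if not math.isclose(rec.fs, target_fs):
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    data = _band_limit(data, target_fs)
    return replace(
        rec,
        data=np.ascontiguousarray(data),
        fs=float(target_fs),
        standardized=True,
    )


def relative_time(rec: Recording) -> Recording:
    """Re-anchor the recording clock so pilocarpine injection is time 0."""
    inj = rec.injection_time()
    return replace(
        rec,
        events=rec.events.shifted(-inj),
        start_time_s=rec.start_time_s - inj,
    )
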