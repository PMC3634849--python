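"""Waveform features tracking seizure evolution.

The central statistic is the *line length* of a window: the summed absolute
difference between successive samples,

    LL = sum_k |x[k] - x[k-1]|,

a cheap combined measure of amplitude and frequency content that rises as
ictal activity develops.  Three views are provided:

* a short-time spectrogram (1000 ms Hamming window, 500 ms hop),
* windowed line length in sliding 3 s windows with 1.5 s overlap,
* the normalized cumulative line length LL_cum over a fixed span from
  seizure onset, an expanding-window running sum normalized by the total so
  the curve rises monotonically from 0 to exactly 1.  Constant seizure power
  gives the straight diagonal; a slowly building seizure is concave-up and
  lies below it.

A simple threshold detector on windowed line length estimates the
electrographic onset relative to the pre-injection baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateSignalError, ParameterError, PreconditionError
from .io_eeg import Recording

#: Sliding-window geometry for line length (seconds).
LL_WINDOW_S = 3.0
LL_OVERLAP_S = 1.5

#: Spectrogram geometry (seconds).
SPEC_WINDOW_S = 1.0
SPEC_OVERLAP_S = 0.5

#: Span of the cumulative line-length curve (seconds = 25 min).
LLCUM_SPAN_S = 1500.0


@dataclass
class WindowedSeries:
    """A per-window feature track for one channel.

    ``times`` are window centers in seconds on the recording clock;
    consecutive centers are spaced ``window_len_s - overlap_s`` apart.
    """

    times: np.ndarray
    values: np.ndarray
    window_len_s: float
    overlap_s: float
    channel: str = ""

    @property
    def hop_s(self) -> float:
        return self.window_len_s - self.overlap_s

    @property
    def starts(self) -> np.ndarray:
        return self.times - self.window_len_s / 2.0


@dataclass
class Spectrogram:
    times: np.ndarray  # seconds, window centers
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (n_freqs, n_times), squared magnitude
    channel: str = ""


@dataclass
class CumulativeLineLengthCurve:
    """Normalized cumulative line length on a common grid from onset.

    ``times`` run from 0 to the analysis span in 1 s steps; ``values`` rise
    monotonically from 0 to exactly 1.  ``truncated`` flags curves computed
    from less than the full span (e.g. recording ended early); these are
    linearly time-normalized onto the common grid.
    """

    times: np.ndarray
    values: np.ndarray
    onset_s: float
    channel: str = ""
    truncated: bool = False


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def line_length(window: np.ndarray) -> float:
    """Sum of absolute first differences of ``window`` (µV)."""
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise PreconditionError("line_length needs a 1-D window of >= 2 samples")
    return float(np.abs(np.diff(x)).sum())


def _window_starts(n_samples: int, win: int, hop: int) -> np.ndarray:
    if n_samples < win:
        raise PreconditionError("recording shorter than one window")
    return np.arange(0, n_samples - win + 1, hop)


def windowed_line_length(
    rec: Recording,
    channel: str,
    window_s: float = LL_WINDOW_S,
    overlap_s: float = LL_OVERLAP_S,
) -> WindowedSeries:
    """Line length in sliding windows (3 s long, 1.5 s overlap by default).

    The trailing partial window is dropped.  Vectorised: the per-sample
    absolute difference is accumulated once and windows are read off its
    cumulative sum.
    """
    x = rec.channel(channel)
    win = int(round(window_s * rec.fs))
    hop = int(round((window_s - overlap_s) * rec.fs))
    if hop <= 0 or win <= 1:
        raise ParameterError("need overlap_s < window_s and window_s > 1 sample")
    starts = _window_starts(x.size, win, hop)
    csum = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(x)))])
    # line length of x[s : s+win] sums diffs s..s+win-2 -> csum[s+win-1]-csum[s]
    vals = csum[starts + win - 1] - csum[starts]
    times = rec.start_time_s + (starts + win / 2.0) / rec.fs
    return WindowedSeries(
        times=times,
        values=vals,
        window_len_s=window_s,
        overlap_s=overlap_s,
        channel=channel,
    )


def spectrogram(
    rec: Recording,
    channel: str,
    window_s: float = SPEC_WINDOW_S,
    overlap_s: float = SPEC_OVERLAP_S,
) -> Spectrogram:
    """Short-time FFT power spectrogram (Hamming window)."""
    x = rec.channel(channel)
    nperseg = int(round(window_s * rec.fs))
    noverlap = int(round(overlap_s * rec.fs))
    freqs, times, sxx = signal.spectrogram(
        x,
        fs=rec.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        mode="magnitude",
        scaling="spectrum",
        detrend=False,
    )
    return Spectrogram(
        times=rec.start_time_s + times,
        freqs=freqs,
        power=sxx**2,
        channel=channel,
    )


def cumulative_line_length(
    rec: Recording,
    channel: str,
    onset_s: float,
    duration_s: float = LLCUM_SPAN_S,
    grid_step_s: float = 1.0,
) -> CumulativeLineLengthCurve:
    """Normalized cumulative line length from ``onset_s`` over ``duration_s``.

    ``onset_s`` is on the recording clock (so after :func:`relative_time`
    it is seconds post-injection).  The expanding-window running sum of
    |x[k]-x[k-1]| is divided by the total over the span, then linearly
    interpolated onto a common 1 s grid for group comparison.  If the
    recording ends before ``onset_s + duration_s`` the available portion is
    used, time-normalized onto the full grid, and flagged ``truncated``.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    i0 = rec.time_to_index(onset_s)
    if i0 < 0 or i0 >= rec.n_samples - 1:
        raise PreconditionError("onset outside the recording")
    i1 = i0 + int(round(duration_s * rec.fs)) + 1  # include the closing sample
    truncated = i1 > rec.n_samples
    i1 = min(i1, rec.n_samples)
    x = rec.channel(channel)[i0:i1]
    increments = np.abs(np.diff(x))
    total = increments.sum()
    if total <= 0:
        raise DegenerateSignalError("flat signal: total line length is zero")
    cum = np.concatenate([[0.0], np.cumsum(increments)]) / total
    span = (x.size - 1) / rec.fs
    sample_t = np.arange(x.size) / rec.fs
    grid = np.arange(0.0, duration_s + grid_step_s / 2, grid_step_s)
    if truncated:
        # map the available span onto the full grid (linear time normalization)
        sample_t = sample_t * (duration_s / span)
    values = np.interp(grid, sample_t, cum, left=0.0, right=1.0)
    values[-1] = 1.0
    return CumulativeLineLengthCurve(
        times=grid,
        values=values,
        onset_s=onset_s,
        channel=channel,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# onset detection
# ---------------------------------------------------------------------------

def detect_onset(
    rec: Recording,
    channel: str,
    k_sd: float = 5.0,
    hold_windows: int = 3,
    min_baseline_s: float = 120.0,
) -> float | None:
    """Estimate electrographic seizure onset, in seconds post-injection.

    Windowed line length is compared against the pre-injection baseline:
    the onset is the start of the first window at or after the injection
    whose value exceeds ``baseline mean + k_sd * SD`` for ``hold_windows``
    consecutive windows.  Returns ``None`` if no such run occurs.
    """
    inj = rec.injection_time()
    if inj - rec.start_time_s < min_baseline_s:
        raise PreconditionError(
            f"need >= {min_baseline_s:.0f} s of pre-injection baseline"
        )
    series = windowed_line_length(rec, channel)
    starts = series.starts
    baseline = series.values[starts + series.window_len_s <= inj]
    if baseline.size < 3:
        raise PreconditionError("too few baseline windows")
    thresh = baseline.mean() + k_sd * baseline.std(ddof=1)
    cand = starts >= inj
    vals = series.values
    above = (vals > thresh) & cand
    run = 0
    for i in np.nonzero(cand)[0]:
        run = run + 1 if above[i] else 0
        if run >= hold_windows:
            first = i - hold_windows + 1
            return float(starts[first] - inj)
    return None
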