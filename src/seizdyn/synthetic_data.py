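"""Synthetic lithium-pilocarpine cohort generator.

No animal recordings were published for this experimental design, so the
whole pipeline is exercised on synthetic cohorts that emulate the described
phenomenology of the model:

* 10 min of baseline EEG, pilocarpine injection, then a group-specific
  seizure-onset delay drawn from a Normal distribution calibrated to the
  printed group statistics (mean, SEM, n; the SD is reconstructed as
  ``SEM * sqrt(n)``), truncated at 2 min post-injection;
* a pre-ictal transition (0.5-3 min) of intermittent low-frequency
  (<20 Hz), low-amplitude (<500 µV) epileptiform spikes ramping in rate and
  amplitude;
* a developed seizure: amplitude-modulated 20-50 Hz oscillation reaching
  >= 500 µV, with a sigmoidal growth envelope.  Optogenetically inhibited
  cohorts grow more slowly and are gated by remission epochs of
  near-normal EEG;
* hippocampal channels lead cortical channels by a small conduction lag;
* a 70-100 Hz high-gamma component on the hippocampal channels whose
  amplitude drops by a multiplicative suppression factor at each light
  onset and relaxes back with a 5 s exponential recovery;
* Racine behavioral scores in 30 s epochs that lead the electrographic
  spiking by 1-3 min.

Everything is fully deterministic given ``(config seed, subject index)``.
The module also houses the fiber-tip irradiance utility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import EPOCH_S, RacineSeries
from .errors import ParameterError
from .io_eeg import CHANNEL_ROLES, EventTimeline, Recording, write_recording

#: Conduction lag by which hippocampal activity leads cortical (seconds).
CORTICAL_LAG_S = 0.025


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic group of animals.

    Onset statistics are given as printed summaries (mean, SEM, n); the
    per-animal onset SD is reconstructed as ``SEM * sqrt(n)``.  Amplitudes
    are in µV, times in the units stated by each field name.
    """

    group: str
    n_subjects: int
    onset_mean_min: float
    onset_sem_min: float
    onset_n_printed: int
    # pre-ictal spiking
    preictal_band: tuple[float, float] = (3.0, 20.0)
    preictal_amp_max: float = 450.0
    spike_rate_range: tuple[float, float] = (1.5, 8.0)
    transition_min: tuple[float, float] = (0.5, 3.0)
    # developed seizure
    developed_band: tuple[float, float] = (20.0, 50.0)
    developed_amp: float = 600.0
    growth_tau_s: float = 30.0
    remission_rate_per_min: float = 0.0
    remission_depth: float = 0.15
    remission_window_min: float = 10.0
    remission_len_s: tuple[float, float] = (15.0, 45.0)
    # illumination
    light_schedule: str = "none"  # none | continuous | intermittent
    light_start_mean_min: float = 8.0
    light_start_sd_min: float = 1.0
    light_on_s: tuple[float, float] = (60.0, 120.0)
    light_gap_s: tuple[float, float] = (60.0, 180.0)
    gamma_suppression: float = 1.0  # multiplicative amplitude factor in (0, 1]
    gamma_tau_s: float = 5.0
    # background / high-gamma
    baseline_sigma: float = 50.0
    hg_amp: float = 10.0
    hg_band: tuple[float, float] = (70.0, 100.0)
    # behaviour
    behavioral_lead_min: tuple[float, float] = (1.0, 3.0)
    racine_tau_s: float = 240.0
    # timing
    fs: float = 512.0
    baseline_min: float = 10.0
    duration_min: float | None = None
    post_onset_min: float = 26.0
    onset_floor_min: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if not (0 < self.gamma_suppression <= 1):
            raise ParameterError("gamma_suppression must lie in (0, 1]")
        for name in ("developed_amp", "baseline_sigma", "hg_amp", "fs"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.light_schedule not in ("none", "continuous", "intermittent"):
            raise ParameterError("unknown light_schedule")

    @property
    def onset_sd_min(self) -> float:
        return self.onset_sem_min * np.sqrt(self.onset_n_printed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in (
            "preictal_band", "spike_rate_range", "transition_min",
            "developed_band", "remission_len_s", "light_on_s", "light_gap_s",
            "behavioral_lead_min", "hg_band",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SeizureProfile:
    """Ground-truth trajectory of one synthetic seizure.

    All times are seconds relative to the pilocarpine injection.  The
    amplitude envelope of the developed oscillation is sigmoidal,
    ``1 - exp(-(t - t1) / growth_tau)`` after the end of the pre-ictal
    transition ``t1``, gated multiplicatively by remission epochs; it is
    nondecreasing outside remissions and zero before the ramp.
    """

    onset_s: float
    transition_s: float
    growth_tau_s: float
    remissions: tuple[tuple[float, float], ...]
    remission_depth: float
    behavioral_lead_s: float
    racine_tau_s: float
    light_epochs: tuple[tuple[float, float], ...]
    spike_rate_range: tuple[float, float]
    spike_amp_range: tuple[float, float]
    spike_tail_s: float = 60.0

    @property
    def developed_start_s(self) -> float:
        return self.onset_s + self.transition_s

    def envelope(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        t1 = self.developed_start_s
        env = np.where(t >= t1, 1.0 - np.exp(-np.maximum(t - t1, 0) / self.growth_tau_s), 0.0)
        for a, b in self.remissions:
            env = np.where((t >= a) & (t < b), env * self.remission_depth, env)
        return env

    def spike_rate(self, t: np.ndarray) -> np.ndarray:
        """Epileptiform spike rate (events/s): ramps across the transition,
        then fades as continuous oscillation takes over."""
        t = np.asarray(t, dtype=float)
        r0, r1 = self.spike_rate_range
        t1 = self.developed_start_s
        ramp = r0 + (r1 - r0) * np.clip((t - self.onset_s) / max(self.transition_s, 1e-9), 0, 1)
        fade = np.clip(1.0 - (t - t1) / self.spike_tail_s, 0, 1)
        rate = np.where(t >= self.onset_s, ramp * np.where(t < t1, 1.0, fade), 0.0)
        for a, b in self.remissions:
            rate = np.where((t >= a) & (t < b), rate * self.remission_depth, rate)
        return rate

    def spike_amp(self, t: np.ndarray) -> np.ndarray:
        a0, a1 = self.spike_amp_range
        frac = np.clip(
            (np.asarray(t, float) - self.onset_s) / max(self.transition_s, 1e-9), 0, 1
        )
        return a0 + (a1 - a0) * frac

    def light_factor(self, t: np.ndarray, suppression: float, tau_s: float) -> np.ndarray:
        """High-gamma amplitude factor: drops to ``suppression`` at each
        light onset and relaxes back to 1 with time constant ``tau_s``."""
        t = np.asarray(t, dtype=float)
        fac = np.ones_like(t)
        for on, off in self.light_epochs:
            inside = (t >= on) & (t < off)
            rec_ = suppression + (1 - suppression) * (1 - np.exp(-(t - on) / tau_s))
            fac = np.where(inside, rec_, fac)
        return fac

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# random draws
# ---------------------------------------------------------------------------

def _subject_rng(cfg_seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(cfg_seed), int(subject_index)))
    )


def draw_onset(cfg: CohortConfig, rng: np.random.Generator) -> float:
    """Onset delay (s post-injection), Normal truncated at the floor."""
    mean = cfg.onset_mean_min * 60.0
    sd = cfg.onset_sd_min * 60.0
    floor = cfg.onset_floor_min * 60.0
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= floor:
            return float(v)
    raise ParameterError("onset distribution is almost entirely below the floor")


def sample_onsets(cfg: CohortConfig, n: int) -> np.ndarray:
    """Ground-truth onset delays (minutes) for ``n`` subjects of a cohort."""
    return np.array(
        [draw_onset(cfg, _subject_rng(cfg.seed, i)) / 60.0 for i in range(n)]
    )


def draw_profile(cfg: CohortConfig, rng: np.random.Generator) -> SeizureProfile:
    onset = draw_onset(cfg, rng)
    transition = rng.uniform(*cfg.transition_min) * 60.0
    lead = rng.uniform(*cfg.behavioral_lead_min) * 60.0

    remissions: list[tuple[float, float]] = []
    if cfg.remission_rate_per_min > 0:
        t1 = onset + transition
        horizon = cfg.remission_window_min * 60.0
        t = t1 + rng.exponential(60.0 / cfg.remission_rate_per_min)
        while t < t1 + horizon:
            dur = rng.uniform(*cfg.remission_len_s)
            remissions.append((float(t), float(t + dur)))
            t = t + dur + rng.exponential(60.0 / cfg.remission_rate_per_min)

    light: list[tuple[float, float]] = []
    end = onset + cfg.post_onset_min * 60.0
    if cfg.light_schedule == "continuous":
        start = max(60.0, rng.normal(cfg.light_start_mean_min, cfg.light_start_sd_min) * 60.0)
        if start < end - 1.0:
            light.append((float(start), float(end)))
    elif cfg.light_schedule == "intermittent":
        t = max(60.0, rng.normal(cfg.light_start_mean_min, cfg.light_start_sd_min) * 60.0)
        while t < end - 1.0:
            dur = rng.uniform(*cfg.light_on_s)
            light.append((float(t), float(min(t + dur, end))))
            t = t + dur + rng.uniform(*cfg.light_gap_s)

    return SeizureProfile(
        onset_s=onset,
        transition_s=transition,
        growth_tau_s=cfg.growth_tau_s,
        remissions=tuple(remissions),
        remission_depth=cfg.remission_depth,
        behavioral_lead_s=lead,
        racine_tau_s=cfg.racine_tau_s,
        light_epochs=tuple(light),
        spike_rate_range=cfg.spike_rate_range,
        spike_amp_range=(0.55 * cfg.preictal_amp_max, cfg.preictal_amp_max),
    )


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def pink_noise(n: int, fs: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-power background noise with RMS amplitude ``sigma`` (µV)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x * (sigma / sd) if sd > 0 else x


def band_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _spike_kernel(fs: float, width_s: float = 0.015) -> np.ndarray:
    """Biphasic (Gaussian-derivative) epileptiform spike, unit peak."""
    tt = np.arange(-4 * width_s, 4 * width_s, 1.0 / fs)
    k = -tt * np.exp(-(tt**2) / (2 * width_s**2))
    return k / np.abs(k).max()


def _spike_train(
    profile: SeizureProfile,
    t: np.ndarray,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Amplitude-weighted delta train of spike events (thinned Poisson)."""
    rmax = max(profile.spike_rate_range) + 1e-9
    t_lo = profile.onset_s
    t_hi = profile.developed_start_s + profile.spike_tail_s
    span = max(t_hi - t_lo, 0.0)
    n_cand = rng.poisson(rmax * span)
    cand = np.sort(rng.uniform(t_lo, t_hi, n_cand))
    keep = rng.uniform(0, rmax, n_cand) < profile.spike_rate(cand)
    times = cand[keep]
    amps = profile.spike_amp(times) * rng.uniform(0.7, 1.3, times.size)
    train = np.zeros_like(t)
    idx = np.round((times - t[0]) * fs).astype(int)
    ok = (idx >= 0) & (idx < t.size)
    np.add.at(train, idx[ok], amps[ok])
    return train


# ---------------------------------------------------------------------------
# subject / cohort generation
# ---------------------------------------------------------------------------

def generate_subject(
    cfg: CohortConfig, subject_index: int
) -> tuple[Recording, RacineSeries, SeizureProfile]:
    """Synthesize one animal: 4-channel recording, Racine series, ground truth."""
    rng = _subject_rng(cfg.seed, subject_index)
    profile = draw_profile(cfg, rng)
    fs = cfg.fs
    baseline_s = cfg.baseline_min * 60.0
    if cfg.duration_min is None:
        dur_s = baseline_s + profile.onset_s + cfg.post_onset_min * 60.0
    else:
        dur_s = cfg.duration_min * 60.0
        if dur_s < baseline_s + profile.onset_s + 60.0:
            raise ParameterError(
                "duration_min too short for the drawn onset; increase it or use auto"
            )
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs - baseline_s  # seconds relative to injection
    lag = int(round(CORTICAL_LAG_S * fs))

    data = np.empty((len(CHANNEL_ROLES), n))
    for ci in range(len(CHANNEL_ROLES)):
        data[ci] = pink_noise(n, fs, cfg.baseline_sigma, rng)

    # pre-ictal spikes: common train, hippocampus leads cortex
    kernel = _spike_kernel(fs)
    train = _spike_train(profile, t, fs, rng)
    spikes_h = signal.fftconvolve(train, kernel, mode="same")
    spikes_c = 0.85 * np.roll(spikes_h, lag)
    spikes_c[:lag] = 0.0

    # developed oscillation: common narrowband source + per-channel part
    env = profile.envelope(t)
    osc_sigma = cfg.developed_amp / 2.0
    common = band_noise(n, fs, cfg.developed_band, rng)
    mix = np.array([0.75, 0.75, 0.9, 0.9])
    common_c = np.roll(common, lag)
    common_c[:lag] = 0.0
    for ci, role in enumerate(CHANNEL_ROLES):
        own = band_noise(n, fs, cfg.developed_band, rng)
        src = common_c if role.startswith("cortical") else common
        w = mix[ci]
        osc = (w * src + np.sqrt(1 - w**2) * own) * env * osc_sigma
        data[ci] += osc + (spikes_c if role.startswith("cortical") else spikes_h)

    # high-gamma component on hippocampal contacts
    hg_fac = profile.light_factor(t, cfg.gamma_suppression, cfg.gamma_tau_s)
    for ci, role in enumerate(CHANNEL_ROLES):
        if role.startswith("hippocampal"):
            hg = band_noise(n, fs, cfg.hg_band, rng) * cfg.hg_amp
            data[ci] += hg * hg_fac * (1.0 + env)

    events = [(baseline_s, "pilocarpine")]
    for on, off in profile.light_epochs:
        off = min(off, dur_s - baseline_s - 0.5)
        if off <= on:
            continue
        events.append((baseline_s + on, "light_on"))
        events.append((baseline_s + off, "light_off"))
    events.append((dur_s - 0.5, "pentobarbital"))
    rec = Recording(
        data=data,
        fs=fs,
        channels=CHANNEL_ROLES,
        events=EventTimeline(tuple(events)),
        subject_id=f"{cfg.group}_{subject_index:02d}",
        group=cfg.group,
    )

    racine = _racine_series(cfg, profile, rng, dur_s - baseline_s - 0.5)
    racine.subject_id = rec.subject_id
    racine.group = cfg.group
    return rec, racine, profile


def _racine_series(
    cfg: CohortConfig,
    profile: SeizureProfile,
    rng: np.random.Generator,
    t_end: float,
) -> RacineSeries:
    """Behavioral scores: sigmoidal severity leading the EEG onset."""
    starts = np.arange(0.0, t_end - EPOCH_S, EPOCH_S)
    b_onset = profile.onset_s - profile.behavioral_lead_s
    sev = 5.0 * (1.0 - np.exp(-np.maximum(starts - b_onset, 0) / profile.racine_tau_s))
    sev = np.where(starts >= b_onset, sev, 0.0)
    noisy = sev + rng.normal(0, 0.35, starts.size)
    scores = np.clip(np.round(noisy), 0, 5).astype(int)
    scores[starts < b_onset] = 0
    return RacineSeries(starts, scores)


def generate_cohorts(
    cfgs: list[CohortConfig],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Write a cohort bundle (recordings, events, Racine, manifest) to disk.

    If ``seed`` is given it deterministically re-seeds each config.  Returns
    the manifest dict; on disk it is ``manifest.json``.
    """
    groups = [c.group for c in cfgs]
    if len(set(groups)) != len(groups):
        raise ParameterError("duplicate group labels")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"groups": {}, "seed": seed}
    for gi, cfg in enumerate(cfgs):
        if seed is not None:
            child = int(
                np.random.SeedSequence((int(seed), gi)).generate_state(1)[0] % (2**31)
            )
            cfg = dataclasses.replace(cfg, seed=child)
        entry = {"config": cfg.to_dict(), "subjects": []}
        for si in range(cfg.n_subjects):
            rec, racine, profile = generate_subject(cfg, si)
            stem = rec.subject_id
            write_recording(rec, out_dir / f"{stem}.csv")
            rdf = out_dir / f"{stem}.racine.csv"
            pd.DataFrame(
                {"epoch_start_s": racine.epoch_starts, "score": racine.scores}
            ).to_csv(rdf, index=False)
            entry["subjects"].append(
                {
                    "subject_id": stem,
                    "recording": f"{stem}.csv",
                    "racine": f"{stem}.racine.csv",
                    "fs": cfg.fs,
                    "profile": profile.to_dict(),
                }
            )
        manifest["groups"][cfg.group] = entry
    text = json.dumps(manifest, indent=1, sort_keys=True)
    (out_dir / "manifest.json").write_text(text)
    manifest["manifest_sha1"] = hashlib.sha1(text.encode()).hexdigest()
    return manifest


# ---------------------------------------------------------------------------
# pulse sessions (seizure-free illumination)
# ---------------------------------------------------------------------------

def generate_pulse_session(
    n_pulses: int = 35,
    pulse_s: float = 5.0,
    gap_s: float = 30.0,
    suppression: float = 0.3,
    fs: float = 512.0,
    seed: int = 0,
    hg_amp: float = 10.0,
    hg_band: tuple[float, float] = (70.0, 100.0),
    baseline_sigma: float = 50.0,
    gamma_tau_s: float = 5.0,
    lead_s: float = 30.0,
) -> Recording:
    """Seizure-free hippocampal recording under a pulsed light protocol.

    ``n_pulses`` light pulses of ``pulse_s`` seconds separated by ``gap_s``
    seconds, with the high-gamma component suppressed by the multiplicative
    ``suppression`` amplitude factor at each onset (exponential recovery,
    ``gamma_tau_s``).
    """
    if n_pulses < 1:
        raise ParameterError("n_pulses must be >= 1")
    if pulse_s <= 0 or gap_s < 0:
        raise ParameterError("pulse_s must be positive and gap_s nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 9_999)))
    dur_s = lead_s + n_pulses * (pulse_s + gap_s)
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    ons = lead_s + np.arange(n_pulses) * (pulse_s + gap_s)
    epochs = tuple((float(o), float(o + pulse_s)) for o in ons)
    fac = np.ones(n)
    for on, off in epochs:
        inside = (t >= on) & (t < off)
        fac = np.where(
            inside,
            suppression + (1 - suppression) * (1 - np.exp(-(t - on) / gamma_tau_s)),
            fac,
        )
    x = pink_noise(n, fs, baseline_sigma, rng)
    x += band_noise(n, fs, hg_band, rng) * hg_amp * fac
    events = []
    for on, off in epochs:
        events.append((on, "light_on"))
        events.append((off, "light_off"))
    return Recording(
        data=x[None, :],
        fs=fs,
        channels=("hippocampal_1",),
        events=EventTimeline(tuple(events)),
        subject_id=f"pulse_session_{seed}",
    )


# ---------------------------------------------------------------------------
# cheap ground-truth curves (no waveform synthesis)
# ---------------------------------------------------------------------------

def llcum_curve_from_profile(
    profile: SeizureProfile,
    cfg: CohortConfig,
    rng: np.random.Generator | None = None,
    duration_s: float = 1500.0,
    grid_step_s: float = 1.0,
    noise_sd: float = 0.2,
) -> np.ndarray:
    """Expected cumulative line-length curve implied by a seizure profile.

    The per-second line-length density is modelled from the profile's
    components (background noise, spikes, developed oscillation) without
    synthesizing a waveform, which makes large calibration simulations
    cheap.  ``noise_sd`` adds per-second lognormal estimation noise.
    """
    t = profile.onset_s + np.arange(0.0, duration_s, grid_step_s)
    base = 0.33 * cfg.baseline_sigma * cfg.fs / 2.0  # background path length / s
    spikes = profile.spike_rate(t) * 4.0 * profile.spike_amp(t)
    f_rms = np.sqrt(np.mean(np.array(cfg.developed_band) ** 2))
    osc = (
        np.sqrt(2 / np.pi)
        * 2
        * np.pi
        * f_rms
        * profile.envelope(t)
        * cfg.developed_amp
        / 2.0
    )
    rate = base + spikes + osc
    if rng is not None and noise_sd > 0:
        rate = rate * np.exp(rng.normal(0, noise_sd, rate.size))
    cum = np.concatenate([[0.0], np.cumsum(rate)])
    return cum / cum[-1]


def sample_llcum_curves(
    cfg: CohortConfig, n: int, duration_s: float = 1500.0
) -> np.ndarray:
    """Matrix (n x grid) of profile-implied cumulative line-length curves."""
    rows = []
    for i in range(n):
        rng = _subject_rng(cfg.seed, i)
        profile = draw_profile(cfg, rng)
        rows.append(
            llcum_curve_from_profile(profile, cfg, rng, duration_s=duration_s)
        )
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# irradiance
# ---------------------------------------------------------------------------

def fiber_irradiance(power_mw: float, diameter_um: float) -> float:
    """Irradiance (mW/mm²) at a flat fiber tip of the given core diameter."""
    if power_mw < 0:
        raise ParameterError("power must be nonnegative")
    if diameter_um <= 0:
        raise ParameterError("diameter must be positive")
    radius_mm = diameter_um / 2000.0
    return power_mw / (np.pi * radius_mm**2)


# ---------------------------------------------------------------------------
# printed-group calibration
# ---------------------------------------------------------------------------

def default_cohorts(seed: int = 0) -> list[CohortConfig]:
    """The four study groups with onset statistics at their printed values.

    Controls share fast seizure dynamics; the experimental (illuminated,
    opsin-expressing) group has the delayed onset distribution, slowed
    envelope growth with remission epochs, and high-gamma suppression under
    light.
    """
    return [
        CohortConfig(
            group="sham_control",
            n_subjects=13,
            onset_mean_min=15.2,
            onset_sem_min=1.1,
            onset_n_printed=13,
            seed=seed,
        ),
        CohortConfig(
            group="nphr_control",
            n_subjects=7,
            onset_mean_min=17.3,
            onset_sem_min=1.3,
            onset_n_printed=7,
            seed=seed + 1,
        ),
        CohortConfig(
            group="light_control",
            n_subjects=8,
            onset_mean_min=16.3,
            onset_sem_min=1.7,
            onset_n_printed=8,
            light_schedule="continuous",
            gamma_suppression=1.0,
            seed=seed + 2,
        ),
        CohortConfig(
            group="experimental",
            n_subjects=16,
            onset_mean_min=21.0,
            onset_sem_min=1.8,
            onset_n_printed=16,
            light_schedule="continuous",
            gamma_suppression=0.3,
            growth_tau_s=300.0,
            remission_rate_per_min=0.6,
            racine_tau_s=420.0,
            seed=seed + 3,
        ),
    ]
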