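"""Synthetic EEG/EOG session generator.

Produces one-hour-style sessions of repeated one-minute "flight" trials, each
followed by a short sleepiness self-report window announced by a beep.  Every
channel is a sum of band-limited oscillations whose amplitudes depend on the
current drowsiness level through per-region gains, 1/f background noise, and
stereotyped blink artifacts coupled into frontal EEG and the EOG references.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .montage import montage, region_of

__all__ = [
    "DriftParams",
    "SimConfig",
    "Event",
    "RawSession",
    "kss_trajectory",
    "inject_blinks",
    "simulate_session",
    "separable_config",
    "null_config",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


# Oscillation bands synthesized by the generator (Hz, half-open).
OSC_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

# Scalp region carrying each drowsiness-modulated band.
BAND_REGION = {"theta": "temporoparietal", "alpha": "occipitoparietal", "beta": "frontal"}


@dataclass(frozen=True)
class DriftParams:
    """Bounded random walk parameters for the sleepiness trajectory."""

    start: float = 1.5
    per_trial: float = 0.13
    sigma: float = 0.4


def _default_band_gains() -> dict[int, dict[str, float]]:
    # Level 1 (very alert) .. 5 (very sleepy). Gains multiply the base RMS of
    # the band's oscillation on its target region; adjacent levels overlap.
    return {
        level: {
            "theta": 1.0 + 0.30 * (level - 1),
            "alpha": 1.0 + 0.35 * (level - 1),
            "beta": 1.0 + 0.25 * (level - 1),
        }
        for level in range(1, 6)
    }


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic session."""

    n_trials: int = 60
    trial_flight_s: float = 60.0
    kss_window_s: float = 10.0
    fs: float = 1000.0
    band_gains: Mapping[int, Mapping[str, float]] = field(default_factory=_default_band_gains)
    osc_base_rms: Mapping[str, float] = field(
        default_factory=lambda: {"delta": 2.5, "theta": 2.0, "alpha": 3.0, "beta": 1.2, "gamma": 0.6}
    )
    noise_exponent: float = 1.0
    noise_rms: float = 8.0
    eog_noise_rms: float = 5.0
    blink_rate: float | Mapping[int, float] = 12.0  # events per minute (optionally per level)
    blink_amp: float = 150.0
    kss_drift: DriftParams = field(default_factory=DriftParams)
    kss_sequence: Sequence[int] | None = None  # explicit per-trial KSS override
    miss_prob: float = 0.15  # probability of a missed report when KSS >= 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.fs <= 100.0:
            raise ConfigError(f"fs must exceed 100 Hz (2 x 50 Hz), got {self.fs}")
        for level, gains in self.band_gains.items():
            for band, g in gains.items():
                if g < 0:
                    raise ConfigError(f"negative gain {g} for band {band!r} at level {level}")
        for band, rms in self.osc_base_rms.items():
            if rms < 0:
                raise ConfigError(f"negative base RMS {rms} for band {band!r}")
        if self.noise_rms < 0 or self.eog_noise_rms < 0:
            raise ConfigError("noise RMS must be non-negative")
        rates = self.blink_rate.values() if isinstance(self.blink_rate, Mapping) else [self.blink_rate]
        if any(r < 0 for r in rates):
            raise ConfigError("blink_rate must be non-negative")
        if self.kss_sequence is not None:
            if len(self.kss_sequence) != self.n_trials:
                raise ConfigError("kss_sequence length must equal n_trials")
            if any(not 1 <= int(v) <= 9 for v in self.kss_sequence):
                raise ConfigError("kss_sequence values must lie in [1, 9]")

    def trial_samples(self) -> int:
        return int(round((self.trial_flight_s + self.kss_window_s) * self.fs))


@dataclass(frozen=True)
class Event:
    """A timeline marker: trial start, beep, or a sleepiness response."""

    sample: int
    kind: str  # trial_start | beep | kss_response
    kss: int | None = None


@dataclass
class RawSession:
    """Continuous multichannel recording with its event timeline."""

    data: np.ndarray  # (n_channels, n_samples) in microvolts
    channel_labels: list[str]
    channel_types: list[str]  # "EEG" | "EOG"
    events: list[Event]
    fs: float
    subject_id: str = "S1"

    def __post_init__(self) -> None:
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if len(self.channel_types) != len(self.channel_labels):
            raise ValueError("channel_types length must match channel_labels")
        if self.channel_types.count("EOG") != 4:
            raise ValueError("exactly 4 EOG channels are required")
        samples = [e.sample for e in self.events]
        if samples != sorted(samples):
            raise ValueError("events must be sorted by sample index")
        for e in self.events:
            if e.kss is not None and not 1 <= e.kss <= 9:
                raise ValueError(f"kss value out of range: {e.kss}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.channel_types) if t == "EEG"])

    def eog_indices(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.channel_types) if t == "EOG"])

    def copy_with(self, data: np.ndarray | None = None, events: list[Event] | None = None,
                  fs: float | None = None) -> "RawSession":
        return RawSession(
            data=self.data.copy() if data is None else data,
            channel_labels=list(self.channel_labels),
            channel_types=list(self.channel_types),
            events=list(self.events) if events is None else events,
            fs=self.fs if fs is None else fs,
            subject_id=self.subject_id,
        )


def kss_trajectory(n_trials: int, drift_params: DriftParams = DriftParams(), seed: int = 0) -> np.ndarray:
    """Integer KSS values (1-9) following a bounded random walk with drift."""
    if n_trials < 1:
        raise ConfigError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    latent = np.empty(n_trials)
    w = drift_params.start
    for t in range(n_trials):
        latent[t] = w
        w = np.clip(w + drift_params.per_trial + drift_params.sigma * rng.standard_normal(), 1.0, 9.0)
    return np.clip(np.rint(latent), 1, 9).astype(int)


_BLINK_DUR_S = 0.3


def blink_template(fs: float) -> np.ndarray:
    """Fixed ~300 ms biphasic raised-cosine blink shape, unit peak amplitude."""
    n = int(round(_BLINK_DUR_S * fs))
    t = np.arange(n) / n
    up = np.where(t < 2 / 3, 0.5 * (1 - np.cos(3 * np.pi * t)), 0.0)
    down = np.where(t >= 1 / 3, 0.5 * (1 - np.cos(3 * np.pi * (t - 1 / 3))), 0.0)
    tpl = up - 0.35 * down
    return tpl / np.max(np.abs(tpl))


def inject_blinks(
    signal: np.ndarray,
    blink_rate: float,
    fs: float,
    mixing_weights: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Add stereotyped blink transients to a multichannel signal.

    Parameters
    ----------
    signal : (n_channels, n_samples) array, modified copy returned.
    blink_rate : expected events per minute (Poisson).
    mixing_weights : per-channel amplitude (microvolts at blink peak).

    Returns
    -------
    (signal_with_blinks, blink_trace, onset_samples) where ``blink_trace`` is
    the unit-amplitude blink time course shared by all channels.
    """
    if blink_rate < 0:
        raise ConfigError(f"blink_rate must be >= 0, got {blink_rate}")
    mixing_weights = np.asarray(mixing_weights, dtype=float)
    if mixing_weights.shape != (signal.shape[0],):
        raise ValueError("mixing_weights must have one entry per channel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = signal.shape[1]
    trace = np.zeros(n)
    duration_min = n / fs / 60.0
    count = rng.poisson(blink_rate * duration_min)
    onsets = np.sort(rng.integers(0, max(n - 1, 1), size=count))
    tpl = blink_template(fs)
    for onset in onsets:
        stop = min(onset + tpl.size, n)
        trace[onset:stop] += tpl[: stop - onset]
    out = signal + mixing_weights[:, None] * trace[None, :]
    return out, trace, onsets


def _one_over_f_noise(n: int, exponent: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, scaled to rms."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    x_rms = np.sqrt(np.mean(x**2))
    return x * (rms / x_rms) if x_rms > 0 else x


def _narrowband_carrier(n: int, low: float, high: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise carrier (realistic PSD width, not a tone)."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    x_rms = np.sqrt(np.mean(x**2))
    return x / x_rms if x_rms > 0 else x


def _blink_mixing(labels: Sequence[str], types: Sequence[str], blink_amp: float) -> np.ndarray:
    """Peak blink amplitude per channel: strongest on EOG, then frontal EEG."""
    eog_w = {"EOG1": 1.0, "EOG2": -0.7, "EOG3": 0.25, "EOG4": 0.25}
    w = np.empty(len(labels))
    for i, (label, typ) in enumerate(zip(labels, types)):
        if typ == "EOG":
            w[i] = eog_w[label]
        elif label in ("Fp1", "Fp2"):
            w[i] = 0.45
        elif label.startswith("F") and not label.startswith("FC"):
            w[i] = 0.20
        elif label.startswith("FC"):
            w[i] = 0.12
        elif region_of(label) == "central":
            w[i] = 0.06
        elif region_of(label) == "temporoparietal":
            w[i] = 0.03
        else:
            w[i] = 0.01
    return w * blink_amp


def _kss_to_level(kss: int) -> int:
    """Collapse KSS 1-9 onto the five drowsiness levels 1-5."""
    return min((kss - 1) // 2 + 1, 5)


def simulate_session(config: SimConfig, subject_id: str = "S1") -> RawSession:
    """Generate one full session per the configured trial paradigm.

    The timeline is ``n_trials`` repetitions of (flight segment, beep, report
    window).  Trials with a missed report carry no kss_response event; the
    effective label downstream is KSS 9.
    """
    config.validate()
    labels = montage()
    types = ["EEG"] * 30 + ["EOG"] * 4
    fs = config.fs
    spt = config.trial_samples()
    flight_samples = int(round(config.trial_flight_s * fs))
    n_total = config.n_trials * spt
    n_ch = len(labels)

    seed_seq = np.random.SeedSequence(config.seed)
    rng_kss, rng_noise, rng_osc, rng_blink, rng_resp = (
        np.random.default_rng(s) for s in seed_seq.spawn(5)
    )

    if config.kss_sequence is not None:
        kss = np.asarray([int(v) for v in config.kss_sequence])
    else:
        kss = kss_trajectory(config.n_trials, config.kss_drift, seed=rng_kss.integers(2**32))
    levels = np.array([_kss_to_level(int(v)) for v in kss])

    data = np.zeros((n_ch, n_total))

    # 1/f background noise on every channel.
    for i in range(n_ch):
        rms = config.noise_rms if types[i] == "EEG" else config.eog_noise_rms
        data[i] += _one_over_f_noise(n_total, config.noise_exponent, rms, rng_noise)

    # Band-limited oscillations on EEG channels, amplitude set per trial by
    # the drowsiness level's region gain (piecewise-constant envelope).
    envelope = np.ones(n_total)
    for band, (low, high) in OSC_BANDS.items():
        base = config.osc_base_rms.get(band, 0.0)
        if base == 0.0:
            continue
        region = BAND_REGION.get(band)
        for i in range(30):
            carrier = _narrowband_carrier(n_total, low, high, fs, rng_osc)
            if region is not None and region_of(labels[i]) == region:
                for trial, level in enumerate(levels):
                    gain = config.band_gains.get(int(level), {}).get(band, 1.0)
                    envelope[trial * spt : (trial + 1) * spt] = gain
                data[i] += base * envelope * carrier
                envelope[:] = 1.0
            else:
                data[i] += base * carrier

    # Blink artifacts (per-trial so the rate can depend on drowsiness level).
    mixing = _blink_mixing(labels, types, config.blink_amp)
    for trial, level in enumerate(levels):
        if isinstance(config.blink_rate, Mapping):
            rate = float(config.blink_rate.get(int(level), 0.0))
        else:
            rate = float(config.blink_rate)
        if rate == 0.0 or config.blink_amp == 0.0:
            continue
        sl = slice(trial * spt, (trial + 1) * spt)
        data[:, sl], _, _ = inject_blinks(data[:, sl], rate, fs, mixing, seed=rng_blink)

    # Event timeline: trial_start, beep after the flight segment, then the
    # response (possibly missed when very drowsy).
    events: list[Event] = []
    window_samples = spt - flight_samples
    for trial in range(config.n_trials):
        t0 = trial * spt
        beep = t0 + flight_samples
        events.append(Event(t0, "trial_start"))
        events.append(Event(beep, "beep"))
        missed = kss[trial] >= 8 and rng_resp.random() < config.miss_prob
        if not missed:
            margin = max(int(0.05 * window_samples), 1)
            latency = int(rng_resp.integers(margin, max(window_samples - margin, margin + 1)))
            events.append(Event(beep + latency, "kss_response", int(kss[trial])))

    return RawSession(data=data, channel_labels=labels, channel_types=types,
                      events=events, fs=fs, subject_id=subject_id)


def separable_config(n_trials: int = 12, fs: float = 200.0, seed: int = 0,
                     trial_flight_s: float = 60.0, kss_window_s: float = 10.0) -> SimConfig:
    """A strongly separable 5-level generator with balanced classes.

    Band gains scale steeply with level and noise is reduced so that 1-s
    epochs of different levels are far apart in band-power space.
    """
    gains = {
        level: {
            "theta": 1.0 + 0.9 * (level - 1),
            "alpha": 1.0 + 1.1 * (level - 1),
            "beta": 1.0 + 0.7 * (level - 1),
        }
        for level in range(1, 6)
    }
    # One KSS value per level, cycling so every level appears equally often.
    level_kss = [1, 3, 5, 7, 9]
    sequence = [level_kss[i % 5] for i in range(n_trials)]
    return SimConfig(
        n_trials=n_trials,
        trial_flight_s=trial_flight_s,
        kss_window_s=kss_window_s,
        fs=fs,
        band_gains=gains,
        noise_rms=3.0,
        blink_rate=0.0,
        kss_sequence=sequence,
        miss_prob=0.0,
        seed=seed,
    )


def null_config(n_trials: int = 12, fs: float = 200.0, seed: int = 0,
                trial_flight_s: float = 60.0, kss_window_s: float = 10.0) -> SimConfig:
    """A generator with labels but no class-dependent signal (chance-level)."""
    gains = {level: {"theta": 1.0, "alpha": 1.0, "beta": 1.0} for level in range(1, 6)}
    level_kss = [1, 3, 5, 7, 9]
    sequence = [level_kss[i % 5] for i in range(n_trials)]
    return SimConfig(
        n_trials=n_trials,
        trial_flight_s=trial_flight_s,
        kss_window_s=kss_window_s,
        fs=fs,
        band_gains=gains,
        blink_rate=0.0,
        kss_sequence=sequence,
        miss_prob=0.0,
        seed=seed,
    )
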