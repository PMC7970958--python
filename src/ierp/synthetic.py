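"""Synthetic ERP experiments with known oscillatory structure.

The generator emulates what the analysis assumes about epoched EEG: each
trial is a sum of oscillatory transients (Hann-windowed bursts with a
chosen centre frequency, latency, amplitude and degree of phase
locking), sitting on 1/f-shaped background noise plus white measurement
noise.  A condition effect is a multiplicative gain on flagged
components, so ground truth about *which time scale* carries the effect
is known exactly — the property the mode-lattice statistics are meant to
recover.  The pseudo-condition construction (the same trials plus white
noise at a fixed SNR) provides an exchangeable null with realistic
autocorrelation for false-alarm checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ChannelLayout, EpochSet

__all__ = [
    "Component",
    "SimSpec",
    "simulate_erp_experiment",
    "make_pseudo_condition",
    "simulate_null_trials",
    "pink_noise",
]


@dataclass(frozen=True)
class Component:
    """One oscillatory burst.

    phase_jitter_ms = 0 means strictly phase/latency-locked; a positive
    value jitters the burst latency per trial with that Gaussian sigma.
    condition_gain multiplies the amplitude in condition "B".
    """

    freq_hz: float
    amplitude_uv: float = 1.0
    latency_s: float = 0.3
    duration_s: float | None = None   # None -> 3 cycles
    phase_jitter_ms: float = 0.0
    condition_gain: float = 1.0

    def duration(self) -> float:
        return self.duration_s if self.duration_s is not None else 3.0 / self.freq_hz


@dataclass
class SimSpec:
    """Study conditions for a two-condition ERP simulation."""

    n_subjects: int = 16
    n_trials: int = 30            # per condition
    n_channels: int = 1
    fs: float = 128.0
    tmin: float = -0.5
    tmax: float = 1.5
    components: list[Component] = field(default_factory=list)
    noise_pink_sigma: float = 1.0     # µV, 1/f background
    noise_pink_exponent: float = 1.0  # spectral slope of the background
    noise_white_sigma: float = 0.25   # µV, sensor noise
    seed: int = 0

    def __post_init__(self):
        for c in self.components:
            if c.freq_hz >= self.fs / 2:
                raise ValueError("component frequency above Nyquist")
            if c.amplitude_uv < 0:
                raise ValueError("amplitudes must be >= 0")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.tmax - self.tmin) * self.fs))
        return self.tmin + np.arange(n) / self.fs


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
               exponent: float = 1.0, sigma: float = 1.0,
               fs: float = 1.0) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise along the
    last axis, scaled to standard deviation ``sigma``."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(freqs)
    nonzero = freqs > 0
    gain[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    gain[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * gain, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd * sigma


def _burst(times: np.ndarray, comp: Component, latency: float,
           amplitude: float) -> np.ndarray:
    dur = comp.duration()
    t0 = latency - dur / 2.0
    local = times - t0
    inside = (local >= 0) & (local <= dur)
    out = np.zeros_like(times)
    win = 0.5 * (1 - np.cos(2 * np.pi * local[inside] / dur))  # Hann
    out[inside] = amplitude * win * np.sin(
        2 * np.pi * comp.freq_hz * (times[inside] - latency))
    return out


def _default_layout(n_channels: int) -> ChannelLayout:
    # synthetic line of sensors 30 mm apart
    coords = np.zeros((n_channels, 3))
    coords[:, 0] = 30.0 * np.arange(n_channels)
    return ChannelLayout(labels=[f"CH{i + 1:02d}" for i in range(n_channels)],
                         coords=coords)


def simulate_erp_experiment(spec: SimSpec) -> list[EpochSet]:
    """Two-condition epochs per subject ("A" and "B"; condition "B"
    scales each component by its condition_gain).

    Ground-truth noiseless component sums per condition are stored in
    each EpochSet's ``ground_truth`` dict.
    """
    times = spec.times
    root = np.random.SeedSequence(spec.seed)
    out: list[EpochSet] = []
    layout = _default_layout(spec.n_channels)
    for s, child in enumerate(root.spawn(spec.n_subjects)):
        rng = np.random.default_rng(child)
        n_total = 2 * spec.n_trials
        data = np.zeros((n_total, spec.n_channels, times.size))
        conditions = np.array(["A"] * spec.n_trials + ["B"] * spec.n_trials)
        truth = {"A": np.zeros(times.size), "B": np.zeros(times.size)}
        for cond in ("A", "B"):
            for comp in spec.components:
                gain = comp.condition_gain if cond == "B" else 1.0
                truth[cond] += _burst(times, comp, comp.latency_s,
                                      comp.amplitude_uv * gain)
        for i in range(n_total):
            cond = conditions[i]
            trial = np.zeros((spec.n_channels, times.size))
            for comp in spec.components:
                gain = comp.condition_gain if cond == "B" else 1.0
                latency = comp.latency_s
                if comp.phase_jitter_ms > 0:
                    latency += rng.normal(0.0, comp.phase_jitter_ms / 1000.0)
                trial += _burst(times, comp, latency,
                                comp.amplitude_uv * gain)[None, :]
            if spec.noise_pink_sigma > 0:
                trial = trial + pink_noise(rng, (spec.n_channels, times.size),
                                           spec.noise_pink_exponent,
                                           spec.noise_pink_sigma, spec.fs)
            if spec.noise_white_sigma > 0:
                trial = trial + rng.normal(0.0, spec.noise_white_sigma,
                                           (spec.n_channels, times.size))
            data[i] = trial
        out.append(EpochSet(data=data, fs=spec.fs, times=times,
                            conditions=conditions, subject=f"S{s + 1:02d}",
                            layout=layout, ground_truth=truth))
    return out


def make_pseudo_condition(epochs: EpochSet, snr: float = 4.0,
                          seed: int | None = 0,
                          pseudo_label: str = "pseudo") -> EpochSet:
    """Append a pseudo-condition: the same trials plus white Gaussian
    noise with variance = per-trial signal variance / snr.

    The two conditions differ only by exchangeable noise, so any test
    contrasting them probes the false-alarm rate on null data with
    realistic signal structure.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    rng = np.random.default_rng(seed)
    var = epochs.data.var(axis=-1, keepdims=True)
    noise = rng.standard_normal(epochs.data.shape) * np.sqrt(var / snr)
    pseudo = epochs.data + noise
    data = np.concatenate([epochs.data, pseudo], axis=0)
    conditions = np.concatenate([
        epochs.conditions.astype(str),
        np.full(epochs.n_trials, pseudo_label)])
    return EpochSet(data=data, fs=epochs.fs, times=epochs.times,
                    conditions=conditions, subject=epochs.subject,
                    layout=epochs.layout, ground_truth=epochs.ground_truth)


def simulate_null_trials(n_trials: int, n_channels: int, fs: float,
                         n_times: int, noise: str = "white",
                         sigma: float = 1.0, exponent: float = 1.0,
                         seed: int | None = 0) -> EpochSet:
    """Pure-noise epochs ("white" or "pink") for calibration runs."""
    rng = np.random.default_rng(seed)
    shape = (n_trials, n_channels, n_times)
    if noise == "white":
        data = rng.normal(0.0, sigma, shape)
    elif noise == "pink":
        data = pink_noise(rng, shape, exponent, sigma, fs)
    else:
        raise ValueError("noise must be 'white' or 'pink'")
    times = np.arange(n_times) / fs
    return EpochSet(data=data, fs=fs, times=times,
                    conditions=np.array(["null"] * n_trials),
                    subject="NULL", layout=_default_layout(n_channels))
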