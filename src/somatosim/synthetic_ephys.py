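"""Ground-truthed synthetic multichannel extracellular recordings.

Emulates the two preparations used to study stimulation transmission
along the somatosensory neuraxis: a 32-channel dorsoventral linear probe
in the spinal cord (25 kHz) and a 32-channel array in the dorsal root
ganglion (30 kHz).  A recording is driven either by a stimulation pulse
train (each pulse recruits each channel's multi-unit with high
probability and sub-millisecond latency jitter, so channels fire almost
synchronously) or by a natural-touch rate profile (channels fire as
independent inhomogeneous Poisson processes, so activity is
asynchronous).

The voltage on each channel is the sum of

* spike waveforms (biphasic ~1 ms template, amplitude in units of the
  background SD) placed at the ground-truth spike times,
* an evoked local-field component: the drive convolved with a damped
  oscillatory kernel, scaled per channel by a Gaussian depth profile
  peaked at the dorsal end of the probe,
* powerline noise at 50 Hz and configured harmonics, slow drift,
  Gaussian background noise, and optional large artifacts.

Everything placed into the signal is recorded in a :class:`GroundTruth`,
which is what makes the downstream detection and comparison pipeline
testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .stim_encoding import RateProfile, StimTrain


@dataclass(frozen=True)
class ProbeGeometry:
    n_channels: int = 32
    layout: str = "linear"
    inter_channel_spacing_um: float = 100.0

    def __post_init__(self) -> None:
        if self.layout not in ("linear", "grid"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "linear" and self.inter_channel_spacing_um <= 0:
            raise ValueError("spacing must be positive for a linear probe")

    @property
    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.inter_channel_spacing_um


@dataclass
class NoiseConfig:
    """Additive noise components, amplitudes in uV."""

    background_sd_uv: float = 8.0
    line_amplitudes_uv: tuple[float, ...] = (4.0, 2.0, 1.0)  # 50, 100, 150 Hz
    line_base_hz: float = 50.0
    drift_amplitude_uv: float = 30.0
    drift_corner_hz: float = 0.5
    artifact_rate_hz: float = 0.0
    artifact_amplitude_sd: float = 20.0
    artifact_width_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.background_sd_uv < 0 or self.drift_amplitude_uv < 0 \
                or any(a < 0 for a in self.line_amplitudes_uv):
            raise ValueError("noise amplitudes must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseConfig":
        return cls(0.0, (), 50.0, 0.0, 0.5, 0.0)


@dataclass
class GroundTruth:
    spike_times: list[np.ndarray]
    artifact_windows: list[tuple[float, float]]
    rate_profile: RateProfile | None
    drive_label: str

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times))


@dataclass
class MultichannelRecording:
    sampling_rate: float
    voltages: np.ndarray  # channels x samples, uV
    geometry: ProbeGeometry
    trial_events: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.voltages = np.atleast_2d(np.asarray(self.voltages))
        if self.voltages.shape[0] != self.geometry.n_channels:
            raise ValueError("channel count does not match probe geometry")
        if not np.all(np.isfinite(self.voltages)):
            raise ValueError("voltages must be finite")

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


# -- building blocks ---------------------------------------------------------

def spike_template(sampling_rate: float) -> np.ndarray:
    """Biphasic extracellular spike template, ~1 ms, negative peak = -1."""
    t = np.arange(int(round(1.2e-3 * sampling_rate))) / sampling_rate
    w = (-np.exp(-0.5 * ((t - 3.0e-4) / 1.0e-4) ** 2)
         + 0.4 * np.exp(-0.5 * ((t - 6.0e-4) / 1.6e-4) ** 2))
    return w / np.abs(w).max()


def lfp_kernel(sampling_rate: float) -> np.ndarray:
    """Evoked-potential kernel per afferent volley: a sharp negative
    compound wave (~15 ms) followed by a large slow negative sink wave
    (~60 ms centre, ~150 ms total), normalised to peak |1|.

    The slow postsynaptic wave dominates the raw amplitude, as in cord
    dorsum potentials.  A 3rd-order 30 Hz high-pass attenuates but does
    not annihilate it, so the burst-rate envelope of the drive survives
    preprocessing at a few percent of its raw amplitude -- which is what
    coarse time-binned CSD analysis picks up, while the fast wave
    provides the in-band (30-300 Hz) single-trial content.
    """
    t = np.arange(int(round(0.18 * sampling_rate))) / sampling_rate
    fast = -np.exp(-0.5 * ((t - 0.012) / 0.006) ** 2)
    slow = -np.exp(-0.5 * ((t - 0.06) / 0.025) ** 2)
    k = 0.6 * fast + slow
    return k / np.abs(k).max()


def depth_profile(geometry: ProbeGeometry, width_mm: float = 1.5) -> np.ndarray:
    """Gaussian depth attenuation peaked at the dorsal end (channel 0),
    where the afferent volley enters the cord.

    The Gaussian peak sits on the probe, so its second spatial derivative
    (the CSD) contains balanced sinks and sources summing to ~zero along
    the probe -- a property the shuffled-channel control relies on.
    """
    z_mm = geometry.depths_um / 1000.0
    return np.exp(-0.5 * (z_mm / width_mm) ** 2)


def _add_at(traces: np.ndarray, channel: int, times: np.ndarray,
            template: np.ndarray, fs: float, amplitude: float) -> None:
    n = traces.shape[1]
    idx = np.round(times * fs).astype(int)
    for i in idx:
        j = min(i + template.size, n)
        if i < n:
            traces[channel, i:j] += amplitude * template[:j - i]


def make_touch_drive(duration: float = 0.8,
                     profile_shape: str = "rub",
                     peak_rate: float = 150.0,
                     seed: int | None = None,
                     bin_width: float = 0.005,
                     stroke_rate_hz: float = 5.5) -> RateProfile:
    """Firing-rate profile of the multi-unit response to a natural touch
    (rubbing the skin with a cotton swab).

    ``rub`` (default): steady-state rubbing.  Each stroke reversal (two
    per back-and-forth cycle, ``stroke_rate_hz`` reversals per second)
    drives a fast-attack volley -- the velocity-driven FA response --
    riding on a sustained floor.  The window emulates a segment cut from
    an ongoing robust response and is aligned to a stroke, so there is no
    contact-onset transient.  ``adapting``: single press with fast rise,
    exponential adaptation towards a plateau and release decay.
    ``bump``: a smooth Hann bump.  A ``seed`` adds reproducible
    low-frequency rate jitter.
    """
    if peak_rate <= 0:
        raise ValueError("peak_rate must be positive")
    edges = np.arange(int(round(duration / bin_width)) + 1) * bin_width
    t = 0.5 * (edges[:-1] + edges[1:])
    if profile_shape == "rub":
        rate = np.zeros_like(t)
        stroke_times = np.arange(0.0, duration, 1.0 / stroke_rate_hz)
        for t0 in stroke_times:
            u = t - t0
            burst = np.where(u >= 0,
                             (1.0 - np.exp(-np.clip(u, 0, None) / 0.008))
                             * np.exp(-np.clip(u, 0, None) / 0.06), 0.0)
            rate += burst
        rate += 0.15  # sustained (slowly adapting) component
    elif profile_shape == "adapting":
        rise = 1.0 - np.exp(-t / 0.02)
        adapt = 0.35 + 0.65 * np.exp(-t / 0.15)
        release = 1.0 / (1.0 + np.exp((t - (duration - 0.06)) / 0.02))
        rate = rise * adapt * release
    elif profile_shape == "bump":
        rate = np.sin(np.pi * t / duration) ** 2
    else:
        raise ValueError(f"unknown profile shape {profile_shape!r}")
    rate = rate / rate.max() * peak_rate
    if seed is not None:
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter1d
        jitter = gaussian_filter1d(rng.standard_normal(rate.size), 4.0)
        rate = np.clip(rate * (1.0 + 0.1 * jitter), 0.0, None)
    return RateProfile(edges, rate)


def volley_times_from_rate(profile: RateProfile,
                           peak_volley_rate_hz: float = 80.0) -> np.ndarray:
    """Deterministic population-volley times whose instantaneous rate
    follows the rate profile (time-rescaling: one volley per unit area of
    the normalised rate), peaking at ``peak_volley_rate_hz``.

    Natural touch synchronises afferents through their common mechanical
    input, so the population emits quasi-synchronous volleys at a rate
    tracking the stimulus -- the same rate-to-event-train dynamics a
    biomimetic frequency-modulated train reproduces, and what a constant
    tonic train does not.
    """
    peak = float(profile.rate_per_bin.max(initial=0.0))
    if peak <= 0:
        return np.empty(0)
    rate = profile.rate_per_bin / peak * peak_volley_rate_hz
    dt = profile.bin_width
    cum = np.concatenate([[0.0], np.cumsum(rate * dt)])
    times = []
    k = 0.0
    for i in range(rate.size):
        if rate[i] <= 0:
            continue
        while k < cum[i + 1] - 1e-12:
            times.append(i * dt + max(k - cum[i], 0.0) / rate[i])
            k += 1.0
    return np.asarray(times)


def _enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Greedily drop events closer than ``refractory`` to the previous one."""
    if times.size < 2 or refractory <= 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def _rate_on_grid(profile: RateProfile, n_samples: int, fs: float) -> np.ndarray:
    """Piecewise-constant rate sampled on the recording grid (Hz)."""
    t = np.arange(n_samples) / fs
    idx = np.searchsorted(profile.bin_edges, t, side="right") - 1
    valid = (idx >= 0) & (idx < profile.rate_per_bin.size)
    out = np.zeros(n_samples)
    out[valid] = profile.rate_per_bin[idx[valid]]
    return out


def synthesize_recording(drive: StimTrain | RateProfile | None,
                         geometry: ProbeGeometry | None = None,
                         noise_cfg: NoiseConfig | None = None,
                         n_trials: int = 10,
                         trial_length: float = 2.0,
                         seed: int = 0,
                         sampling_rate: float = 25000.0,
                         p_recruit: float = 0.9,
                         latency_ms: float = 1.5,
                         latency_jitter_ms: float = 0.5,
                         spike_amplitude_sd: float = 6.0,
                         lfp_gain_uv: float | None = None,
                         lfp_width_mm: float | None = None,
                         channel_rate_spread: float = 0.15,
                         spike_refractory_s: float = 1.5e-3,
                         depression_steady: float = 0.5,
                         depression_tau_s: float = 0.1,
                         lfp_amp_noise: float = 0.3,
                         lfp_local_ratio: float = 0.4,
                         drive_label: str | None = None,
                         ) -> tuple[MultichannelRecording, GroundTruth]:
    """Synthesize ``n_trials`` back-to-back trials of one drive condition.

    ``drive`` semantics: a :class:`StimTrain` is an electrical drive
    (synchronised recruitment, pulse-locked evoked LFP); a
    :class:`RateProfile` is a natural drive (independent inhomogeneous
    Poisson spiking per channel); ``None`` leaves only noise.
    """
    if trial_length <= 0:
        raise ValueError("trial_length must be positive")
    geometry = geometry or ProbeGeometry()
    noise_cfg = noise_cfg or NoiseConfig()
    rng = np.random.default_rng(seed)

    n_ch = geometry.n_channels
    n_per_trial = int(round(trial_length * sampling_rate))
    n_samples = n_per_trial * n_trials
    fs = sampling_rate
    volts = np.zeros((n_ch, n_samples), dtype=np.float32)
    trial_onsets = np.arange(n_trials) * trial_length

    sd = noise_cfg.background_sd_uv
    template = spike_template(fs)
    if lfp_width_mm is None:
        lfp_width_mm = 1.5
    depth = depth_profile(geometry, lfp_width_mm)

    spikes_per_ch: list[list[np.ndarray]] = [[] for _ in range(n_ch)]
    lfp_impulses = np.zeros(n_samples)
    rate_profile: RateProfile | None = None

    if isinstance(drive, StimTrain):
        label = drive_label or drive.encoding_label
        if lfp_gain_uv is None:
            lfp_gain_uv = 120.0  # evoked compound wave per pulse volley
        pulses = drive.pulse_onsets[drive.pulse_onsets < trial_length]
        # evoked-potential amplitude depresses over the stimulation run
        # (short-term synaptic depression, running in absolute time since
        # trials are delivered back to back) and fluctuates pulse to
        # pulse; both are characteristic of repetitive stimulation and
        # keep the evoked response from being perfectly periodic
        lat = latency_ms * 1e-3
        jit = latency_jitter_ms * 1e-3
        for k, t0 in enumerate(trial_onsets):
            depression = depression_steady + (1.0 - depression_steady) \
                * np.exp(-(pulses + t0) / depression_tau_s)
            weights = depression * np.clip(
                1.0 + lfp_amp_noise * rng.standard_normal(pulses.size),
                0.0, None)
            idx = np.round((pulses + t0) * fs).astype(int).clip(0, n_samples - 1)
            np.add.at(lfp_impulses, idx, weights)
            for ch in range(n_ch):
                recruited = rng.uniform(size=pulses.size) < p_recruit
                t = pulses[recruited] + lat + jit * rng.standard_normal(
                    int(recruited.sum()))
                t = np.sort(t[(t >= 0) & (t < trial_length)])
                spikes_per_ch[ch].append(t + t0)
    elif isinstance(drive, RateProfile):
        label = drive_label or "NATURAL"
        rate_profile = drive
        if lfp_gain_uv is None:
            lfp_gain_uv = 100.0  # compound wave per natural volley
        peak = float(drive.rate_per_bin.max(initial=0.0))
        gains = np.clip(1.0 + channel_rate_spread * rng.standard_normal(n_ch),
                        0.2, None)
        for k, t0 in enumerate(trial_onsets):
            for ch in range(n_ch):
                lam = peak * gains[ch]
                n_cand = rng.poisson(lam * trial_length)
                cand = np.sort(rng.uniform(0, trial_length, n_cand))
                idx = np.clip((cand / drive.bin_width).astype(int), 0,
                              drive.rate_per_bin.size - 1)
                ok = (cand < drive.span) & \
                     (rng.uniform(size=n_cand) * lam
                      < drive.rate_per_bin[idx] * gains[ch])
                spikes_per_ch[ch].append(
                    _enforce_refractory(cand[ok], spike_refractory_s) + t0)
    elif drive is None:
        label = drive_label or "NONE"
        lfp_gain_uv = 0.0
    else:
        raise TypeError(f"unknown drive type {type(drive).__name__}")

    spike_times = [np.sort(np.concatenate(s)) if s else np.empty(0)
                   for s in spikes_per_ch]

    # the natural drive's field potential is generated by population
    # volleys locked to the touch profile (replayed every trial), with
    # the same per-event amplitude variability as the electrical drives
    if isinstance(drive, RateProfile):
        volleys = volley_times_from_rate(drive)
        volleys = volleys[volleys < trial_length]
        for t0 in trial_onsets:
            w = np.clip(1.0 + lfp_amp_noise * rng.standard_normal(volleys.size),
                        0.0, None)
            idx = np.round((volleys + t0) * fs).astype(int).clip(0, n_samples - 1)
            np.add.at(lfp_impulses, idx, w)

    # spikes
    if sd > 0 or spike_amplitude_sd > 0:
        amp = spike_amplitude_sd * (sd if sd > 0 else 1.0)
        for ch in range(n_ch):
            _add_at(volts, ch, spike_times[ch], template, fs, amp)

    # evoked LFP: a volume-conducted common component (every volley evokes
    # lfp_gain_uv of compound potential on channel 0, depth-attenuated)
    # plus a channel-local component driven by each channel's own spiking
    # population
    if lfp_gain_uv and lfp_impulses.any():
        kern = lfp_kernel(fs)
        common = sps.oaconvolve(lfp_impulses, kern)[:n_samples]
        volts += (lfp_gain_uv * depth)[:, None] * \
            common[None, :].astype(np.float32)
        if lfp_local_ratio > 0:
            local_amp = lfp_local_ratio * lfp_gain_uv
            for ch in range(n_ch):
                if spike_times[ch].size == 0:
                    continue
                imp = np.zeros(n_samples)
                np.add.at(imp, np.round(spike_times[ch] * fs).astype(int)
                          .clip(0, n_samples - 1), 1.0)
                volts[ch] += (local_amp * depth[ch]) * sps.oaconvolve(
                    imp, kern)[:n_samples].astype(np.float32)

    # noise components
    if sd > 0:
        for ch in range(n_ch):
            volts[ch] += rng.standard_normal(n_samples).astype(np.float32) * sd
    if noise_cfg.line_amplitudes_uv:
        t = np.arange(n_samples) / fs
        line = np.zeros(n_samples, dtype=np.float32)
        for h, a in enumerate(noise_cfg.line_amplitudes_uv, start=1):
            if a > 0:
                line += (a * np.sin(2 * np.pi * noise_cfg.line_base_hz * h * t
                                    + rng.uniform(0, 2 * np.pi))).astype(np.float32)
        volts += line[None, :]
    if noise_cfg.drift_amplitude_uv > 0:
        sos = sps.butter(1, noise_cfg.drift_corner_hz, "lowpass", fs=fs,
                         output="sos")
        for ch in range(n_ch):
            d = sps.sosfilt(sos, rng.standard_normal(n_samples))
            rms = np.sqrt(np.mean(d ** 2))
            if rms > 0:
                volts[ch] += (d / rms * noise_cfg.drift_amplitude_uv
                              ).astype(np.float32)

    recording = MultichannelRecording(fs, volts, geometry, trial_onsets)
    truth = GroundTruth(spike_times, [], rate_profile, label)

    if noise_cfg.artifact_rate_hz > 0 and sd > 0:
        n_art = rng.poisson(noise_cfg.artifact_rate_hz * recording.duration)
        times = np.sort(rng.uniform(0, recording.duration * 0.99, n_art))
        recording, truth = embed_artifacts(
            recording, truth, times, noise_cfg.artifact_amplitude_sd,
            noise_cfg.artifact_width_ms, background_sd_uv=sd)
    return recording, truth


def embed_artifacts(recording: MultichannelRecording,
                    truth: GroundTruth,
                    times: np.ndarray,
                    amplitude_sd_multiple: float = 20.0,
                    width_ms: float = 5.0,
                    background_sd_uv: float | None = None,
                    ) -> tuple[MultichannelRecording, GroundTruth]:
    """Add large transient artifacts on every channel at ``times``.

    Amplitude is ``amplitude_sd_multiple`` times the background SD
    (estimated robustly from the recording when not given); the inserted
    windows are appended to the ground truth.
    """
    times = np.atleast_1d(np.asarray(times, float))
    if times.size == 0:
        return recording, truth
    if np.any(times < 0) or np.any(times > recording.duration):
        raise ValueError("artifact time outside recording span")
    if background_sd_uv is None:
        x = recording.voltages[0]
        background_sd_uv = float(np.median(np.abs(x - np.median(x))) / 0.6745)
    fs = recording.sampling_rate
    width_s = width_ms * 1e-3
    shape_t = np.arange(int(round(width_s * fs))) / fs
    shape = np.exp(-shape_t / (width_s / 4.0))
    volts = recording.voltages.copy()
    windows = list(truth.artifact_windows)
    for t in times:
        for ch in range(recording.n_channels):
            _add_at(volts, ch, np.array([t]), shape, fs,
                    amplitude_sd_multiple * background_sd_uv)
        windows.append((float(t), float(min(t + width_s, recording.duration))))
    new_rec = MultichannelRecording(fs, volts, recording.geometry,
                                    recording.trial_events)
    new_truth = replace(truth, artifact_windows=windows)
    return new_rec, new_truth


def synchrony_index(spike_times: list[np.ndarray],
                    window: float = 1e-3) -> float:
    """Fraction of spikes with a spike on a *different* channel within
    ``window``.  Electrical drives synchronise channels; natural drives
    do not."""
    total = sum(t.size for t in spike_times)
    if total == 0:
        return 0.0
    sync = 0
    for ch, t in enumerate(spike_times):
        if t.size == 0:
            continue
        others = np.sort(np.concatenate(
            [u for k, u in enumerate(spike_times) if k != ch] or [np.empty(0)]))
        if others.size == 0:
            continue
        pos = np.searchsorted(others, t)
        left = np.abs(t - others[np.clip(pos - 1, 0, others.size - 1)])
        right = np.abs(others[np.clip(pos, 0, others.size - 1)] - t)
        sync += int(np.sum(np.minimum(left, right) <= window))
    return sync / total


def spinal_preset() -> dict:
    """Recording parameters of the spinal linear-probe preparation."""
    return dict(geometry=ProbeGeometry(32, "linear", 100.0),
                sampling_rate=25000.0)


def drg_preset() -> dict:
    """Recording parameters of the DRG array preparation."""
    return dict(geometry=ProbeGeometry(32, "grid", 400.0),
                sampling_rate=30000.0)
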