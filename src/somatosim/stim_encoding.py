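"""Encoding of afferent activity or sensor pressure into stimulation trains.

The central encoder is *biomimetic frequency modulation*: the smoothed
population PSTH of simulated afferents modulates the instantaneous pulse
frequency of a charge-balanced biphasic train while the amplitude stays
constant.  Five comparison encodings are provided alongside it: tonic
(constant 50 Hz), linear amplitude modulation of charge by pressure,
time-discrete bursts at contact transients, sinusoidal pulse-width
modulation, and a Poisson train with exponential inter-pulse intervals.
Every generated train can be checked against a per-pulse charge safety
limit (default 120 nC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ENCODING_LABELS = ("BIOM_SA1", "BIOM_SA2", "BIOM_FA1", "BIOM_FA2", "BIOM_FULL",
                   "TONIC", "LIN", "DISC", "SINUS_PW", "POISSON")

#: Default per-pulse charge safety limit (nC) for intrafascicular electrodes.
CHARGE_LIMIT_NC = 120.0


@dataclass
class RateProfile:
    """Binned firing-rate profile (a PSTH) with provenance metadata."""

    bin_edges: np.ndarray
    rate_per_bin: np.ndarray
    n_trials: int = 1
    bin_width_provenance: str = "fixed"
    smoothing_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.rate_per_bin = np.asarray(self.rate_per_bin, float)
        if self.bin_edges.ndim != 1 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.rate_per_bin.size != self.bin_edges.size - 1:
            raise ValueError("n_bins must equal n_edges - 1")
        if np.any(self.rate_per_bin < 0):
            raise ValueError("rates must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def span(self) -> float:
        return float(self.bin_edges[-1] - self.bin_edges[0])


@dataclass
class FrequencyProfile:
    """Instantaneous stimulation frequency sampled on a uniform grid."""

    time_step: float
    freq_samples: np.ndarray
    f_min: float
    f_max: float

    def __post_init__(self) -> None:
        self.freq_samples = np.asarray(self.freq_samples, float)
        if self.f_min < 0 or self.f_max < self.f_min:
            raise ValueError("need f_max >= f_min >= 0")
        if np.any(self.freq_samples < self.f_min - 1e-9) or \
           np.any(self.freq_samples > self.f_max + 1e-9):
            raise ValueError("frequency samples outside [f_min, f_max]")

    @property
    def span(self) -> float:
        return self.freq_samples.size * self.time_step


@dataclass
class StimTrain:
    """Charge-balanced, cathodic-first biphasic pulse train.

    ``charge_per_pulse_nc`` is derived exactly as
    ``amplitude_ua * pulse_width_us / 1000``.
    """

    pulse_onsets: np.ndarray
    amplitude_ua: np.ndarray
    pulse_width_us: np.ndarray
    encoding_label: str
    waveform: str = "biphasic-symmetric-cathodic-first"

    def __post_init__(self) -> None:
        self.pulse_onsets = np.asarray(self.pulse_onsets, float)
        self.amplitude_ua = np.broadcast_to(
            np.asarray(self.amplitude_ua, float), self.pulse_onsets.shape).copy()
        self.pulse_width_us = np.broadcast_to(
            np.asarray(self.pulse_width_us, float), self.pulse_onsets.shape).copy()
        if self.encoding_label not in ENCODING_LABELS:
            raise ValueError(f"unknown encoding label {self.encoding_label!r}")
        if np.any(np.diff(self.pulse_onsets) < 0):
            raise ValueError("pulse onsets must be sorted")
        if self.pulse_onsets.size > 1:
            biphasic_s = 2.0 * self.pulse_width_us[:-1] * 1e-6
            if np.any(np.diff(self.pulse_onsets) <= biphasic_s):
                raise ValueError("inter-pulse interval shorter than the "
                                 "biphasic pulse itself")

    def __len__(self) -> int:
        return self.pulse_onsets.size

    @property
    def charge_per_pulse_nc(self) -> np.ndarray:
        return self.amplitude_ua * self.pulse_width_us / 1000.0

    @property
    def duration(self) -> float:
        return float(self.pulse_onsets[-1]) if len(self) else 0.0


@dataclass
class ChargeSafetyReport:
    limit_nc: float
    violations: list[int]

    @property
    def passed(self) -> bool:
        return not self.violations


def smooth_profile(profile: RateProfile,
                   kernel: str = "gaussian",
                   width_s: float = 0.03) -> RateProfile:
    """Smooth a rate profile on its own bin grid.

    ``width_s`` is the Gaussian sigma or the moving-average window.
    Reflecting boundaries keep the total rate mass of interior bins
    conserved and leave a constant profile unchanged.
    """
    if width_s <= 0:
        raise ValueError("width_s must be positive")
    dt = profile.bin_width
    if width_s < dt:
        raise ValueError("smoothing width smaller than one bin")
    x = profile.rate_per_bin
    if kernel == "gaussian":
        from scipy.ndimage import gaussian_filter1d
        y = gaussian_filter1d(x, sigma=width_s / dt, mode="reflect")
    elif kernel == "moving_average":
        from scipy.ndimage import uniform_filter1d
        y = uniform_filter1d(x, size=max(1, int(round(width_s / dt))),
                             mode="reflect")
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return RateProfile(profile.bin_edges.copy(), np.clip(y, 0.0, None),
                       n_trials=profile.n_trials,
                       bin_width_provenance=profile.bin_width_provenance,
                       smoothing_meta={"kernel": kernel, "width_s": width_s})


def profile_to_frequency(profile: RateProfile,
                         f_min: float = 0.0,
                         f_max: float = 100.0) -> FrequencyProfile:
    """Affine map of a (smoothed) rate profile onto [f_min, f_max].

    Zero rate maps to ``f_min`` and the profile maximum to ``f_max``.
    """
    if not f_max > f_min >= 0:
        raise ValueError("need f_max > f_min >= 0")
    peak = float(profile.rate_per_bin.max(initial=0.0))
    if peak <= 0:
        raise ValueError("all-zero profile has no frequency scale")
    freq = f_min + profile.rate_per_bin / peak * (f_max - f_min)
    return FrequencyProfile(profile.bin_width, freq, f_min, f_max)


def frequency_to_pulse_times(freq_profile: FrequencyProfile,
                             duration: float | None = None,
                             amplitude_ua: float = 60.0,
                             pulse_width_us: float = 500.0,
                             encoding_label: str = "BIOM_FULL") -> StimTrain:
    """Place pulses by time-rescaling of the integrated frequency profile.

    A pulse is emitted each time the cumulative integral of f(t) reaches
    the next integer (0, 1, 2, ...), so the total pulse count equals
    ``floor(integral of f dt)`` and a constant profile reduces to a
    regular tonic train starting at t = 0.
    """
    f = freq_profile.freq_samples
    if np.any(f < 0):
        raise ValueError("negative frequency sample")
    dt = freq_profile.time_step
    if duration is None:
        duration = freq_profile.span
    if duration > freq_profile.span + 1e-12:
        raise ValueError("duration exceeds profile span")
    n = min(f.size, int(np.ceil(duration / dt - 1e-12)))
    seg_len = np.full(n, dt)
    seg_len[-1] = duration - (n - 1) * dt
    cum = np.concatenate([[0.0], np.cumsum(f[:n] * seg_len)])
    n_pulses = int(np.floor(cum[-1] + 1e-9))
    onsets: list[float] = []
    k = 0.0
    for i in range(n):
        fi = f[i]
        if fi <= 0 or k >= n_pulses:
            continue
        # levels k with cum[i] <= k < cum[i+1] are crossed inside segment i;
        # only levels backed by a full interval of rate mass are emitted,
        # so the total count is floor(integral of f)
        while k < cum[i + 1] - 1e-12 and k < n_pulses:
            t = i * dt + max(k - cum[i], 0.0) / fi
            onsets.append(min(t, duration))
            k += 1.0
    return StimTrain(np.asarray(onsets), amplitude_ua, pulse_width_us,
                     encoding_label)


def make_tonic(freq: float = 50.0,
               duration: float = 2.0,
               amplitude_ua: float = 60.0,
               pulse_width_us: float = 500.0) -> StimTrain:
    """Constant-frequency train, first pulse at t = 0."""
    if freq <= 0:
        raise ValueError("frequency must be positive")
    n = int(np.floor(freq * duration + 1e-9))
    onsets = np.arange(n) / freq
    return StimTrain(onsets, amplitude_ua, pulse_width_us, "TONIC")


def make_poisson(mean_freq: float = 50.0,
                 duration: float = 2.0,
                 seed: int | None = None,
                 refractory: float | None = None,
                 amplitude_ua: float = 60.0,
                 pulse_width_us: float = 500.0) -> StimTrain:
    """Poisson train: i.i.d. exponential inter-pulse intervals.

    The ``refractory`` (default: just over the biphasic pulse duration,
    the shortest interval a stimulator can realise) shifts each interval
    while preserving the mean interval ``1/mean_freq``, so the expected
    count stays ``mean_freq * duration``; it must stay below
    ``1/mean_freq``.
    """
    if mean_freq <= 0:
        raise ValueError("mean_freq must be positive")
    if refractory is None:
        refractory = 2.0 * pulse_width_us * 1e-6 * 1.05
    if refractory >= 1.0 / mean_freq:
        raise ValueError("refractory must be below the mean interval")
    rng = np.random.default_rng(seed)
    mean_free = 1.0 / mean_freq - refractory
    onsets = []
    t = rng.exponential(1.0 / mean_freq)
    while t < duration:
        onsets.append(t)
        t += refractory + rng.exponential(mean_free)
    return StimTrain(np.asarray(onsets), amplitude_ua, pulse_width_us, "POISSON")


def make_linear(pressure_trace: np.ndarray,
                time_step: float,
                q_min_nc: float = 10.0,
                q_max_nc: float = 60.0,
                freq: float = 50.0,
                pulse_width_us: float = 500.0,
                pressure_threshold: float = 0.0) -> StimTrain:
    """Linear charge modulation: regular 50 Hz train whose per-pulse charge
    follows the normalised pressure, ``q = q_min + p * (q_max - q_min)``.

    Epochs at or below ``pressure_threshold`` emit no pulses (below the
    perceptual threshold).  Amplitude realises the charge at the fixed
    pulse width.
    """
    p = np.asarray(pressure_trace, float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("pressure must be normalised to [0, 1]")
    if not q_min_nc < q_max_nc:
        raise ValueError("need q_min < q_max")
    duration = p.size * time_step
    grid = np.arange(int(np.floor(freq * duration + 1e-9))) / freq
    p_at = np.interp(grid, np.arange(p.size) * time_step, p)
    keep = p_at > pressure_threshold
    grid, p_at = grid[keep], p_at[keep]
    charge = q_min_nc + p_at * (q_max_nc - q_min_nc)
    amp = charge * 1000.0 / pulse_width_us
    return StimTrain(grid, amp, pulse_width_us, "LIN")


def make_discrete(contact_events: list[tuple[float, str]],
                  burst_duration: float = 0.5,
                  freq: float = 50.0,
                  amplitude_ua: float = 60.0,
                  pulse_width_us: float = 500.0) -> StimTrain:
    """One short tonic burst per contact transient (press or release).

    Overlapping bursts are merged so no duplicate pulses are emitted.
    """
    times = [t for t, _ in contact_events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("contact events must be sorted")
    for _, kind in contact_events:
        if kind not in ("press", "release"):
            raise ValueError(f"unknown event type {kind!r}")
    merged: list[list[float]] = []
    for t in times:
        if merged and t <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t + burst_duration)
        else:
            merged.append([t, t + burst_duration])
    onsets = []
    for start, end in merged:
        n = int(np.ceil((end - start) * freq - 1e-9))
        onsets.extend(start + np.arange(n) / freq)
    return StimTrain(np.asarray(onsets), amplitude_ua, pulse_width_us, "DISC")


def make_sinusoidal_pw(freq: float = 50.0,
                       duration: float = 2.0,
                       amplitude_ua: float = 60.0,
                       pw_min_us: float = 200.0,
                       pw_max_us: float = 500.0,
                       modulation_freq: float = 1.0) -> StimTrain:
    """Regular train with sinusoidally modulated pulse width.

    The width starts at the midpoint, peaks at a quarter period and
    bottoms at three quarters; amplitude is constant.
    """
    if modulation_freq <= 0:
        raise ValueError("modulation_freq must be positive")
    if pw_min_us > pw_max_us:
        raise ValueError("need pw_min <= pw_max")
    n = int(np.floor(freq * duration + 1e-9))
    onsets = np.arange(n) / freq
    mid = 0.5 * (pw_min_us + pw_max_us)
    amp = 0.5 * (pw_max_us - pw_min_us)
    widths = mid + amp * np.sin(2 * np.pi * modulation_freq * onsets)
    return StimTrain(onsets, amplitude_ua, widths, "SINUS_PW")


def validate_charge(train: StimTrain,
                    limit_nc: float = CHARGE_LIMIT_NC) -> ChargeSafetyReport:
    """Flag every pulse whose charge exceeds the safety limit."""
    charge = train.charge_per_pulse_nc
    violations = np.nonzero(charge > limit_nc)[0].tolist()
    return ChargeSafetyReport(limit_nc, violations)


def design_biomimetic_train(composition: str = "FULL",
                            n_units: int = 120,
                            duration: float = 2.0,
                            bin_width: float = 0.01,
                            smooth_width_s: float = 0.03,
                            f_min: float = 0.0,
                            f_max: float = 100.0,
                            amplitude_ua: float = 60.0,
                            pulse_width_us: float = 500.0,
                            seed: int = 0) -> tuple[StimTrain, FrequencyProfile]:
    """Full biomimetic design chain: afferent population response to a
    ramp-and-hold stimulus -> population PSTH -> smoothing -> frequency
    modulation -> pulse train.  Amplitude stays constant along the train.
    """
    from . import afferent_sim as af

    pop = af.build_population(composition, n_units, seed=seed)
    stim = af.make_ramp_and_hold(duration=duration, seed=seed)
    spikes = af.simulate_responses(pop, stim, seed=seed)
    psth = af.population_psth(spikes, bin_width)
    smoothed = smooth_profile(psth, "gaussian", smooth_width_s)
    freq = profile_to_frequency(smoothed, f_min, f_max)
    label = "BIOM_FULL" if composition == "FULL" else f"BIOM_{composition}"
    train = frequency_to_pulse_times(freq, duration, amplitude_ua,
                                     pulse_width_us, label)
    return train, freq
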