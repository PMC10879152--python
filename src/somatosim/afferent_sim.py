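"""Simulation of foot-sole tactile afferent populations.

Four classes of low-threshold mechanoreceptive afferents innervate the
glabrous skin of the foot sole: slowly adapting type 1 and 2 (SA1, SA2),
which fire throughout a sustained indentation, and fast adapting type 1
and 2 (FA1, FA2), which fire only at skin-motion transients.  This module
populates a two-dimensional sole with parametrised units of these classes
and converts a ramp-and-hold pressure stimulus into stochastic spike
trains, one per unit.

The per-class firing-rate models are deliberately simple, fully stated
parametric equations (see :func:`compute_rate`): pressure is used directly
as the stress proxy ``s(t)`` driving each unit, so the mechanical
skin-deformation stage of a full biomechanical model is not reproduced.
Spikes are drawn from the instantaneous rate as an inhomogeneous Poisson
process by thinning, with a 1 ms absolute refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AFFERENT_CLASSES = ("SA1", "SA2", "FA1", "FA2")

#: Absolute refractory period enforced on every generated spike train (s).
REFRACTORY_S = 1e-3

# Steady-state level of the SA1 adaptation variable during sustained
# pressure, and the ratio of the recovery to the decay time constant.
_SA1_ADAPT_FLOOR = 0.3
_SA1_RECOVERY_RATIO = 5.0

#: Per-class mean firing-model parameters.  Gains are in spikes/s per
#: pressure unit (static), per pressure-unit/s (dynamic, SA1/FA1) or per
#: pressure-unit/s^2 (dynamic, FA2); time constants in s; rates in
#: spikes/s.  Individual units are drawn around these means (lognormal,
#: sigma = 0.2) to reflect natural response variability.
CLASS_DEFAULTS: dict[str, dict[str, float]] = {
    "SA1": dict(static_gain=80.0, dynamic_gain=1.2, tau_adapt=0.6,
                saturation_rate=300.0, spontaneous_rate=0.5),
    "SA2": dict(static_gain=30.0, dynamic_gain=0.0, tau_adapt=1.5,
                saturation_rate=150.0, spontaneous_rate=3.0),
    "FA1": dict(static_gain=0.0, dynamic_gain=3.0, tau_adapt=0.1,
                saturation_rate=400.0, spontaneous_rate=0.5),
    "FA2": dict(static_gain=0.0, dynamic_gain=0.02, tau_adapt=0.05,
                saturation_rate=500.0, spontaneous_rate=0.5),
}

#: Default rectangular sole outline, mm (width across the foot, length
#: heel to toes).
SOLE_OUTLINE_MM = (90.0, 240.0)

#: Smoothing windows for the transient-sensitive classes (s).
FA1_SMOOTH_S = 0.020
FA2_SMOOTH_S = 0.005


@dataclass(frozen=True)
class PressureStimulus:
    """Sampled pressure waveform applied uniformly over the sole.

    ``samples`` are non-negative pressure amplitudes (arbitrary units,
    peak normalised to the requested amplitude before noise).
    """

    time_step: float
    samples: np.ndarray
    noise_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        object.__setattr__(self, "samples", np.asarray(self.samples, float))
        if np.any(self.samples < 0):
            raise ValueError("pressure samples must be non-negative")

    @property
    def duration(self) -> float:
        return self.samples.size * self.time_step

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.time_step


@dataclass(frozen=True)
class AfferentUnit:
    """A single afferent with its class, sole location and rate model."""

    afferent_class: str
    location_mm: tuple[float, float]
    static_gain: float
    dynamic_gain: float
    tau_adapt: float
    saturation_rate: float
    spontaneous_rate: float

    def __post_init__(self) -> None:
        if self.afferent_class not in AFFERENT_CLASSES:
            raise ValueError(f"unknown afferent class {self.afferent_class!r}")
        if self.static_gain < 0 or self.dynamic_gain < 0:
            raise ValueError("gains must be non-negative")
        if self.saturation_rate <= 0:
            raise ValueError("saturation rate must be positive")
        if self.tau_adapt <= 0:
            raise ValueError("adaptation time constant must be positive")


@dataclass(frozen=True)
class AfferentPopulation:
    units: tuple[AfferentUnit, ...]
    composition_label: str
    seed: int

    def __len__(self) -> int:
        return len(self.units)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in AFFERENT_CLASSES}
        for u in self.units:
            counts[u.afferent_class] += 1
        return {c: n for c, n in counts.items() if n}


@dataclass
class SpikeTrainSet:
    """Per-unit sorted spike times for one stimulus presentation."""

    spike_times: list[np.ndarray]
    duration: float
    trial_index: int = 0
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.spike_times:
            if t.size and (np.any(np.diff(t) < REFRACTORY_S - 1e-12)
                           or t[0] < 0 or t[-1] > self.duration):
                raise ValueError("invalid spike train")

    def pooled(self) -> np.ndarray:
        if not self.spike_times:
            return np.empty(0)
        return np.sort(np.concatenate(self.spike_times))


def _allocate_counts(n_total: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``n_total`` units to classes."""
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions sum to {total}, expected 1")
    ideal = {c: n_total * f for c, f in fractions.items()}
    counts = {c: int(np.floor(v)) for c, v in ideal.items()}
    short = n_total - sum(counts.values())
    # ties broken by canonical class order
    order = sorted(fractions, key=lambda c: (-(ideal[c] - counts[c]),
                                             AFFERENT_CLASSES.index(c)))
    for c in order[:short]:
        counts[c] += 1
    return counts


def build_population(composition_label: str,
                     n_units: int,
                     class_fractions: dict[str, float] | None = None,
                     seed: int = 0,
                     sole_outline_mm: tuple[float, float] = SOLE_OUTLINE_MM,
                     ) -> AfferentPopulation:
    """Populate the sole with afferents of one class or a mixed population.

    For ``composition_label == "FULL"`` the ``n_units`` total is split
    between the four classes by ``class_fractions`` (largest-remainder
    rounding, so the counts are deterministic); any single-class label
    yields exactly ``n_units`` units of that class.  Locations are uniform
    over the sole outline and per-unit parameters are lognormal draws
    around the class means, reproducible under ``seed``.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if composition_label == "FULL":
        if class_fractions is None:
            class_fractions = {"SA1": 0.30, "SA2": 0.15, "FA1": 0.40, "FA2": 0.15}
        unknown = set(class_fractions) - set(AFFERENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown afferent classes {sorted(unknown)}")
        counts = _allocate_counts(n_units, class_fractions)
    elif composition_label in AFFERENT_CLASSES:
        counts = {composition_label: n_units}
    else:
        raise ValueError(f"unknown composition label {composition_label!r}")

    rng = np.random.default_rng(seed)
    units = []
    for cls in AFFERENT_CLASSES:
        n = counts.get(cls, 0)
        base = CLASS_DEFAULTS[cls]
        for _ in range(n):
            loc = (float(rng.uniform(0, sole_outline_mm[0])),
                   float(rng.uniform(0, sole_outline_mm[1])))
            jit = {k: float(v * rng.lognormal(0.0, 0.2)) if v > 0 else 0.0
                   for k, v in base.items()}
            units.append(AfferentUnit(cls, loc, **jit))
    return AfferentPopulation(tuple(units), composition_label, seed)


def make_ramp_and_hold(duration: float = 2.0,
                       on_phase: float = 0.15,
                       off_phase: float = 0.3,
                       amplitude: float = 1.0,
                       noise_fraction: float = 0.005,
                       time_step: float = 1e-3,
                       seed: int | None = None,
                       ramp_fraction: float = 0.2,
                       ) -> PressureStimulus:
    """Repeated ramp-and-hold pressure cycles with environmental noise.

    One cycle is ``on_phase`` of pressure (linear rise and fall each
    lasting ``ramp_fraction * on_phase``, plateau at ``amplitude`` in
    between) followed by ``off_phase`` of zero pressure; cycles tile the
    full ``duration``.  Additive uniform noise is bounded by
    ``noise_fraction * amplitude`` and the waveform is clipped at zero.
    """
    if duration <= 0 or time_step <= 0:
        raise ValueError("duration and time_step must be positive")
    if duration <= on_phase + off_phase:
        raise ValueError("duration must exceed one on+off cycle")
    if not 0 <= noise_fraction <= 1:
        raise ValueError("noise_fraction must lie in [0, 1]")

    t = np.arange(int(round(duration / time_step))) * time_step
    cycle = on_phase + off_phase
    phase = np.mod(t, cycle)
    rise = ramp_fraction * on_phase
    fall = ramp_fraction * on_phase
    plateau_end = on_phase - fall
    s = np.zeros_like(t)
    in_rise = phase < rise
    in_plateau = (phase >= rise) & (phase < plateau_end)
    in_fall = (phase >= plateau_end) & (phase < on_phase)
    s[in_rise] = phase[in_rise] / rise
    s[in_plateau] = 1.0
    s[in_fall] = (on_phase - phase[in_fall]) / fall
    s *= amplitude

    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.uniform(-1.0, 1.0, s.size) * noise_fraction * amplitude
        s = np.clip(s, 0.0, None)
    return PressureStimulus(time_step, s, noise_fraction)


def _moving_average(x: np.ndarray, width_s: float, dt: float) -> np.ndarray:
    w = max(1, int(round(width_s / dt)))
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def _sa1_adaptation(s: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exponential adaptation variable: decays towards a floor while the
    skin is loaded, recovers towards 1 while unloaded (slower, by
    ``_SA1_RECOVERY_RATIO``)."""
    a = np.empty_like(s)
    val = 1.0
    k_on = dt / tau
    k_off = dt / (tau * _SA1_RECOVERY_RATIO)
    loaded = s > 0
    for i in range(s.size):
        if loaded[i]:
            val += (_SA1_ADAPT_FLOOR - val) * k_on
        else:
            val += (1.0 - val) * k_off
        a[i] = val
    return a


def compute_rate(unit: AfferentUnit, stimulus: PressureStimulus) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) of ``unit`` for ``stimulus``.

    Class rate models (``s`` = pressure, ``v = ds/dt``, ``a = dv/dt``,
    ``[.]+`` = positive part):

    * SA1: ``g_s * [s]+ * A(t) + g_d * [v]+`` with exponential adaptation A
    * SA2: ``g_s * [s]+`` (sustained, low gain, no adaptation)
    * FA1: ``g_d * |v|`` smoothed over 20 ms
    * FA2: ``g_d * |a|`` smoothed over 5 ms

    plus the spontaneous rate, clipped to ``[0, saturation_rate]``.
    """
    s = stimulus.samples
    dt = stimulus.time_step
    v = np.gradient(s, dt)
    cls = unit.afferent_class
    if cls == "SA1":
        adapt = _sa1_adaptation(s, dt, unit.tau_adapt)
        rate = (unit.static_gain * np.clip(s, 0, None) * adapt
                + unit.dynamic_gain * np.clip(v, 0, None))
    elif cls == "SA2":
        rate = unit.static_gain * np.clip(s, 0, None)
    elif cls == "FA1":
        rate = unit.dynamic_gain * _moving_average(np.abs(v), FA1_SMOOTH_S, dt)
    else:  # FA2
        acc = np.gradient(v, dt)
        rate = unit.dynamic_gain * _moving_average(np.abs(acc), FA2_SMOOTH_S, dt)
    rate = rate + unit.spontaneous_rate
    return np.clip(rate, 0.0, unit.saturation_rate)


def sample_spikes(rate: np.ndarray, time_step: float,
                  rng: np.random.Generator,
                  refractory: float = REFRACTORY_S) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning, with an absolute
    refractory period.  ``rate`` is sampled on a uniform grid."""
    duration = rate.size * time_step
    lam_max = float(rate.max())
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    idx = np.minimum((cand / time_step).astype(int), rate.size - 1)
    keep = rng.uniform(0.0, 1.0, n_cand) * lam_max < rate[idx]
    cand = cand[keep]
    if cand.size == 0:
        return cand
    out = [cand[0]]
    for t in cand[1:]:
        if t - out[-1] >= refractory:
            out.append(t)
    return np.asarray(out)


def simulate_responses(population: AfferentPopulation,
                       stimulus: PressureStimulus,
                       seed: int = 0,
                       trial_index: int = 0) -> SpikeTrainSet:
    """Simulate one presentation of ``stimulus`` to every unit."""
    if len(population) == 0:
        raise ValueError("population is empty")
    if stimulus.duration <= 0:
        raise ValueError("stimulus duration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, trial_index)))
    trains, classes = [], []
    for unit in population.units:
        rate = compute_rate(unit, stimulus)
        trains.append(sample_spikes(rate, stimulus.time_step, rng))
        classes.append(unit.afferent_class)
    return SpikeTrainSet(trains, stimulus.duration, trial_index, classes)


def population_psth(spikes: SpikeTrainSet, bin_width: float):
    """Pool all units of one presentation into a population PSTH.

    Returns a :class:`somatosim.stim_encoding.RateProfile` whose rate is
    the mean per-afferent firing rate (spikes/s), i.e. pooled counts
    divided by ``n_units * bin_width``.
    """
    from .stim_encoding import RateProfile

    n_bins = max(1, int(round(spikes.duration / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(spikes.pooled(), bins=edges)
    n_units = max(1, len(spikes.spike_times))
    return RateProfile(bin_edges=edges,
                       rate_per_bin=counts / (n_units * bin_width),
                       n_trials=n_units,
                       bin_width_provenance="fixed")
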