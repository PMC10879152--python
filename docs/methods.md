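# Methods

`somatosim` implements, on synthetic data, the computational chain behind
biomimetic peripheral-nerve stimulation: design of frequency-modulated
stimulation patterns from a simulated foot-sole afferent population, and
the electrophysiological analyses used to compare electrically evoked and
naturally evoked neural dynamics in multichannel spinal/DRG recordings.
This note documents the models, their assumptions, the parameters that
matter, and the limits of what the synthetic experiments can show.

## Afferent population model

Four afferent classes innervate the glabrous foot sole: SA1 and SA2
(slowly adapting, sustained response to maintained pressure) and FA1 and
FA2 (fast adapting, responding to pressure change and its derivative).
Full microneurography-fitted firing models are not reproduced here;
instead each unit carries a small, fully stated parametric rate model
driven by the pressure trace `s(t)` directly (the mechanical
skin-deformation stage is deliberately omitted):

* SA1: `g_s [s]+ A(t) + g_d [ds/dt]+`, where the adaptation variable
  `A(t)` decays exponentially towards a floor of 0.3 while the skin is
  loaded (time constant `tau_adapt`, default 0.6 s) and recovers five
  times more slowly while unloaded. The slow recovery makes successive
  stimulus cycles progressively weaker, as real SA responses do.
* SA2: `g_s [s]+` — sustained, low gain, no adaptation.
* FA1: `g_d |ds/dt|` smoothed over 20 ms.
* FA2: `g_d |d^2 s/dt^2|` smoothed over 5 ms.

Rates add a spontaneous term and are clipped to `[0, saturation]`.
Per-class means (gains in spikes/s per pressure unit or its derivatives)
are in `afferent_sim.CLASS_DEFAULTS`; individual units are lognormal
draws around them (sigma 0.2) to reflect response variability. Spikes are
generated as an inhomogeneous Poisson process by thinning with a 1 ms
absolute refractory period. The refractory period biases realised counts
below the rate integral by roughly `rate x 1 ms`; at the default rates
this is a few percent, and the count-vs-integral property is therefore
asserted in the low-rate regime where the bias is far below Monte-Carlo
error.

The design stimulus is a repeating ramp-and-hold pressure cycle (0.15 s
on phase, 0.3 s off phase, rise and fall each 20% of the on phase)
tiling a 2 s window, with additive uniform noise bounded by 0.5% of the
peak amplitude. The on/off figures describe one cycle; the 2 s stimulus
contains repeated cycles.

## Stimulation encoding

The biomimetic chain is: population PSTH (10 ms bins, pooled over units,
in mean spikes/s per afferent) → Gaussian smoothing (30 ms sigma) →
affine map onto a stimulation-frequency range (default 0–100 Hz; zero
rate → `f_min`, the profile maximum → `f_max`) → pulse placement by
time-rescaling. A pulse is emitted each time the running integral of the
frequency profile reaches the next integer, and only levels backed by a
full interval of rate mass are emitted, so the pulse count equals
`floor(∫ f dt)` and a constant profile reduces exactly to a tonic train
starting at t = 0. Amplitude and pulse width stay constant along every
biomimetic train.

Comparison encodings: tonic (constant 50 Hz), Poisson (exponential
inter-pulse intervals, mean 50 Hz, refractory-shifted so the biphasic
pulses cannot overlap while preserving the mean), linear (regular 50 Hz
train whose per-pulse charge follows normalised sensor pressure between
a perceptual-threshold and a maximum-comfort charge), discrete (0.5 s
tonic bursts at contact press/release transients, overlaps merged) and
sinusoidal pulse-width modulation (1 Hz default). All trains are
charge-balanced biphasic, and `validate_charge` flags any pulse above
the 120 nC per-pulse safety limit; the reference 60 µA / 500 µs pulse
carries 30 nC.

## Synthetic recordings

`synthetic_ephys` generates 32-channel recordings at 25 kHz (spinal
linear probe, 100 µm spacing) or 30 kHz (DRG array). A drive is either a
stimulation train (electrical) or a firing-rate profile (natural touch).

Spiking: under electrical drive every pulse recruits each channel's
multi-unit with probability 0.9 at 1.5 ms latency with 0.5 ms jitter, so
channels fire near-synchronously; under natural drive channels are
independent inhomogeneous Poisson processes (per-channel gain spread
15%, 1.5 ms refractory), so activity is asynchronous. Spikes are placed
as ~1 ms biphasic templates with amplitude 6x the background SD.

Evoked LFP: each afferent volley evokes a compound potential — a sharp
~15 ms negative wave carrying the 30–300 Hz content, plus a larger slow
negative sink wave (~60 ms), as in cord potentials. The common
(volume-conducted) component is scaled per channel by a Gaussian depth
profile peaked at the dorsal end of the probe (width 1.5 mm). The peak
of the Gaussian lies on the probe, so the second spatial derivative of
the profile — what CSD analysis measures — contains balanced sinks and
sources summing to approximately zero along the probe; the
shuffled-channel control relies on that balance. A channel-local
component (0.4 of the common gain) driven by each channel's own spikes
decorrelates residual noise across channels. Per-pulse evoked amplitude
depresses over the stimulation run (steady state 0.5, tau 0.1 s, in
absolute time, since trials are delivered back to back) and fluctuates
pulse-to-pulse by 30% — both characteristic of repetitive stimulation,
and the reason a nominally periodic tonic response still has single-trial
content after comb filtering.

The natural drive's LFP is driven by deterministic population volleys
obtained by time-rescaling the touch rate profile (peak volley rate
80 Hz): natural touch synchronises afferents through their common
mechanical input, and this rate-to-event-train dynamic is exactly what a
biomimetic frequency-modulated train reproduces and a constant tonic
train does not. The default natural profile emulates steady-state
rubbing: velocity-driven volleys at each stroke reversal (5.5 reversals
per second) on a sustained floor, with the 0.8 s analysis window aligned
to a stroke — a segment cut from an ongoing robust response rather than
an onset-aligned contact.

Noise: Gaussian background (8 µV SD), powerline at 50/100/150 Hz, slow
drift, and optional large artifacts (recorded in the ground truth).

What the generator does *not* emulate: biophysical volume conduction,
spike-sorting-grade waveform diversity, electrode drift and impedance
changes, behavioural variability of manual rubbing across trials, or
stimulation artifacts. Passing tests demonstrate that the analysis chain
recovers what was constructed; they do not certify performance on real
recordings.

## Analysis pipeline

Preprocessing follows the recording protocol: a comb filter notching
50 Hz and every harmonic (realised as a zero-phase feedback comb run
through its polyphase decomposition into `fs/50` first-order branches,
-3 dB notch width 50/Q with Q = 35), a 3rd-order 30 Hz Butterworth
high-pass for drift, and artifact blanking (samples within 10 ms of any
crossing of 15 robust sigma are zeroed). The robust noise SD is
`median(|x|)/0.6745` — for the stated formula, which omits the division
sign, the package uses the standard reading of the median-absolute-value
estimator. All filters are applied forward-backward so trigger averages
are not skewed in time.

Multi-unit activity is detected in the 800–5000 Hz band by signed
threshold crossing (-3 sigma spinal, -4 sigma DRG; thresholds estimated
on the concatenation of all recordings from a site; 1 ms dead time) and
summarised as PSTHs (fixed 10 ms bins for transmission analysis, 50 ms
for condition comparison, or Freedman–Diaconis widths `2 IQR N^(-1/3)`).
LFP is the 30–300 Hz band. Comparison statistics:

* **Summed normalised activity** — each condition's PSTH normalised to
  [0, 1] by its own maximum, summed, divided by the largest sum; a flat
  (tonic-like) PSTH scores 1 by construction.
* **KL divergence** of LFP amplitude histograms (shared edges over the
  pooled range, 100 bins, 1e-10 regulariser, in nats) of each electrical
  condition against the natural-touch reference, on the twelve most
  active channels (ranked by trigger-averaged peak-to-peak).
* **CSD** along the linear probe: three-point second spatial difference
  with duplicated edges, time-binned by averaging (100 ms electrical,
  40 ms natural — the same bin count for a 2 s and a 0.8 s response) and
  normalised per condition to max |value| = 1.
* **Channel-wise CSD correlation** across time bins, pooled r with
  Fisher-z CI, and a shuffled-channel null (permute the channel order of
  one map, 100 permutations); the control statistic is the magnitude of
  the null's median r.

### A caveat on coarse-binned CSD correlations

The 30 Hz high-pass and the 30–300 Hz band remove essentially all signal
below 30 Hz, while 100 ms/40 ms bin means only retain content below
5/12.5 Hz; the signed binned CSD time courses are therefore dominated by
aliasing residuals of band-edge (30–45 Hz) carrier phase rather than by
response envelopes, and because the two conditions are binned at
different widths no frequency band transfers coherently between them.
Cross-condition per-channel correlations computed this way are
intrinsically near-null — in line with the small published values of this
kind of comparison — and the biomimetic-vs-tonic ordering of their
medians is not a robust statistic of the synthetic experiment. The
shuffled-channel control, the KL ordering and the summed-activity
ordering are robust; the CSD median ordering is reported but should be
interpreted as noise-scale.

## Study statistics

Ratings and task tables use a tie-corrected Kruskal–Wallis omnibus test,
Dunn pairwise post-hoc z-tests with Bonferroni correction, and a Cohen's
f effect size derived from the rank epsilon-squared
(`eps2 = (H - k + 1)/(n - k)`, `f = sqrt(eps2/(1 - eps2))`) — the
post-hoc method and effect-size definition are package choices where the
protocol names none. Normality screening is a one-sample
Kolmogorov–Smirnov test against a standard normal applied to z-scored
data by default (raw-scale data cannot plausibly match N(0,1)), with QQ
points and a histogram summary. Learning effects are Spearman rank
correlations of a metric against session index. Synthetic rating/task
tables matching the study schema are generated around the reported group
levels (biomimetic naturalness median 3 vs linear 1 on the 0–5 VAS;
stairs speed 4.9 laps/session under biomimetic feedback, etc.) so the
whole statistical chain runs without the deposited data.

## Problem sizes

The end-to-end synthetic experiment uses the recording protocol's trial
counts (90 trials per electrical pattern, 15 natural trials) at the
spinal preset (32 channels, 25 kHz), with one extra buffer trial on each
side excluded from analysis; it completes in a few minutes on one CPU.
Unit and property tests use smaller probes (4–16 channels) and trial
counts chosen so the full suite runs in minutes.
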