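# Methods

This note documents the models, parameter choices and numerical
decisions behind `snnhfo`, and what the synthetic-data experiments do
and do not establish.

## Signal model and pre-processing

Recordings are multichannel sampled signals in μV. Analyses run per
bipolar channel (anode − cathode of adjacent contacts, named in the
clinical "AR2-3" style); when no montage is given, adjacent contacts on
the same shaft are paired by name-numeric order — a standard clinical
convention, chosen here as the default because no single montage rule
is universal. All timestamps are seconds from recording start, and all
intervals are half-open `[start, end)`.

Band-limiting uses Butterworth filters in second-order sections:
ripple 80–250 Hz, fast ripple (FR) 250–500 Hz, artifact band
500–900 Hz. The default is order 2 applied once forward (causal),
matching the behavior of second-order analog resonators in a real-time
front end; a zero-phase (forward-backward) mode exists for offline
analyses such as SNR measurement, where phase lag would bias interval
alignment. Intracranial EEG is analyzed in ripple + FR, intraoperative
ECoG in FR only, scalp EEG in ripple plus the artifact band.

## Baseline estimation and spike encoding

The asynchronous delta modulator (ADM) emits an UP (DN) event whenever
the filtered signal rises (falls) by at least δ from a running
reference, which then moves by ±δ (classic tracking semantics — these
give the sup-norm reconstruction bound |x − x̂| ≤ δ at zero
refractory). A shared refractory period blocks both polarities after
any event, as a single-circuit modulator would. The boundary case
"moved by exactly δ" emits an event. One event at most is emitted per
sample; signals may be linearly upsampled by an integer interpolation
factor before encoding.

δ is a fixed fraction of a *baseline amplitude* estimated from the
filtered signal: the signal is cut into 1 s windows, each summarized by
the 99.9th percentile of |x| (≈3.29 σ for Gaussian noise, a sampling-
rate-independent envelope-peak statistic), and the baseline is the
median of the lower half of the window values. Sparse events inflate
only the upper half of the window distribution, so the estimate moves
by <15% even with 5% of the signal occupied by large bursts. The
percentile is deliberately an envelope *peak* rather than a mean: δ
then sits above the bulk of background excursions, so background
produces sparse spike trains while events 2–4× larger encode densely —
the contrast the downstream network thresholds exploit. (A
mean-amplitude statistic ≈1.25 σ was evaluated and rejected: it puts δ
inside the noise bulk and floods the network with background spikes.)

Modality presets (δ fraction of baseline, refractory): iEEG ripple
0.5 / FR 0.3 at 300 μs; ECoG FR 0.5 at 300 μs; scalp ripple 0.3 at
1 ms plus artifact band 0.3 at 300 μs.

## Neuron and synapse model

Neurons are current-based leaky integrate-and-fire units:
τ_m dm/dt = −m + Σ_c I_c + tonic, where each synapse carries a current
that jumps by its weight on a presynaptic spike and decays with its own
τ_syn. On crossing threshold the neuron spikes, resets, and ignores
input for its refractory period (default 1 ms). τ_m defaults to 15 ms.
Weights are dimensionless relative magnitudes (1, 2, 2.5, 3); in these
units the time-averaged current of a synapse driven at rate ν is
w·ν·τ_syn, so a 2-unit synapse at ripple-band inter-spike intervals
(≈3 ms, τ_syn 4.5 ms) sustains ≈3 units.

**Integration.** The per-step update propagates the coupled linear
(currents, membrane) system with its exact analytic solution
(exponential coefficients precomputed per connection), so subthreshold
trajectories are machine-precision regardless of dt; the time step
(default 0.05 ms) only quantizes spike times, refractory windows and
input delivery. Forward Euler was considered and rejected: its O(dt)
error cannot meet a 10⁻⁶ agreement with event-driven integration, while
the exact propagator gets it for free at identical cost. A degenerate
τ_syn = τ_m is handled by the analytic limit (t·e^(−t/τ)). Non-finite
membrane states abort with the offending neuron index.

**Core network.** Per second-layer neuron (default 256), the
excitatory time constant is drawn uniformly from 3–6 ms and the
inhibitory one is shorter by a uniform 0.1–1 ms draw; weight magnitudes
are equiprobably 1 or 2. UP inputs are excitatory, DN inhibitory. The
3–6 ms range makes each neuron a weak detector tuned inside the HFO
band (its count-weighted preferred probe period grows with τ_exc), and
the ensemble covers the spectral variety of real events. Sampling uses
one seed with per-neuron substreams, so draws do not depend on the
layer size.

**Detection thresholds.** The second-layer threshold is the one free
constant of the network; it was calibrated once on synthetic band
noise so that noise-driven activity stays (almost) subthreshold across
the ensemble while oscillations at clinical SNR (2.3–4) fire it, and
then frozen per modality: 6.0 membrane units for the four-train iEEG
map, 2.5 (ECoG) and 2.75 (scalp) for two-train maps. A threshold low
enough that a lone 2-unit synapse at ripple ISI fires the neuron
rejects nothing: band-limited background *is* an oscillation in-band,
and only the amplitude contrast (spike density after δ thresholding)
separates it from events.

**In-band rejection circuit.** Both UP and DN trains excite a
dis-inhibitory neuron (weight 3, τ_syn 5 ms) which inhibits a
global-inhibitory neuron (weight 2.5, τ_syn 20 ms); the
global-inhibitory neuron carries a constant drive solved analytically
to make it fire at 200 Hz in isolation, and inhibits every second-layer
neuron (weight 2.5, τ_syn 5 ms). Sustained oscillations silence the
global inhibition via the dis-inhibitory path and release the layer;
brief sharp transients (~8 ms, ≈2 UP-DN cycles) end before the release
takes effect and stay suppressed. The circuit thresholds are fixed at
9.0 (dis-inhibitory; it must ignore background) and 1.0
(global-inhibitory; it must be easy to silence). The dis-inhibitory
membrane time constant is per-modality (15 ms ECoG, 5 ms scalp):
the release latency should be about one oscillation cycle, and a cycle
corresponds to ~3 ms of ≈2 kHz spiking in the ECoG FR band but ~8 ms of
≈0.9 kHz spiking in the scalp ripple band — no single τ gives
one-cycle latency in both.

**Artifact-detection network.** For scalp EEG a parallel network with
the same sampled parameter ranges is fed by the 500–900 Hz band trains.
Its layer threshold is 9.0: the wide-band, short-refractory artifact
trains are denser than HFO-band trains, and the network must stay
silent on background while responding to high-amplitude artifacts.

## Event marking and rejection

The recording is tiled into consecutive 15 ms windows anchored at
t = 0; any second-layer spike marks its window, and maximal runs of
marked windows merge into one event with boundaries on the window grid.
Fixed tiling (rather than a sliding window) was chosen for determinism;
anchoring is at recording start. Neurons occupying more than half of
all windows are treated as uninformative outliers and removed globally
for the whole recording before marking (the 50% occupancy criterion is
configurable). Artifact-network spikes define 15 ms artifact intervals;
an event of interest intersecting any of them is rejected, the rest
become HFO.

## Clinical statistics

Rates are accepted-HFO counts divided by recording minutes. The three
decision rules: (i) iEEG — channels whose mean rate strictly exceeds
the 95th percentile (linear-interpolation quantile) of the channel-rate
distribution form the HFO area; complete resection of the area predicts
seizure freedom (with all-equal rates, the strict inequality yields an
empty area, trivially "resected"); (ii) ECoG — a maximal post-resection
channel rate ≥ 1 HFO/min predicts seizure recurrence; (iii) scalp — a
median affected-hemisphere rate > 0.25 HFO/min predicts active
epilepsy. Confusion metrics carry exact Clopper–Pearson 95% CIs
computed on each metric's own numerator/denominator; percentages are
displayed rounded half-up, with exact fractions retained. Zero
denominators render as "–". The rate/seizure-frequency relation is fit
by OLS on log₁₀-transformed pairs (zero rates or frequencies are
excluded and counted, since a power law implies positive values) plus
Spearman correlation with average ranks on ties. The
logistic-regression baseline scores 45 ms windows advanced by 35 ms
(10 ms overlap) as the weighted sum of the four trains' mean firing
rates with weights (0.0052, 0.0086, 0.00044, 0.0031) for UP-ripple,
DN-ripple, UP-FR, DN-FR; the intercept (0) and decision point (0.5 on
the logistic) are configurable because no published values exist for
them.

## Synthetic data: what it emulates and what it does not

Backgrounds are white or 1/f ("pink", via spectral shaping of white
Gaussian noise) processes — stationary by construction. HFO are
Tukey-windowed sinusoids with an exact cycle count (flat center keeps
the count well defined); sharp transients are single biphasic pulses
(Hann-windowed single sine cycle, default 8 ms, matching the reported
median transient duration); high-frequency artifacts are windowed
tones in 500–900 Hz. Event amplitude is controlled as the *measured*
in-band SNR: the band-filtered peak-to-peak inside the event over the
mean peak-to-peak of the equal-length flanks. Because filtering is
linear, the generator solves for the event scale against the realized
local background by bisection, so a planted `amplitude_ratio` of 4.0
is recovered by the flank-based measurement to within a few percent.
Study conditions used throughout testing follow the clinical recording
regimes: iEEG 4 kHz with ripple SNR 3.9 / FR SNR 2.3; ECoG 2 kHz with
FR SNR 7.3; scalp 10 kHz with ripple SNR 4.0. Planted artifacts use
in-band SNR 40 — muscle and electrode artifacts are an order of
magnitude above background, and only at such amplitudes does a
>500 Hz tone leak detectably into the ripple band.

What passing tests show: the pipeline detects ≥80% of planted events
at clinical SNR, rejects sharp transients through the dis-inhibitory
circuit, and strictly reduces false detections with the
artifact-detection network enabled. What they do not show: performance
on real EEG. Synthetic backgrounds lack spikes-and-waves, line noise,
movement and electrode artifacts, non-stationarity and physiologic
(non-epileptic) high-frequency activity; planted events are purer in
spectrum and envelope than real HFO. One visible consequence: at these
SNRs the ADM encodes events at refractory saturation, compressing the
within-event inter-spike-interval distribution (Q1 ≈ Q3 ≈ the
refractory/grid floor) relative to the broader 0.5–6.3 ms interquartile
range seen in clinical ripple-band trains.

## Problem sizes and runtime choices

End-to-end experiments use 60 s single-channel recordings at the
modality's clinical sampling rate with 8–16 planted events — enough for
stable hit fractions while keeping each pipeline run in the
ten-second range on one CPU. The simulator's hot loops (ADM encoding
and network integration) are numba-jitted with pure-Python fallbacks.
Statistical checks use the sizes stated with them (10⁵ draws for
sampling means, n = 100 pairs at σ = 0.2 for regression recovery).

## Known limitations

- The baseline estimator and the UP-DN cycle definition (a maximal UP
  run followed by a maximal DN run) are this package's own documented
  choices; the original algorithms were not published in detail.
- Table-level hardware quantities (per-connection "strength" in fA)
  have no software counterpart here; the effective synaptic increment
  ("weight" 1/2/2.5/3) is the single coupling constant per connection.
- Detection operates at a knife's edge by design at FR SNR ≈ 2.3: a
  single fixed threshold cannot separate the tails of noise-driven and
  event-driven drive completely, so a few percent of events are missed
  and occasional noise windows are marked, as reflected in the
  detection-rate figures.
- The ECoG decision threshold is applied as ≥ 1 HFO/min (the reported
  decision-table convention; the accompanying prose uses a strict
  inequality — the difference matters only for a rate of exactly 1).
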