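# snnhfo

Detection of high-frequency oscillations (HFO) in EEG with spiking
neural networks, plus the downstream clinical statistics used in
epilepsy surgery evaluation and therapy monitoring.

Interictal HFO — brief oscillations of at least four cycles in the
80–500 Hz band that clearly stand out of the background — are a
biomarker of epileptogenic tissue. `snnhfo` implements a fully
unsupervised detection pipeline designed around the constraints of
neuromorphic hardware:

1. **Band-pass filtering** (causal order-2 Butterworth) into the ripple
   (80–250 Hz), fast-ripple (FR, 250–500 Hz) and artifact (500–900 Hz)
   bands;
2. **Baseline-adaptive signal-to-spike conversion** by an asynchronous
   delta modulator (ADM): UP/DN events are emitted whenever the
   filtered signal moves by δ from a running reference, with δ set as a
   fraction of an automatically estimated background amplitude and a
   refractory period bounding the event rate;
3. **A two-layer spiking neural network** of current-based
   leaky-integrate-and-fire neurons: the UP/DN trains drive 256 neurons
   whose excitatory synaptic time constants are drawn from 3–6 ms and
   whose inhibitory ones are 0.1–1 ms shorter — an ensemble of weak,
   band-tuned detectors. Optional circuits add in-band rejection of
   sharp transients (a dis-inhibitory neuron that silences a tonically
   active global-inhibitory neuron only during sustained oscillations)
   and a parallel artifact-detection network fed by the >500 Hz band;
4. **Event marking**: any second-layer spike marks its 15 ms window;
   consecutive marked windows merge into one HFO, and events
   overlapping an artifact-network interval are rejected;
5. **Clinical decision rules** on per-channel HFO rates: the "HFO area"
   (channels above the 95th rate percentile) versus the resected area
   for intracranial EEG, the residual-HFO rule (max post-resection rate
   ≥ 1 HFO/min) for intraoperative ECoG, and the median-rate threshold
   (> 0.25 HFO/min over the affected hemisphere) for scalp EEG —
   with confusion metrics and exact Clopper–Pearson 95% confidence
   intervals, rate/seizure-frequency power-law regression, and a
   windowed logistic-regression baseline detector.

A seed-deterministic synthetic-EEG generator (pink/white background
with planted ripples, fast ripples, sharp transients and >500 Hz
artifacts at controlled in-band SNR) makes the whole pipeline testable
without any recordings.

## Worked example

```python
from snnhfo import pipeline, synthetic_data as sd
from snnhfo.clinical_stats import confusion_metrics

# one minute of 4 kHz "depth electrode" EEG with ten planted ripples
spec = sd.SyntheticSpec(
    duration=60, sampling_rate=4000, seed=7,
    event_plan=[sd.EventSpec("ripple_hfo", onset=3 + 5 * i,
                             amplitude_ratio=3.9) for i in range(10)])
rec, truth = sd.generate(spec)

det = pipeline.run_detection(rec, "ieeg", seed=1)
print(det.hfo_events().head(3).to_string(index=False))
print(f"rate: {det.rates['ch0']:.1f} HFO/min")
```

```
channel  start_s  end_s status  n_spikes
    ch0    0.345   0.36    HFO         1
    ch0    3.015   3.06    HFO        28
    ch0    7.395   7.41    HFO         1
rate: 22.0 HFO/min
```

Each row is one detected event: `start_s`/`end_s` are the merged 15 ms
marking windows and `n_spikes` counts the contributing second-layer
spikes. The planted ripples appear as multi-spike events (here the one
at 3.015 s, with 28 contributing spikes); single-spike windows are
noise-driven detections, which inflate the rate above the 10/min
planted density — mirroring the false detections any unsupervised
rate-based detector must tolerate.

Cohort statistics use the same machinery as the clinical decision
rules; for example, an iEEG cohort with one true-positive recurrence
prediction, six true negatives and two false negatives:

```python
print(confusion_metrics(TP=1, TN=6, FP=0, FN=2).render())
```

```
sensitivity: 33 (1 91%)
specificity: 100 (54 100%)
ppv: 100 (3 100%)
npv: 75 (35 97%)
accuracy: 78 (40 97%)
```

i.e. 78% accuracy with a 95% exact binomial CI of 40–97%, and 100%
specificity with CI 54–100%.

The command line mirrors the library: `hfo simulate` (synthetic
recordings), `hfo detect` (run a modality preset over an EDF/CSV
recording), `hfo sweep` (rank ADM parameters against reference marks)
and `hfo report` (cohort confusion metrics). See `hfo --help`.

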