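"""Shared fixtures: synthetic study-condition recordings and pipeline runs.

The end-to-end fixtures are session-scoped because each one runs the
full filter → ADM → SNN → marking chain on a minute-scale recording.
Study conditions follow the clinical recording regimes: iEEG at 4 kHz
with ripple events at SNR 3.9 and fast-ripple events at SNR 2.3; ECoG
at 2 kHz with fast-ripple events at SNR 7.3 plus 8 ms sharp transients;
scalp EEG at 10 kHz with ripple events at SNR 4.0 plus high-frequency
(>500 Hz) artifacts.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from snnhfo import pipeline, synthetic_data as sd


def hit_count(events_df, truth: np.ndarray, pad: float = 0.0) -> int:
    """Number of truth intervals intersected by at least one event."""
    return sum(
        1 for s, e in truth
        if ((events_df["start_s"] < e + pad) & (events_df["end_s"] > s - pad)).any()
    )


@pytest.fixture(scope="session")
def ieeg_run():
    events = [sd.EventSpec("ripple_hfo", onset=3 + i * 5.0, amplitude_ratio=3.9,
                           center_freq=100 + 10 * i, n_cycles=5 + i % 4)
              for i in range(10)]
    events += [sd.EventSpec("fr_hfo", onset=5.5 + i * 10.0, amplitude_ratio=2.3,
                            center_freq=280 + 40 * i, n_cycles=6 + 2 * i)
               for i in range(5)]
    spec = sd.SyntheticSpec(duration=60.0, sampling_rate=4000.0,
                            event_plan=events, seed=7)
    rec, truth = sd.generate(spec)
    det = pipeline.run_detection(rec, "ieeg", seed=1, keep_spike_trains=True)
    return rec, truth, det


@pytest.fixture(scope="session")
def ecog_runs():
    hfo = [sd.EventSpec("fr_hfo", onset=3 + i * 6.0, amplitude_ratio=7.3,
                        center_freq=280 + 20 * (i % 5), n_cycles=7 + i % 4)
           for i in range(8)]
    transients = [sd.EventSpec("sharp_transient", onset=6 + i * 6.0,
                               amplitude_ratio=7.3) for i in range(8)]
    spec = sd.SyntheticSpec(duration=60.0, sampling_rate=2000.0,
                            event_plan=hfo + transients, seed=5)
    rec, truth = sd.generate(spec)
    preset = pipeline.PRESETS["ecog"]
    det_on = pipeline.run_detection(rec, preset, seed=1)
    det_off = pipeline.run_detection(
        rec, replace(preset, architecture="core"), seed=1)
    return rec, truth, det_on, det_off


@pytest.fixture(scope="session")
def scalp_runs():
    hfo = [sd.EventSpec("ripple_hfo", onset=3 + i * 6.0, amplitude_ratio=4.0,
                        center_freq=100 + 15 * (i % 5), n_cycles=6 + i % 4)
           for i in range(8)]
    artifacts = [sd.EventSpec("hf_artifact", onset=6 + i * 6.0,
                              amplitude_ratio=40.0,
                              center_freq=550 + 50 * (i % 4), n_cycles=20)
                 for i in range(8)]
    spec = sd.SyntheticSpec(duration=60.0, sampling_rate=10000.0,
                            event_plan=hfo + artifacts, seed=9)
    rec, truth = sd.generate(spec)
    det_on = pipeline.run_detection(rec, "scalp", seed=1)
    det_off = pipeline.run_detection(rec, "scalp", seed=1,
                                     with_artifact_rejection=False)
    return rec, truth, det_on, det_off
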