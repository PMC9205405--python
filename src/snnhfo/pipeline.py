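"""Configuration-driven orchestration: filter → baseline → ADM → SNN →
events → rates → clinical decision, per modality.

Modality presets (band δ-fractions as fraction of estimated baseline,
refractory):

- iEEG: ripple δ 0.5 + fast-ripple δ 0.3, 300 μs, core SNN, HFO-area rule;
- ECoG: fast-ripple δ 0.5, 300 μs, core + in-band rejection, max-rate
  >= 1 HFO/min rule;
- scalp: ripple δ 0.3, 1 ms + artifact band (>500 Hz) δ 0.3, 300 μs,
  core + in-band rejection + artifact-detection SNN, median-rate
  > 0.25 HFO/min rule.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bandpass, clinical_stats, event_detection, snn_engine, spike_codec
from .bandpass import BandSpec
from .eeg_io import TimeSeriesRecording, ClinicalTable
from .spike_codec import ADMParams, SpikeTrain
from .synthetic_data import GroundTruth

logger = logging.getLogger("snnhfo")

__all__ = ["ModalityPreset", "PRESETS", "DetectionResult", "run_detection",
           "sweep_adm"]


@dataclass(frozen=True)
class ModalityPreset:
    """Everything a modality needs: bands, ADM settings, architecture,
    marking window and decision rule."""

    modality: str
    hfo_bands: tuple[str, ...]          # bands feeding the core SNN
    artifact_band: str | None           # band feeding the artifact SNN
    adm: dict[str, ADMParams]           # per-band ADM parameters
    architecture: str
    window_ms: float = 15.0
    decision_rule: str = "none"
    decision_threshold: float = 0.0
    #: calibrated second-layer detection threshold (membrane units);
    #: scales with the number of input trains driving each neuron
    layer_threshold: float = snn_engine.SECOND_LAYER_THRESHOLD
    #: membrane time constant of the dis-inhibitory neuron; sets how many
    #: oscillation cycles elapse before the in-band circuit releases the
    #: second layer, so it scales with the band's spike density
    dis_tau_mem_ms: float = snn_engine.DIS_TAU_MEM_MS


PRESETS: dict[str, ModalityPreset] = {
    "ieeg": ModalityPreset(
        modality="ieeg",
        hfo_bands=("ripple", "FR"),
        artifact_band=None,
        adm={"ripple": ADMParams(0.5, 300e-6), "FR": ADMParams(0.3, 300e-6)},
        architecture="core",
        decision_rule="hfo_area",
        decision_threshold=95.0,
        layer_threshold=6.0,
    ),
    "ecog": ModalityPreset(
        modality="ecog",
        hfo_bands=("FR",),
        artifact_band=None,
        adm={"FR": ADMParams(0.5, 300e-6)},
        architecture="core+inband",
        decision_rule="max_rate",
        decision_threshold=1.0,
        layer_threshold=2.5,
        dis_tau_mem_ms=15.0,
    ),
    "scalp": ModalityPreset(
        modality="scalp",
        hfo_bands=("ripple",),
        artifact_band="artifact",
        adm={"ripple": ADMParams(0.3, 1e-3), "artifact": ADMParams(0.3, 300e-6)},
        architecture="core+inband+artifact",
        decision_rule="median_rate",
        decision_threshold=0.25,
        layer_threshold=2.75,
        dis_tau_mem_ms=5.0,
    ),
}


@dataclass
class DetectionResult:
    """Everything one run produced."""

    events: pd.DataFrame                 # channel, start_s, end_s, status, n_spikes
    rates: pd.Series                     # channel -> HFO/min
    network: snn_engine.NetworkSpec | None
    prediction: dict | None = None
    spike_trains: dict[str, dict[str, SpikeTrain]] = field(default_factory=dict)

    def hfo_events(self, channel: str | None = None) -> pd.DataFrame:
        df = self.events[self.events["status"] == "HFO"]
        if channel is not None:
            df = df[df["channel"] == channel]
        return df


def _encode_channel(
    x: np.ndarray,
    fs: float,
    band: BandSpec,
    adm: ADMParams,
    channel: str,
) -> SpikeTrain:
    filtered = bandpass.filter_band(
        TimeSeriesRecording(x[None, :], fs, [channel]), band).samples[0]
    baseline = spike_codec.estimate_baseline(filtered, fs)
    if baseline <= 0:
        raise RuntimeError(
            f"zero baseline in band {band.name}, channel {channel}")
    return spike_codec.adm_encode(filtered, fs, adm, baseline,
                                  source_band=band.name, channel=channel)


def _named_inputs(trains: dict[str, SpikeTrain], bands: tuple[str, ...],
                  prefix_map: dict[str, str] | None = None
                  ) -> dict[str, SpikeTrain]:
    """Split per-band trains into the UP/DN-named inputs of a network."""
    out = {}
    for b in bands:
        name = (prefix_map or {}).get(b, b)
        up, dn = trains[b].split_polarity()
        out[f"{name}_UP"] = up
        out[f"{name}_DN"] = dn
    return out


def run_detection(
    recording: TimeSeriesRecording,
    preset: ModalityPreset | str,
    clinical: ClinicalTable | pd.DataFrame | None = None,
    seed: int = 0,
    n_second_layer: int = 256,
    dt_ms: float = 0.05,
    with_artifact_rejection: bool = True,
    keep_spike_trains: bool = False,
) -> DetectionResult:
    """Run the full HFO detection pipeline on every channel.

    One network is sampled from ``seed`` and reused across channels (as
    a single hardware core would be). With ``with_artifact_rejection``
    False, the artifact-detection stage of the scalp preset is ablated
    (all events of interest are accepted as HFO).

    Fully reproducible from (recording, preset, seed).
    """
    if isinstance(preset, str):
        preset = PRESETS[preset.lower()]
    fs = recording.sampling_rate
    minutes = recording.duration / 60.0

    input_map = [f"{b}_{p}" for b in preset.hfo_bands for p in ("UP", "DN")]
    network = snn_engine.build_network(
        preset.architecture, input_map, n_second_layer, seed=seed,
        neuron=snn_engine.NeuronParams(threshold=preset.layer_threshold),
        dis_neuron=snn_engine.NeuronParams(
            tau_mem_ms=preset.dis_tau_mem_ms,
            threshold=snn_engine.DIS_THRESHOLD),
    ) if recording.n_channels else None

    all_events: list[event_detection.HFOEvent] = []
    rates = {}
    trains_by_channel: dict[str, dict[str, SpikeTrain]] = {}
    for ci, channel in enumerate(recording.channel_names):
        t0 = time.perf_counter()
        try:
            trains: dict[str, SpikeTrain] = {}
            for bname in preset.hfo_bands:
                trains[bname] = _encode_channel(
                    recording.samples[ci], fs, bandpass.BANDS[bname],
                    preset.adm[bname], channel)
            inputs = _named_inputs(trains, preset.hfo_bands)
            res = snn_engine.simulate(network, inputs, dt_ms=dt_ms,
                                      span=recording.duration)
            neurons, times = res.population_spikes("second_layer")
            neurons, times, _ = event_detection.suppress_outlier_neurons(
                neurons, times, recording.duration, preset.window_ms)
            eoi = event_detection.mark_events(times, recording.duration,
                                              preset.window_ms, channel)
            if preset.artifact_band and with_artifact_rejection:
                trains[preset.artifact_band] = _encode_channel(
                    recording.samples[ci], fs,
                    bandpass.BANDS[preset.artifact_band],
                    preset.adm[preset.artifact_band], channel)
                art_inputs = _named_inputs(
                    trains, (preset.artifact_band,),
                    {preset.artifact_band: "artifact"})
                art_res = snn_engine.simulate(
                    network.artifact_subnet, art_inputs, dt_ms=dt_ms,
                    span=recording.duration)
                _, art_times = art_res.population_spikes("second_layer")
                events = event_detection.reject_artifacts(
                    eoi, art_times, preset.window_ms)
            else:
                events = [event_detection.HFOEvent(
                    e.channel, e.start, e.end, e.n_contributing_spikes, "HFO")
                    for e in eoi]
        except Exception as exc:
            raise RuntimeError(
                f"detection failed at channel {channel!r} "
                f"({preset.modality} preset): {exc}") from exc
        all_events.extend(events)
        rates[channel] = clinical_stats.hfo_rate(events, minutes)
        if keep_spike_trains:
            trains_by_channel[channel] = trains
        logger.info("channel %s: %d events, %.2f HFO/min (%.1f s)",
                    channel, len(events), rates[channel],
                    time.perf_counter() - t0)

    result = DetectionResult(
        events=event_detection.events_frame(all_events),
        rates=pd.Series(rates, dtype=float, name="rate_per_min"),
        network=network,
        spike_trains=trains_by_channel,
    )
    if clinical is not None and recording.n_channels:
        result.prediction = _apply_decision_rule(result.rates, preset, clinical)
    return result


def _apply_decision_rule(rates: pd.Series, preset: ModalityPreset,
                         clinical: ClinicalTable | pd.DataFrame) -> dict:
    table = clinical.table if isinstance(clinical, ClinicalTable) else clinical
    if preset.decision_rule == "hfo_area":
        area = clinical_stats.hfo_area(rates, preset.decision_threshold)
        resected = set(table.loc[table["resected"] == 1, "channel"])
        outcome = table["outcome"].dropna().iloc[0]
        return {
            "rule": "hfo_area",
            "hfo_area": sorted(area),
            "resected": sorted(resected),
            "label": clinical_stats.predict_outcome_ieeg(area, resected, outcome),
        }
    if preset.decision_rule == "max_rate":
        pred = clinical_stats.predict_outcome_ecog(rates, preset.decision_threshold)
        return {"rule": "max_rate", "max_rate": float(rates.max()),
                "prediction": pred}
    if preset.decision_rule == "median_rate":
        affected = set(table.loc[table["hemisphere"] == "affected", "channel"])
        sel = rates[rates.index.isin(affected)] if affected else rates
        pred = clinical_stats.predict_epilepsy_scalp(sel, preset.decision_threshold)
        return {"rule": "median_rate", "median_rate": float(sel.median()),
                "prediction": pred}
    return {"rule": preset.decision_rule}


def _intersects(ev: tuple[float, float], refs: np.ndarray) -> bool:
    if refs.size == 0:
        return False
    return bool(np.any((refs[:, 0] < ev[1]) & (refs[:, 1] > ev[0])))


def sweep_adm(
    recording: TimeSeriesRecording,
    grid: list[ADMParams],
    reference: GroundTruth | np.ndarray,
    band: str = "ripple",
    architecture: str = "core",
    seed: int = 0,
    n_second_layer: int = 256,
    dt_ms: float = 0.05,
    channel: int = 0,
) -> pd.DataFrame:
    """Rank ADM parameter sets against reference event marks.

    For each grid point the single-band core pipeline runs on one
    channel; detections with any temporal intersection with a reference
    interval count as agreements, the rest as disagreements. Rows are
    ranked lexicographically by (agreements desc, disagreements asc).
    """
    if not grid:
        raise ValueError("empty parameter grid")
    refs = (reference.intervals(channel) if isinstance(reference, GroundTruth)
            else np.atleast_2d(np.asarray(reference, dtype=float)))
    net = snn_engine.build_network(
        architecture, [f"{band}_UP", f"{band}_DN"], n_second_layer, seed=seed)
    fs = recording.sampling_rate
    rows = []
    for params in grid:
        train = _encode_channel(recording.samples[channel], fs,
                                bandpass.BANDS[band], params,
                                recording.channel_names[channel])
        inputs = _named_inputs({band: train}, (band,))
        res = snn_engine.simulate(net, inputs, dt_ms=dt_ms,
                                  span=recording.duration)
        neurons, times = res.population_spikes("second_layer")
        neurons, times, _ = event_detection.suppress_outlier_neurons(
            neurons, times, recording.duration)
        events = event_detection.mark_events(times, recording.duration)
        agree = sum(_intersects((e.start, e.end), refs) for e in events)
        rows.append({
            "threshold_fraction": params.threshold_fraction,
            "refractory_s": params.refractory,
            "interpolation_factor": params.interpolation_factor,
            "agreements": agree,
            "disagreements": len(events) - agree,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["agreements", "disagreements"],
                          ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
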