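"""Annotated synthetic EEG with embedded HFO, transients and artifacts.

Generates multichannel background noise (white or pink/1/f) with planted
events of four kinds:

- ``ripple_hfo``: Tukey-enveloped sinusoid, 80–250 Hz, >= 4 cycles;
- ``fr_hfo``: the same in the fast-ripple band 250–500 Hz;
- ``hf_artifact``: a high-frequency oscillation above the HFO range
  (500–900 Hz), emulating muscle/electrode artifacts in scalp EEG;
- ``sharp_transient``: a single biphasic pulse (default 8 ms total),
  emulating the fast transients seen in intraoperative ECoG.

Event amplitude is controlled through ``amplitude_ratio``, the target
in-band signal-to-noise ratio, defined the way SNR is measured
clinically: the peak-to-peak amplitude of the band-filtered signal
inside the event divided by the mean peak-to-peak of the equal-length
flanking background before and after it. Band filtering is linear, so
the generator can solve for the event scale against the realized local
background exactly; a planted ``amplitude_ratio`` of 4 is recovered by
the flank-based SNR measurement (zero-phase filtering) to within ~15%.

Amplitude units are arbitrary (nominally μV); the downstream pipeline is
scale-invariant because spike-conversion thresholds are relative to the
estimated baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .bandpass import BANDS, BandSpec, zero_phase, design_sos
from .eeg_io import TimeSeriesRecording

__all__ = [
    "EventSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "hfo_template",
    "transient_template",
]

#: Admissible centre-frequency range (Hz) per event kind.
KIND_BANDS = {
    "ripple_hfo": (80.0, 250.0),
    "fr_hfo": (250.0, 500.0),
    "hf_artifact": (500.0, 900.0),
}

#: Band used to calibrate each kind's in-band amplitude.
_CALIBRATION_BAND = {
    "ripple_hfo": "ripple",
    "fr_hfo": "FR",
    "hf_artifact": "artifact",
    "sharp_transient": "FR",  # transients matter where they mimic fast ripples
}


@dataclass
class EventSpec:
    """One planted event.

    amplitude_ratio is the in-band SNR control (see module docstring);
    for HFO kinds n_cycles >= 4; sharp transients are non-oscillatory
    pulses of duration <= 10 ms (duration_s, default 8 ms).
    """

    kind: str
    onset: float
    n_cycles: int = 6
    center_freq: float = 120.0
    amplitude_ratio: float = 4.0
    channel: int = 0
    duration_s: float = 0.008  # used by sharp_transient only

    def validate(self) -> None:
        if self.kind == "sharp_transient":
            if self.duration_s > 0.010:
                raise ValueError(
                    f"sharp_transient at onset {self.onset}s: duration "
                    f"{self.duration_s * 1e3:.1f} ms exceeds 10 ms"
                )
            return
        if self.kind not in KIND_BANDS:
            raise ValueError(f"unknown event kind {self.kind!r} at onset {self.onset}s")
        lo, hi = KIND_BANDS[self.kind]
        if not (lo <= self.center_freq <= hi):
            raise ValueError(
                f"{self.kind} at onset {self.onset}s: center_freq "
                f"{self.center_freq} Hz outside [{lo}, {hi}] Hz"
            )
        if self.kind in ("ripple_hfo", "fr_hfo") and self.n_cycles < 4:
            raise ValueError(
                f"{self.kind} at onset {self.onset}s: n_cycles "
                f"{self.n_cycles} < 4 (an HFO needs at least four cycles)"
            )

    @property
    def duration(self) -> float:
        if self.kind == "sharp_transient":
            return self.duration_s
        return self.n_cycles / self.center_freq


@dataclass
class SyntheticSpec:
    """Full description of a synthetic recording; seed-deterministic."""

    duration: float = 60.0
    sampling_rate: float = 2000.0
    n_channels: int = 1
    background_model: str = "pink"  # "white" | "pink"
    background_amplitude: float = 10.0  # RMS of the broadband noise, μV
    event_plan: list[EventSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate < 2000:
            raise ValueError("sampling_rate must be >= 2000 Hz to resolve "
                             "500 Hz content with margin")
        if self.background_model not in ("white", "pink"):
            raise ValueError(f"unknown background model {self.background_model!r}")
        for ev in self.event_plan:
            ev.validate()
            if not (0 <= ev.onset and ev.onset + ev.duration <= self.duration):
                raise ValueError(
                    f"event {ev.kind} at onset {ev.onset}s does not fit in "
                    f"the {self.duration}s recording"
                )
            if not (0 <= ev.channel < self.n_channels):
                raise ValueError(f"event channel {ev.channel} out of range")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["event_plan"] = [EventSpec(**e) for e in d.get("event_plan", [])]
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-channel annotated intervals, sorted by start; half-open [start, end)."""

    events: pd.DataFrame  # columns: channel, kind, start_s, end_s

    COLUMNS = ("channel", "kind", "start_s", "end_s")

    def __post_init__(self) -> None:
        if self.events.empty:
            self.events = pd.DataFrame(columns=list(self.COLUMNS))
        self.events = self.events.sort_values(
            ["channel", "start_s"]).reset_index(drop=True)

    def intervals(self, channel: int | str | None = None,
                  kinds: tuple[str, ...] | None = None) -> np.ndarray:
        """(n, 2) array of [start, end) intervals, optionally filtered."""
        df = self.events
        if channel is not None:
            df = df[df["channel"] == channel]
        if kinds is not None:
            df = df[df["kind"].isin(kinds)]
        return df[["start_s", "end_s"]].to_numpy(dtype=float)

    def write_tsv(self, path: str | Path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def hfo_template(center_freq: float, n_cycles: int, sampling_rate: float,
                 amplitude: float = 1.0, alpha: float = 0.5) -> np.ndarray:
    """Tukey-enveloped sinusoid with exactly ``n_cycles`` periods.

    The Tukey window (flat centre, default taper fraction 0.5) keeps the
    cycle count well defined while avoiding hard onset edges.
    """
    n = int(round(n_cycles / center_freq * sampling_rate))
    t = np.arange(n) / sampling_rate
    return amplitude * sps.windows.tukey(n, alpha) * np.sin(
        2 * np.pi * center_freq * t)


def transient_template(duration_s: float, sampling_rate: float,
                       amplitude: float = 1.0) -> np.ndarray:
    """Single biphasic pulse: one Hann-windowed sine cycle of given width."""
    n = max(int(round(duration_s * sampling_rate)), 4)
    t = np.arange(n) / n
    return amplitude * np.hanning(n) * np.sin(2 * np.pi * t)


def _event_template(ev: EventSpec, fs: float) -> np.ndarray:
    if ev.kind == "sharp_transient":
        return transient_template(ev.duration_s, fs)
    return hfo_template(ev.center_freq, ev.n_cycles, fs)


# ---------------------------------------------------------------------------
# Background noise
# ---------------------------------------------------------------------------

def _background(model: str, rms: float, n_channels: int, n_samples: int,
                rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal((n_channels, n_samples))
    if model == "white":
        x = white
    else:  # pink: spectral 1/f power shaping of white Gaussian noise
        spec = np.fft.rfft(white, axis=1)
        f = np.fft.rfftfreq(n_samples)
        shaping = np.ones_like(f)
        shaping[1:] = f[1:] ** -0.5
        spec *= shaping
        spec[:, 0] = 0.0
        x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= rms / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


def _solve_event_scale(bg_win: np.ndarray, tmpl_band: np.ndarray,
                       target_p2p: float) -> float:
    """Scale s such that ptp(bg_win + s·tmpl_band) == target_p2p.

    ptp is non-decreasing in s once the template dominates; bisection on
    a bracket, with a linear fallback when the background alone already
    reaches the target.
    """
    tmpl_p2p = float(np.ptp(tmpl_band))
    if tmpl_p2p <= 0:
        raise ValueError("degenerate (flat) event template")

    def f(s: float) -> float:
        return float(np.ptp(bg_win + s * tmpl_band)) - target_p2p

    if f(0.0) >= 0:
        return max(target_p2p - float(np.ptp(bg_win)), 0.0) / tmpl_p2p
    hi = 2.0 * (target_p2p + float(np.ptp(bg_win))) / tmpl_p2p
    while f(hi) < 0:
        hi *= 2.0
    lo = 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate(spec: SyntheticSpec) -> tuple[TimeSeriesRecording, GroundTruth]:
    """Generate the recording and its annotations.

    Deterministic: identical spec and seed give bit-identical output.
    Each event is scaled so that the flank-based in-band SNR of the
    composite signal equals ``amplitude_ratio`` (see module docstring).
    """
    spec.validate()
    fs = spec.sampling_rate
    n_samples = int(round(spec.duration * fs))
    rng = np.random.default_rng(spec.seed)
    x = _background(spec.background_model, spec.background_amplitude,
                    spec.n_channels, n_samples, rng)
    background = x.copy()  # calibration always against the event-free noise

    band_filtered: dict[tuple[int, str], np.ndarray] = {}

    rows = []
    for ev in spec.event_plan:
        band = BANDS[_CALIBRATION_BAND[ev.kind]]
        template = _event_template(ev, fs)
        win = template.size
        key = (ev.channel, band.name)
        if key not in band_filtered:
            sos = design_sos(zero_phase(band), fs)
            band_filtered[key] = sps.sosfiltfilt(sos, background[ev.channel])
        bg_band = band_filtered[key]

        i0 = int(round(ev.onset * fs))
        # realized flank amplitude defines the SNR denominator
        lo, hi = max(i0 - win, 0), min(i0 + 2 * win, n_samples)
        flanks = []
        if i0 - lo > 0:
            flanks.append(np.ptp(bg_band[lo:i0]))
        if hi - (i0 + win) > 0:
            flanks.append(np.ptp(bg_band[i0 + win : hi]))
        denom = float(np.mean(flanks))

        # in-band response of the unit template, aligned to the window
        sos = design_sos(zero_phase(band), fs)
        pad = int(0.05 * fs)
        padded = np.concatenate([np.zeros(pad), template, np.zeros(pad)])
        tmpl_band = sps.sosfiltfilt(sos, padded)[pad : pad + win]

        scale = _solve_event_scale(bg_band[i0 : i0 + win], tmpl_band,
                                   ev.amplitude_ratio * denom)
        x[ev.channel, i0 : i0 + win] += scale * template
        rows.append({
            "channel": ev.channel,
            "kind": ev.kind,
            "start_s": i0 / fs,
            "end_s": (i0 + win) / fs,
        })

    rec = TimeSeriesRecording(
        samples=x,
        sampling_rate=fs,
        channel_names=[f"ch{i}" for i in range(spec.n_channels)],
    )
    return rec, GroundTruth(pd.DataFrame(rows, columns=list(GroundTruth.COLUMNS)))
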