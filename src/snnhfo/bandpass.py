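"""Band-limiting of recordings to ripple, fast-ripple and artifact bands.

Butterworth filters applied in second-order sections. The default is
order 2 applied once forward (causal), mimicking the second-order analog
resonators of a real-time front end; forward-backward (zero-phase)
application is available for offline analysis parity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .eeg_io import TimeSeriesRecording

__all__ = ["BandSpec", "RIPPLE", "FR", "ARTIFACT", "BANDS", "filter_band",
           "modality_bands"]


@dataclass(frozen=True)
class BandSpec:
    """A band-pass specification.

    name: band identifier (ripple, FR, artifact);
    low/high: corner frequencies in Hz; order: Butterworth order;
    causal: apply once forward if True, forward-backward otherwise.
    """

    name: str
    low: float
    high: float
    order: int = 2
    causal: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"need 0 < low < high, got ({self.low}, {self.high})")
        if self.order < 1:
            raise ValueError("order must be >= 1")


RIPPLE = BandSpec("ripple", 80.0, 250.0)
FR = BandSpec("FR", 250.0, 500.0)
ARTIFACT = BandSpec("artifact", 500.0, 900.0)
BANDS = {b.name: b for b in (RIPPLE, FR, ARTIFACT)}

#: Analysis bands per recording modality: intracranial EEG uses ripple and
#: fast-ripple; intraoperative ECoG the fast-ripple band only; scalp EEG the
#: ripple band plus the >500 Hz band for artifact detection.
_MODALITY_BANDS = {
    "ieeg": ("ripple", "FR"),
    "ecog": ("FR",),
    "scalp": ("ripple", "artifact"),
}


def modality_bands(modality: str) -> list[BandSpec]:
    try:
        names = _MODALITY_BANDS[modality.lower()]
    except KeyError:
        raise ValueError(f"unknown modality {modality!r}") from None
    return [BANDS[n] for n in names]


def design_sos(band: BandSpec, sampling_rate: float) -> np.ndarray:
    """Second-order sections for the band at the given sampling rate."""
    nyq = sampling_rate / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name} high corner {band.high} Hz >= Nyquist {nyq} Hz"
        )
    return signal.butter(band.order, [band.low, band.high],
                         btype="bandpass", fs=sampling_rate, output="sos")


def filter_band(rec: TimeSeriesRecording, band: BandSpec) -> TimeSeriesRecording:
    """Band-pass every channel of a recording.

    Causal mode filters once forward (phase lag as in a real-time analog
    chain); non-causal mode uses ``sosfiltfilt`` for zero phase.
    """
    sos = design_sos(band, rec.sampling_rate)
    if band.causal:
        out = signal.sosfilt(sos, rec.samples, axis=1)
    else:
        out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return TimeSeriesRecording(
        samples=np.asarray(out),
        sampling_rate=rec.sampling_rate,
        channel_names=list(rec.channel_names),
    )


def band_gain(band: BandSpec, freq: float, sampling_rate: float) -> float:
    """Magnitude response of the digital filter at ``freq`` Hz."""
    sos = design_sos(band, sampling_rate)
    _, h = signal.sosfreqz(sos, worN=[freq], fs=sampling_rate)
    g = float(np.abs(h[0]))
    return g * g if not band.causal else g  # filtfilt squares the magnitude


def zero_phase(band: BandSpec) -> BandSpec:
    return replace(band, causal=False)
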