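"""Recording I/O, bipolar montage construction, and clinical side-information.

Amplitudes are carried in microvolts (μV) throughout. All timestamps are
seconds from recording start; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TimeSeriesRecording",
    "ClinicalTable",
    "read_recording",
    "write_recording",
    "make_bipolar",
    "default_bipolar_pairs",
]


@dataclass
class TimeSeriesRecording:
    """Multichannel sampled signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in μV.
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    channel_names : list of str
        One name per channel, order preserved.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n_samples / sampling_rate)."""
        return self.samples.shape[1] / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.samples[idx]


@dataclass
class ClinicalTable:
    """Per-patient / per-channel clinical side information.

    Wraps a DataFrame with columns: patient_id, channel, modality
    (iEEG | ECoG | scalp), resected (0/1), hemisphere (affected |
    non-affected), phase (pre | post), outcome (seizure_free | recurrence),
    seizure_freq_per_month.
    """

    table: pd.DataFrame

    COLUMNS = (
        "patient_id",
        "channel",
        "modality",
        "resected",
        "hemisphere",
        "phase",
        "outcome",
        "seizure_freq_per_month",
    )

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.table.columns:
                self.table[col] = np.nan
        freq = pd.to_numeric(self.table["seizure_freq_per_month"], errors="coerce")
        if (freq.dropna() < 0).any():
            raise ValueError("seizure_freq_per_month must be >= 0")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ClinicalTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def patient(self, patient_id: str) -> pd.DataFrame:
        return self.table[self.table["patient_id"] == patient_id]


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path: Path, sampling_rate: float | None) -> TimeSeriesRecording:
    if sampling_rate is None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh)
            sampling_rate = float(meta["sampling_rate"])
        else:
            raise ValueError(
                f"sampling rate for {path} not given and no sidecar "
                f"{sidecar.name} found"
            )
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError(f"ragged or missing samples in {path}")
    return TimeSeriesRecording(
        samples=df.to_numpy().T,
        sampling_rate=sampling_rate,
        channel_names=[str(c) for c in df.columns],
    )


def _write_csv(rec: TimeSeriesRecording, path: Path) -> None:
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_names)
    df.to_csv(path, index=False)
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump({"sampling_rate": float(rec.sampling_rate)}, fh)


# ---------------------------------------------------------------------------
# EDF. Reading goes through MNE; writing is a minimal standard-EDF
# (16-bit integer, one data record per second) encoder, since no EDF
# writer library is available.
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: TimeSeriesRecording, path: str | Path) -> None:
    """Write a standard 16-bit EDF file (physical dimension "uV").

    The sampling rate must be a positive integer (one data record per
    second). Amplitudes are quantized to the int16 range over each
    channel's physical min/max.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = int(np.ceil(rec.n_samples / fs))
    nchan = rec.n_channels
    # pad to whole records with zeros
    padded = np.zeros((nchan, n_rec * fs))
    padded[:, : rec.n_samples] = rec.samples

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    # avoid zero span on constant channels
    span = np.where(phys_max - phys_min < 1e-12, 1.0, phys_max - phys_min)
    phys_max = phys_min + span
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _edf_field("0", 8),  # version
            _edf_field("X X X X", 80),  # patient id
            _edf_field("Startdate X", 80),  # recording id
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (nchan + 1)), 8),
            _edf_field("", 44),
            _edf_field(str(n_rec), 8),
            _edf_field("1", 8),  # record duration, s
            _edf_field(str(nchan), 4),
        ]
    )
    labels = b"".join(_edf_field(n, 16) for n in rec.channel_names)
    transducer = b"".join(_edf_field("", 80) for _ in range(nchan))
    dim = b"".join(_edf_field("uV", 8) for _ in range(nchan))
    pmin = b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_min)
    pmax = b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_max)
    dmin = b"".join(_edf_field(str(dig_min), 8) for _ in range(nchan))
    dmax = b"".join(_edf_field(str(dig_max), 8) for _ in range(nchan))
    prefilter = b"".join(_edf_field("", 80) for _ in range(nchan))
    nsamp = b"".join(_edf_field(str(fs), 8) for _ in range(nchan))
    reserved = b"".join(_edf_field("", 32) for _ in range(nchan))

    gains = (dig_max - dig_min) / span
    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + pmin + pmax + dmin
                 + dmax + prefilter + nsamp + reserved)
        for r in range(n_rec):
            for c in range(nchan):
                seg = padded[c, r * fs : (r + 1) * fs]
                dig = np.round((seg - phys_min[c]) * gains[c]) + dig_min
                fh.write(struct.pack(f"<{fs}h", *dig.astype(np.int16)))


def _read_edf(path: Path) -> TimeSeriesRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return TimeSeriesRecording(
        samples=raw.get_data() * 1e6,  # MNE returns volts
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    sampling_rate: float | None = None,
) -> TimeSeriesRecording:
    """Read a recording from EDF or CSV.

    CSV files need the sampling rate, either as an argument or from a
    ``<file>.csv.yaml`` sidecar with a ``sampling_rate`` key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").upper()
    format = format.upper()
    if format == "EDF":
        return _read_edf(path)
    if format == "CSV":
        return _read_csv(path, sampling_rate)
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(rec: TimeSeriesRecording, path: str | Path,
                    format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").upper()
    format = format.upper()
    if format == "EDF":
        write_edf(rec, path)
    elif format == "CSV":
        _write_csv(rec, path)
    else:
        raise ValueError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# Bipolar montage
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def bipolar_name(anode: str, cathode: str) -> str:
    """Clinical-style bipolar channel name: ("AR2", "AR3") -> "AR2-3"."""
    ma, mc = _NAME_RE.match(anode), _NAME_RE.match(cathode)
    if ma and mc and ma.group(1) == mc.group(1):
        return f"{anode}-{mc.group(2)}"
    return f"{anode}-{cathode}"


def default_bipolar_pairs(channel_names: list[str]) -> list[tuple[str, str]]:
    """Adjacent-contact pairs on each shaft/strip by numeric order.

    Channels named ``<letters><number>`` are grouped by their letter prefix
    and paired (n, n+1) within each group; unmatched names are skipped.
    """
    groups: dict[str, list[tuple[int, str]]] = {}
    for name in channel_names:
        m = _NAME_RE.match(name)
        if m:
            groups.setdefault(m.group(1), []).append((int(m.group(2)), name))
    pairs = []
    for _, members in groups.items():
        members.sort()
        for (na, a), (nc, c) in zip(members, members[1:]):
            if nc == na + 1:
                pairs.append((a, c))
    return pairs


def make_bipolar(
    rec: TimeSeriesRecording,
    pairs: list[tuple[str, str]] | None = None,
) -> TimeSeriesRecording:
    """Construct bipolar channels (anode − cathode).

    With no explicit pair list, adjacent contacts on the same shaft are
    paired by name-numeric order.
    """
    if pairs is None:
        pairs = default_bipolar_pairs(rec.channel_names)
    out, names = [], []
    for anode, cathode in pairs:
        for name in (anode, cathode):
            if name not in rec.channel_names:
                raise KeyError(f"missing electrode {name!r} for bipolar pair")
        out.append(rec.channel(anode) - rec.channel(cathode))
        names.append(bipolar_name(anode, cathode))
    return TimeSeriesRecording(
        samples=np.array(out) if out else np.empty((0, rec.n_samples)),
        sampling_rate=rec.sampling_rate,
        channel_names=names,
    )
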