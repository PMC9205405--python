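"""Clinical decision rules and statistics on detected HFO.

Per-channel HFO rates feed three modality-specific decision rules:

- iEEG: channels whose rate strictly exceeds the 95th percentile of the
  per-channel rate distribution form the "HFO area"; full resection of
  the HFO area predicts seizure freedom, otherwise seizure recurrence.
- ECoG: a maximal post-resection channel rate >= 1 HFO/min ("residual
  HFO") predicts seizure recurrence.
- scalp EEG: a median rate > 0.25 HFO/min over affected-hemisphere
  channels predicts active epilepsy (>= 1 seizure/month).

Confusion metrics carry exact (Clopper–Pearson) 95% binomial confidence
intervals on each metric's own numerator/denominator. The scalp HFO
rate is additionally related to seizure frequency by ordinary least
squares on log10-transformed pairs and by Spearman correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.proportion import proportion_confint

from .event_detection import HFOEvent

__all__ = [
    "RateTable",
    "ConfusionSummary",
    "hfo_rate",
    "hfo_area",
    "predict_outcome_ieeg",
    "predict_outcome_ecog",
    "predict_epilepsy_scalp",
    "confusion_metrics",
    "rate_seizure_regression",
    "snr",
    "lr_baseline_score",
    "LR_WEIGHTS",
]

#: Logistic-regression feature weights for the four spike-train firing
#: rates, in train order (UP ripple, DN ripple, UP FR, DN FR).
LR_WEIGHTS = (0.0052, 0.0086, 0.00044, 0.0031)

ECOG_RATE_THRESHOLD = 1.0      # HFO/min, residual-HFO rule
SCALP_RATE_THRESHOLD = 0.25    # HFO/min, active-epilepsy rule
HFO_AREA_PERCENTILE = 95.0


@dataclass
class RateTable:
    """Per (patient, channel) HFO rates; rate = count / minutes."""

    table: pd.DataFrame  # columns: patient_id, channel, rate_per_min,
    #                      minutes, modality

    def per_patient_channel_means(self, patient_id: str) -> pd.Series:
        """Mean rate per channel across a patient's recordings."""
        df = self.table[self.table["patient_id"] == patient_id]
        return df.groupby("channel")["rate_per_min"].mean()

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def hfo_rate(events: list[HFOEvent], minutes: float) -> float:
    """HFO per minute: count of status=HFO events over recording minutes."""
    if minutes <= 0:
        raise ValueError("recording duration must be positive")
    return sum(1 for e in events if e.status == "HFO") / minutes


def hfo_area(rates: dict[str, float] | pd.Series,
             percentile: float = HFO_AREA_PERCENTILE) -> set[str]:
    """Channels whose rate strictly exceeds the rate-distribution percentile.

    With all-equal rates the strict inequality yields an empty area.
    Percentiles interpolate linearly between order statistics.
    """
    s = pd.Series(rates, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 channels for an HFO area")
    cut = np.percentile(s.to_numpy(), percentile)
    return set(s.index[s > cut])


def _label(predicted_recurrence: bool, recurred: bool) -> str:
    if predicted_recurrence:
        return "TP" if recurred else "FP"
    return "FN" if recurred else "TN"


def predict_outcome_ieeg(area: set[str], resected: set[str],
                         outcome: str) -> str:
    """Label a patient TP/TN/FP/FN under the HFO-area resection rule.

    HFO area fully resected predicts seizure freedom; any unresected
    HFO-area channel predicts recurrence. ``outcome`` is
    "seizure_free" or "recurrence".
    """
    if outcome not in ("seizure_free", "recurrence"):
        raise ValueError(f"unknown outcome {outcome!r}")
    predicted_recurrence = not area <= resected
    return _label(predicted_recurrence, outcome == "recurrence")


def predict_outcome_ecog(post_rates: dict[str, float] | pd.Series,
                         threshold: float = ECOG_RATE_THRESHOLD) -> str:
    """Residual-HFO rule: max post-resection rate >= threshold predicts
    seizure recurrence, else seizure freedom."""
    s = pd.Series(post_rates, dtype=float)
    if s.empty:
        raise ValueError("empty post-resection rate table")
    return "recurrence" if s.max() >= threshold else "seizure_free"


def predict_epilepsy_scalp(affected_rates: dict[str, float] | pd.Series,
                           threshold: float = SCALP_RATE_THRESHOLD) -> str:
    """Median affected-hemisphere rate > threshold predicts active epilepsy."""
    s = pd.Series(affected_rates, dtype=float)
    if s.empty:
        raise ValueError("no affected-hemisphere channels")
    return "active_epilepsy" if s.median() > threshold else "seizure_free"


def clopper_pearson(x: int, n: int, alpha: float = 0.05
                    ) -> tuple[float, float]:
    """Exact two-sided binomial CI as (lower, upper) proportions."""
    return proportion_confint(x, n, alpha=alpha, method="beta")


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


@dataclass
class ConfusionSummary:
    """Counts plus derived metrics, each with an exact 95% CI.

    metrics maps name -> (point %, ci_low %, ci_high %) or None where
    the denominator is zero (rendered "–" in reports). Display values
    round half-up to integer percent; exact fractions are retained in
    ``fractions`` as (numerator, denominator).
    """

    TP: int
    TN: int
    FP: int
    FN: int
    metrics: dict[str, tuple[float, float, float] | None]
    fractions: dict[str, tuple[int, int]]

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def rounded(self) -> dict[str, tuple[int, int, int] | None]:
        return {
            k: None if v is None else tuple(_round_half_up(x) for x in v)
            for k, v in self.metrics.items()
        }

    def render(self) -> str:
        lines = []
        for k, v in self.rounded().items():
            lines.append(f"{k}: –" if v is None
                         else f"{k}: {v[0]} ({v[1]} {v[2]}%)")
        return "\n".join(lines)


def confusion_metrics(TP: int, TN: int, FP: int, FN: int) -> ConfusionSummary:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs."""
    for v in (TP, TN, FP, FN):
        if v < 0:
            raise ValueError("counts must be non-negative")
    N = TP + TN + FP + FN
    if N < 1:
        raise ValueError("need at least one case")
    fractions = {
        "sensitivity": (TP, TP + FN),
        "specificity": (TN, TN + FP),
        "ppv": (TP, TP + FP),
        "npv": (TN, TN + FN),
        "accuracy": (TP + TN, N),
    }
    metrics: dict[str, tuple[float, float, float] | None] = {}
    for name, (num, den) in fractions.items():
        if den == 0:
            metrics[name] = None
            continue
        lo, hi = clopper_pearson(num, den)
        metrics[name] = (100 * num / den, 100 * lo, 100 * hi)
    return ConfusionSummary(TP, TN, FP, FN, metrics, fractions)


def rate_seizure_regression(
    rates_per_min: np.ndarray,
    seizures_per_month: np.ndarray,
) -> dict[str, float]:
    """Power-law fit of seizure frequency on HFO rate.

    OLS on log10-transformed pairs (zeros excluded and counted) plus
    Spearman correlation on the raw pairs (average ranks on ties).
    Returns slope, intercept, r_squared, spearman_rho, spearman_p,
    n_used, n_excluded.
    """
    x = np.asarray(rates_per_min, dtype=float)
    y = np.asarray(seizures_per_month, dtype=float)
    if x.size != y.size:
        raise ValueError("rate and seizure arrays differ in length")
    usable = (x > 0) & (y > 0)
    if usable.sum() < 3:
        raise ValueError("need >= 3 strictly positive pairs for the log-log fit")
    lr = sstats.linregress(np.log10(x[usable]), np.log10(y[usable]))
    rho, p = sstats.spearmanr(x, y)
    return {
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "r_squared": float(lr.rvalue**2),
        "spearman_rho": float(rho),
        "spearman_p": float(p),
        "n_used": int(usable.sum()),
        "n_excluded": int((~usable).sum()),
    }


def snr(signal: np.ndarray, sampling_rate: float,
        intervals: np.ndarray) -> np.ndarray:
    """In-band SNR per event interval.

    Peak-to-peak amplitude inside [start, end) divided by the mean
    peak-to-peak of the equal-length flanking segments before and after
    the event. Flanks that would extend beyond the recording are
    shrunk, with a warning.
    """
    x = np.asarray(signal, dtype=float)
    out = []
    for start, end in np.atleast_2d(np.asarray(intervals, dtype=float)):
        i0, i1 = int(round(start * sampling_rate)), int(round(end * sampling_rate))
        if i1 <= i0:
            raise ValueError("empty event interval")
        length = i1 - i0
        lo = max(i0 - length, 0)
        hi = min(i1 + length, x.size)
        if lo > i0 - length or hi < i1 + length:
            warnings.warn("flank shrunk at recording edge")
        flanks = []
        if i0 - lo > 0:
            flanks.append(np.ptp(x[lo:i0]))
        if hi - i1 > 0:
            flanks.append(np.ptp(x[i1:hi]))
        if not flanks:
            raise ValueError("no flanking context for SNR")
        out.append(np.ptp(x[i0:i1]) / np.mean(flanks))
    return np.asarray(out)


def lr_baseline_score(
    trains: list[np.ndarray],
    duration: float,
    window_s: float = 0.045,
    overlap_s: float = 0.010,
    weights: tuple[float, ...] = LR_WEIGHTS,
    threshold: float = 0.5,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Windowed logistic-regression baseline score.

    Features are the mean firing rates (spikes/s) of the four trains
    (UP ripple, DN ripple, UP FR, DN FR) in 45 ms windows advanced by
    35 ms (10 ms overlap); the score is their weighted sum. Labels
    threshold the logistic of (score + intercept); the intercept
    defaults to 0 and the decision point to 0.5.
    """
    if len(trains) != len(weights):
        raise ValueError(f"expected {len(weights)} spike trains")
    if window_s > duration:
        raise ValueError("window longer than recording")
    step = window_s - overlap_s
    starts = np.arange(0, duration - window_s + 1e-12, step)
    rates = np.zeros((starts.size, len(trains)))
    for k, t in enumerate(trains):
        t = np.asarray(t, dtype=float)
        for i, s in enumerate(starts):
            rates[i, k] = np.count_nonzero((t >= s) & (t < s + window_s)) / window_s
    score = rates @ np.asarray(weights)
    prob = 1.0 / (1.0 + np.exp(-(score + intercept)))
    return pd.DataFrame({
        "start_s": starts,
        "end_s": starts + window_s,
        "score": score,
        "label": prob > threshold,
    })
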