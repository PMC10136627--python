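"""ERP preprocessing chain.

The chain is fixed: band-pass filter -> epoch & baseline-correct ->
amplitude-threshold rejection -> average reference -> resample ->
per-condition trial averaging. Each stage is a pure function on the
:class:`EpochedData` container; :func:`preprocess_participant` composes
them and records per-stage counts.

Artifact handling is deliberately simple: the amplitude threshold is a
stand-in for the manual ICA/visual-inspection cleaning used on real
recordings, not an equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

from msconn.config import CONDITIONS, PreprocessConfig


def times_for_window(window: tuple[float, float], sampling_rate: float) -> np.ndarray:
    """Sample times (ms) for a half-open epoch window [start, end).

    Sample 0 of the post-baseline part falls exactly on 0 ms (stimulus
    onset) when the window start is an integer number of samples.
    """
    start, end = window
    step = 1000.0 / sampling_rate
    n = int(round((end - start) / step))
    return start + step * np.arange(n)


@dataclass
class EpochedData:
    """Per-participant epoched potentials: trials x channels x samples (µV)."""

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray  # ms, uniform spacing 1000/sampling_rate
    conditions: np.ndarray  # condition label per trial
    participant_id: str = "p0"
    group: str = "control"
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, _, n_samples = self.data.shape
        if len(self.conditions) != n_trials:
            raise ValueError("one condition label per trial required")
        if len(self.times) != n_samples:
            raise ValueError("times length must match the sample axis")
        if n_samples >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1000.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniform at 1000/sampling_rate ms")
        if self.trial_ids is None:
            self.trial_ids = np.arange(n_trials)
        else:
            self.trial_ids = np.asarray(self.trial_ids)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class ERP:
    """Condition-wise trial average: channels x samples (µV)."""

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray
    condition: str
    participant_id: str = "p0"
    group: str = "control"
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ERP data must be channels x samples")


@dataclass
class RejectionLog:
    threshold: float
    rejected_trial_ids: list = field(default_factory=list)
    n_in: int = 0
    n_out: int = 0


def bandpass_filter(
    data: np.ndarray, sampling_rate: float, low: float, high: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last (time) axis.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective
    order but introduces no phase distortion, so ERP component latencies
    are preserved.

    When the data span fewer than two cycles of the low edge (e.g. a
    0.1 Hz edge on a 5 s epoch), an IIR high-pass is numerically
    meaningless — its transient dwarfs the signal — so the high-pass is
    replaced by linear detrending and only the low-pass is applied.
    """
    data = np.asarray(data, dtype=float)
    nyq = sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq})")
    n = data.shape[-1]
    if n < 2 * sampling_rate / low:
        detrended = signal.detrend(data, axis=-1, type="linear")
        sos = signal.butter(order, high, btype="lowpass", fs=sampling_rate, output="sos")
        return signal.sosfiltfilt(sos, detrended, axis=-1)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def epoch_and_baseline(
    epochs: EpochedData,
    window: tuple[float, float] | None = None,
    baseline: tuple[float, float] = (-200.0, 0.0),
) -> EpochedData:
    """Crop to a half-open [start, end) window and subtract the
    per-channel mean over the baseline window from every sample."""
    if window is None:
        window = (epochs.times[0], epochs.times[-1] + 1000.0 / epochs.sampling_rate)
    b0, b1 = baseline
    w0, w1 = window
    if b0 < w0 or b1 > w1:
        raise ValueError("baseline window must lie inside the epoch window")
    keep = (epochs.times >= w0) & (epochs.times < w1)
    if not keep.any():
        raise ValueError("epoch window selects no samples")
    data = epochs.data[:, :, keep]
    times = epochs.times[keep]
    bmask = (times >= b0) & (times < b1)
    if not bmask.any():
        raise ValueError("baseline window selects no samples")
    data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    return replace(epochs, data=data, times=times)


def reject_epochs(epochs: EpochedData, threshold: float = 100.0) -> tuple[EpochedData, RejectionLog]:
    """Drop any trial containing a sample with \\|amplitude\\| above
    ``threshold`` µV; the log records which trial ids were removed."""
    bad = np.abs(epochs.data).max(axis=(1, 2)) > threshold
    log = RejectionLog(
        threshold=threshold,
        rejected_trial_ids=list(np.asarray(epochs.trial_ids)[bad]),
        n_in=epochs.n_trials,
        n_out=int((~bad).sum()),
    )
    kept = replace(
        epochs,
        data=epochs.data[~bad],
        conditions=epochs.conditions[~bad],
        trial_ids=np.asarray(epochs.trial_ids)[~bad],
    )
    return kept, log


def rereference_average(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous channel mean (channel axis = -2).

    Idempotent; leaves reference-free quantities such as GFP unchanged.
    """
    data = np.asarray(data, dtype=float)
    return data - data.mean(axis=-2, keepdims=True)


def resample(epochs: EpochedData, target_rate: float) -> EpochedData:
    """Polyphase resampling to ``target_rate`` Hz (duration preserved
    to within one sample)."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if np.isclose(target_rate, epochs.sampling_rate):
        return epochs
    frac = Fraction(target_rate / epochs.sampling_rate).limit_denominator(1000)
    data = signal.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    step = 1000.0 / target_rate
    times = epochs.times[0] + step * np.arange(data.shape[-1])
    return replace(epochs, data=data, times=times, sampling_rate=target_rate)


def average_erp(epochs: EpochedData, condition: str) -> ERP:
    """Trial-average ERP for one condition."""
    mask = epochs.conditions == condition
    if not mask.any():
        raise ValueError(f"no trials with condition {condition!r}")
    return ERP(
        data=epochs.data[mask].mean(axis=0),
        sampling_rate=epochs.sampling_rate,
        times=epochs.times,
        condition=condition,
        participant_id=epochs.participant_id,
        group=epochs.group,
        n_trials=int(mask.sum()),
    )


def preprocess_participant(
    epochs: EpochedData,
    config: PreprocessConfig | None = None,
    conditions: Sequence[str] = CONDITIONS,
) -> tuple[dict[str, ERP], EpochedData, dict]:
    """Run the full fixed chain on one participant.

    Returns the per-condition ERPs, the cleaned epoched data (used later
    for trial-wise phase estimation) and a stage report with counts.
    """
    config = config or PreprocessConfig()
    report: dict = {"participant_id": epochs.participant_id, "n_trials_in": epochs.n_trials}

    filtered = replace(
        epochs,
        data=bandpass_filter(epochs.data, epochs.sampling_rate, *config.band, config.filter_order),
    )
    epoched = epoch_and_baseline(filtered, config.epoch_window, config.baseline)
    cleaned, rej = reject_epochs(epoched, config.reject_threshold)
    report["n_rejected"] = len(rej.rejected_trial_ids)
    report["rejected_trial_ids"] = [int(t) for t in rej.rejected_trial_ids]
    cleaned = replace(cleaned, data=rereference_average(cleaned.data))
    cleaned = resample(cleaned, config.resample_rate)
    report["n_trials_out"] = cleaned.n_trials
    report["n_samples"] = cleaned.n_samples
    erps = {c: average_erp(cleaned, c) for c in conditions if (cleaned.conditions == c).any()}
    report["trials_per_condition"] = {c: erps[c].n_trials for c in erps}
    return erps, cleaned, report
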