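"""Preprocessing and quality control of epoched EEG.

Order of operations mirrors a standard single-trial decoding pipeline:
zero-phase FIR band-pass (1-40 Hz), downsampling to 256 Hz, re-windowing to
-100..800 ms, then behavioral trial selection (correct responses between
100 and 1200 ms, congruent/incongruent conditions only) and exclusion of
participants with fewer than 35 correct trials in either condition.

Filtering and resampling delegate to MNE-Python's default FIR machinery
(Hamming window, automatic transition bandwidths), applied per trial.
No baseline correction is performed; the 1 Hz high-pass removes drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from mne.filter import create_filter, filter_data, resample as _mne_resample

from .simgen import CONDITIONS, EpochSet

__all__ = [
    "QCReport",
    "PrepParams",
    "bandpass",
    "resample",
    "crop",
    "select_correct_trials",
    "apply_min_trial_filter",
    "run_prep",
]

RT_MIN_MS = 100.0
RT_MAX_MS = 1200.0
DEFAULT_MIN_TRIALS = 35


@dataclass(frozen=True)
class QCReport:
    """Per-participant quality-control outcome."""

    participant_id: str
    n_correct_per_condition: dict[str, int]
    excluded: bool
    exclusion_reason: str = "none"   # min_trials | data_quality | none

    def __post_init__(self):
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError("excluded flag inconsistent with reason")


def bandpass(epochs: EpochSet, low: float, high: float) -> EpochSet:
    """Zero-phase FIR band-pass, per channel per trial; shape unchanged.

    Epochs are typically shorter than the default FIR kernel (845 taps for
    a 1-40 Hz band at 256 Hz), so each trial is reflect-padded by the
    kernel length before filtering to preserve the designed passband and
    stopband response.
    """
    nyq = epochs.sfreq / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < {nyq} Hz")
    n_trials, n_ch, n_samp = epochs.data.shape
    kernel = create_filter(None, epochs.sfreq, low, high, verbose="error")
    pad = len(kernel)
    flat = epochs.data.reshape(n_trials * n_ch, n_samp)
    padded = np.pad(flat, ((0, 0), (pad, pad)), mode="reflect")
    filtered = filter_data(padded, sfreq=epochs.sfreq, l_freq=low,
                           h_freq=high, verbose="error")[:, pad:pad + n_samp]
    out = epochs.copy()
    out.data = filtered.reshape(n_trials, n_ch, n_samp)
    return out


def resample(epochs: EpochSet, target_sfreq: float) -> EpochSet:
    """FFT-based resampling to ``target_sfreq``.

    The new sample count is round(n_samples * target/sfreq); times are
    rebuilt from the first sample at the new rate.
    """
    if target_sfreq <= 0:
        raise ValueError("target_sfreq must be > 0")
    if target_sfreq > epochs.sfreq:
        raise ValueError("target_sfreq must not exceed the current rate")
    if target_sfreq == epochs.sfreq:
        return epochs.copy()
    data = _mne_resample(epochs.data, up=target_sfreq, down=epochs.sfreq,
                         npad="auto", verbose="error")
    out = epochs.copy()
    out.data = data
    out.sfreq = target_sfreq
    out.times = epochs.times[0] + np.arange(data.shape[2]) / target_sfreq
    return out


def crop(epochs: EpochSet, start_ms: float, end_ms: float) -> EpochSet:
    """Re-window the epoch to the sample grid covering [start, end].

    Both edges are floored onto the integer sample grid (k/sfreq), matching
    the simulator's epoch construction: -100..800 ms at 256 Hz keeps samples
    k = -26..204, i.e. 231 samples.
    """
    sf = epochs.sfreq
    k0 = math.floor(start_ms / 1000.0 * sf + 1e-9)
    k1 = math.floor(end_ms / 1000.0 * sf + 1e-9)
    k = np.round(epochs.times * sf).astype(int)
    mask = (k >= k0) & (k <= k1)
    if not mask.any():
        raise ValueError("crop window contains no samples")
    out = epochs.copy()
    out.data = epochs.data[:, :, mask].copy()
    out.times = epochs.times[mask].copy()
    return out


def select_correct_trials(epochs: EpochSet) -> EpochSet:
    """Keep correct congruent/incongruent trials with RT in [100, 1200] ms.

    Bounds are inclusive; trials from any other condition (e.g. neutral)
    are dropped. May return an empty EpochSet.
    """
    keep = (epochs.correctness
            & (epochs.rt >= RT_MIN_MS) & (epochs.rt <= RT_MAX_MS)
            & np.isin(epochs.trial_labels, CONDITIONS))
    return epochs.select_trials(keep)


def apply_min_trial_filter(
    dataset: list[EpochSet],
    min_trials: int = DEFAULT_MIN_TRIALS,
    manual_exclusions: tuple[str, ...] = (),
) -> tuple[list[EpochSet], list[QCReport]]:
    """Drop participants with < ``min_trials`` trials in either condition.

    Expects trials already restricted to correct responses. A QC report is
    emitted for every participant; ``manual_exclusions`` flags participants
    excluded by eye for poor data quality (no automatic detector exists).
    """
    kept: list[EpochSet] = []
    reports: list[QCReport] = []
    for ep in dataset:
        counts = {c: int(np.sum(ep.trial_labels == c)) for c in CONDITIONS}
        if ep.participant_id in manual_exclusions:
            reason = "data_quality"
        elif any(counts[c] < min_trials for c in CONDITIONS):
            reason = "min_trials"
        else:
            reason = "none"
        reports.append(QCReport(ep.participant_id, counts,
                                excluded=reason != "none",
                                exclusion_reason=reason))
        if reason == "none":
            kept.append(ep)
    return kept, reports


@dataclass(frozen=True)
class PrepParams:
    """Parameters of the full preprocessing chain."""

    l_freq: float = 1.0
    h_freq: float = 40.0
    sfreq: float = 256.0
    tmin_ms: float = -100.0
    tmax_ms: float = 800.0
    min_trials: int = DEFAULT_MIN_TRIALS


def run_prep(dataset: list[EpochSet], params: PrepParams = PrepParams(),
             manual_exclusions: tuple[str, ...] = (),
             ) -> tuple[list[EpochSet], list[QCReport]]:
    """filter -> resample -> crop -> correct-trial selection -> QC."""
    processed = []
    for ep in dataset:
        ep = bandpass(ep, params.l_freq, params.h_freq)
        if params.sfreq < ep.sfreq:
            ep = resample(ep, params.sfreq)
        ep = crop(ep, params.tmin_ms, params.tmax_ms)
        processed.append(select_correct_trials(ep))
    return apply_min_trial_filter(processed, params.min_trials,
                                  manual_exclusions)
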