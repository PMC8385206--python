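"""Epoching, trimming, low-pass filtering and average referencing.

Analysis epochs span [-1.0, +15.36] s around stimulus onset (16.36 s).
Before spectral analysis the first 2.28 s are discarded -- the 1 s
pre-stimulus interval plus the first four-word sequence -- to exclude the
transient onset response, leaving 11 sequences (14.08 s, an integer number
of sentence periods, so the target rates fall exactly on DFT bins).
A zero-phase Butterworth low-pass at 25 Hz precedes trimming, and data are
re-referenced to the common average after reconstructing the original
recording reference as an all-zero channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .design import DesignParams, InvalidParameterError, SessionPlan
from .simulate import EpochSet

__all__ = ["TrimSpec", "segment_and_trim", "filter_and_reference", "preprocess"]


class BoundaryError(ValueError):
    """An epoch would extend beyond the available data."""


@dataclass(frozen=True)
class TrimSpec:
    """How much of each epoch precedes the analysed window."""

    prestim: float = 1.0
    discard: float = 2.28
    analysed_duration: float = 14.08

    @classmethod
    def from_design(cls, params: DesignParams) -> "TrimSpec":
        discard = params.prestim + params.sequence_duration
        total = params.prestim + params.trial_duration
        return cls(
            prestim=params.prestim,
            discard=discard,
            analysed_duration=total - discard,
        )


def _n_samples(duration: float, fs: float) -> int:
    # round-half-to-even on the product, applied once per epoch edge
    return int(np.round(duration * fs))


def segment_and_trim(
    source: EpochSet | np.ndarray,
    plan: SessionPlan | None = None,
    trim: TrimSpec | None = None,
    *,
    onsets: np.ndarray | None = None,
    sampling_rate: float | None = None,
) -> EpochSet:
    """Cut (if needed) and trim epochs to the analysed window.

    ``source`` is either an :class:`EpochSet` of pre-trim epochs
    ([-prestim, +trial end]) or a continuous channels x samples recording,
    in which case ``onsets`` (stimulus-onset times in seconds),
    ``sampling_rate`` and ``plan`` are required for epoching.
    """
    trim = trim or (TrimSpec.from_design(plan.params) if plan is not None else TrimSpec())
    if isinstance(source, np.ndarray):
        if source.ndim != 2:
            raise InvalidParameterError("continuous recording must be channels x samples")
        if onsets is None or sampling_rate is None or plan is None:
            raise InvalidParameterError("epoching a recording requires onsets, sampling_rate, plan")
        fs = float(sampling_rate)
        total = trim.discard + trim.analysed_duration
        n_epoch = _n_samples(total, fs)
        epochs = []
        for onset in np.asarray(onsets, float):
            start = int(np.round((onset - trim.prestim) * fs))
            stop = start + n_epoch
            if start < 0 or stop > source.shape[1]:
                raise BoundaryError(
                    f"epoch [{start}, {stop}) exceeds recording of {source.shape[1]} samples"
                )
            epochs.append(source[:, start:stop])
        epochset = EpochSet(
            data=np.stack(epochs),
            sampling_rate=fs,
            t0=-trim.prestim,
            conditions=tuple(t.condition for t in plan.trials)[: len(epochs)],
            group=plan.group,
            participant_id="imported",
            trimmed=False,
        )
    else:
        epochset = source
    if epochset.trimmed:
        return epochset

    fs = epochset.sampling_rate
    n_discard = _n_samples(trim.discard, fs)
    n_keep = _n_samples(trim.analysed_duration, fs)
    offset = int(np.round((-trim.prestim - epochset.t0) * fs))  # allow t0 != -prestim
    start = offset + n_discard
    if start + n_keep > epochset.n_samples:
        raise BoundaryError("epochs too short for the requested trim")
    return EpochSet(
        data=epochset.data[:, :, start : start + n_keep],
        sampling_rate=fs,
        t0=epochset.t0 + start / fs,
        conditions=epochset.conditions,
        group=epochset.group,
        participant_id=epochset.participant_id,
        trimmed=True,
    )


def filter_and_reference(
    epochs: EpochSet,
    cutoff: float = 25.0,
    order: int = 4,
    *,
    n_recorded: int | None = None,
    reconstruct_reference: bool = False,
) -> EpochSet:
    """Zero-phase Butterworth low-pass, then common-average re-reference.

    With ``reconstruct_reference=True`` (or when the channel count equals
    ``n_recorded``), an all-zero channel standing for the original
    recording reference is appended *before* averaging, mirroring how a
    referenced recording regains its reference electrode: after average
    referencing the reconstructed channel carries minus the channel mean.
    """
    nyquist = epochs.sampling_rate / 2.0
    if not (0 < cutoff < nyquist):
        raise InvalidParameterError(f"cutoff must lie in (0, {nyquist}) Hz")
    sos = butter(order, cutoff, btype="low", fs=epochs.sampling_rate, output="sos")
    data = sosfiltfilt(sos, np.asarray(epochs.data), axis=-1)
    if reconstruct_reference or (n_recorded is not None and epochs.n_channels == n_recorded):
        ref = np.zeros((data.shape[0], 1, data.shape[2]))
        data = np.concatenate([data, ref], axis=1)
    data = data - data.mean(axis=1, keepdims=True)
    return EpochSet(
        data=data,
        sampling_rate=epochs.sampling_rate,
        t0=epochs.t0,
        conditions=epochs.conditions,
        group=epochs.group,
        participant_id=epochs.participant_id,
        trimmed=epochs.trimmed,
    )


def preprocess(
    epochs: EpochSet,
    trim: TrimSpec | None = None,
    cutoff: float = 25.0,
) -> EpochSet:
    """Standard order: low-pass + average reference, then trim."""
    filtered = filter_and_reference(epochs, cutoff=cutoff)
    return segment_and_trim(filtered, trim=trim)
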