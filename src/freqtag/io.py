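"""File formats: EDF epochs, WAV envelopes, onset TSVs, provenance JSON.

Epoched EEG is exchanged as one EDF+ file per participant with the epochs
concatenated in time and an annotation marking each stimulus onset
("trial <k> <condition>"), readable by any EDF tool.  Import goes through
:func:`mne.io.read_raw_edf`; export uses the small EDF+C writer below
(16-bit, one-second data records).  Electrode coordinates travel as
SFP-style whitespace-delimited ``label x y z`` text (see
:mod:`freqtag.layout`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .design import DesignParams, InvalidParameterError, SessionPlan, TrialPlan
from .preprocessing import TrimSpec, segment_and_trim
from .simulate import EpochSet

__all__ = [
    "write_edf_epochs",
    "read_edf_epochs",
    "write_envelope_wav",
    "write_word_onsets",
    "write_session_plan",
    "read_session_plan",
    "write_provenance",
    "write_table",
]


def _pad(value: str, width: int) -> bytes:
    s = value[:width]
    return s.encode("ascii") + b" " * (width - len(s))


def _num8(value: float) -> str:
    """Shortest representation of ``value`` fitting the 8-char EDF fields."""
    for prec in range(6, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return s
    return "0"


def write_edf_epochs(path, epochs: EpochSet, labels=None) -> None:
    """Write concatenated epochs as EDF+C with onset annotations.

    Each epoch is laid out back to back on a continuous time axis; an
    annotation "trial <k> <condition>" is placed at each stimulus onset
    (epoch start minus ``t0``).  The sampling rate must be an integer
    (one-second data records with ``fs`` samples each).
    """
    fs = epochs.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise InvalidParameterError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_trials, n_ch, n_samp = epochs.data.shape
    labels = list(labels) if labels is not None else [f"E{c + 1:03d}" for c in range(n_ch)]
    data = np.asarray(epochs.data, float).transpose(1, 0, 2).reshape(n_ch, n_trials * n_samp)
    total = data.shape[1]
    n_records = int(np.ceil(total / fs))
    if n_records * fs > total:  # zero-pad the tail record
        data = np.pad(data, ((0, 0), (0, n_records * fs - total)))

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin[:, None]) * scale[:, None] + dmin), dmin, dmax
    ).astype("<i2")

    onsets = [k * n_samp / fs - epochs.t0 for k in range(n_trials)]
    notes = [f"trial {k} {cond}" for k, cond in enumerate(epochs.conditions)]
    ann_per_record: list[bytes] = []
    ann_samples = 60  # 120 bytes per record for the annotations signal
    for rec in range(n_records):
        tal = f"+{rec}\x14\x14\x00".encode("ascii")
        for onset, note in zip(onsets, notes):
            if rec <= onset < rec + 1:
                tal += f"+{onset:.4f}\x14{note}\x14\x00".encode("ascii")
        if len(tal) > 2 * ann_samples:
            raise InvalidParameterError("annotation record overflow")
        ann_per_record.append(tal + b"\x00" * (2 * ann_samples - len(tal)))

    ns = n_ch + 1
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad(f"Startdate X X X X {epochs.participant_id}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (ns + 1)), 8))
        fh.write(_pad("EDF+C", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))
        for lab in labels:
            fh.write(_pad(lab, 16))
        fh.write(_pad("EDF Annotations", 16))
        for _ in range(n_ch):
            fh.write(_pad("AgAgCl electrode", 80))
        fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        fh.write(_pad("", 8))
        for v in pmin:
            fh.write(_pad(_num8(v), 8))
        fh.write(_pad("-1", 8))
        for v in pmax:
            fh.write(_pad(_num8(v), 8))
        fh.write(_pad("1", 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dmin), 8))
        fh.write(_pad("-32768", 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dmax), 8))
        fh.write(_pad("32767", 8))
        for _ in range(ns):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad(str(fs), 8))
        fh.write(_pad(str(ann_samples), 8))
        for _ in range(ns):
            fh.write(_pad("", 32))
        for rec in range(n_records):
            fh.write(digital[:, rec * fs : (rec + 1) * fs].tobytes())
            fh.write(ann_per_record[rec])


def read_edf_epochs(
    path,
    plan: SessionPlan | None = None,
    trim: TrimSpec | None = None,
    group: str = "imported",
) -> EpochSet:
    """Read an EDF+ file written by :func:`write_edf_epochs` (or an
    externally epoched recording following the same annotation scheme)
    back into an :class:`EpochSet` of *pre-trim* epochs."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")  # keep the microvolt scale the file was written in
    fs = float(raw.info["sfreq"])
    onsets, conditions = [], []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        parts = desc.split()
        if parts and parts[0] == "trial":
            onsets.append(float(onset))
            conditions.append(parts[2] if len(parts) > 2 else "unknown")
    if not onsets:
        raise InvalidParameterError("no 'trial' annotations found in EDF file")
    trim = trim or TrimSpec()
    total = trim.discard + trim.analysed_duration
    n_epoch = int(np.round(total * fs))
    epochs = []
    for onset in onsets:
        start = int(np.round((onset - trim.prestim) * fs))
        epochs.append(data[:, start : start + n_epoch])
    eset = EpochSet(
        data=np.stack(epochs),
        sampling_rate=fs,
        t0=-trim.prestim,
        conditions=tuple(conditions),
        group=plan.group if plan is not None else group,
        participant_id=Path(path).stem,
        trimmed=False,
    )
    return eset


def write_envelope_wav(path, envelope, sampling_rate: float | None = None) -> None:
    """Write an amplitude envelope as mono float32 WAV."""
    samples = getattr(envelope, "samples", envelope)
    fs = sampling_rate if sampling_rate is not None else envelope.sampling_rate
    wavfile.write(path, int(round(fs)), np.asarray(samples, np.float32))


def write_word_onsets(path, trial: TrialPlan, params: DesignParams) -> None:
    """TSV of word onsets for one trial: onset_s, label, category, sequence_index."""
    from .design import ORDERS, _CAT_OF_LETTER  # categories from the order template

    rows = []
    t = 0.0
    for s_idx, seq in enumerate(trial.sequences):
        for letter, word in zip(ORDERS[seq.order], seq.words):
            rows.append(
                {
                    "onset_s": round(t, 6),
                    "label": word,
                    "category": _CAT_OF_LETTER[letter],
                    "sequence_index": s_idx,
                }
            )
            t += params.word_duration
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_session_plan(path, plan: SessionPlan) -> None:
    """Serialise a session plan (trial structure, words, aISIs) as JSON."""
    import dataclasses

    record = {
        "group": plan.group,
        "params": dataclasses.asdict(plan.params),
        "trials": [
            {
                "condition": t.condition,
                "aisi": t.aisi,
                "sequences": [
                    {"order": s.order, "words": list(s.words),
                     "is_violation": s.is_violation}
                    for s in t.sequences
                ],
            }
            for t in plan.trials
        ],
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1)
        fh.write("\n")


def read_session_plan(path) -> SessionPlan:
    from .design import SequenceSpec

    with open(path) as fh:
        record = json.load(fh)
    params = record["params"]
    params["aisi_range"] = tuple(params["aisi_range"])
    trials = tuple(
        TrialPlan(
            condition=t["condition"],
            aisi=t["aisi"],
            sequences=tuple(
                SequenceSpec(order=s["order"], words=tuple(s["words"]),
                             is_violation=s["is_violation"])
                for s in t["sequences"]
            ),
        )
        for t in record["trials"]
    )
    return SessionPlan(group=record["group"], trials=trials,
                       params=DesignParams(**params))


def write_table(path, frame: pd.DataFrame) -> None:
    """Result table as TSV with a header row, stable float formatting."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_provenance(path, record: dict) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
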