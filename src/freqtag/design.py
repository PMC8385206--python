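"""Experimental design and stimulus-envelope construction.

The paradigm presents continuous streams of isochronous monosyllabic words
(320 ms each), so that hierarchical linguistic units are "tagged" at fixed
rates: words at 3.125 Hz, two-word phrases at 1.5625 Hz and four-word
sentences at 0.78125 Hz.  A trial is 12 four-word sequences (15.36 s of
audio).  Sentential trials use adjective-noun-verb-noun (ANVN) sequences;
scrambled trials use the two non-grammatical orders NNAV and AVNN in equal
numbers, which removes any phrase- or sentence-level regularity while
keeping the word-rate acoustics identical.

This module builds the timed session structure for one participant and a
physically plausible amplitude envelope of the audio stream.  The envelope
renders every word as the same tapered burst (with small i.i.d. amplitude
jitter), so by construction it carries no spectral energy at the phrase or
sentence rates beyond the noise floor -- the property the chance-frequency
control analysis verifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DesignParams",
    "RateSet",
    "Lexicon",
    "SequenceSpec",
    "TrialPlan",
    "SessionPlan",
    "EnvelopeTrace",
    "derive_rates",
    "build_lexicon",
    "plan_session",
    "synthesize_envelope",
    "GROUPS",
    "CONDITIONS",
    "ORDERS",
]

GROUPS = ("passive", "word", "sentence")
CONDITIONS = ("sentential", "scrambled")

#: category templates for the three sequence orders
ORDERS: dict[str, str] = {
    "ANVN": "anvn",
    "NNAV": "nnav",
    "AVNN": "avnn",
}
_VIOLATION_ORDERS = ("NNAV", "AVNN")

Category = Literal["noun", "adjective", "verb"]
_CAT_OF_LETTER = {"a": "adjective", "n": "noun", "v": "verb"}


class InvalidParameterError(ValueError):
    """Raised when a design parameter violates its stated constraints."""


@dataclass(frozen=True)
class DesignParams:
    """Timing and counting parameters of the experimental design."""

    word_duration: float = 0.320
    words_per_sequence: int = 4
    sequences_per_trial: int = 12
    trials_per_condition: int = 50
    prestim: float = 1.0
    aisi_range: tuple[float, float] = (1.0, 1.5)
    violation_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.word_duration <= 0 or self.prestim <= 0:
            raise InvalidParameterError("durations must be positive")
        if self.words_per_sequence < 1 or self.sequences_per_trial < 1:
            raise InvalidParameterError("sequence counts must be >= 1")
        if self.trials_per_condition < 1:
            raise InvalidParameterError("trials_per_condition must be >= 1")
        if not (0.0 <= self.violation_fraction <= 1.0):
            raise InvalidParameterError("violation_fraction must be in [0, 1]")
        lo, hi = self.aisi_range
        if not (0 < lo <= hi):
            raise InvalidParameterError("aISI range must satisfy 0 < lo <= hi")

    @property
    def trial_duration(self) -> float:
        """Stimulus duration of one trial in seconds (excl. pre-stimulus)."""
        return self.word_duration * self.words_per_sequence * self.sequences_per_trial

    @property
    def sequence_duration(self) -> float:
        return self.word_duration * self.words_per_sequence


@dataclass(frozen=True)
class RateSet:
    """Stimulation rates (Hz) of the three linguistic levels."""

    word_rate: float
    phrase_rate: float
    sentence_rate: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.word_rate, self.phrase_rate, self.sentence_rate)


def derive_rates(params: DesignParams) -> RateSet:
    """Stimulation rates implied by the word duration and sequence length.

    Words at ``1/word_duration`` Hz; sentences at one per sequence; phrases
    (two-word units) at twice the sentence rate.  Values are exact
    reciprocals -- rounding (3.125 / 1.56 / 0.78 Hz in reports) happens only
    at presentation time.
    """
    if params.word_duration <= 0:
        raise InvalidParameterError("word_duration must be positive")
    word = 1.0 / params.word_duration
    sentence = word / params.words_per_sequence
    return RateSet(word_rate=word, phrase_rate=2.0 * sentence, sentence_rate=sentence)


@dataclass(frozen=True)
class Lexicon:
    """Synthetic word inventory: unique labels with syntactic categories."""

    tokens: tuple[tuple[str, str], ...]

    def labels(self, category: str | None = None) -> list[str]:
        return [t for t, c in self.tokens if category is None or c == category]

    def __len__(self) -> int:
        return len(self.tokens)


def build_lexicon(
    counts: tuple[int, int, int] = (144, 72, 72),
    rng: np.random.Generator | None = None,
) -> Lexicon:
    """Build a lexicon of ``counts = (nouns, adjectives, verbs)`` placeholder
    tokens.

    Labels are category-prefixed indices (``noun_001`` ...); they never enter
    any numeric computation.  The (optional) generator shuffles label order
    deterministically so downstream sampling is seed-stable.
    """
    n_noun, n_adj, n_verb = counts
    if min(counts) < 1:
        raise InvalidParameterError("each category count must be >= 1")
    tokens: list[tuple[str, str]] = []
    for cat, n in (("noun", n_noun), ("adjective", n_adj), ("verb", n_verb)):
        width = max(3, len(str(n)))
        tokens += [(f"{cat}_{i + 1:0{width}d}", cat) for i in range(n)]
    if rng is not None:
        order = rng.permutation(len(tokens))
        tokens = [tokens[i] for i in order]
    return Lexicon(tokens=tuple(tokens))


@dataclass(frozen=True)
class SequenceSpec:
    """One four-word sequence: order template, word labels, violation flag."""

    order: str
    words: tuple[str, ...]
    is_violation: bool = False

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise InvalidParameterError(f"unknown order {self.order!r}")
        if len(self.words) != len(ORDERS[self.order]):
            raise InvalidParameterError("word count does not match order template")


@dataclass(frozen=True)
class TrialPlan:
    """One trial: condition label, its sequences and the trailing aISI."""

    condition: str
    sequences: tuple[SequenceSpec, ...]
    aisi: float

    @property
    def has_violation(self) -> bool:
        return any(s.is_violation for s in self.sequences)


@dataclass(frozen=True)
class SessionPlan:
    """The complete timed trial structure for one participant."""

    group: str
    trials: tuple[TrialPlan, ...]
    params: DesignParams = field(default_factory=DesignParams)

    def trials_of(self, condition: str) -> list[TrialPlan]:
        return [t for t in self.trials if t.condition == condition]

    def word_onsets(self, trial_index: int) -> np.ndarray:
        """Word onset times (s) within the stimulus of one trial."""
        p = self.params
        n_words = p.words_per_sequence * p.sequences_per_trial
        return np.arange(n_words) * p.word_duration


def _sample_sequence(
    order: str,
    by_cat: dict[str, list[str]],
    rng: np.random.Generator,
    *,
    is_violation: bool = False,
) -> SequenceSpec:
    words = tuple(
        by_cat[_CAT_OF_LETTER[letter]][rng.integers(len(by_cat[_CAT_OF_LETTER[letter]]))]
        for letter in ORDERS[order]
    )
    return SequenceSpec(order=order, words=words, is_violation=is_violation)


def _sentential_trial(
    by_cat: dict[str, list[str]],
    params: DesignParams,
    rng: np.random.Generator,
    *,
    violation: bool,
) -> list[SequenceSpec]:
    """12 ANVN sequences, no exact four-word sentence repeated within the
    trial; violation trials replace one random slot by a non-grammatical
    sequence."""
    seqs: list[SequenceSpec] = []
    seen: set[tuple[str, ...]] = set()
    for _ in range(params.sequences_per_trial):
        for _attempt in range(1000):
            seq = _sample_sequence("ANVN", by_cat, rng)
            if seq.words not in seen:
                break
        else:  # pragma: no cover - requires pathologically small lexicon
            raise InvalidParameterError(
                "lexicon too small to avoid within-trial sentence repetition"
            )
        seen.add(seq.words)
        seqs.append(seq)
    if violation:
        slot = int(rng.integers(params.sequences_per_trial))
        order = _VIOLATION_ORDERS[int(rng.integers(2))]
        seqs[slot] = _sample_sequence(order, by_cat, rng, is_violation=True)
    return seqs


def _scrambled_trial(
    by_cat: dict[str, list[str]],
    params: DesignParams,
    rng: np.random.Generator,
) -> list[SequenceSpec]:
    """Half NNAV, half AVNN, in shuffled slot order (exactly balanced)."""
    n = params.sequences_per_trial
    if n % 2:
        raise InvalidParameterError("sequences_per_trial must be even for scrambled trials")
    orders = ["NNAV"] * (n // 2) + ["AVNN"] * (n // 2)
    perm = rng.permutation(n)
    return [_sample_sequence(orders[i], by_cat, rng) for i in perm]


def plan_session(
    group: str,
    lexicon: Lexicon,
    params: DesignParams | None = None,
    rng: np.random.Generator | None = None,
) -> SessionPlan:
    """Construct a full session for one participant of the given group.

    Passive and word groups receive ``trials_per_condition`` sentential and
    as many scrambled trials, randomly interleaved.  The sentence group
    hears only sentential trials, a ``violation_fraction`` of which contain
    exactly one grammatically incorrect sequence (the behavioural target).
    """
    if group not in GROUPS:
        raise InvalidParameterError(f"group must be one of {GROUPS}")
    params = params or DesignParams()
    rng = rng if rng is not None else np.random.default_rng()
    by_cat = {c: lexicon.labels(c) for c in ("noun", "adjective", "verb")}
    for cat, labels in by_cat.items():
        if not labels:
            raise InvalidParameterError(f"lexicon has no {cat}s")
    if len(by_cat["noun"]) < 2:
        raise InvalidParameterError("need at least 2 nouns to fill ANVN/NNAV/AVNN")

    n = params.trials_per_condition
    trials: list[TrialPlan] = []
    lo, hi = params.aisi_range

    def aisi() -> float:
        return float(rng.uniform(lo, hi))

    if group == "sentence":
        n_viol = int(round(params.violation_fraction * n))
        viol_slots = set(rng.choice(n, size=n_viol, replace=False).tolist())
        for i in range(n):
            seqs = _sentential_trial(by_cat, params, rng, violation=i in viol_slots)
            trials.append(TrialPlan("sentential", tuple(seqs), aisi()))
    else:
        conditions = ["sentential"] * n + ["scrambled"] * n
        for i in rng.permutation(2 * n):
            cond = conditions[i]
            if cond == "sentential":
                seqs = _sentential_trial(by_cat, params, rng, violation=False)
            else:
                seqs = _scrambled_trial(by_cat, params, rng)
            trials.append(TrialPlan(cond, tuple(seqs), aisi()))
    return SessionPlan(group=group, trials=tuple(trials), params=params)


@dataclass(frozen=True)
class EnvelopeTrace:
    """Amplitude envelope (a.u., non-negative) of one trial's audio stream."""

    samples: np.ndarray
    sampling_rate: float
    trial_index: int = 0

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


def synthesize_envelope(
    trial: TrialPlan,
    params: DesignParams,
    sampling_rate: float,
    rng: np.random.Generator | None = None,
    *,
    trial_index: int = 0,
    amplitude: float = 1.0,
    amplitude_jitter_sd: float = 0.05,
    modulation_sd: float = 0.1,
    modulation_bandwidth_hz: float = 8.0,
) -> EnvelopeTrace:
    """Render a trial as a word-rate train of Hann-windowed amplitude bursts.

    Every word position gets an identical tapered burst whose peak is
    jittered i.i.d. as N(1, ``amplitude_jitter_sd``^2) (clipped at 0), and
    the whole train is multiplied by (1 + m(t)) with m a smooth band-limited
    noise of standard deviation ``modulation_sd``, i.i.d. across trials --
    the aperiodic loudness fluctuation any natural recording carries.
    Because both perturbations are independent of the sequence structure,
    the expected spectrum has deterministic energy only at the word rate
    and its harmonics; phrase- and sentence-rate bins stay at the noise
    floor.  (The broadband modulation also matters for *phase* statistics:
    per-word amplitude jitter alone combines word phasors at exactly half
    the word rate in antiphase, which would make the phrase bin's phase
    distribution degenerate rather than uniform.)
    """
    rate = derive_rates(params).word_rate
    if sampling_rate < 2 * rate:
        raise InvalidParameterError("sampling_rate below Nyquist for the word rate")
    rng = rng if rng is not None else np.random.default_rng()
    n_words = params.words_per_sequence * params.sequences_per_trial
    n_total = int(np.round(n_words * params.word_duration * sampling_rate))
    env = np.zeros(n_total)
    edges = np.round(np.arange(n_words + 1) * params.word_duration * sampling_rate).astype(int)
    for w in range(n_words):
        a, b = edges[w], min(edges[w + 1], n_total)
        peak = amplitude * max(0.0, 1.0 + amplitude_jitter_sd * rng.standard_normal())
        env[a:b] = peak * np.hanning(b - a)
    if modulation_sd > 0 and amplitude > 0:
        spec = np.fft.rfft(rng.standard_normal(n_total))
        f = np.fft.rfftfreq(n_total, d=1.0 / sampling_rate)
        spec[(f == 0) | (f > modulation_bandwidth_hz)] = 0.0
        m = np.fft.irfft(spec, n=n_total)
        sd = m.std()
        if sd > 0:
            env *= np.maximum(0.0, 1.0 + modulation_sd * m / sd)
    return EnvelopeTrace(samples=env, sampling_rate=sampling_rate, trial_index=trial_index)
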