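"""Synthetic multichannel EEG with controllable rhythmic phase locking.

Each trial/channel is a sum of phase-locked cosines at the word, phrase and
sentence stimulation rates plus 1/f background noise:

    x(t) = sum_r  a_r * g_r(channel) * cos(2*pi*f_r*t + phi_r + eps_{r,trial})
           + noise(t)

with r in {word, phrase, sentence}.  ``g_r`` is a smooth scalp topography
(Gaussian bump on the sphere; word: central, phrase/sentence: left
temporal), ``phi_r`` a per-participant base phase and ``eps`` i.i.d.
trial-wise phase jitter.  Scrambled trials carry no phrase- or
sentence-rate component (word streams without sentential structure evoke
no higher-level tracking); in the sentence group the sentence-rate
amplitude is multiplied by ``sentence_attention_gain`` on the left
fronto-temporal region, emulating the attentional enhancement of sentence
tracking.

The background is 1/f-shaped noise, part channel-independent and part
shared across the scalp through a handful of smoothly projected sources,
so that electrode-level statistics show realistic spatial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .design import (
    CONDITIONS,
    GROUPS,
    DesignParams,
    InvalidParameterError,
    SessionPlan,
    build_lexicon,
    derive_rates,
    plan_session,
)
from .layout import SensorLayout, make_layout

__all__ = [
    "GeneratorParams",
    "EpochSet",
    "ParticipantSpec",
    "CohortDataset",
    "simulate_participant",
    "simulate_cohort",
    "one_over_f_noise",
]

_RATE_NAMES = ("word", "phrase", "sentence")

# topography centres (unit directions): word central, phrase/sentence left temporal
_TOPO_CENTRES = {
    "word": np.array([0.0, 0.30, 0.95]),
    "phrase": np.array([-0.75, -0.15, 0.55]),
    "sentence": np.array([-0.70, 0.35, 0.55]),
}


@dataclass(frozen=True)
class GeneratorParams:
    """Signal-model parameters of the synthetic EEG generator.

    Amplitudes are in the same arbitrary units as ``noise_scale``; the
    defaults put single-trial spectral SNR in a range where 50-trial ITPC
    at the word bin is ~0.45 and at the phrase/sentence bins ~0.2, the
    scale of group-level ITPC spectra seen in frequency-tagging studies.
    ``phase_jitter_sd`` may be a scalar (radians, all rates) or a mapping
    per rate name.
    """

    sampling_rate: float = 250.0
    amp_word: float = 1.0
    amp_phrase: float = 0.55
    amp_sentence: float = 0.55
    phase_jitter_sd: float | Mapping[str, float] = 0.4
    sentence_attention_gain: float = 2.0
    attention_region: str = "left_frontotemporal"
    noise_exponent: float = 1.0
    noise_scale: float = 18.0
    noise_floor_hz: float = 0.1
    noise_spatial_coherence: float = 0.5
    n_noise_sources: int = 6
    topography_width: float = 0.8

    def __post_init__(self) -> None:
        if min(self.amp_word, self.amp_phrase, self.amp_sentence) < 0:
            raise InvalidParameterError("component amplitudes must be >= 0")
        if self.sentence_attention_gain < 0:
            raise InvalidParameterError("sentence_attention_gain must be >= 0")
        if self.sampling_rate < 50:
            raise InvalidParameterError("sampling_rate must be >= 50 Hz")
        if not (0.0 <= self.noise_spatial_coherence <= 1.0):
            raise InvalidParameterError("noise_spatial_coherence must be in [0, 1]")

    def jitter_sd(self, rate_name: str) -> float:
        if isinstance(self.phase_jitter_sd, Mapping):
            return float(self.phase_jitter_sd[rate_name])
        return float(self.phase_jitter_sd)


@dataclass
class EpochSet:
    """Epoched EEG of one participant: trials x channels x samples."""

    data: np.ndarray
    sampling_rate: float
    t0: float  # time of first sample relative to stimulus onset (s)
    conditions: tuple[str, ...]
    group: str
    participant_id: str
    trimmed: bool = False

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise InvalidParameterError("EpochSet data must be trials x channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("EpochSet data must be finite")
        if len(self.conditions) != self.data.shape[0]:
            raise InvalidParameterError("one condition label per trial required")

    def select(self, condition: str) -> "EpochSet":
        idx = [i for i, c in enumerate(self.conditions) if c == condition]
        return EpochSet(
            data=self.data[idx],
            sampling_rate=self.sampling_rate,
            t0=self.t0,
            conditions=tuple(self.conditions[i] for i in idx),
            group=self.group,
            participant_id=self.participant_id,
            trimmed=self.trimmed,
        )


def gaussian_topography(layout: SensorLayout, centre: np.ndarray, width: float) -> np.ndarray:
    """Smooth bump on the sphere: exp(-d^2 / (2 w^2)), d = chord distance."""
    c = np.asarray(centre, float)
    c = c / np.linalg.norm(c)
    d2 = np.sum((layout.positions3d - c) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width**2))


def one_over_f_noise(
    shape: tuple[int, ...],
    n_samples: int,
    sampling_rate: float,
    rng: np.random.Generator,
    exponent: float = 1.0,
    floor_hz: float = 0.1,
    dtype=np.float32,
) -> np.ndarray:
    """1/f^exponent noise, synthesized directly in the frequency domain
    (complex Gaussian spectrum shaped by f^(-exponent/2)), unit variance.

    ``shape`` indexes independent realisations; the last axis has
    ``n_samples`` points.  ``floor_hz`` bounds the divergence at DC.
    """
    import scipy.fft as sfft

    n_freq = n_samples // 2 + 1
    re = rng.standard_normal(shape + (n_freq,), dtype=dtype)
    im = rng.standard_normal(shape + (n_freq,), dtype=dtype)
    f = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    gain = (np.maximum(f, floor_hz)) ** (-exponent / 2.0)
    gain[0] = 0.0  # no DC drift
    spec = (re + 1j * im) * gain.astype(dtype)
    shaped = sfft.irfft(spec, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _component_gains(
    layout: SensorLayout, params: GeneratorParams, group: str
) -> dict[str, np.ndarray]:
    gains = {
        name: gaussian_topography(layout, _TOPO_CENTRES[name], params.topography_width)
        for name in _RATE_NAMES
    }
    if group == "sentence" and params.sentence_attention_gain != 1.0:
        mask = layout.region_mask(params.attention_region)
        g = gains["sentence"].copy()
        g[mask] *= params.sentence_attention_gain
        gains["sentence"] = g
    return gains


def simulate_participant(
    plan: SessionPlan,
    params: GeneratorParams,
    layout: SensorLayout,
    rng: np.random.Generator,
    participant_id: str = "sim-000",
) -> EpochSet:
    """Generate one participant's pre-trim epochs ([-prestim, +15.36] s).

    Stimulus-locked components start at t = 0; the pre-stimulus interval
    contains noise only.  Phrase/sentence amplitudes are zeroed on
    scrambled trials.  Output is float32 (one participant at default sizes
    is ~200 MB as float64; nothing downstream needs better than single
    precision).
    """
    if layout.n_channels < 1:
        raise InvalidParameterError("layout must have at least one channel")
    dp = plan.params
    fs = params.sampling_rate
    rates = derive_rates(dp)
    f_of = dict(zip(_RATE_NAMES, rates.as_tuple()))
    n_samples = int(np.round((dp.prestim + dp.trial_duration) * fs))
    t = np.arange(n_samples) / fs - dp.prestim
    stim_on = (t >= 0) & (t < dp.trial_duration)
    gains = _component_gains(layout, params, plan.group)
    base_phase = {name: float(rng.uniform(0, 2 * np.pi)) for name in _RATE_NAMES}
    amp = {"word": params.amp_word, "phrase": params.amp_phrase, "sentence": params.amp_sentence}

    # per-participant shared-noise topographies
    n_src = params.n_noise_sources
    if n_src > 0 and params.noise_spatial_coherence > 0:
        centres = rng.standard_normal((n_src, 3))
        centres[:, 2] = np.abs(centres[:, 2])
        src_topo = np.stack(
            [gaussian_topography(layout, c, params.topography_width) for c in centres]
        )  # (n_src, n_ch)
    else:
        src_topo = None

    n_trials = len(plan.trials)
    n_ch = layout.n_channels
    data = np.zeros((n_trials, n_ch, n_samples), dtype=np.float32)
    c_mix = params.noise_spatial_coherence
    scrambled = np.array([tr.condition == "scrambled" for tr in plan.trials])

    # rhythmic components, vectorised over trials
    for name in _RATE_NAMES:
        a = np.full(n_trials, amp[name], dtype=np.float32)
        eps = rng.normal(0.0, params.jitter_sd(name), size=n_trials)
        if name in ("phrase", "sentence"):
            a[scrambled] = 0.0
        if not np.any(a):
            continue
        phase = 2 * np.pi * f_of[name] * t + base_phase[name]
        wave = np.cos(phase[None, :] + eps[:, None]).astype(np.float32) * stim_on
        g = (a[:, None] * gains[name][None, :]).astype(np.float32)  # (K, C)
        # chunked accumulation keeps the (K, C, N) temporaries small
        step = max(1, 2**24 // (n_ch * n_samples))
        for k0 in range(0, n_trials, step):
            k1 = min(k0 + step, n_trials)
            data[k0:k1] += g[k0:k1, :, None] * wave[k0:k1, None, :]

    if params.noise_scale > 0:
        step = max(1, 2**23 // (n_ch * n_samples))
        for k0 in range(0, n_trials, step):
            k1 = min(k0 + step, n_trials)
            ind = one_over_f_noise(
                (k1 - k0, n_ch), n_samples, fs, rng,
                params.noise_exponent, params.noise_floor_hz,
            )
            if src_topo is not None and c_mix > 0:
                shared = one_over_f_noise(
                    (k1 - k0, n_src), n_samples, fs, rng,
                    params.noise_exponent, params.noise_floor_hz,
                )
                proj = np.einsum("sc,ksn->kcn", src_topo.astype(np.float32), shared)
                psd = proj.std(axis=-1, keepdims=True)
                psd[psd == 0] = 1.0
                noise = np.sqrt(1 - c_mix) * ind + np.sqrt(c_mix) * proj / psd
            else:
                noise = ind
            data[k0:k1] += params.noise_scale * noise
    return EpochSet(
        data=data,
        sampling_rate=fs,
        t0=-dp.prestim,
        conditions=tuple(tr.condition for tr in plan.trials),
        group=plan.group,
        participant_id=participant_id,
        trimmed=False,
    )


@dataclass(frozen=True)
class ParticipantSpec:
    """Deferred description of one simulated participant (epochs are
    materialised on demand so that no stage holds more than one
    participant's raw data)."""

    participant_id: str
    group: str
    seed: int
    plan: SessionPlan


@dataclass
class CohortDataset:
    """A simulated cohort: lazy per-participant epochs + shared layout."""

    members: tuple[ParticipantSpec, ...]
    layout: SensorLayout
    params: GeneratorParams
    provenance: dict = field(default_factory=dict)

    def epochs_for(self, spec: ParticipantSpec) -> EpochSet:
        rng = np.random.default_rng(spec.seed)
        return simulate_participant(spec.plan, self.params, self.layout, rng, spec.participant_id)

    def __iter__(self) -> Iterator[tuple[ParticipantSpec, EpochSet]]:
        for spec in self.members:
            yield spec, self.epochs_for(spec)

    def group_members(self, group: str) -> list[ParticipantSpec]:
        return [m for m in self.members if m.group == group]


def simulate_cohort(
    group_sizes: tuple[int, int, int] = (20, 23, 22),
    params: GeneratorParams | None = None,
    seed: int = 0,
    design: DesignParams | None = None,
    layout: SensorLayout | None = None,
    lexicon_counts: tuple[int, int, int] = (144, 72, 72),
) -> CohortDataset:
    """Plan a cohort of (passive, word, sentence) participants.

    Each participant gets an independent child seed derived from ``seed``
    (``numpy.random.SeedSequence`` spawning), so the dataset is
    bit-reproducible and participants are statistically independent.
    Sentence-group participants receive sentential-only sessions.
    """
    if any(s < 0 for s in group_sizes):
        raise InvalidParameterError("group sizes must be >= 0")
    if sum(group_sizes) == 0:
        raise InvalidParameterError("at least one participant required")
    params = params or GeneratorParams()
    design = design or DesignParams()
    ss = np.random.SeedSequence(seed)
    layout = layout if layout is not None else make_layout(125, np.random.default_rng(ss.spawn(1)[0]))
    n_total = sum(group_sizes)
    children = ss.spawn(n_total)
    members: list[ParticipantSpec] = []
    idx = 0
    for group, size in zip(GROUPS, group_sizes):
        for j in range(size):
            child = children[idx]
            plan_seed, sim_seed = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2)]
            lex = build_lexicon(lexicon_counts, np.random.default_rng(plan_seed))
            plan = plan_session(group, lex, design, np.random.default_rng(plan_seed + 1))
            members.append(
                ParticipantSpec(
                    participant_id=f"{group}-{j + 1:02d}", group=group, seed=sim_seed, plan=plan
                )
            )
            idx += 1
    return CohortDataset(
        members=tuple(members),
        layout=layout,
        params=params,
        provenance={"seed": seed, "group_sizes": tuple(group_sizes)},
    )
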