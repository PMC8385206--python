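"""Stimulus design: rates, lexicon, session plans and envelopes."""

import numpy as np
import pytest

from freqtag.design import (
    DesignParams,
    InvalidParameterError,
    build_lexicon,
    derive_rates,
    plan_session,
    synthesize_envelope,
)


class TestRates:
    @pytest.mark.parametrize(
        "word_duration,words_per_seq,expected",
        [
            (0.320, 4, (3.125, 1.5625, 0.78125)),
            (0.5, 4, (2.0, 1.0, 0.5)),
            (0.25, 2, (4.0, 4.0, 2.0)),
        ],
    )
    def test_rates_are_exact_reciprocals(self, word_duration, words_per_seq, expected):
        params = DesignParams(word_duration=word_duration, words_per_sequence=words_per_seq)
        rates = derive_rates(params)
        assert rates.as_tuple() == pytest.approx(expected, abs=0)

    def test_reported_rounding_matches_conventional_labels(self):
        rates = derive_rates(DesignParams())
        assert round(rates.sentence_rate, 2) == 0.78
        assert round(rates.phrase_rate, 2) == 1.56

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidParameterError):
            DesignParams(word_duration=0.0)


class TestLexicon:
    @pytest.mark.parametrize(
        "counts,total", [((144, 72, 72), 288), ((1, 1, 1), 3), ((4, 2, 2), 8)]
    )
    def test_counts_and_uniqueness(self, counts, total):
        lex = build_lexicon(counts, np.random.default_rng(0))
        labels = lex.labels()
        assert len(labels) == total
        assert len(set(labels)) == total
        for cat, n in zip(("noun", "adjective", "verb"), counts):
            assert len(lex.labels(cat)) == n

    def test_deterministic_under_seed(self):
        a = build_lexicon((6, 3, 3), np.random.default_rng(5))
        b = build_lexicon((6, 3, 3), np.random.default_rng(5))
        assert a == b

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_lexicon((0, 1, 1))


class TestSessionPlan:
    def test_passive_session_structure(self, passive_plan, default_design):
        plan = passive_plan
        p = default_design
        for cond in ("sentential", "scrambled"):
            trials = plan.trials_of(cond)
            assert len(trials) == p.trials_per_condition
            n_seq = sum(len(t.sequences) for t in trials)
            assert n_seq == p.trials_per_condition * p.sequences_per_trial == 600
        # conditions are interleaved, not blocked
        conds = [t.condition for t in plan.trials]
        assert conds != sorted(conds)

    def test_scrambled_trials_exactly_balanced(self, passive_plan):
        for trial in passive_plan.trials_of("scrambled"):
            orders = [s.order for s in trial.sequences]
            assert orders.count("NNAV") == 6
            assert orders.count("AVNN") == 6

    def test_no_sentence_repeated_within_trial(self, passive_plan):
        for trial in passive_plan.trials_of("sentential"):
            words = [s.words for s in trial.sequences]
            assert len(set(words)) == len(words)

    def test_sentence_group_violations(self, default_design, small_lexicon):
        plan = plan_session(
            "sentence", small_lexicon, default_design, np.random.default_rng(3)
        )
        assert len(plan.trials) == 50
        assert all(t.condition == "sentential" for t in plan.trials)
        viol_trials = [t for t in plan.trials if t.has_violation]
        assert len(viol_trials) == 5  # 10% of 50
        for t in viol_trials:
            viols = [s for s in t.sequences if s.is_violation]
            assert len(viols) == 1
            assert viols[0].order in ("NNAV", "AVNN")

    def test_aisi_within_configured_range(self, passive_plan, default_design):
        lo, hi = default_design.aisi_range
        assert all(lo <= t.aisi <= hi for t in passive_plan.trials)

    def test_plan_is_deterministic(self, default_design, small_lexicon):
        a = plan_session("word", small_lexicon, default_design, np.random.default_rng(9))
        b = plan_session("word", small_lexicon, default_design, np.random.default_rng(9))
        assert a == b

    def test_invalid_group_and_lexicon_rejected(self, default_design, small_lexicon):
        with pytest.raises(InvalidParameterError):
            plan_session("listener", small_lexicon, default_design)
        thin = build_lexicon((1, 1, 1), np.random.default_rng(0))
        with pytest.raises(InvalidParameterError):
            plan_session("passive", thin, default_design, np.random.default_rng(0))


class TestEnvelope:
    def test_length_and_nonnegativity(self, passive_plan, default_design):
        env = synthesize_envelope(
            passive_plan.trials[0], default_design, 250.0, np.random.default_rng(0)
        )
        assert len(env.samples) == 3840  # 15.36 s x 250 Hz
        assert env.duration == pytest.approx(15.36)
        assert np.all(env.samples >= 0)

    def test_zero_amplitude_gives_silence(self, passive_plan, default_design):
        env = synthesize_envelope(
            passive_plan.trials[0], default_design, 250.0,
            np.random.default_rng(0), amplitude=0.0,
        )
        assert np.all(env.samples == 0)

    def test_deterministic_under_seed(self, passive_plan, default_design):
        a = synthesize_envelope(passive_plan.trials[0], default_design, 250.0,
                                np.random.default_rng(4))
        b = synthesize_envelope(passive_plan.trials[0], default_design, 250.0,
                                np.random.default_rng(4))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_sub_nyquist_sampling_rejected(self, passive_plan, default_design):
        with pytest.raises(InvalidParameterError):
            synthesize_envelope(passive_plan.trials[0], default_design, 5.0)

    def test_spectrum_peaks_only_at_word_rate(self, default_design, small_lexicon):
        """Mean power over many trials: >=20x elevation at the word rate,
        phrase/sentence bins indistinguishable from their neighbourhood."""
        rng = np.random.default_rng(11)
        fs = 250.0
        plan = plan_session("sentence", small_lexicon, default_design, rng)
        n_seq = int(round(default_design.sequence_duration * fs))
        spectra = []
        for rep in range(3):  # 3 x 50 = 150 trials
            for trial in plan.trials:
                env = synthesize_envelope(trial, default_design, fs, rng)
                x = env.samples[n_seq:]  # analysed 11-sequence window
                spectra.append(np.abs(np.fft.rfft(x - x.mean())) ** 2)
        power = np.mean(spectra, axis=0)
        freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
        band = (freqs > 0.3) & (freqs < 5.0)
        word_bin = np.argmin(np.abs(freqs - 3.125))
        assert power[word_bin] >= 20 * np.median(power[band])
        for f0 in (1.5625, 0.78125):
            b = np.argmin(np.abs(freqs - f0))
            surround = np.r_[b - 8 : b, b + 1 : b + 9]
            # indistinguishable from its neighbourhood (any deterministic
            # component would tower over the surrounding noise bins)
            assert power[b] <= 1.15 * power[surround].max()
            assert power[b] >= 0.85 * power[surround].min()
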