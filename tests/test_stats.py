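"""Peak tests, FDR, bootstrap chance-frequency control, ANOVA, Bayes factors."""

import numpy as np
import pandas as pd
import pytest

from freqtag.design import InvalidParameterError
from freqtag.itpc import ITPCMap
from freqtag.stats import (
    InsufficientSampleError,
    attention_anova,
    bootstrap_monte_carlo,
    eligible_chance_bins,
    fdr_bh,
    jzs_bf_from_t,
    jzs_bf_two_sample,
    peak_test,
    peak_tests,
    top_fraction_electrodes,
)

TARGETS = (3.125, 1.5625, 0.78125)


class TestPeakTest:
    def test_exact_null_gives_t0_p1(self):
        spectra = np.full((8, 15), 0.2)
        res = peak_test(spectra, np.arange(15.0), target=7.0)
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.md == 0.0

    def test_detects_injected_peak(self, rng):
        spectra = rng.normal(0.12, 0.01, size=(20, 15))
        spectra[:, 7] += 0.1
        res = peak_test(spectra, np.arange(15.0), target=7.0)
        assert res.p < 1e-6
        assert res.md == pytest.approx(0.1, abs=0.02)
        assert res.ci[0] < res.md < res.ci[1]
        assert res.df == 19

    def test_fdr_applied_across_targets(self, rng):
        freqs = np.arange(0, 5, 1 / 14.08)
        spectra = rng.normal(0.12, 0.01, size=(12, len(freqs)))
        results = peak_tests(spectra, freqs, TARGETS)
        assert len(results) == 3
        assert all(r.p_fdr >= r.p for r in results)

    def test_too_few_participants_rejected(self):
        with pytest.raises(InsufficientSampleError):
            peak_test(np.zeros((2, 15)), np.arange(15.0), 7.0)

    def test_edge_target_rejected(self):
        with pytest.raises(InvalidParameterError):
            peak_test(np.zeros((5, 15)), np.arange(15.0), target=2.0)


class TestFDR:
    def test_step_up_oracle(self):
        """Hand-computed BH: (0.01, 0.02, 0.03) -> (0.03, 0.03, 0.03)."""
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_reordering_permutes_outputs_identically(self, rng):
        p = rng.uniform(size=9)
        perm = rng.permutation(9)
        np.testing.assert_allclose(fdr_bh(p)[perm], fdr_bh(p[perm]))


class TestBootstrapMonteCarlo:
    fs = 250.0
    n = 3520  # 14.08 s

    def _tone_trials(self, freq, k=30, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(self.n) / self.fs
        return np.cos(2 * np.pi * freq * t)[None, :] + noise * rng.standard_normal((k, self.n))

    def test_locked_word_rate_reaches_floor(self):
        trials = self._tone_trials(3.125)
        res = bootstrap_monte_carlo(
            trials, self.fs, TARGETS, n_rep=50, n_draw=30, n_chance=100,
            rng=np.random.default_rng(1),
        )
        assert res.p_mc[0] == res.p_floor == 1 / 101
        assert res.at_floor[0]
        assert res.target_itpc[0] > 0.99

    def test_white_noise_p_uniform_over_seeds(self):
        """At null frequencies the Monte-Carlo p is ~uniform across seeds;
        its median over runs lands mid-range."""
        ps = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            trials = rng.standard_normal((25, self.n))
            res = bootstrap_monte_carlo(
                trials, self.fs, TARGETS, n_rep=30, n_draw=25, n_chance=60, rng=rng
            )
            ps.append(res.p_mc)
        med = np.median(ps, axis=0)
        assert np.all(med > 0.15) and np.all(med < 0.85)

    def test_scale_invariance(self):
        trials = self._tone_trials(3.125, noise=0.3)
        kwargs = dict(n_rep=20, n_draw=30, n_chance=50)
        a = bootstrap_monte_carlo(trials, self.fs, TARGETS,
                                  rng=np.random.default_rng(3), **kwargs)
        b = bootstrap_monte_carlo(7.5 * trials, self.fs, TARGETS,
                                  rng=np.random.default_rng(3), **kwargs)
        np.testing.assert_allclose(a.target_itpc, b.target_itpc, rtol=1e-6)
        np.testing.assert_array_equal(a.p_mc, b.p_mc)

    def test_multichannel_input_averages_channels(self):
        rng = np.random.default_rng(4)
        trials = rng.standard_normal((20, 3, self.n))
        res = bootstrap_monte_carlo(trials, self.fs, TARGETS, n_rep=10,
                                    n_draw=20, n_chance=40, rng=rng)
        assert res.chance_itpc.shape == (40,)
        assert np.all((res.p_mc >= res.p_floor) & (res.p_mc <= 1))

    def test_chance_bins_exclude_targets_and_harmonics(self):
        freqs = np.fft.rfftfreq(self.n, 1 / self.fs)
        pool = eligible_chance_bins(freqs, TARGETS)
        chance = freqs[pool]
        assert np.all((chance > 0.3) & (chance < 5.0))
        for f0 in TARGETS:
            for m in range(1, int(5.0 / f0) + 1):
                assert np.abs(chance - m * f0).min() > 1.5 / 14.08  # > 1 bin away

    def test_insufficient_trials_rejected(self):
        with pytest.raises(InsufficientSampleError):
            bootstrap_monte_carlo(np.zeros((10, self.n)), self.fs, TARGETS,
                                  n_draw=50, rng=np.random.default_rng(0))


class TestTopElectrodes:
    def _map(self, values):
        values = np.asarray(values, float)[:, None]
        return ITPCMap(values=values, freqs=np.array([0.0]),
                       convention="resultant_length", K=10)

    def test_fraction_counts(self, rng):
        for n, frac, k in ((125, 0.05, 6), (100, 0.10, 10), (10, 0.01, 1)):
            vals = rng.uniform(size=n)
            sel = top_fraction_electrodes(self._map(vals), 0.0, frac)
            assert len(sel) == k
            assert set(vals[sel]) == set(np.sort(vals)[-k:])

    def test_ties_broken_by_ascending_index(self):
        sel = top_fraction_electrodes(self._map(np.ones(40)), 0.0, 0.1)
        np.testing.assert_array_equal(sel, [0, 1, 2, 3])

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidParameterError):
            top_fraction_electrodes(self._map(np.ones(10)), 0.0, 0.0)


def anova_table(word_vals, sentence_vals):
    rows = []
    for group, vals in (("word", word_vals), ("sentence", sentence_vals)):
        for i, (w, s) in enumerate(vals):
            pid = f"{group}-{i}"
            rows.append({"participant": pid, "group": group, "frequency": "word_bin", "itpc": w})
            rows.append({"participant": pid, "group": group, "frequency": "sentence_bin", "itpc": s})
    return pd.DataFrame(rows)


class TestAttentionAnova:
    def test_null_effect_size_small(self, rng):
        vals = rng.normal(0.3, 0.05, size=(2, 40, 2))
        res = attention_anova(anova_table(vals[0], vals[1]))
        assert res.eta_sq < 0.01
        assert res.F >= 0

    def test_interaction_detected_with_sentence_gain(self, rng):
        word_vals = rng.normal(0.3, 0.03, size=(22, 2))
        sent_vals = rng.normal(0.3, 0.03, size=(22, 2))
        sent_vals[:, 1] += 0.15  # sentence-bin boost in the sentence group
        res = attention_anova(anova_table(word_vals, sent_vals))
        assert res.p < 1e-4
        labels = {ph.label: ph for ph in res.posthoc}
        assert labels["sentence_bin"].p < 1e-4
        assert labels["sentence_bin"].md == pytest.approx(0.15, abs=0.05)
        assert labels["word_bin"].p > 0.01

    def test_mixed_and_between_degrees_of_freedom(self, rng):
        word_vals = rng.normal(size=(23, 2))
        sent_vals = rng.normal(size=(22, 2))
        mixed = attention_anova(anova_table(word_vals, sent_vals))
        assert mixed.df == (1, 43)
        between = attention_anova(anova_table(word_vals, sent_vals), formulation="between")
        assert between.df == (1, 86)

    def test_missing_cell_rejected(self, rng):
        table = anova_table(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))
        with pytest.raises(InvalidParameterError):
            attention_anova(table[table["group"] == "word"])


class TestJZSBayesFactor:
    def test_evidence_thresholds(self):
        assert jzs_bf_from_t(0.0, 25, 25) < 1 / 3
        assert jzs_bf_from_t(5.0, 25, 25) > 3

    def test_matches_pingouin_reference(self):
        """Independent cross-check against pingouin's JZS implementation."""
        import pingouin as pg

        for t in (-3.0, -1.0, 0.0, 0.5, 2.0, 4.0):
            for n1, n2 in ((5, 5), (20, 25), (23, 22)):
                mine = jzs_bf_from_t(t, n1, n2)
                ref = float(pg.bayesfactor_ttest(t, n1, n2, paired=False))
                assert mine == pytest.approx(ref, rel=1e-3)

    def test_monotone_in_t_magnitude(self):
        bfs = [jzs_bf_from_t(t, 20, 20) for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_sample_interface_and_errors(self, rng):
        x, y = rng.normal(size=30), rng.normal(loc=2.0, size=30)
        assert jzs_bf_two_sample(x, y) > 3
        with pytest.raises(InsufficientSampleError):
            jzs_bf_two_sample([1.0], [1.0, 2.0])
        with pytest.raises(InvalidParameterError):
            jzs_bf_two_sample([1.0, 1.0], [2.0, 2.0])
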