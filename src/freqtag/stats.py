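"""Peak statistics, chance-frequency controls, ANOVA and Bayes factors.

Four families of inference on ITPC data:

* ``peak_test`` / ``peak_tests`` -- is coherence at a target frequency
  elevated above its spectral neighbourhood (+-7 bins ~ +-0.5 Hz)?
  Paired t-tests across participants, Benjamini-Hochberg FDR across the
  three target rates within each group x condition.
* ``bootstrap_monte_carlo`` -- the stimulus-material control: resample
  trials with replacement (1000 x 50 by default), compute ITPC at the
  target rates and at 500 chance frequencies unrelated (non-harmonic) to
  them, and rank the target coherence within the chance distribution.
* ``attention_anova`` -- group (attend words vs attend sentences) x
  tracking-frequency interaction on top-electrode ITPC, with post-hoc
  two-sample t-tests.
* ``jzs_bf_two_sample`` -- default-prior (Jeffreys-Zellner-Siow) Bayes
  factor for two-sample contrasts, applied per electrode to quantify
  evidence for the *absence* of attention effects at the word rate
  (BF10 < 1/3 substantial evidence for the null, > 3 for the effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import integrate, stats as sps
from statsmodels.stats.multitest import multipletests

from .design import InvalidParameterError, RateSet
from .itpc import ITPCMap, resultant_length

__all__ = [
    "PeakTestResult",
    "BootstrapResult",
    "AnovaResult",
    "BFMap",
    "peak_test",
    "peak_tests",
    "fdr_bh",
    "bootstrap_monte_carlo",
    "eligible_chance_bins",
    "top_fraction_electrodes",
    "attention_anova",
    "jzs_bf_two_sample",
    "jzs_bf_from_t",
    "bf_map_two_sample",
    "simulate_null_itpc",
]


class InsufficientSampleError(ValueError):
    """Too few participants/trials for the requested statistic."""


# --------------------------------------------------------------------------
# peak tests at target frequencies

@dataclass
class PeakTestResult:
    target: float
    t: float
    df: int
    p: float
    p_fdr: float
    md: float
    ci: tuple[float, float]
    label: str = ""


def fdr_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def peak_test(
    spectra: np.ndarray,
    freqs: np.ndarray,
    target: float,
    halfwidth_bins: int = 7,
) -> PeakTestResult:
    """Paired t-test: target-bin ITPC vs the mean of its +-halfwidth
    neighbour bins (target excluded), across participants.

    ``spectra`` is participants x frequencies (ITPC averaged over all
    electrodes beforehand, one spectrum per participant).
    """
    spectra = np.asarray(spectra, float)
    if spectra.ndim != 2 or spectra.shape[0] < 3:
        raise InsufficientSampleError("need >= 3 participants of electrode-averaged spectra")
    freqs = np.asarray(freqs, float)
    b = int(np.argmin(np.abs(freqs - target)))
    lo, hi = b - halfwidth_bins, b + halfwidth_bins
    if lo < 0 or hi >= len(freqs):
        raise InvalidParameterError("target too close to the spectrum edge for +-halfwidth bins")
    neigh = np.r_[lo:b, b + 1 : hi + 1]
    diff = spectra[:, b] - spectra[:, neigh].mean(axis=1)
    n = len(diff)
    md = float(diff.mean())
    se = diff.std(ddof=1) / np.sqrt(n)
    if se == 0.0:
        # exact null (target identically equals the neighbour mean)
        t, p = (0.0, 1.0) if md == 0.0 else (np.inf * np.sign(md), 0.0)
    else:
        t, p = sps.ttest_rel(spectra[:, b], spectra[:, neigh].mean(axis=1))
    tcrit = sps.t.ppf(0.975, n - 1)
    return PeakTestResult(
        target=float(freqs[b]),
        t=float(t),
        df=n - 1,
        p=float(p),
        p_fdr=float("nan"),
        md=md,
        ci=(md - tcrit * se, md + tcrit * se),
    )


def peak_tests(
    spectra: np.ndarray,
    freqs: np.ndarray,
    targets: Sequence[float] | RateSet,
    halfwidth_bins: int = 7,
) -> list[PeakTestResult]:
    """Peak tests at several targets with BH-FDR across them (one family
    per group x condition, i.e. per call)."""
    if isinstance(targets, RateSet):
        targets = targets.as_tuple()
    results = [peak_test(spectra, freqs, f, halfwidth_bins) for f in targets]
    adj = fdr_bh([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


# --------------------------------------------------------------------------
# bootstrap Monte-Carlo control against chance frequencies

@dataclass
class BootstrapResult:
    targets: np.ndarray          # target frequencies (Hz)
    target_itpc: np.ndarray      # mean ITPC per target
    chance_freqs: np.ndarray     # (n_chance,) sampled chance frequencies
    chance_itpc: np.ndarray      # (n_chance,) mean ITPC per chance frequency
    p_mc: np.ndarray             # Monte-Carlo p per target
    n_rep: int
    n_draw: int

    @property
    def p_floor(self) -> float:
        return 1.0 / (len(self.chance_freqs) + 1)

    @property
    def at_floor(self) -> np.ndarray:
        """Targets whose p equals the smallest attainable value (the rank
        statistic cannot go lower; smaller exceedance would need more
        chance frequencies)."""
        return np.isclose(self.p_mc, self.p_floor)


def eligible_chance_bins(
    freqs: np.ndarray,
    targets: Sequence[float],
    band: tuple[float, float] = (0.3, 5.0),
    guard_bins: int = 1,
) -> np.ndarray:
    """DFT bins usable as chance frequencies: inside ``band``, excluding
    every target, all integer harmonics of each target, and ``guard_bins``
    adjacent bins on either side of each excluded bin."""
    freqs = np.asarray(freqs, float)
    ok = (freqs > band[0]) & (freqs < band[1])
    fmax = band[1]
    for f0 in targets:
        for m in range(1, int(np.floor(fmax / f0)) + 1):
            b = int(np.argmin(np.abs(freqs - m * f0)))
            lo = max(0, b - guard_bins)
            ok[lo : b + guard_bins + 1] = False
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise InvalidParameterError("no eligible chance bins in the requested band")
    return idx


def boot_mean_itpc(arr: np.ndarray, sel: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Bootstrap-averaged ITPC of one participant at selected DFT bins.

    ``arr`` is trials x samples (a single phase source such as a stimulus
    envelope) or trials x channels x samples (ITPC is computed per channel
    and averaged over channels, matching electrode-averaged ITPC on
    average-referenced EEG -- averaging the *signal* over channels would
    cancel exactly there).  ``counts`` (repetitions x trials) holds the
    multinomial resampling counts of each repetition.
    """
    spec = np.fft.rfft(np.asarray(arr, np.float64), axis=-1)[..., sel]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (spec / np.abs(spec)).astype(np.complex64)
    z[~np.isfinite(z)] = 0.0
    if z.ndim == 2:
        z = z[:, None, :]
    K, C, B = z.shape
    n_rep = counts.shape[0]
    n_draw = int(counts[0].sum())
    zf = z.reshape(K, C * B)
    acc = np.zeros(C * B)
    step = max(1, 2**24 // max(1, C * B))
    cc = counts.astype(np.complex64)
    for r0 in range(0, n_rep, step):
        m = cc[r0 : r0 + step] @ zf
        acc += np.abs(m).sum(axis=0)
    return acc.reshape(C, B).mean(axis=0) / (n_draw * n_rep)


def bootstrap_monte_carlo(
    trial_data: Sequence[np.ndarray] | np.ndarray,
    sampling_rate: float,
    targets: Sequence[float] | RateSet,
    n_rep: int = 1000,
    n_draw: int = 50,
    n_chance: int = 500,
    rng: np.random.Generator | None = None,
    band: tuple[float, float] = (0.3, 5.0),
) -> BootstrapResult:
    """Chance-frequency Monte-Carlo test of ITPC at the target rates.

    ``trial_data``: one array per participant, either trials x samples
    (stimulus envelopes) or trials x channels x samples (EEG; channel-wise
    ITPC averaged over channels), all trimmed to the same analysed
    duration.  Per repetition, ``n_draw`` trials are drawn
    with replacement per participant and ITPC (resultant length) computed
    at the target bins and at ``n_chance`` chance bins; values are
    averaged over repetitions and participants, and each target's p is its
    rank in the chance distribution: p = (1 + #{chance >= target}) /
    (n_chance + 1) -- never exactly zero.

    At the 0.071 Hz resolution of 14.08 s epochs only a few dozen DFT bins
    in (0.3, 5) Hz survive the non-harmonic exclusions, so the ``n_chance``
    chance frequencies are sampled from the eligible bins *with
    replacement*.
    """
    if isinstance(targets, RateSet):
        targets = targets.as_tuple()
    rng = rng if rng is not None else np.random.default_rng()
    if isinstance(trial_data, np.ndarray) and trial_data.ndim in (2, 3):
        trial_data = [trial_data]
    n_samples = trial_data[0].shape[-1]
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    target_bins = np.array([int(np.argmin(np.abs(freqs - f))) for f in targets])
    pool = eligible_chance_bins(freqs, targets, band)
    chance_bins = rng.choice(pool, size=n_chance, replace=True)
    sel = np.r_[target_bins, chance_bins]

    means = []
    for arr in trial_data:
        arr = np.asarray(arr)
        if arr.shape[-1] != n_samples:
            raise InvalidParameterError("all participants must share the trial length")
        K = arr.shape[0]
        if K < n_draw:
            raise InsufficientSampleError(f"{K} trials available, {n_draw} required per draw")
        # n_draw i.i.d. draws with replacement == multinomial trial counts
        counts = rng.multinomial(n_draw, np.full(K, 1.0 / K), size=n_rep)  # (n_rep, K)
        means.append(boot_mean_itpc(arr, sel, counts))
    mean_itpc = np.mean(means, axis=0)
    t_vals = mean_itpc[: len(target_bins)]
    c_vals = mean_itpc[len(target_bins) :]
    p_mc = np.array([(1 + np.sum(c_vals >= tv)) / (n_chance + 1) for tv in t_vals])
    return BootstrapResult(
        targets=freqs[target_bins],
        target_itpc=t_vals,
        chance_freqs=freqs[chance_bins],
        chance_itpc=c_vals,
        p_mc=p_mc,
        n_rep=n_rep,
        n_draw=n_draw,
    )


# --------------------------------------------------------------------------
# electrode selection

def top_fraction_electrodes(
    itpc_map: ITPCMap, freq: float, fraction: float = 0.05
) -> np.ndarray:
    """Indices of the top-``fraction`` electrodes by ITPC at ``freq``
    (k = floor(fraction * n), at least 1; ties broken by ascending index)."""
    if not (0 < fraction <= 1):
        raise InvalidParameterError("fraction must be in (0, 1]")
    values = itpc_map.at(freq)
    n = len(values)
    if n == 0:
        raise InvalidParameterError("empty ITPC map")
    k = max(1, int(np.floor(fraction * n)))
    order = np.lexsort((np.arange(n), -values))
    return np.sort(order[:k])


# --------------------------------------------------------------------------
# attention x frequency ANOVA

@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    eta_sq: float
    posthoc: list[PeakTestResult] = field(default_factory=list)
    table: pd.DataFrame | None = None
    formulation: str = "mixed"


def _two_sample_summary(x: np.ndarray, y: np.ndarray, label: str) -> PeakTestResult:
    """Pooled-variance two-sample t with mean difference and 95% CI."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    t, p = sps.ttest_ind(x, y, equal_var=True)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df)
    se = sp * np.sqrt(1 / n1 + 1 / n2)
    md = float(x.mean() - y.mean())
    tc = sps.t.ppf(0.975, df)
    return PeakTestResult(
        target=float("nan"), t=float(t), df=df, p=float(p), p_fdr=float("nan"),
        md=md, ci=(md - tc * se, md + tc * se), label=label,
    )


def attention_anova(table: pd.DataFrame, formulation: str = "mixed") -> AnovaResult:
    """Group x tracking-frequency ANOVA on top-electrode ITPC.

    ``table`` is long-form with columns ``participant``, ``group`` (word /
    sentence), ``frequency`` (word_bin / sentence_bin) and ``itpc``; each
    participant contributes both frequency rows.  Default formulation
    treats frequency as a within-subject factor (mixed design); the
    fully-between variant is available for comparison.  ``eta_sq`` is the
    classical eta-squared of the interaction (SS_interaction / SS_total).
    """
    required = {"participant", "group", "frequency", "itpc"}
    if not required.issubset(table.columns):
        raise InvalidParameterError(f"table must have columns {sorted(required)}")
    counts = table.groupby(["group", "frequency"])["participant"].nunique()
    if len(counts) < 4 or (counts < 2).any():
        raise InvalidParameterError("need >= 2 participants in every group x frequency cell")
    ss_total = float(((table["itpc"] - table["itpc"].mean()) ** 2).sum())
    if formulation == "mixed":
        aov = pg.mixed_anova(
            data=table, dv="itpc", within="frequency", subject="participant", between="group"
        )
        row = aov.loc[aov["Source"] == "Interaction"].iloc[0]
        df = (int(row["DF1"]), int(row["DF2"]))
    elif formulation == "between":
        aov = pg.anova(data=table, dv="itpc", between=["group", "frequency"], detailed=True)
        row = aov.loc[aov["Source"] == "group * frequency"].iloc[0]
        df = (int(row["DF"]), int(aov.loc[aov["Source"] == "Residual", "DF"].iloc[0]))
    else:
        raise InvalidParameterError("formulation must be 'mixed' or 'between'")
    posthoc = []
    for freq_level in ("word_bin", "sentence_bin"):
        sub = table[table["frequency"] == freq_level]
        if sub.empty:
            continue
        groups = sorted(sub["group"].unique())
        a = sub.loc[sub["group"] == groups[-1], "itpc"].to_numpy()  # word group
        b = sub.loc[sub["group"] == groups[0], "itpc"].to_numpy()
        # report sentence-minus-word for the sentence bin, word-minus-... by level
        x, y = (b, a) if freq_level == "sentence_bin" else (a, b)
        posthoc.append(_two_sample_summary(x, y, label=freq_level))
    eta = float(row["SS"]) / ss_total if ss_total > 0 else 0.0
    return AnovaResult(
        F=float(row["F"]),
        df=df,
        p=float(row["p_unc"]),
        eta_sq=eta,
        posthoc=posthoc,
        table=aov,
        formulation=formulation,
    )


# --------------------------------------------------------------------------
# JZS Bayes factors

@dataclass
class BFMap:
    bf10: np.ndarray
    prior_scale: float

    @property
    def fraction_null(self) -> float:
        """Fraction of electrodes with substantial evidence for the null."""
        return float(np.mean(self.bf10 < 1.0 / 3.0))


def jzs_bf_from_t(t: float, n1: int, n2: int, prior_scale: float = np.sqrt(2) / 2) -> float:
    """Two-sample JZS Bayes factor (BF10) from a t statistic.

    Default Cauchy prior of scale ``prior_scale`` on the standardised
    effect, integrated numerically over the JZS mixing variable g
    (g ~ inverse-chi^2 as in the Rouder et al. default-prior t-test).
    """
    n_eff = n1 * n2 / (n1 + n2)
    df = n1 + n2 - 2
    if df < 1 or n_eff <= 0:
        raise InsufficientSampleError("each sample needs >= 2 observations")
    r2 = prior_scale**2

    def integrand(g: float) -> float:
        a = 1.0 + n_eff * g * r2
        return (
            a ** -0.5
            * (1.0 + t**2 / (a * df)) ** (-(df + 1) / 2.0)
            * (2 * np.pi) ** -0.5
            * g ** -1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    marginal_h1, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    marginal_h0 = (1.0 + t**2 / df) ** (-(df + 1) / 2.0)
    return float(marginal_h1 / marginal_h0)


def jzs_bf_two_sample(
    x: np.ndarray, y: np.ndarray, prior_scale: float = np.sqrt(2) / 2
) -> float:
    """JZS BF10 for the two-sample contrast of ``x`` vs ``y``."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientSampleError("each sample needs >= 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise InvalidParameterError("degenerate input: zero variance in both samples")
    t, _ = sps.ttest_ind(x, y, equal_var=True)
    return jzs_bf_from_t(float(t), len(x), len(y), prior_scale)


def bf_map_two_sample(
    a_maps: np.ndarray, b_maps: np.ndarray, prior_scale: float = np.sqrt(2) / 2
) -> BFMap:
    """Per-electrode two-sample JZS BF10 (``a_maps``/``b_maps``:
    participants x electrodes)."""
    a_maps, b_maps = np.asarray(a_maps, float), np.asarray(b_maps, float)
    bf = np.array(
        [
            jzs_bf_two_sample(a_maps[:, e], b_maps[:, e], prior_scale)
            for e in range(a_maps.shape[1])
        ]
    )
    return BFMap(bf10=bf, prior_scale=prior_scale)


# --------------------------------------------------------------------------
# null-calibration helper

def simulate_null_itpc(
    n_participants: int,
    n_bins: int,
    n_trials: int,
    rng: np.random.Generator,
    n_electrodes: int = 1,
) -> np.ndarray:
    """Participants x bins ITPC under phase-uniform trials (the
    no-phase-locking null used for type-I-error calibration).

    With ``n_electrodes`` > 1 the resultant lengths are averaged over that
    many independent electrodes, matching the electrode-averaged spectra
    the peak test consumes."""
    theta = rng.uniform(-np.pi, np.pi, size=(n_participants, n_trials, n_electrodes, n_bins))
    return resultant_length(theta, axis=1).mean(axis=1)
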