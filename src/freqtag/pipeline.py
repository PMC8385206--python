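"""End-to-end study orchestration: simulate -> preprocess -> ITPC -> stats.

``run_study`` executes the full analysis on a (synthetic or imported)
cohort and writes tabular reports:

* per-group/condition electrode-averaged ITPC spectra,
* peak tests at the word/phrase/sentence rates with FDR (the Table-1
  analogue),
* the bootstrap chance-frequency control for the stimulus envelope and
  for the EEG,
* cluster-mass permutation maps (sentential vs scrambled at the sentence
  bin, paired one-tailed; attention group contrasts at the word and
  sentence bins, independent two-tailed),
* the attention x frequency ANOVA on top-5% electrodes with post-hoc
  t-tests and per-electrode Bayes-factor maps,
* a provenance record (all parameters and derived seeds).

Participants are processed one at a time; only reduced statistics
(spectra, target-bin electrode maps, electrode-averaged trial series)
are retained, never more than one participant's raw epochs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ftio
from .cluster import build_adjacency, cluster_mass_test
from .design import DesignParams, InvalidParameterError, RateSet, derive_rates, synthesize_envelope
from .itpc import CONVENTIONS, compute_itpc, itpc_from_phases, trial_phases
from .layout import SensorLayout
from .preprocessing import TrimSpec, preprocess
from .simulate import CohortDataset, GeneratorParams, simulate_cohort
from .stats import (
    BootstrapResult,
    attention_anova,
    bf_map_two_sample,
    boot_mean_itpc,
    bootstrap_monte_carlo,
    eligible_chance_bins,
    peak_tests,
    top_fraction_electrodes,
)

__all__ = ["StatsParams", "StudyConfig", "ConfigError", "run_study", "StudyResult"]

TARGET_LABELS = ("word", "phrase", "sentence")


class ConfigError(ValueError):
    """Config schema violation; carries the offending keys."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid config: " + "; ".join(problems))


@dataclass(frozen=True)
class StatsParams:
    """Statistics settings of one study run."""

    n_perm: int = 1000
    n_chance: int = 500
    n_boot_rep: int = 1000
    n_boot_draw: int = 50
    top_fraction: float = 0.05
    halfwidth_bins: int = 7
    alpha_one_tailed: float = 0.05
    alpha_two_tailed: float = 0.025
    min_cluster_size: int = 4
    bf_prior_scale: float = float(np.sqrt(2) / 2)
    chance_band: tuple[float, float] = (0.3, 5.0)
    n_boot_channels: int = 16  # spaced electrode subset for the EEG bootstrap


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one study run."""

    design: DesignParams = field(default_factory=DesignParams)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    stats: StatsParams = field(default_factory=StatsParams)
    group_sizes: tuple[int, int, int] = (20, 23, 22)
    seed: int = 0
    itpc_convention: str = "resultant_length"
    subsample_fraction: float | None = None
    n_envelope_sessions: int = 12
    out_dir: str | None = None
    schema_version: int = 1

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        problems: list[str] = []
        kwargs: dict = {}
        known = {f.name: f for f in dataclasses.fields(cls)}
        nested = {"design": DesignParams, "generator": GeneratorParams, "stats": StatsParams}
        for key, value in raw.items():
            if key not in known:
                problems.append(f"unknown key '{key}'")
                continue
            if key in nested:
                sub_known = {f.name for f in dataclasses.fields(nested[key])}
                bad = [k for k in value if k not in sub_known]
                if bad:
                    problems += [f"unknown key '{key}.{k}'" for k in bad]
                    continue
                try:
                    value = {
                        k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                    }
                    value = nested[key](**value)
                except (TypeError, ValueError) as err:
                    problems.append(f"invalid value in '{key}': {err}")
                    continue
            if key == "group_sizes":
                value = tuple(value)
            kwargs[key] = value
        if "itpc_convention" in kwargs and kwargs["itpc_convention"] not in CONVENTIONS:
            problems.append(f"invalid value 'itpc_convention': must be one of {CONVENTIONS}")
        sf = kwargs.get("subsample_fraction")
        if sf is not None and not (0 < sf <= 1):
            problems.append("invalid value 'subsample_fraction': must be in (0, 1]")
        if problems:
            raise ConfigError(problems)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class StudyResult:
    """All result tables of one study run (also written as TSV)."""

    tables: dict[str, pd.DataFrame]
    provenance: dict
    cluster_details: dict
    layout: SensorLayout


# --------------------------------------------------------------------------


def _collect_participant(epochs, convention, rates, stats_params, trim):
    """Reduce one participant's epochs to the statistics inputs."""
    pre = preprocess(epochs, trim=trim)
    out = {}
    for condition in sorted(set(pre.conditions)):
        sub = pre.select(condition)
        phases = trial_phases(sub)
        imap = itpc_from_phases(phases, convention)
        out[condition] = {
            "freqs": imap.freqs,
            "spectrum": imap.electrode_average(),
            "maps": {lab: imap.at(f) for lab, f in zip(TARGET_LABELS, rates.as_tuple())},
            "itpc_map": imap,
            "n_trials": sub.n_trials,
            "_epochs": sub,
        }
    return out


def _subsampled_spectrum(epochs, convention, fraction, rng):
    """Electrode-averaged ITPC from a random fraction of trials."""
    n = epochs.n_trials
    k = max(2, int(round(fraction * n)))
    idx = np.sort(rng.choice(n, size=k, replace=False))
    sub = dataclasses.replace(
        epochs,
        data=epochs.data[idx],
        conditions=tuple(epochs.conditions[i] for i in idx),
    )
    return compute_itpc(sub, convention).electrode_average()


def run_study(config: StudyConfig, cohort: CohortDataset | None = None) -> StudyResult:
    """Execute the full pipeline for ``config`` and return/write reports."""
    rates = derive_rates(config.design)
    trim = TrimSpec.from_design(config.design)
    sp = config.stats
    if cohort is None:
        cohort = simulate_cohort(
            group_sizes=config.group_sizes,
            params=config.generator,
            seed=config.seed,
            design=config.design,
        )
    layout = cohort.layout
    adjacency = build_adjacency(layout)
    master = np.random.SeedSequence(entropy=config.seed, spawn_key=(101,))
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("boot_eeg", "boot_env", "cluster", "subsample"), master.spawn(4)
        )
    }

    # ---- streamed per-participant reduction -------------------------------
    # chance-frequency machinery is fixed up front so each participant's
    # bootstrap contribution can be computed in-stream and discarded
    fs = config.generator.sampling_rate
    n_keep = int(np.round(trim.analysed_duration * fs))
    freqs_full = np.fft.rfftfreq(n_keep, d=1.0 / fs)
    target_bins = np.array(
        [int(np.argmin(np.abs(freqs_full - f))) for f in rates.as_tuple()]
    )
    boot_rng = np.random.default_rng(seeds["boot_eeg"])
    pool = eligible_chance_bins(freqs_full, rates.as_tuple(), sp.chance_band)
    chance_bins = boot_rng.choice(pool, size=sp.n_chance, replace=True)
    sel_bins = np.r_[target_bins, chance_bins]

    records = []  # (spec, {condition: reduced})
    boot_means = []
    sub_spectra = []
    sub_rng = np.random.default_rng(seeds["subsample"])
    for spec, epochs in cohort:
        reduced = _collect_participant(epochs, config.itpc_convention, rates, sp, trim)
        if "sentential" in reduced:
            sub = reduced["sentential"].pop("_epochs")
            n_draw = min(sp.n_boot_draw, sub.n_trials)
            counts = boot_rng.multinomial(
                n_draw, np.full(sub.n_trials, 1.0 / sub.n_trials), size=sp.n_boot_rep
            )
            ch = np.unique(
                np.linspace(0, sub.n_channels - 1, sp.n_boot_channels).round().astype(int)
            )
            boot_means.append(boot_mean_itpc(sub.data[:, ch, :], sel_bins, counts))
        for condition in list(reduced):
            reduced[condition].pop("_epochs", None)
        if config.subsample_fraction:
            pre = preprocess(epochs, trim=trim)
            for condition in sorted(set(pre.conditions)):
                sub_spectra.append(
                    (
                        spec,
                        condition,
                        _subsampled_spectrum(
                            pre.select(condition),
                            config.itpc_convention,
                            config.subsample_fraction,
                            sub_rng,
                        ),
                    )
                )
        records.append((spec, reduced))
        del epochs
    freqs = records[0][1][next(iter(records[0][1]))]["freqs"]

    # ---- (a) ITPC spectra table ------------------------------------------
    spec_rows = []
    for group in ("passive", "word", "sentence"):
        for condition in ("sentential", "scrambled"):
            stack = [
                r[condition]["spectrum"] for s, r in records if s.group == group and condition in r
            ]
            if not stack:
                continue
            arr = np.vstack(stack)
            fmask = freqs <= 5.0  # report the analysis band
            for f, m, sd in zip(
                freqs[fmask], arr.mean(0)[fmask], arr.std(0, ddof=1)[fmask] / np.sqrt(len(arr))
            ):
                spec_rows.append(
                    {"group": group, "condition": condition, "freq_hz": f,
                     "mean_itpc": m, "sem_itpc": sd, "n": len(arr)}
                )
    itpc_table = pd.DataFrame(spec_rows)

    # ---- (b) peak tests with FDR (Table-1 analogue) -----------------------
    peak_rows = []
    for group in ("passive", "word", "sentence"):
        for condition in ("sentential", "scrambled"):
            stack = [
                r[condition]["spectrum"] for s, r in records if s.group == group and condition in r
            ]
            if len(stack) < 3:
                continue
            results = peak_tests(np.vstack(stack), freqs, rates, sp.halfwidth_bins)
            for lab, res in zip(TARGET_LABELS, results):
                peak_rows.append(
                    {"group": group, "condition": condition, "target": lab,
                     "target_hz": res.target, "n": len(stack), "t": res.t, "df": res.df,
                     "p": res.p, "p_fdr": res.p_fdr, "md": res.md,
                     "ci_low": res.ci[0], "ci_high": res.ci[1]}
                )
    peak_table = pd.DataFrame(peak_rows)

    # ---- (c) bootstrap chance-frequency control ---------------------------
    boot_rows = []
    # EEG: channel-averaged ITPC, bootstrap means accumulated in-stream
    eeg_mean = np.mean(boot_means, axis=0)
    n_targets = len(target_bins)
    eeg_p = np.array(
        [
            (1 + np.sum(eeg_mean[n_targets:] >= tv)) / (sp.n_chance + 1)
            for tv in eeg_mean[:n_targets]
        ]
    )
    boot_eeg = BootstrapResult(
        targets=freqs_full[target_bins],
        target_itpc=eeg_mean[:n_targets],
        chance_freqs=freqs_full[chance_bins],
        chance_itpc=eeg_mean[n_targets:],
        p_mc=eeg_p,
        n_rep=sp.n_boot_rep,
        n_draw=sp.n_boot_draw,
    )
    # envelope: synthetic audio sessions (sentential trial structure)
    env_rng = np.random.default_rng(seeds["boot_env"])
    fs_env = config.generator.sampling_rate
    n_seq = int(np.round(config.design.sequence_duration * fs_env))
    env_sessions = []
    members = cohort.members[: config.n_envelope_sessions]
    for spec in members:
        trials = [t for t in spec.plan.trials if t.condition == "sentential"]
        env = np.stack(
            [
                synthesize_envelope(t, config.design, fs_env, env_rng).samples[n_seq:]
                for t in trials
            ]
        )
        env_sessions.append(env)
    boot_env = bootstrap_monte_carlo(
        env_sessions, fs_env, rates,
        n_rep=sp.n_boot_rep, n_draw=min(sp.n_boot_draw, min(len(e) for e in env_sessions)),
        n_chance=sp.n_chance, rng=env_rng, band=sp.chance_band,
    )
    for source, boot in (("eeg", boot_eeg), ("envelope", boot_env)):
        for lab, f, v, p in zip(TARGET_LABELS, boot.targets, boot.target_itpc, boot.p_mc):
            boot_rows.append(
                {"source": source, "target": lab, "target_hz": f, "itpc": v,
                 "p_mc": p, "p_floor": boot.p_floor, "at_floor": bool(p <= boot.p_floor + 1e-12)}
            )
    boot_table = pd.DataFrame(boot_rows)

    # ---- (d) cluster-mass permutation tests -------------------------------
    def group_maps(groups, condition, target):
        stack = [
            r[condition]["maps"][target]
            for s, r in records
            if s.group in groups and condition in r
        ]
        if not stack:
            return np.zeros((0, layout.n_channels))
        return np.vstack(stack)

    cl_rng = np.random.default_rng(seeds["cluster"])
    cluster_rows = []
    cluster_details = {}

    contrasts = [
        ("sentential_vs_scrambled@sentence", "paired", "one",
         sp.alpha_one_tailed,
         group_maps(("passive", "word"), "sentential", "sentence"),
         group_maps(("passive", "word"), "scrambled", "sentence")),
        ("word_vs_passive@word", "independent", "two", sp.alpha_two_tailed,
         group_maps(("word",), "sentential", "word"),
         group_maps(("passive",), "sentential", "word")),
        ("word_vs_sentence@word", "independent", "two", sp.alpha_two_tailed,
         group_maps(("word",), "sentential", "word"),
         group_maps(("sentence",), "sentential", "word")),
        ("sentence_vs_pooled@sentence", "independent", "two", sp.alpha_two_tailed,
         group_maps(("sentence",), "sentential", "sentence"),
         group_maps(("passive", "word"), "sentential", "sentence")),
    ]
    for name, design_kind, tail, alpha, a, b in contrasts:
        if len(a) < 2 or len(b) < 2 or (design_kind == "paired" and len(a) != len(b)):
            continue
        res = cluster_mass_test(
            a, b, adjacency, design=design_kind, tail=tail, alpha=alpha,
            cluster_alpha=alpha, min_size=sp.min_cluster_size,
            n_perm=sp.n_perm, rng=cl_rng,
        )
        cluster_details[name] = res
        if not res.clusters:
            cluster_rows.append(
                {"contrast": name, "design": design_kind, "tail": tail, "alpha": alpha,
                 "cluster": -1, "sign": 0, "n_electrodes": 0, "mass": 0.0, "p": 1.0,
                 "significant": False, "electrodes": ""}
            )
        for ci, cl in enumerate(res.clusters):
            cluster_rows.append(
                {"contrast": name, "design": design_kind, "tail": tail, "alpha": alpha,
                 "cluster": ci, "sign": cl.sign, "n_electrodes": len(cl.electrodes),
                 "mass": cl.mass, "p": cl.p, "significant": cl.p <= res.cluster_alpha,
                 "electrodes": ",".join(layout.labels[e] for e in cl.electrodes)}
            )
    cluster_table = pd.DataFrame(cluster_rows)

    # ---- (e) ANOVA + post hoc + Bayes factor maps -------------------------
    anova_rows, posthoc_rows, bf_rows = [], [], []
    long_rows = []
    for spec, r in records:
        if spec.group not in ("word", "sentence") or "sentential" not in r:
            continue
        imap = r["sentential"]["itpc_map"]
        for lab, f in (("word_bin", rates.word_rate), ("sentence_bin", rates.sentence_rate)):
            top = top_fraction_electrodes(imap, f, sp.top_fraction)
            long_rows.append(
                {"participant": spec.participant_id, "group": spec.group,
                 "frequency": lab, "itpc": float(imap.at(f)[top].mean())}
            )
    anova_table_long = pd.DataFrame(long_rows)
    anova = None
    if not anova_table_long.empty:
        counts = anova_table_long.groupby(["group", "frequency"])["participant"].nunique()
        if len(counts) == 4 and (counts >= 2).all():
            anova = attention_anova(anova_table_long)
            anova_rows.append(
                {"effect": "group_x_frequency", "formulation": anova.formulation,
                 "F": anova.F, "df_num": anova.df[0], "df_den": anova.df[1],
                 "p": anova.p, "eta_sq": anova.eta_sq}
            )
            for ph in anova.posthoc:
                posthoc_rows.append(
                    {"frequency": ph.label, "t": ph.t, "df": ph.df, "p": ph.p,
                     "md": ph.md, "ci_low": ph.ci[0], "ci_high": ph.ci[1]}
                )
    # BF maps: attention contrasts at the word bin
    for name, groups_a, groups_b in (
        ("word_vs_passive@word", ("word",), ("passive",)),
        ("word_vs_sentence@word", ("word",), ("sentence",)),
    ):
        a = group_maps(groups_a, "sentential", "word")
        b = group_maps(groups_b, "sentential", "word")
        if len(a) < 2 or len(b) < 2:
            continue
        bfm = bf_map_two_sample(a, b, sp.bf_prior_scale)
        for e, bf in enumerate(bfm.bf10):
            bf_rows.append(
                {"contrast": name, "electrode": layout.labels[e], "bf10": bf,
                 "substantial_null": bf < 1 / 3, "substantial_effect": bf > 3}
            )

    tables = {
        "itpc_spectra": itpc_table,
        "peak_tests": peak_table,
        "bootstrap_control": boot_table,
        "cluster_tests": cluster_table,
        "anova": pd.DataFrame(anova_rows),
        "anova_posthoc": pd.DataFrame(posthoc_rows),
        "anova_input": anova_table_long,
        "bf_map": pd.DataFrame(bf_rows),
    }
    if sub_spectra:
        rows = []
        full = {(s.participant_id, c): r[c]["spectrum"] for s, r in records for c in r}
        for spec, condition, spectrum in sub_spectra:
            tb = [np.argmin(np.abs(freqs - f)) for f in rates.as_tuple()]
            for lab, bi in zip(TARGET_LABELS, tb):
                rows.append(
                    {"participant": spec.participant_id, "group": spec.group,
                     "condition": condition, "target": lab,
                     "itpc_full": full[(spec.participant_id, condition)][bi],
                     "itpc_subsampled": spectrum[bi],
                     "fraction": config.subsample_fraction}
                )
        tables["subsample_itpc"] = pd.DataFrame(rows)

    provenance = {
        "schema_version": config.schema_version,
        "config": config.to_dict(),
        "derived_seeds": seeds,
        "rates_hz": dict(zip(TARGET_LABELS, rates.as_tuple())),
        "n_participants": len(records),
        "freq_resolution_hz": float(freqs[1] - freqs[0]),
    }
    result = StudyResult(
        tables=tables, provenance=provenance, cluster_details=cluster_details, layout=layout
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            ftio.write_table(out / f"{name}.tsv", frame)
        ftio.write_provenance(out / "provenance.json", provenance)
    return result
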