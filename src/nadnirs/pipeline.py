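"""End-to-end orchestration: simulate, preprocess both branches, test, assemble.

`run_pipeline` executes the full analysis on a simulated cohort from a single
configuration: stimulus lists and session schedules, two-wavelength recordings,
the task branch (ΔHb conversion, trial rejection, 0.02–0.5 Hz filtering, 28-s
block averaging, window means, paired permutation t tests, seed selection) and,
for sessions with rest phases, the connectivity branch (wavelet correction,
motion masking, 0.01–0.1 Hz filtering, DPF conversion, >= 90-s segment
extraction, Fisher-z matrices, group and contrast tests, seed-based
connectivity-activation correlations, network assembly, baseline dependence).
Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import AnalysisParams
from .synthdata import (SimParams, simulate_cohort, DEFAULT_SEED_CHANNELS,
                        NEONATE_PREFRONTAL, make_probe_layout)
from .preproc_task import preprocess_task_subject, CONDITIONS
from .activation_stats import window_means, run_contrasts, select_seeds, CONTRASTS
from .preproc_fc import preprocess_fc_subject, FC_PHASES
from .fc_network import (fc_matrix, group_fc_test, fc_contrast,
                         seed_activation_correlation, assemble_network,
                         baseline_dependence, pair_list, LearningNetwork)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineResult",
           "subject_activation_table"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    experiment: str = "neonate"
    n_subjects: int | None = None        # None -> 21 neonates / 19 infants
    seed: int = 0
    n_perm: int | None = None            # None -> AnalysisParams.n_perm (50,000)
    params: AnalysisParams = field(default_factory=AnalysisParams)
    sim: SimParams = field(default_factory=SimParams)
    out_dir: str | None = None
    #: None -> recompute seeds from the data with a prefrontal region mask;
    #: a tuple -> fixed seed-channel preset (the study's six prefrontal channels
    #: are available as synthdata.DEFAULT_SEED_CHANNELS)
    seed_channels: tuple[int, ...] | None = None
    run_fc: bool = True

    def resolved_n_subjects(self) -> int:
        if self.n_subjects is not None:
            return self.n_subjects
        return 21 if self.experiment == "neonate" else 19

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = AnalysisParams(**{k: tuple(v) if isinstance(v, list) else v
                                            for k, v in d["params"].items()})
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimParams(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in d["sim"].items()})
        if isinstance(d.get("seed_channels"), list):
            d["seed_channels"] = tuple(d["seed_channels"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the analysis-defining fields (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validate_config(config: PipelineConfig | dict | None) -> PipelineConfig:
    """Normalize and range-check a configuration; raise listing every problem."""
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        try:
            config = PipelineConfig.from_dict(config)
        except TypeError as e:
            raise ConfigError(f"unknown configuration field: {e}") from None
    errors = []
    if config.experiment not in ("neonate", "infant"):
        errors.append(f"experiment must be neonate|infant, got {config.experiment!r}")
    if config.resolved_n_subjects() < 1:
        errors.append("n_subjects must be >= 1")
    if config.n_perm is not None and config.n_perm < 1:
        errors.append("n_perm must be >= 1")
    if config.seed < 0:
        errors.append("seed must be >= 0")
    try:
        config.params.validate(config.sim.fs)
    except ValueError as e:
        errors.append(str(e))
    try:
        config.sim.validate()
    except ValueError as e:
        errors.append(str(e))
    if errors:
        raise ConfigError("; ".join(errors))
    return config


def subject_activation_table(stats: pd.DataFrame, channels: list[int]) -> pd.DataFrame:
    """Per-subject Incorrect-Correct window-mean (HbO) at the given channels.

    This is the "degree of response" entering the seed-based correlation stage:
    rows indexed by subject, one column per channel.
    """
    hbo = stats[(stats.chromophore == "HbO") & stats.channel.isin(channels)]
    piv = hbo.pivot_table(index=["subject", "channel"], columns="condition",
                          values="window_mean")
    diff = (piv["incorrect_trial"] - piv["correct_trial"]).unstack("channel")
    diff.columns = [int(c) for c in diff.columns]
    return diff


@dataclass
class PipelineResult:
    config: PipelineConfig
    summary: dict
    activation_results: pd.DataFrame
    window_stats: pd.DataFrame
    seeds: list[int]
    group_fc: dict               # phase -> DataFrame
    contrasts: dict              # name -> DataFrame
    seed_corrs: pd.DataFrame | None
    network: LearningNetwork | None
    baseline_dep: pd.DataFrame | None


def run_pipeline(config: PipelineConfig | dict | None = None,
                 verbose: bool = False) -> PipelineResult:
    """Execute every stage on a freshly simulated cohort; see module docstring."""
    cfg = validate_config(config)
    log = print if verbose else (lambda *a, **k: None)
    n_subjects = cfg.resolved_n_subjects()
    n_perm = cfg.n_perm if cfg.n_perm is not None else cfg.params.n_perm

    log(f"[simulate] {n_subjects} {cfg.experiment} subjects, seed={cfg.seed}")
    recordings = simulate_cohort(n_subjects, cfg.experiment, cfg.sim, cfg.seed)
    layout = recordings[0].layout

    log("[task] preprocessing + block averaging")
    averages = [preprocess_task_subject(r, cfg.params) for r in recordings]
    included = [a for a in averages if a.included]
    stats = window_means(averages, cfg.params, cfg.experiment)

    log(f"[activation] permutation tests (n_perm={n_perm})")
    results = run_contrasts(stats, cfg.params, seed=cfg.seed, n_perm=n_perm)
    if cfg.seed_channels is not None:
        seeds = list(cfg.seed_channels)
    else:
        mask = (list(NEONATE_PREFRONTAL) if cfg.experiment == "neonate" else None)
        seeds = select_seeds(results, cfg.params.alpha, region_mask=mask)

    mean_valid = {}
    for cond in CONDITIONS:
        per = [np.mean(a.n_valid[cond]) for a in included]
        mean_valid[cond] = float(np.mean(per)) if per else float("nan")

    summary = {
        "config_hash": cfg.config_hash(),
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "n_subjects": n_subjects,
        "n_included_task": len(included),
        "mean_valid_blocks": mean_valid,
        "significant_channels": {
            c: sorted(int(ch) for ch in results[
                (results.contrast == c) & (results.chromophore == "HbO")
                & results.computed & (results.p < cfg.params.alpha)].channel)
            for c in CONTRASTS},
        "seed_channels": seeds,
    }

    group_fc: dict = {}
    contrasts: dict = {}
    seed_corrs = network = baseline_dep = None

    has_rest = cfg.run_fc and cfg.experiment == "neonate"
    if has_rest:
        log("[fc] connectivity preprocessing + matrices")
        matrices: dict[str, list] = {ph: [] for ph in FC_PHASES}
        for rec in recordings:
            segments = preprocess_fc_subject(rec, cfg.params)
            for ph, seg in segments.items():
                if seg.usable:
                    matrices[ph].append(fc_matrix(seg))
        summary["n_valid_fc"] = {ph: len(ms) for ph, ms in matrices.items()}

        for ph, ms in matrices.items():
            if len(ms) >= 2:
                g = group_fc_test(ms, cfg.params.bonferroni_levels)
                group_fc[ph] = g
        summary["significant_fc_counts"] = {
            ph: {f"{lv:g}": int(g[f"passed_{lv:g}"].sum())
                 for lv in cfg.params.bonferroni_levels}
            for ph, g in group_fc.items()}

        log("[fc] phase contrasts + network assembly")
        for name, a, b in (("Learning-PreRest", "Learning", "PreRest"),
                           ("PostRest-PreRest", "PostRest", "PreRest")):
            con = fc_contrast(matrices[a], matrices[b])
            contrasts[name] = con
            if len(con):
                sig = con.computed & (con.p < cfg.params.alpha)
                summary[f"n_changed_fc_{name}"] = int(sig.sum())

        con = contrasts.get("Learning-PreRest")
        if con is not None and len(con) and seeds:
            subjects = con.attrs["subjects"]
            delta_z = con.attrs["delta_z"]
            eligible = (con.computed & (con.p < cfg.params.alpha)).values
            activation = subject_activation_table(stats, seeds)
            seed_corrs = seed_activation_correlation(
                delta_z, activation, seeds, eligible, layout.n_channels,
                subjects, cfg.params.alpha)
            network = assemble_network(seed_corrs, delta_z, activation, seeds,
                                       eligible, layout.n_channels, subjects,
                                       cfg.params.alpha)
            summary["network_edges"] = sorted(network.edge_pairs)
            summary["n_network_edges"] = len(network.edge_pairs)

            pre_ms = {m.subject: m for m in matrices["PreRest"]}
            z_pre = np.vstack([pre_ms[s].z for s in subjects])
            pairs = pair_list(layout.n_channels)
            edge_idx = [k for k, pr in enumerate(pairs)
                        if tuple(sorted(pr)) in network.edge_pairs]
            baseline_dep = baseline_dependence(z_pre, delta_z, edge_idx)
            if len(baseline_dep):
                sig_neg = baseline_dep.computed & (baseline_dep.p < cfg.params.alpha) \
                    & (baseline_dep.r < 0)
                summary["n_negative_baseline_dependence"] = int(sig_neg.sum())

    result = PipelineResult(cfg, summary, results, stats, seeds, group_fc,
                            contrasts, seed_corrs, network, baseline_dep)
    if cfg.out_dir:
        _write_outputs(result, Path(cfg.out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    ff = "%.6g"
    result.activation_results.to_csv(out / "activation_tests.tsv", sep="\t",
                                     index=False, float_format=ff)
    result.window_stats.to_csv(out / "window_means.tsv", sep="\t", index=False,
                               float_format=ff)
    for ph, g in result.group_fc.items():
        g.to_csv(out / f"group_fc_{ph}.tsv", sep="\t", index=False, float_format=ff)
    for name, c in result.contrasts.items():
        c.to_csv(out / f"fc_contrast_{name}.tsv", sep="\t", index=False,
                 float_format=ff)
    if result.seed_corrs is not None:
        result.seed_corrs.to_csv(out / "seed_correlations.tsv", sep="\t",
                                 index=False, float_format=ff)
    if result.network is not None:
        result.network.edges.to_csv(out / "network_edges.tsv", sep="\t",
                                    index=False, float_format=ff)
    if result.baseline_dep is not None:
        result.baseline_dep.to_csv(out / "baseline_dependence.tsv", sep="\t",
                                   index=False, float_format=ff)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2,
                                                 default=str))
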