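"""Window-mean statistics and channel-wise paired permutation t tests.

For each subject, channel and condition the response is summarised as the mean
ΔHbO (or ΔHbR) within a fixed post-onset window — 7.5–12.5 s for neonates,
10.5–15.5 s for 6- to 7-month-olds — alongside the 5-s pre-stimulus baseline
mean. Group inference uses paired permutation t tests: the null distribution is
built by random sign flips of the per-subject differences (or exhaustive
enumeration of all 2^n sign patterns for small n), with the add-one estimator
p = (1 + #{|t*| >= |t|}) / (1 + n_perm), which is two-sided and strictly positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import AnalysisParams
from .preproc_task import SubjectAverage, CONDITIONS

__all__ = [
    "window_means", "permutation_paired_ttest", "run_contrasts", "select_seeds",
    "CONTRASTS",
]

CONTRASTS = ("Correct-Baseline", "Incorrect-Baseline", "Incorrect-Correct")
_COND_OF = {"Correct": "correct_trial", "Incorrect": "incorrect_trial"}


class StatsError(ValueError):
    pass


def window_means(averages: list[SubjectAverage],
                 params: AnalysisParams = AnalysisParams(),
                 experiment: str | None = None) -> pd.DataFrame:
    """Tabulate window and baseline means per subject/channel/condition/chromophore.

    Only included subjects contribute. The response window is taken from the
    experiment's configuration (half-open sample indexing from stimulus onset);
    ``baseline_mean`` is the mean of the 5-s pre-stimulus segment of the same
    condition's average epoch.
    """
    rows = []
    for avg in averages:
        if not avg.included:
            continue
        exp = experiment or avg.experiment
        lo, hi = params.window(exp)
        fs = avg.sample_rate
        pre = int(round(params.pre_baseline * fs))
        i0, i1 = pre + int(np.floor(lo * fs)), pre + int(np.floor(hi * fs))
        n_ep = next(iter(avg.mean_hbo.values())).shape[-1]
        if i1 > n_ep:
            raise StatsError(f"window {(lo, hi)} s exceeds the {n_ep}-sample epoch")
        for chrom, table in (("HbO", avg.mean_hbo), ("HbR", avg.mean_hbr)):
            for cond in CONDITIONS:
                ep = table[cond]
                wm = ep[:, i0:i1].mean(axis=1)
                bm = ep[:, :pre].mean(axis=1)
                for ch in range(ep.shape[0]):
                    rows.append({
                        "subject": avg.subject, "channel": ch + 1,
                        "condition": cond, "chromophore": chrom,
                        "window_mean": wm[ch], "baseline_mean": bm[ch],
                        "channel_valid": bool(avg.channel_valid[ch]),
                    })
    return pd.DataFrame(rows)


def _t_stat(d: np.ndarray) -> float:
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return np.inf * np.sign(d.mean()) if d.mean() != 0 else 0.0
    return float(d.mean() / (sd / np.sqrt(n)))


def _perm_t(signed: np.ndarray) -> np.ndarray:
    """Row-wise paired t statistics of a (n_perm, n) matrix of signed differences."""
    n = signed.shape[1]
    mean = signed.mean(axis=1)
    sd = signed.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0
    return t


def permutation_paired_ttest(x, y, n_perm: int = 50_000, seed: int | None = 0,
                             exact: bool = False):
    """Two-sided paired permutation t test on d = x - y.

    Returns ``(t, p, degenerate)``. Monte-Carlo mode flips the sign of each
    subject's difference independently and uses the add-one estimator
    ``p = (1 + #{|t*| >= |t|}) / (1 + n_perm)``. With ``exact=True`` (n <= 20)
    all 2^n sign patterns are enumerated and ``p = #{|t*| >= |t|} / 2^n``.
    All-zero differences are flagged degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise StatsError("x and y must be 1-d arrays of equal length n >= 2")
    d = x - y
    n = len(d)
    if np.all(d == 0):
        return 0.0, 1.0, True
    t_obs = _t_stat(d)
    if exact:
        if n > 20:
            raise StatsError("exact enumeration limited to n <= 20")
        patterns = np.arange(2 ** n, dtype=np.int64)
        signs = 1 - 2 * ((patterns[:, None] >> np.arange(n)) & 1)
        t_null = _perm_t(signs * d)
        p = float(np.mean(np.abs(t_null) >= abs(t_obs) - 1e-12))
        return t_obs, p, False
    rng = np.random.default_rng(seed)
    count = 0
    batch = 10_000
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        signs = rng.integers(0, 2, size=(b, n)) * 2 - 1
        t_null = _perm_t(signs * d)
        count += int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12))
        done += b
    p = (1 + count) / (1 + n_perm)
    return t_obs, float(p), False


def run_contrasts(stats: pd.DataFrame, params: AnalysisParams = AnalysisParams(),
                  seed: int = 0, n_perm: int | None = None,
                  valid_only: bool = True) -> pd.DataFrame:
    """Per channel x chromophore x contrast permutation test table.

    Condition-vs-baseline contrasts pair each subject's window mean against the
    same condition's pre-stimulus baseline mean; Incorrect-Correct pairs the two
    conditions' window means. Channels with fewer than 2 contributing subjects
    are flagged ``computed=False``. Seeding is counter-based per
    (channel, contrast, chromophore) so results do not depend on execution order.
    """
    n_perm = params.n_perm if n_perm is None else n_perm
    if stats.empty:
        return pd.DataFrame(columns=["channel", "chromophore", "contrast", "t", "p",
                                     "n_subjects", "computed"])
    if valid_only and "channel_valid" in stats:
        stats = stats[stats.channel_valid]
    rows = []
    for (ch, chrom), g in stats.groupby(["channel", "chromophore"], sort=True):
        pivot_w = g.pivot_table(index="subject", columns="condition",
                                values="window_mean")
        pivot_b = g.pivot_table(index="subject", columns="condition",
                                values="baseline_mean")
        for ci, contrast in enumerate(CONTRASTS):
            if contrast == "Incorrect-Correct":
                cols = ("incorrect_trial", "correct_trial")
                if not all(c in pivot_w for c in cols):
                    x = y = np.array([])
                else:
                    sub = pivot_w[list(cols)].dropna()
                    x, y = sub[cols[0]].values, sub[cols[1]].values
            else:
                cond = _COND_OF[contrast.split("-")[0]]
                if cond not in pivot_w:
                    x = y = np.array([])
                else:
                    sub = pd.concat([pivot_w[cond], pivot_b[cond]], axis=1).dropna()
                    x, y = sub.iloc[:, 0].values, sub.iloc[:, 1].values
            chrom_i = 0 if chrom == "HbO" else 1
            if len(x) < 2:
                rows.append({"channel": ch, "chromophore": chrom, "contrast": contrast,
                             "t": np.nan, "p": np.nan, "n_subjects": len(x),
                             "computed": False})
                continue
            sub_seed = np.random.SeedSequence([seed, int(ch), ci, chrom_i])
            t, p, degen = permutation_paired_ttest(
                x, y, n_perm=n_perm, seed=sub_seed)
            rows.append({"channel": ch, "chromophore": chrom, "contrast": contrast,
                         "t": t, "p": p, "n_subjects": len(x),
                         "computed": not degen})
    return pd.DataFrame(rows)


def select_seeds(results: pd.DataFrame, alpha: float = 0.05,
                 region_mask: list[int] | None = None,
                 contrast: str = "Incorrect-Correct",
                 chromophore: str = "HbO") -> list[int]:
    """Channels significant on the chosen contrast, optionally region-restricted.

    The study's seed definition: prefrontal channels with p < alpha on the HbO
    Incorrect-Correct contrast during the test phase. Returns a sorted channel
    list; empty output is a flagged outcome, not an error.
    """
    sel = results[(results.contrast == contrast)
                  & (results.chromophore == chromophore)
                  & results.computed
                  & (results.p < alpha)]
    seeds = sorted(int(c) for c in sel.channel)
    if region_mask is not None:
        seeds = [c for c in seeds if c in set(region_mask)]
    return seeds
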