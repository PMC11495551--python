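"""Functional-connectivity matrices, group tests, and network discovery.

Per subject and phase, connectivity is the Pearson correlation of the whole
ΔHbO time course over all channel pairs ((46 x 45)/2 = 1,035 pairs for the
46-channel layout), Fisher r-to-z transformed. Group analyses: one-sample t
tests of z against zero per phase (Bonferroni-corrected at five family-wise
levels), paired t tests for phase contrasts (Learning vs Pre-Rest, Post-Rest
vs Pre-Rest, uncorrected p < 0.05), Pearson correlations between
connectivity-change strength and test-phase activation at prefrontal seed
channels, and assembly of the learning-related network from seed-touching
edges plus non-seed edges whose change correlates with every seed's activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .preproc_fc import PhaseSegment

__all__ = [
    "FCMatrix", "LearningNetwork", "pair_list", "fc_matrix", "group_fc_test",
    "fc_contrast", "seed_activation_correlation", "assemble_network",
    "baseline_dependence", "Z_CLIP",
]

#: |r| ceiling before atanh, keeping z finite for degenerate pairs
Z_CLIP = 1.0 - 1e-7


class FCError(ValueError):
    pass


def pair_list(n_channels: int) -> list[tuple[int, int]]:
    """Upper-triangular channel pairs (1-based ids), row-major order."""
    return [(i + 1, j + 1) for i in range(n_channels) for j in range(i + 1, n_channels)]


@dataclass
class FCMatrix:
    """One subject-phase connectivity vector over the condensed upper triangle."""
    subject: int
    phase: str
    z: np.ndarray                # (n_pairs,)
    flagged: np.ndarray          # bool, True where r was degenerate/clipped
    n_channels: int
    n_samples: int

    @property
    def n_pairs(self) -> int:
        return len(self.z)


def fc_matrix(segment: PhaseSegment | np.ndarray, subject: int = 0,
              phase: str = "", min_samples: int = 900) -> FCMatrix:
    """Pairwise Pearson r over the whole segment on ΔHbO, Fisher transformed.

    ``segment`` may be a :class:`PhaseSegment` (must be usable, >= 900 samples)
    or a raw (n_channels, n_samples) array. Zero-variance channels yield
    flagged, NaN pairs; |r| at the clip ceiling is flagged but kept finite
    (z = atanh(clip(r, ±(1 - 1e-7)))).
    """
    if isinstance(segment, PhaseSegment):
        if not segment.usable or segment.hbo is None:
            raise FCError(f"segment {segment.phase} unusable "
                          f"({segment.duration:.1f} s < floor)")
        if segment.n_samples < min_samples:
            raise FCError(f"segment has {segment.n_samples} samples < {min_samples}")
        data = segment.hbo
        subject, phase = segment.subject, segment.phase
    else:
        data = np.asarray(segment, dtype=float)
    n_ch, n_samp = data.shape
    sd = data.std(axis=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    iu = np.triu_indices(n_ch, k=1)
    r_vec = r[iu]
    flagged = np.zeros(len(r_vec), dtype=bool)
    undef = zero_var[iu[0]] | zero_var[iu[1]] | ~np.isfinite(r_vec)
    clipped = np.abs(r_vec) >= Z_CLIP
    flagged |= undef | clipped
    z = np.full(len(r_vec), np.nan)
    ok = ~undef
    z[ok] = np.arctanh(np.clip(r_vec[ok], -Z_CLIP, Z_CLIP))
    return FCMatrix(subject, phase, z, flagged, n_ch, n_samp)


def _stack(matrices: list[FCMatrix]) -> tuple[np.ndarray, int]:
    n_ch = matrices[0].n_channels
    if any(m.n_channels != n_ch for m in matrices):
        raise FCError("mixed channel counts")
    return np.vstack([m.z for m in matrices]), n_ch


def group_fc_test(matrices: list[FCMatrix],
                  levels: tuple[float, ...] = (0.05, 5e-6, 5e-7, 5e-8, 5e-9)
                  ) -> pd.DataFrame:
    """One-sample t of Fisher z against zero per pair, Bonferroni-read-out.

    ``passed_<level>`` columns hold the Bonferroni-corrected decision at each
    family-wise level (per-pair threshold = level / n_pairs); passing a stricter
    level implies passing every looser one.
    """
    if len(matrices) < 2:
        raise FCError("need >= 2 subjects")
    z, n_ch = _stack(matrices)
    n_pairs = z.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sstats.ttest_1samp(z, 0.0, axis=0, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    pairs = pair_list(n_ch)
    out = pd.DataFrame({
        "ch_a": [a for a, _ in pairs], "ch_b": [b for _, b in pairs],
        "phase": matrices[0].phase,
        "mean_z": np.nanmean(z, axis=0), "t": t, "p": p,
        "n_subjects": np.sum(~np.isnan(z), axis=0),
    })
    for level in sorted(levels, reverse=True):
        out[f"passed_{level:g}"] = p < level / n_pairs
    return out


def fc_contrast(matrices_a: list[FCMatrix], matrices_b: list[FCMatrix]
                ) -> pd.DataFrame:
    """Paired t per pair on z differences (phase A minus phase B).

    Subjects are matched by subject id; fewer than 2 paired subjects flags the
    whole contrast not-computed. Zero-variance differences yield t = 0, p = 1.
    Adds ``delta_z`` rows per subject via the companion array returned in
    ``attrs['delta_z']`` (subjects x pairs) for downstream correlation stages.
    """
    by_a = {m.subject: m for m in matrices_a}
    by_b = {m.subject: m for m in matrices_b}
    common = sorted(set(by_a) & set(by_b))
    if len(common) < 2:
        df = pd.DataFrame(columns=["ch_a", "ch_b", "t", "p", "direction", "computed"])
        df.attrs["delta_z"] = np.zeros((0, 0))
        df.attrs["subjects"] = []
        return df
    za = np.vstack([by_a[s].z for s in common])
    zb = np.vstack([by_b[s].z for s in common])
    d = za - zb
    n = len(common)
    mean = np.nanmean(d, axis=0)
    sd = np.nanstd(d, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * sstats.t.sf(np.abs(t), df=n - 1)
    degenerate = (sd == 0) | ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    n_ch = by_a[common[0]].n_channels
    pairs = pair_list(n_ch)
    out = pd.DataFrame({
        "ch_a": [a for a, _ in pairs], "ch_b": [b for _, b in pairs],
        "t": t, "p": p,
        "direction": np.where(mean > 0, "increased", "decreased"),
        "computed": ~np.isnan(mean),
    })
    out.attrs["delta_z"] = d
    out.attrs["subjects"] = common
    return out


def seed_activation_correlation(delta_z: np.ndarray, activation: pd.DataFrame,
                                seeds: list[int], eligible: np.ndarray,
                                n_channels: int, subjects: list[int],
                                alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r between connectivity change and seed activation, across subjects.

    ``delta_z`` is (subjects x pairs); ``activation`` indexes subject ->
    per-seed activation (Incorrect-Correct window mean at that channel);
    ``eligible`` is a boolean pair mask (significant change AND touching >= 1
    seed is applied here). Combinations with n < 3 subjects or constant inputs
    are flagged not-computed.
    """
    pairs = pair_list(n_channels)
    seed_set = set(seeds)
    rows = []
    act = activation.loc[[s for s in subjects if s in activation.index]]
    for k, (a, b) in enumerate(pairs):
        if not eligible[k] or not ({a, b} & seed_set):
            continue
        keep = [i for i, s in enumerate(subjects) if s in act.index]
        dz = delta_z[keep, k]
        for seed in seeds:
            y = act.loc[[subjects[i] for i in keep], seed].values
            ok = np.isfinite(dz) & np.isfinite(y)
            if ok.sum() < 3 or np.std(dz[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append({"ch_a": a, "ch_b": b, "seed": seed, "r": np.nan,
                             "p": np.nan, "n": int(ok.sum()), "computed": False,
                             "significant": False})
                continue
            r, p = sstats.pearsonr(dz[ok], y[ok])
            rows.append({"ch_a": a, "ch_b": b, "seed": seed, "r": r, "p": p,
                         "n": int(ok.sum()), "computed": True,
                         "significant": bool(p < alpha)})
    return pd.DataFrame(rows,
                        columns=["ch_a", "ch_b", "seed", "r", "p", "n",
                                 "computed", "significant"])


@dataclass
class LearningNetwork:
    """The assembled set of learning-related connectivity edges."""
    seeds: tuple[int, ...]
    edges: pd.DataFrame          # ch_a, ch_b, edge_type, seed, r, p

    @property
    def edge_pairs(self) -> set[tuple[int, int]]:
        return {tuple(sorted((int(a), int(b))))
                for a, b in zip(self.edges.ch_a, self.edges.ch_b)}

    def to_graph(self):
        import networkx as nx
        g = nx.Graph()
        for _, row in self.edges.iterrows():
            g.add_edge(int(row.ch_a), int(row.ch_b),
                       edge_type=row.edge_type, r=row.r, p=row.p)
        return g


def assemble_network(seed_corrs: pd.DataFrame, delta_z: np.ndarray,
                     activation: pd.DataFrame, seeds: list[int],
                     eligible: np.ndarray, n_channels: int, subjects: list[int],
                     alpha: float = 0.05) -> LearningNetwork:
    """Assemble the learning-related network.

    Seed edges: eligible pairs touching a seed whose connectivity change
    correlates significantly with the activation of at least one seed channel
    (every eligible pair is tested against all seeds; the hit metadata records
    which). Non-seed candidates: the non-seed channels appearing in those seed
    edges; a non-seed pair joins the network only if its change correlates
    significantly with the activation of *every* seed.
    """
    seed_set = set(seeds)
    rows = []
    if not seed_corrs.empty:
        sig = seed_corrs[seed_corrs.significant]
        for _, row in sig.iterrows():
            rows.append({"ch_a": int(row.ch_a), "ch_b": int(row.ch_b),
                         "edge_type": "seed_edge", "seed": int(row.seed),
                         "r": row.r, "p": row.p})
    nonseed_channels = sorted({c for e in rows for c in (e["ch_a"], e["ch_b"])}
                              - seed_set)
    pairs = pair_list(n_channels)
    act = activation.loc[[s for s in subjects if s in activation.index]]
    keep = [i for i, s in enumerate(subjects) if s in act.index]
    for k, (a, b) in enumerate(pairs):
        if not eligible[k] or ({a, b} & seed_set):
            continue
        if a not in nonseed_channels or b not in nonseed_channels:
            continue
        dz = delta_z[keep, k]
        stats_all = []
        for seed in seeds:
            y = act[seed].values
            ok = np.isfinite(dz) & np.isfinite(y)
            if ok.sum() < 3 or np.std(dz[ok]) == 0 or np.std(y[ok]) == 0:
                stats_all = []
                break
            r, p = sstats.pearsonr(dz[ok], y[ok])
            if p >= alpha:
                stats_all = []
                break
            stats_all.append((seed, r, p))
        for seed, r, p in stats_all:
            rows.append({"ch_a": a, "ch_b": b, "edge_type": "nonseed_edge",
                         "seed": seed, "r": r, "p": p})
    edges = pd.DataFrame(rows, columns=["ch_a", "ch_b", "edge_type", "seed",
                                        "r", "p"])
    return LearningNetwork(tuple(seeds), edges)


def baseline_dependence(z_baseline: np.ndarray, delta_z: np.ndarray,
                        pair_indices: list[int] | None = None) -> pd.DataFrame:
    """Correlate baseline connectivity with its subsequent change, per edge.

    For each selected pair, Pearson r across subjects between Pre-Rest z and
    (Learning - Pre-Rest) z. Note the built-in regression-to-baseline bias of
    this statistic: for i.i.d. baseline and follow-up, corr(X, Y - X) has
    expectation -1/sqrt(2) ~= -0.71, so negative values arise even without any
    physiological coupling; results should be read against that analytic null.
    """
    n_subj, n_pairs = z_baseline.shape
    if delta_z.shape != z_baseline.shape:
        raise FCError("z_baseline and delta_z must align (subjects x pairs)")
    idx = range(n_pairs) if pair_indices is None else pair_indices
    rows = []
    for k in idx:
        x, d = z_baseline[:, k], delta_z[:, k]
        ok = np.isfinite(x) & np.isfinite(d)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(d[ok]) == 0:
            rows.append({"pair_index": k, "r": np.nan, "p": np.nan,
                         "n": int(ok.sum()), "computed": False})
            continue
        r, p = sstats.pearsonr(x[ok], d[ok])
        rows.append({"pair_index": k, "r": r, "p": p, "n": int(ok.sum()),
                     "computed": True})
    return pd.DataFrame(rows)
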