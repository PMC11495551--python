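"""Task-branch preprocessing: OD -> ΔHb, trial rejection, filtering, block averaging.

Order of operations: optical density is inverted to ΔHbO/ΔHbR (mM·mm, no pathlength
division); trial-level artifact flags are computed on the *unfiltered* series; the
continuous series is then band-pass filtered (0.02–0.5 Hz, zero-phase third-order
Butterworth), segmented into 28-s blocks (5-s pre-baseline + 11.5-s stimulation +
11.5-s post-baseline), linearly baseline-corrected between the first and last 5 s,
and averaged over valid blocks per channel and condition.

Indexing convention: time t maps to sample ``floor(t*fs)``; epoch windows are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .params import AnalysisParams
from .stimuli import SessionSchedule
from .synthdata import RawRecording, extinction_matrix

__all__ = [
    "HbSeries", "BlockSet", "SubjectAverage", "od_to_hb", "flag_bad_trials",
    "bandpass_task", "segment_blocks", "linear_baseline_correct", "average_subject",
    "preprocess_task_subject",
]

CONDITIONS = ("correct_trial", "incorrect_trial")


class PreprocError(ValueError):
    pass


@dataclass
class HbSeries:
    """Per-channel ΔHbO/ΔHbR time series in mM·mm (concentration x pathlength)."""
    hbo: np.ndarray          # (n_channels, n_samples)
    hbr: np.ndarray
    sample_rate: float
    schedule: SessionSchedule | None = None

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]


def od_to_hb(raw: RawRecording, table=None) -> HbSeries:
    """Invert the modified Beer-Lambert system per sample.

    Solves ``OD = E [ΔHbO, ΔHbR]^T`` with E the 2x2 extinction matrix of the
    recording's wavelength pair. No differential-pathlength division is applied,
    so units remain mM·mm; this is the task-branch convention.
    """
    E = extinction_matrix(raw.wavelengths, table)
    det = np.linalg.det(E)
    if abs(det) < 1e-12:
        raise PreprocError("singular extinction matrix")
    Einv = np.linalg.inv(E)
    od = raw.od  # (n_ch, 2, T)
    hbo = Einv[0, 0] * od[:, 0, :] + Einv[0, 1] * od[:, 1, :]
    hbr = Einv[1, 0] * od[:, 0, :] + Einv[1, 1] * od[:, 1, :]
    return HbSeries(hbo, hbr, raw.sample_rate, raw.schedule)


def _epoch_bounds(onset: float, fs: float, params: AnalysisParams) -> tuple[int, int]:
    start = int(np.floor((onset - params.pre_baseline) * fs))
    return start, start + int(round(params.epoch_duration * fs))


def flag_bad_trials(hb: HbSeries, schedule: SessionSchedule | None = None,
                    params: AnalysisParams = AnalysisParams()) -> np.ndarray:
    """Per-trial, per-channel validity flags on the unfiltered series.

    A trial is invalid for a channel if, within its 28-s epoch span,
    |Δ(ΔHbO+ΔHbR)| between two consecutive samples exceeds 0.15 mM·mm (strict >),
    or any |ΔHbO| or |ΔHbR| sample exceeds the 5 mM·mm saturation ceiling.
    Epochs extending past the recording bounds are marked invalid.

    Returns a boolean array of shape (n_trials, n_channels), True = valid.
    """
    schedule = schedule or hb.schedule
    if schedule is None:
        raise PreprocError("no schedule attached to the series")
    fs = hb.sample_rate
    trials = schedule.target_trials()
    total = hb.hbo + hb.hbr
    step = np.abs(np.diff(total, axis=1))
    sat = (np.abs(hb.hbo) > params.saturation_threshold) | \
          (np.abs(hb.hbr) > params.saturation_threshold)
    valid = np.ones((len(trials), hb.n_channels), dtype=bool)
    for k, ev in enumerate(trials):
        i0, i1 = _epoch_bounds(ev.onset, fs, params)
        if i0 < 0 or i1 > hb.n_samples:
            valid[k, :] = False
            continue
        motion = step[:, i0:max(i0, i1 - 1)].max(axis=1) > params.motion_threshold
        saturated = sat[:, i0:i1].any(axis=1)
        valid[k] = ~(motion | saturated)
    return valid


def bandpass_task(hb: HbSeries, params: AnalysisParams = AnalysisParams()) -> HbSeries:
    """Zero-phase third-order Butterworth band-pass (0.02–0.5 Hz) per channel."""
    lo, hi = params.task_band
    nyq = hb.sample_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise PreprocError(f"band {params.task_band} outside (0, Nyquist={nyq})")
    sos = sps.butter(params.task_filter_order, (lo, hi), btype="bandpass",
                     fs=hb.sample_rate, output="sos")
    return HbSeries(sps.sosfiltfilt(sos, hb.hbo, axis=1),
                    sps.sosfiltfilt(sos, hb.hbr, axis=1),
                    hb.sample_rate, hb.schedule)


@dataclass
class BlockSet:
    """Segmented 28-s epochs, time-locked to stimulus onset minus 5 s."""
    epochs_hbo: np.ndarray     # (n_trials, n_channels, n_epoch_samples)
    epochs_hbr: np.ndarray
    conditions: list[str]      # per trial
    valid: np.ndarray          # (n_trials, n_channels) bool
    reasons: list[str]         # per trial: "" | "artifact" | "bounds"
    sample_rate: float

    @property
    def n_trials(self) -> int:
        return len(self.conditions)


def segment_blocks(hb: HbSeries, schedule: SessionSchedule | None = None,
                   flags: np.ndarray | None = None,
                   params: AnalysisParams = AnalysisParams()) -> BlockSet:
    """Cut one 28-s epoch per target trial per channel from the filtered series.

    Validity is copied from ``flags`` (computed on unfiltered data); out-of-bounds
    epochs are marked invalid with reason ``"bounds"``. Epoch sample index
    ``pre_baseline*fs`` (50 at 10 Hz) corresponds to stimulus onset.
    """
    schedule = schedule or hb.schedule
    if schedule is None:
        raise PreprocError("no schedule attached to the series")
    fs = hb.sample_rate
    trials = schedule.target_trials()
    n_ep = int(round(params.epoch_duration * fs))
    if flags is None:
        flags = np.ones((len(trials), hb.n_channels), dtype=bool)
    if flags.shape != (len(trials), hb.n_channels):
        raise PreprocError("flags shape does not match schedule/channels")
    epochs_hbo = np.zeros((len(trials), hb.n_channels, n_ep))
    epochs_hbr = np.zeros_like(epochs_hbo)
    valid = flags.copy()
    reasons = []
    conditions = []
    for k, ev in enumerate(trials):
        conditions.append(ev.kind)
        i0, i1 = _epoch_bounds(ev.onset, fs, params)
        if i0 < 0 or i1 > hb.n_samples:
            valid[k, :] = False
            reasons.append("bounds")
            continue
        epochs_hbo[k] = hb.hbo[:, i0:i1]
        epochs_hbr[k] = hb.hbr[:, i0:i1]
        reasons.append("" if flags[k].all() else "artifact")
    return BlockSet(epochs_hbo, epochs_hbr, conditions, valid, reasons, fs)


def linear_baseline_correct(block: np.ndarray, sample_rate: float = 10.0,
                            anchor: float = 5.0) -> np.ndarray:
    """Subtract the line through the mean levels of the first and last 5 s.

    The anchor points are the temporal midpoints of the two 5-s windows; after
    correction both anchor-window means are zero (to rounding). Works on the last
    axis of any (..., n_samples) array.
    """
    block = np.asarray(block, dtype=float)
    n = block.shape[-1]
    w = int(round(anchor * sample_rate))
    idx = np.arange(n, dtype=float)
    x1 = idx[:w].mean()
    x2 = idx[-w:].mean()
    m1 = block[..., :w].mean(axis=-1, keepdims=True)
    m2 = block[..., -w:].mean(axis=-1, keepdims=True)
    slope = (m2 - m1) / (x2 - x1)
    line = m1 + slope * (idx - x1)
    return block - line


@dataclass
class SubjectAverage:
    """Per-channel condition-mean epochs plus the subject inclusion decision."""
    subject: int
    mean_hbo: dict               # condition -> (n_channels, n_epoch_samples)
    mean_hbr: dict
    n_valid: dict                # condition -> per-channel valid-trial counts
    channel_valid: np.ndarray    # bool per channel
    included: bool
    sample_rate: float
    experiment: str = "neonate"


def average_subject(blockset: BlockSet, params: AnalysisParams = AnalysisParams(),
                    subject: int = 0, experiment: str = "neonate") -> SubjectAverage:
    """Average valid baseline-corrected blocks per channel and condition.

    A channel is valid if it retains at least ``min_trials_per_condition`` valid
    trials in *each* condition; the subject is excluded (flagged, not an error)
    if more than half of the channels are invalid.
    """
    n_ch = blockset.epochs_hbo.shape[1]
    cond_idx = {c: np.array([k for k, ck in enumerate(blockset.conditions) if ck == c])
                for c in CONDITIONS}
    mean_hbo, mean_hbr, n_valid = {}, {}, {}
    counts = np.zeros((len(CONDITIONS), n_ch), dtype=int)
    for ci, cond in enumerate(CONDITIONS):
        idx = cond_idx[cond]
        v = blockset.valid[idx]                      # (n_cond_trials, n_ch)
        counts[ci] = v.sum(axis=0)
        n_valid[cond] = counts[ci].copy()
        ep_o = linear_baseline_correct(blockset.epochs_hbo[idx], blockset.sample_rate)
        ep_r = linear_baseline_correct(blockset.epochs_hbr[idx], blockset.sample_rate)
        w = v[:, :, None].astype(float)
        denom = np.maximum(counts[ci][:, None], 1)
        mean_hbo[cond] = (ep_o * w).sum(axis=0) / denom
        mean_hbr[cond] = (ep_r * w).sum(axis=0) / denom
    channel_valid = (counts >= params.min_trials_per_condition).all(axis=0)
    included = channel_valid.sum() >= int(np.ceil(n_ch / 2))
    return SubjectAverage(subject, mean_hbo, mean_hbr, n_valid, channel_valid,
                          included, blockset.sample_rate, experiment)


def preprocess_task_subject(raw: RawRecording,
                            params: AnalysisParams = AnalysisParams()) -> SubjectAverage:
    """Full task branch for one recording: OD -> flags -> filter -> blocks -> average."""
    hb = od_to_hb(raw)
    flags = flag_bad_trials(hb, raw.schedule, params)
    filtered = bandpass_task(hb, params)
    blocks = segment_blocks(filtered, raw.schedule, flags, params)
    return average_subject(blocks, params, subject=raw.subject,
                           experiment=raw.layout.experiment)
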