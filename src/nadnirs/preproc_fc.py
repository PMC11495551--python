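"""Connectivity-branch preprocessing.

Order of operations, fixed as the pipeline's contract: per-channel wavelet
motion correction of ΔOD (outlier detail coefficients zeroed, infant tuning
iqr = 0.5) -> Homer-style sliding-window motion masking (tMotion = tMask = 1 s,
stdThresh = 15, ampThresh = 0.4) -> 0.01–0.1 Hz band-pass -> conversion to
haemoglobin concentration with DPF = 5 over the 20-mm separation -> extraction,
per rest/learning phase, of the longest contiguous span that is artifact-free
on every channel, requiring at least 90 s (900 samples at 10 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .params import AnalysisParams
from .stimuli import SessionSchedule
from .synthdata import RawRecording, extinction_matrix

__all__ = [
    "PhaseSegment", "wavelet_motion_correct", "mask_motion_segments",
    "bandpass_fc", "od_to_conc", "extract_phase_segments", "preprocess_fc_subject",
    "FC_PHASES",
]

FC_PHASES = ("PreRest", "Learning", "PostRest")


class FCPreprocError(ValueError):
    pass


def wavelet_motion_correct(od: np.ndarray, iqr_mult: float = 0.5,
                           wavelet: str = "db2", level: int | None = None) -> np.ndarray:
    """Zero outlying wavelet detail coefficients per channel, then reconstruct.

    For every decomposition level, detail coefficients falling outside
    ``[Q1 - iqr_mult*IQR, Q3 + iqr_mult*IQR]`` of that level's coefficient
    distribution are set to zero. Spike-like motion artifacts concentrate in
    large detail coefficients across levels and are strongly attenuated, while
    smooth low-frequency signal lives in the approximation and is preserved.
    Decomposition depth defaults to the maximal dyadic depth (at least 4 when
    the series allows). Series too short for one level pass through unchanged
    with a warning. Works on the last axis of any (..., n_samples) array.
    """
    od = np.asarray(od, dtype=float)
    n = od.shape[-1]
    wav = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(n, wav.dec_len)
    if max_level < 1:
        warnings.warn("series shorter than one wavelet level; passed through")
        return od.copy()
    level = max_level if level is None else min(level, max_level)

    flat = od.reshape(-1, n)
    coeffs = pywt.wavedec(flat, wav, level=level, axis=-1)
    cleaned = [coeffs[0]]
    for c in coeffs[1:]:
        q1, q3 = np.percentile(c, [25, 75], axis=-1, keepdims=True)
        iqr = q3 - q1
        keep = (c >= q1 - iqr_mult * iqr) & (c <= q3 + iqr_mult * iqr)
        cleaned.append(np.where(keep, c, 0.0))
    out = pywt.waverec(cleaned, wav, axis=-1)[..., :n]
    return out.reshape(od.shape)


def mask_motion_segments(od: np.ndarray, sample_rate: float = 10.0,
                         t_motion: float = 1.0, t_mask: float = 1.0,
                         std_thresh: float = 15.0, amp_thresh: float = 0.4,
                         ) -> np.ndarray:
    """Sliding-window motion detection per channel (Homer-style semantics).

    Within every window of length ``t_motion`` the signal excursion (max - min)
    is compared against ``std_thresh`` x a robust per-channel noise scale
    (1.4826 x median absolute deviation of the first-differenced series) and
    against the absolute threshold ``amp_thresh`` (OD units). Samples of any
    offending window, padded by ``t_mask`` on both sides, are marked bad.

    ``od`` has shape (..., n_samples); leading axes (channel, wavelength) are
    reduced with "bad anywhere = bad" onto shape (n_channels, n_samples) when a
    3-d (n_ch, n_wl, T) array is given, else the mask matches the input shape.
    Returns a boolean array, True = bad.
    """
    od = np.asarray(od, dtype=float)
    n = od.shape[-1]
    w = max(2, int(round(t_motion * sample_rate)))
    pad = int(round(t_mask * sample_rate))
    flat = od.reshape(-1, n)
    bad = np.zeros_like(flat, dtype=bool)
    for i, x in enumerate(flat):
        dx = np.diff(x)
        mad = np.median(np.abs(dx - np.median(dx)))
        noise_sd = 1.4826 * mad
        # rolling max-min over trailing windows of length w
        hi = maximum_filter1d(x, size=w, origin=-(w // 2), mode="nearest")
        lo = minimum_filter1d(x, size=w, origin=-(w // 2), mode="nearest")
        rng_w = hi - lo
        thresh = amp_thresh if noise_sd == 0 else min(std_thresh * noise_sd, amp_thresh)
        hit = rng_w > thresh
        if hit.any():
            # flag the window plus t_mask on each side of every hit
            dil = maximum_filter1d(hit.astype(np.uint8), size=w + 2 * pad,
                                   origin=0, mode="constant")
            bad[i] = dil.astype(bool)
    bad = bad.reshape(od.shape)
    if bad.ndim == 3:
        bad = bad.any(axis=1)
    return bad


def bandpass_fc(series: np.ndarray, sample_rate: float = 10.0,
                band: tuple[float, float] = (0.01, 0.1), order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass in the spontaneous-activity band."""
    lo, hi = band
    nyq = sample_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise FCPreprocError(f"band {band} outside (0, Nyquist={nyq})")
    sos = sps.butter(order, (lo, hi), btype="bandpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=-1)


def od_to_conc(od: np.ndarray, wavelengths, dpf: float = 5.0,
               separation_mm: float = 20.0, table=None) -> tuple[np.ndarray, np.ndarray]:
    """Convert two-wavelength ΔOD to concentration changes (mM).

    Solves the modified Beer-Lambert system and divides by the effective photon
    path ``separation x DPF``. ``od`` has shape (n_channels, 2, n_samples).
    """
    E = extinction_matrix(wavelengths, table)
    if abs(np.linalg.det(E)) < 1e-12:
        raise FCPreprocError("singular extinction matrix")
    Einv = np.linalg.inv(E)
    path = separation_mm * dpf
    hbo = (Einv[0, 0] * od[:, 0, :] + Einv[0, 1] * od[:, 1, :]) / path
    hbr = (Einv[1, 0] * od[:, 0, :] + Einv[1, 1] * od[:, 1, :]) / path
    return hbo, hbr


@dataclass
class PhaseSegment:
    """Longest all-channel-clean span of one phase, in concentration units."""
    subject: int
    phase: str
    hbo: np.ndarray | None       # (n_channels, n_samples) or None if unusable
    hbr: np.ndarray | None
    duration: float              # seconds of the extracted span (0 if none)
    usable: bool
    n_bad_spans: int
    sample_rate: float = 10.0

    @property
    def n_samples(self) -> int:
        return 0 if self.hbo is None else self.hbo.shape[1]


def _longest_clean_run(clean: np.ndarray) -> tuple[int, int]:
    """Start/stop (half-open) of the longest True run; (0, 0) if none."""
    best = (0, 0)
    start = None
    for i, ok in enumerate(clean):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None and len(clean) - start > best[1] - best[0]:
        best = (start, len(clean))
    return best


def extract_phase_segments(hbo: np.ndarray, hbr: np.ndarray,
                           schedule: SessionSchedule, mask: np.ndarray,
                           sample_rate: float = 10.0, min_continuous: float = 90.0,
                           subject: int = 0) -> dict[str, PhaseSegment]:
    """Per rest/learning phase, extract the longest contiguous all-clean span.

    A sample is clean only if no channel is masked there (the whole-matrix
    connectivity computation needs every channel simultaneously). Spans shorter
    than ``min_continuous`` seconds render the subject-phase unusable (flagged,
    not an error).
    """
    n = hbo.shape[1]
    any_bad = mask.any(axis=0) if mask.ndim == 2 else mask
    segments = {}
    for phase in FC_PHASES:
        try:
            t0, t1 = schedule.phase_span(phase)
        except KeyError:
            continue
        i0, i1 = int(np.floor(t0 * sample_rate)), min(n, int(np.floor(t1 * sample_rate)))
        clean = ~any_bad[i0:i1]
        s, e = _longest_clean_run(clean)
        n_bad = int(np.diff(np.r_[0, any_bad[i0:i1].astype(int), 0]).clip(min=0).sum())
        dur = (e - s) / sample_rate
        if dur >= min_continuous:
            segments[phase] = PhaseSegment(
                subject, phase, hbo[:, i0 + s:i0 + e], hbr[:, i0 + s:i0 + e],
                dur, True, n_bad, sample_rate)
        else:
            segments[phase] = PhaseSegment(subject, phase, None, None, dur,
                                           False, n_bad, sample_rate)
    return segments


def preprocess_fc_subject(raw: RawRecording,
                          params: AnalysisParams = AnalysisParams()
                          ) -> dict[str, PhaseSegment]:
    """Full connectivity branch for one recording."""
    od = wavelet_motion_correct(raw.od, iqr_mult=params.wavelet_iqr,
                                wavelet=params.wavelet_name,
                                level=params.wavelet_level)
    mask = mask_motion_segments(od, raw.sample_rate, params.t_motion, params.t_mask,
                                params.std_thresh, params.amp_thresh)
    od_f = bandpass_fc(od, raw.sample_rate, params.fc_band, params.fc_filter_order)
    hbo, hbr = od_to_conc(od_f, raw.wavelengths, dpf=params.dpf,
                          separation_mm=raw.layout.separation_mm)
    return extract_phase_segments(hbo, hbr, raw.schedule, mask, raw.sample_rate,
                                  params.min_continuous, subject=raw.subject)
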