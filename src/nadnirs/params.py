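"""Analysis parameters for the task-activation and functional-connectivity branches.

All numeric tuning values of the pipeline live in :class:`AnalysisParams` so that a
single object documents the analysis configuration: artifact-rejection thresholds in
mM·mm, Butterworth pass-bands in Hz, the per-experiment response windows in seconds,
permutation count, and the Homer-style motion-masking thresholds used by the
connectivity branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace


@dataclass(frozen=True)
class AnalysisParams:
    #: maximum |change of ΔHbO+ΔHbR| between 2 consecutive samples (mM·mm), strict >
    motion_threshold: float = 0.15
    #: absolute saturation ceiling on ΔHb (mM·mm), strict >
    saturation_threshold: float = 5.0
    #: task-branch band-pass (Hz) and Butterworth order
    task_band: tuple[float, float] = (0.02, 0.5)
    task_filter_order: int = 3
    #: connectivity-branch band-pass (Hz)
    fc_band: tuple[float, float] = (0.01, 0.1)
    fc_filter_order: int = 3
    #: response window (s from stimulus onset) per age group
    window_neonate: tuple[float, float] = (7.5, 12.5)
    window_infant: tuple[float, float] = (10.5, 15.5)
    #: pre-stimulus baseline length inside each epoch (s); epoch = pre + stim + post
    pre_baseline: float = 5.0
    stimulus_duration: float = 11.5
    post_baseline: float = 11.5
    n_perm: int = 50_000
    alpha: float = 0.05
    #: family-wise levels at which Bonferroni-corrected connectivity tests are read out
    bonferroni_levels: tuple[float, ...] = (0.05, 5e-6, 5e-7, 5e-8, 5e-9)
    #: differential pathlength factor for concentration conversion (FC branch)
    dpf: float = 5.0
    #: wavelet motion-correction outlier multiplier on the coefficient IQR
    wavelet_iqr: float = 0.5
    wavelet_name: str = "db2"
    #: decomposition depth; 6 removes spike energy down to ~0.08 Hz at 10 Hz
    #: sampling while leaving the bulk of the 0.01-0.1 Hz connectivity band in
    #: the untouched approximation
    wavelet_level: int = 6
    #: Homer-style segment masking thresholds
    t_motion: float = 1.0
    t_mask: float = 1.0
    std_thresh: float = 15.0
    amp_thresh: float = 0.4
    #: subject-inclusion floor: valid trials per condition per channel
    min_trials_per_condition: int = 2
    #: minimum continuous artifact-free span for connectivity (s)
    min_continuous: float = 90.0

    @property
    def epoch_duration(self) -> float:
        """Total block length in seconds (5 + 11.5 + 11.5 = 28)."""
        return self.pre_baseline + self.stimulus_duration + self.post_baseline

    def window(self, experiment: str) -> tuple[float, float]:
        """Response window (s from stimulus onset) for ``'neonate'`` or ``'infant'``."""
        if experiment == "neonate":
            return self.window_neonate
        if experiment == "infant":
            return self.window_infant
        raise ValueError(f"unknown experiment {experiment!r}")

    def validate(self, sample_rate: float = 10.0) -> "AnalysisParams":
        """Range-check every field; raise ``ValueError`` listing all violations."""
        errors = []
        nyq = sample_rate / 2.0
        for name in ("motion_threshold", "saturation_threshold", "dpf",
                     "wavelet_iqr", "t_motion", "t_mask", "std_thresh",
                     "amp_thresh", "min_continuous", "alpha"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        for name in ("n_perm", "min_trials_per_condition", "task_filter_order",
                     "fc_filter_order"):
            if getattr(self, name) < 1:
                errors.append(f"{name} must be >= 1")
        for name in ("task_band", "fc_band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                errors.append(f"{name} must satisfy 0 < low < high (got {lo}, {hi})")
            elif hi >= nyq:
                errors.append(f"{name} high edge {hi} not below Nyquist {nyq}")
        for name in ("window_neonate", "window_infant"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= self.stimulus_duration + self.post_baseline):
                errors.append(f"{name} must lie inside the post-onset epoch")
        if not all(0 < lv <= 1 or lv < 1 for lv in self.bonferroni_levels):
            errors.append("bonferroni_levels must be in (0, 1]")
        if errors:
            raise ValueError("invalid AnalysisParams: " + "; ".join(errors))
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **kw) -> "AnalysisParams":
        return replace(self, **kw)


DEFAULT_PARAMS = AnalysisParams()
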