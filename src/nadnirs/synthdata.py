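"""Simulated two-wavelength fNIRS recordings with a known answer key.

The simulator emulates optical recordings at 10 Hz on the study probe layouts:
one 3x5 pad plus two 3x3 pads (46 channels) for the neonate experiment, two 3x5
pads (22 channels each) for the 6- to 7-month-old experiment. Per subject it
builds latent ΔHbO/ΔHbR signals as

    condition boxcars * infant HRF x planted amplitudes
    + band-limited (0.01-0.1 Hz) latent-factor network signal
    + cardiac / respiratory / Mayer-wave sinusoids + 1/f drift + white noise,

injects motion spikes and saturation episodes, and converts the result to
two-wavelength optical density through the forward modified Beer-Lambert model.
Every planted quantity is recorded in a :class:`GroundTruth` sidecar so the
downstream preprocessing and statistics stages can be validated against it.

A per-subject latent scalar couples the learning-phase strength of the planted
network edges to the activation amplitude measured in the test phase, which is
what the seed-based connectivity-activation correlation stage must recover; the
default coupling is negative, mirroring the direction the analysis is designed
to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .stimuli import SessionSchedule, build_stimulus_lists, schedule_session

__all__ = [
    "ProbeLayout", "Channel", "GroundTruth", "RawRecording", "SimParams",
    "make_probe_layout", "simulate_cohort", "simulate_subject", "hb_to_od",
    "EXTINCTION_MM_MM", "extinction_matrix", "infant_hrf",
    "write_snirf", "read_snirf",
]


class SimulationError(ValueError):
    """Raised for invalid simulator parameters or layout requests."""


# ---------------------------------------------------------------------------
# Probe layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    channel_id: int        # 1-based, stable across runs
    source_id: int
    detector_id: int
    pad: int
    region: str


@dataclass(frozen=True)
class ProbeLayout:
    experiment: str
    pads: tuple[tuple[int, int], ...]   # (rows, cols) per pad
    channels: tuple[Channel, ...]
    separation_mm: float = 20.0

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def region_of(self, channel_id: int) -> str:
        return self.channels[channel_id - 1].region

    def channels_in_regions(self, prefixes: tuple[str, ...]) -> list[int]:
        return [c.channel_id for c in self.channels
                if any(p in c.region for p in prefixes)]


def _pad_channels(rows: int, cols: int):
    """Nearest-neighbour source-detector pairs of one rectangular pad.

    Optode roles alternate on the grid ((row+col) even = source), giving
    8 sources / 7 detectors on a 3x5 pad. Channels are ordered row-major by the
    position of the source-detector midpoint: horizontal pairs of row r, then
    vertical pairs between rows r and r+1.
    """
    role = {}
    number = {}
    ns = nd = 0
    for r in range(rows):
        for c in range(cols):
            if (r + c) % 2 == 0:
                ns += 1
                role[(r, c)], number[(r, c)] = "S", ns
            else:
                nd += 1
                role[(r, c)], number[(r, c)] = "D", nd
    pairs = []  # (midpoint row, midpoint col, optode a, optode b)
    for r in range(rows):
        for c in range(cols - 1):
            pairs.append((r, c + 0.5, (r, c), (r, c + 1)))
        if r < rows - 1:
            for c in range(cols):
                pairs.append((r + 0.5, c, (r, c), (r + 1, c)))
    # drop the trailing row of horizontal pairs ordering artifact: order is already
    # row-major (horizontal row r, vertical r/r+1, horizontal r+1, ...)
    out = []
    for _, mid_c, a, b in pairs:
        src = a if role[a] == "S" else b
        det = b if role[b] == "D" else a
        out.append((number[src], number[det], mid_c))
    return out


# Static channel -> cortical region lookup. This is a fixed synthetic stand-in
# for atlas-based virtual registration: labels are anchored to the published
# channel positions (e.g., frontal-pad midline channels 31/40, temporal-pad
# midpoints) and filled in by pad geometry.
_NEONATE_LEFT = ["L-PostCG", "L-SMG", "L-PreCG", "L-SMG", "L-IFGoper", "L-STG",
                 "L-SMG", "L-IFGoper", "L-STG", "L-MTG", "L-STG", "L-STG"]
_NEONATE_RIGHT = ["R-PostCG", "R-SMG", "R-PreCG", "R-SMG", "R-IFGoper", "R-STG",
                  "R-STG", "R-IFGoper", "R-STG", "R-PreCG", "R-STG", "R-STG"]
_NEONATE_FRONTAL = ["L-FP", "L-FP", "R-FP", "R-FP",
                    "L-DLPFC/L-FP", "L-FP", "FP", "R-FP", "R-DLPFC/R-FP",
                    "L-DLPFC/L-FP", "L-FP", "R-FP", "R-DLPFC/R-FP",
                    "L-DLPFC/L-IFGtri", "L-DLPFC/L-FP", "DLPFC",
                    "R-DLPFC/R-FP", "R-DLPFC/R-IFGtri",
                    "L-DLPFC", "L-DLPFC", "R-DLPFC", "R-DLPFC"]
_INFANT_LEFT = ["L-DLPFC", "L-PreCG", "L-PostCG", "L-SMG",
                "L-IFGtri", "L-IFGtri", "L-PreCG", "L-PostCG", "L-SMG",
                "L-IFGtri", "L-IFGtri", "L-PreCG", "L-STG",
                "L-IFGtri", "L-IFGoper", "L-STG", "L-STG/L-MTG", "L-SMG",
                "L-IFGoper", "L-STG", "L-STG", "L-MTG"]
_INFANT_RIGHT = ["R-SMG" if i == 0 else "R-PreCG/R-IFGoper" if i == 6
                 else lab.replace("L-", "R-") for i, lab in enumerate(_INFANT_LEFT)]

#: frontal-pad channels of the neonate layout (candidate seed region)
NEONATE_PREFRONTAL = tuple(range(25, 47))
#: the six prefrontal channels reported as test-phase seeds
DEFAULT_SEED_CHANNELS = (30, 34, 35, 38, 39, 43)
#: non-seed channels participating in the learning-related network
DEFAULT_NONSEED_CHANNELS = (2, 9, 17, 19, 22)

DEFAULT_WAVELENGTHS = {"neonate": (695.0, 830.0), "infant": (780.0, 830.0)}


def make_probe_layout(experiment: str) -> ProbeLayout:
    """Build the probe layout of one experiment with stable channel ids.

    Neonate: left 3x3 pad (channels 1-12), right 3x3 pad (13-24), frontal 3x5
    pad (25-46); the frontal midline vertical channels fall at ids 31 and 40.
    Infant: left 3x5 pad (1-22), right 3x5 pad (23-44).
    """
    if experiment == "neonate":
        pads = [(3, 3), (3, 3), (3, 5)]
        labels = _NEONATE_LEFT + _NEONATE_RIGHT + _NEONATE_FRONTAL
    elif experiment == "infant":
        pads = [(3, 5), (3, 5)]
        labels = _INFANT_LEFT + _INFANT_RIGHT
    else:
        raise SimulationError(f"unknown experiment {experiment!r}")
    channels = []
    cid = 0
    for pad_idx, (rows, cols) in enumerate(pads):
        for src, det, _ in _pad_channels(rows, cols):
            cid += 1
            channels.append(Channel(cid, src, det, pad_idx, labels[cid - 1]))
    return ProbeLayout(experiment, tuple(pads), tuple(channels))


# ---------------------------------------------------------------------------
# Forward modified Beer-Lambert model
# ---------------------------------------------------------------------------

#: extinction coefficients (eps_HbO, eps_HbR) in mm^-1 mM^-1 at the instrument
#: wavelengths; standard literature values.
EXTINCTION_MM_MM = {
    695.0: (0.00287, 0.01923),
    780.0: (0.00740, 0.01075),
    830.0: (0.00974, 0.00693),
}


def extinction_matrix(wavelengths, table=None) -> np.ndarray:
    """2x2 matrix E with rows per wavelength, columns (HbO, HbR)."""
    table = EXTINCTION_MM_MM if table is None else table
    rows = []
    for wl in wavelengths:
        if float(wl) not in table:
            raise SimulationError(f"wavelength {wl} nm missing from extinction table")
        rows.append(table[float(wl)])
    return np.asarray(rows, dtype=float)


def hb_to_od(delta_hbo: np.ndarray, delta_hbr: np.ndarray, wavelengths,
             table=None) -> tuple[np.ndarray, np.ndarray]:
    """Forward model: OD_lambda = eps_HbO(lambda)·ΔHbO + eps_HbR(lambda)·ΔHbR.

    Chromophore inputs are concentration x pathlength products (mM·mm), so no
    pathlength term appears here. Returns one OD series per wavelength.
    """
    E = extinction_matrix(wavelengths, table)
    dhbo = np.asarray(delta_hbo, dtype=float)
    dhbr = np.asarray(delta_hbr, dtype=float)
    return (E[0, 0] * dhbo + E[0, 1] * dhbr, E[1, 0] * dhbo + E[1, 1] * dhbr)


def infant_hrf(fs: float, peak: float = 6.0, undershoot: float = 14.0,
               ratio: float = 0.25, duration: float = 30.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalised to 1."""
    t = np.arange(0, duration, 1.0 / fs)
    from scipy.stats import gamma
    h = gamma.pdf(t, peak) - ratio * gamma.pdf(t, undershoot)
    return h / np.max(h)


# ---------------------------------------------------------------------------
# Simulation parameters and containers
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Generator settings. Defaults define the simulated study conditions."""
    fs: float = 10.0
    # --- planted task activation (mM·mm at the HRF peak) ---
    amp_correct: float = -0.04          # habituation-like deactivation
    amp_incorrect: float = 0.06         # violation response
    activation_channels: tuple[int, ...] | None = None  # None -> per-experiment default
    act_subject_sd: float = 0.07        # between-subject SD of the Incorrect offset
    #: fraction of the coupling-orthogonal amplitude variance shared across
    #: activation channels (prefrontal responses co-fluctuate within subject)
    act_shared_frac: float = 0.7
    act_channel_sd: float = 0.005       # per-channel amplitude jitter
    hrf_peak: float = 6.0
    # --- planted connectivity network ---
    #: channel cliques each sharing one latent factor; every within-component
    #: pair is a planted network edge. None -> the per-experiment default
    #: (a 4-channel clique {30, 34, 2, 9} plus four 2-channel components,
    #: giving 9 seed-touching edges and the non-seed edge (2, 9)).
    network_components: tuple[tuple[int, ...], ...] | None = None
    network_amp: float = 0.13           # mM·mm per unit latent factor
    loading_prerest: float = 0.03
    loading_learning: float = 0.18
    loading_postrest: float = 0.08
    #: SD of ln(s_i): the per-subject edge-strength scalar is lognormal,
    #: s_i = exp(sd * u), so connectivity z responds ~linearly to the latent u
    subject_scale_sd: float = 1.10
    coupling: float = -0.70             # corr(latent edge strength, activation offset)
    # --- physiology and noise ---
    noise_sd: float = 0.015
    cardiac_freq: float = 2.5           # ~150 bpm
    cardiac_amp: float = 0.010
    resp_freq: float = 0.7
    resp_amp: float = 0.010
    mayer_freq: float = 0.1
    mayer_amp: float = 0.015
    drift_amp: float = 0.02             # 1/f drift SD
    hbr_ratio: float = -0.4
    hbr_noise_sd: float = 0.008
    # --- artifacts ---
    p_trial_artifact: float = 0.2       # per target trial
    spike_amp: tuple[float, float] = (0.3, 1.0)   # mM·mm, > 2x the 0.15 criterion
    background_spike_rate: float = 1.0 / 300.0    # per second outside target trials
    saturation_rate: float = 0.02       # per subject; one 2-s episode in the test phase
    saturation_value: float = 6.0       # mM·mm, above the 5 mM·mm ceiling
    # --- session ---
    pre_rest: float = 240.0
    post_rest: float = 230.0

    def validate(self) -> "SimParams":
        errors = []
        if self.fs <= 0:
            errors.append("fs must be positive")
        for name in ("noise_sd", "network_amp", "act_subject_sd", "hbr_noise_sd",
                     "drift_amp", "cardiac_amp", "resp_amp", "mayer_amp"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        for name in ("p_trial_artifact", "saturation_rate"):
            if not 0 <= getattr(self, name) <= 1:
                errors.append(f"{name} must be in [0, 1]")
        if not -1 <= self.coupling <= 1:
            errors.append("coupling must be in [-1, 1]")
        for name in ("loading_prerest", "loading_learning", "loading_postrest"):
            if not 0 <= getattr(self, name) <= 1:
                errors.append(f"{name} must be in [0, 1]")
        if errors:
            raise SimulationError("invalid SimParams: " + "; ".join(errors))
        return self

    def null(self) -> "SimParams":
        """Copy with all signal, noise and artifact sources switched off."""
        import dataclasses
        return dataclasses.replace(
            self, amp_correct=0.0, amp_incorrect=0.0, act_subject_sd=0.0,
            act_channel_sd=0.0, network_amp=0.0, noise_sd=0.0, cardiac_amp=0.0,
            resp_amp=0.0, mayer_amp=0.0, drift_amp=0.0, hbr_noise_sd=0.0,
            p_trial_artifact=0.0, background_spike_rate=0.0, saturation_rate=0.0)


@dataclass
class GroundTruth:
    """The simulator's answer key for one subject."""
    activation_map: dict            # condition -> per-channel amplitude array
    network_edges: list             # [(ch_a, ch_b, {phase: loading})]
    artifact_times: list            # [(onset s, kind)]
    coupling_latent: float          # u_i, the subject's shared latent scalar
    edge_scale: float               # s_i, multiplies learning-phase loadings

    def to_json(self) -> str:
        d = {
            "activation_map": {k: np.asarray(v).tolist()
                               for k, v in self.activation_map.items()},
            "network_edges": [[a, b, lo] for a, b, lo in self.network_edges],
            "artifact_times": [[float(t), k] for t, k in self.artifact_times],
            "coupling_latent": self.coupling_latent,
            "edge_scale": self.edge_scale,
        }
        return json.dumps(d, indent=2)


@dataclass
class RawRecording:
    subject: int
    layout: ProbeLayout
    sample_rate: float
    wavelengths: tuple[float, float]
    od: np.ndarray                  # (n_channels, 2 wavelengths, n_samples)
    schedule: SessionSchedule
    ground_truth: GroundTruth | None = None

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]


def _default_activation_channels(experiment: str) -> tuple[int, ...]:
    return DEFAULT_SEED_CHANNELS if experiment == "neonate" else (4, 6, 17, 23, 29)


def _default_network_components(experiment: str) -> tuple[tuple[int, ...], ...]:
    if experiment == "neonate":
        return ((30, 34, 2, 9), (35, 17), (38, 19), (39, 22), (43, 40))
    return ()


def component_edges(components) -> list[tuple[int, int]]:
    """All within-component channel pairs (the planted network edges)."""
    out = []
    for comp in components:
        comp = sorted(comp)
        for i in range(len(comp)):
            for j in range(i + 1, len(comp)):
                out.append((comp[i], comp[j]))
    return out


def _one_over_f(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD noise with ~1/f power spectrum (spectral shaping)."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _phase_weights(schedule: SessionSchedule, fs: float, n: int, sp: SimParams,
                   edge_scale: float, ramp_s: float = 45.0) -> np.ndarray:
    """Per-sample factor loading implied by the phase structure.

    Loadings transition smoothly (~45-s Hann smoothing) rather than stepping at
    phase boundaries: learning-related connectivity builds up and decays over
    tens of seconds, and a step would bleed across boundaries once the
    zero-phase 0.01-0.1 Hz filter is applied downstream.
    """
    w = np.full(n, sp.loading_prerest)
    for name, onset, dur in schedule.phases:
        i0, i1 = int(onset * fs), min(n, int((onset + dur) * fs))
        if name == "Learning":
            target = min(1.0, sp.loading_learning * edge_scale)
            w[i0:i1] = target
            k = min(int(round(ramp_s * fs)), (i1 - i0) // 3)
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))  # 0 -> 1, inside phase
            w[i0:i0 + k] = sp.loading_prerest + (target - sp.loading_prerest) * ramp
            w[i1 - k:i1] = sp.loading_prerest + (target - sp.loading_prerest) * ramp[::-1]
        elif name == "PostRest":
            w[i0:i1] = sp.loading_postrest
    return w


def simulate_subject(subject: int, schedule: SessionSchedule, layout: ProbeLayout,
                     sp: SimParams, rng: np.random.Generator,
                     wavelengths=None) -> RawRecording:
    """Generate one subject's two-wavelength OD recording plus ground truth."""
    sp.validate()
    fs = sp.fs
    n_ch = layout.n_channels
    n = int(round(schedule.duration * fs))
    t = np.arange(n) / fs
    wavelengths = wavelengths or DEFAULT_WAVELENGTHS[layout.experiment]

    u = float(rng.standard_normal())            # shared latent scalar
    s_i = float(np.exp(sp.subject_scale_sd * u))    # edge-strength multiplier
    rho = sp.coupling
    orth = np.sqrt(max(0.0, 1 - rho ** 2))
    eta_shared = float(rng.standard_normal())

    act_channels = (sp.activation_channels
                    if sp.activation_channels is not None
                    else _default_activation_channels(layout.experiment))
    amp = {"correct_trial": np.zeros(n_ch), "incorrect_trial": np.zeros(n_ch)}
    f_sh = np.sqrt(sp.act_shared_frac)
    f_ch = np.sqrt(1.0 - sp.act_shared_frac)
    for ch in act_channels:
        # corr(amplitude, u) = coupling at every channel; the orthogonal residual
        # is part shared (co-fluctuating responses) and part channel-specific
        eta = f_sh * eta_shared + f_ch * float(rng.standard_normal())
        offset = sp.act_subject_sd * (rho * u + orth * eta)
        jit = sp.act_channel_sd * rng.standard_normal(2)
        amp["correct_trial"][ch - 1] = sp.amp_correct + jit[0]
        amp["incorrect_trial"][ch - 1] = sp.amp_incorrect + offset + jit[1]

    signal_part = np.zeros((n_ch, n))           # activation + network (for HbR scaling)

    # --- condition-locked haemodynamics ---
    # The single-trial response (11.5-s boxcar convolved with the HRF) is
    # peak-normalised so planted amplitudes are in mM·mm at the response peak.
    hrf = infant_hrf(fs, peak=sp.hrf_peak)
    trial_len = int(round(11.5 * fs))
    single = sps.fftconvolve(np.ones(trial_len), hrf)
    peak = np.max(single) if len(single) else 1.0
    for cond in ("correct_trial", "incorrect_trial"):
        box = np.zeros(n)
        for ev in schedule.events:
            if ev.kind == cond:
                i0 = int(ev.onset * fs)
                box[i0:int((ev.onset + ev.duration) * fs)] = 1.0
        resp = sps.fftconvolve(box, hrf)[:n] / peak
        signal_part += np.outer(amp[cond], resp)

    # --- latent-factor network signal, band-limited to 0.01-0.1 Hz ---
    # One factor per component; every member channel carries the same
    # amp * w(t) * F(t) contribution, so all within-component pairs correlate.
    components = (sp.network_components if sp.network_components is not None
                  else _default_network_components(layout.experiment))
    loadings = {"PreRest": sp.loading_prerest,
                "Learning": min(1.0, sp.loading_learning * s_i),
                "PostRest": sp.loading_postrest}
    gt_edges = [(a, b, dict(loadings) if sp.network_amp > 0 else
                 {k: 0.0 for k in loadings})
                for a, b in component_edges(components)]
    if components and sp.network_amp > 0:
        sos = sps.butter(3, (0.01, 0.1), btype="bandpass", fs=fs, output="sos")
        w = _phase_weights(schedule, fs, n, sp, s_i)
        for comp in components:
            f = sps.sosfiltfilt(sos, rng.standard_normal(n))
            f /= f.std()
            contrib = sp.network_amp * w * f
            for ch in comp:
                signal_part[ch - 1] += contrib

    hbo = signal_part.copy()

    # --- physiological oscillations ---
    # Per-channel phase AND ~5 % frequency jitter: equal-frequency sinusoids would
    # correlate across channels (corr = cos Δφ) and plant spurious connectivity.
    for freq, a in ((sp.cardiac_freq, sp.cardiac_amp),
                    (sp.resp_freq, sp.resp_amp),
                    (sp.mayer_freq, sp.mayer_amp)):
        if a > 0:
            phases = rng.uniform(0, 2 * np.pi, n_ch)
            freqs = freq * (1.0 + 0.05 * rng.standard_normal(n_ch))
            hbo += a * np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                              + phases[:, None])

    if sp.drift_amp > 0:
        for ch in range(n_ch):
            hbo[ch] += sp.drift_amp * _one_over_f(rng, n)
    if sp.noise_sd > 0:
        hbo += sp.noise_sd * rng.standard_normal((n_ch, n))

    hbr = sp.hbr_ratio * signal_part
    if sp.hbr_noise_sd > 0:
        hbr += sp.hbr_noise_sd * rng.standard_normal((n_ch, n))

    # --- artifacts ---
    artifacts = []
    # biphasic (zero-area) excursion: sudden shift up then back below baseline,
    # the typical shape of a brief probe-motion artifact
    spike_shape = np.array([1.0, 1.0, -1.0, -1.0])
    def plant_spike(onset_s: float):
        a = rng.uniform(*sp.spike_amp)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        i0 = int(onset_s * fs)
        if i0 + len(spike_shape) >= n:
            return
        hbo[:, i0:i0 + len(spike_shape)] += sign * a * spike_shape
        hbr[:, i0:i0 + len(spike_shape)] += sign * a * 0.5 * spike_shape
        artifacts.append((onset_s, "spike"))

    for ev in schedule.target_trials():
        if rng.random() < sp.p_trial_artifact:
            plant_spike(float(rng.uniform(ev.onset, ev.onset + ev.duration - 1.0)))
    for name, onset, dur in schedule.phases:
        if name in ("PreRest", "Learning", "PostRest") and sp.background_spike_rate > 0:
            k = rng.poisson(sp.background_spike_rate * dur)
            for _ in range(k):
                plant_spike(float(rng.uniform(onset, onset + dur - 1.0)))
    if sp.saturation_rate > 0 and rng.random() < sp.saturation_rate:
        t0, t1 = schedule.phase_span("Test")
        onset_s = float(rng.uniform(t0, t1 - 2.0))
        i0, i1 = int(onset_s * fs), int((onset_s + 2.0) * fs)
        ch = int(rng.integers(n_ch))
        hbo[ch, i0:i1] = sp.saturation_value
        artifacts.append((onset_s, "saturation"))

    od1, od2 = hb_to_od(hbo, hbr, wavelengths)
    od = np.stack([od1, od2], axis=1)
    gt = GroundTruth({k: v for k, v in amp.items()}, gt_edges, artifacts, u, s_i)
    return RawRecording(subject, layout, fs, tuple(wavelengths), od, schedule, gt)


def simulate_cohort(n_subjects: int, experiment: str = "neonate",
                    sim_params: SimParams | None = None, seed: int = 0,
                    schedules: list[SessionSchedule] | None = None) -> list[RawRecording]:
    """Simulate a cohort of subjects; deterministic given ``seed``.

    Stimulus-list assignment is counterbalanced across subjects (cycling the 4
    lists). Defaults emulate the study cohorts: use ``n_subjects=21`` for the
    neonate experiment, ``19`` for the infant experiment.
    """
    if n_subjects < 1:
        raise SimulationError("n_subjects must be >= 1")
    sp = (sim_params or SimParams()).validate()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects + 1)
    list_rng = np.random.default_rng(children[0])
    lists = build_stimulus_lists(list_rng)
    layout = make_probe_layout(experiment)
    recordings = []
    for i in range(n_subjects):
        rng = np.random.default_rng(children[i + 1])
        sched = (schedules[i] if schedules is not None else
                 schedule_session(experiment, lists[i % 4], rng,
                                  pre_rest=sp.pre_rest, post_rest=sp.post_rest))
        recordings.append(simulate_subject(i, sched, layout, sp, rng))
    return recordings


# ---------------------------------------------------------------------------
# SNIRF-style HDF5 I/O
# ---------------------------------------------------------------------------

def write_snirf(recording: RawRecording, path: str | Path) -> Path:
    """Write a recording as a SNIRF-shaped HDF5 file plus sidecars.

    Layout follows the SNIRF convention: ``/nirs/data1/dataTimeSeries`` holds
    time x measurement columns (one column per channel x wavelength),
    ``measurementList<k>`` groups give source/detector/wavelength indices.
    Ground truth (if present) goes to ``<stem>_groundtruth.json`` and events to
    ``<stem>_events.tsv``.
    """
    import h5py

    path = Path(path)
    n_ch = recording.layout.n_channels
    T = recording.n_samples
    data = recording.od.transpose(2, 0, 1).reshape(T, n_ch * 2)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        f["nirs/metaDataTags/LengthUnit"] = "mm"
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.arange(T) / recording.sample_rate)
        k = 0
        for ch in recording.layout.channels:
            for wl_idx in (1, 2):
                k += 1
                ml = d1.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=ch.source_id)
                ml.create_dataset("detectorIndex", data=ch.detector_id)
                ml.create_dataset("wavelengthIndex", data=wl_idx)
                ml.create_dataset("dataType", data=99999)  # processed (ΔOD)
                ml.create_dataset("channelId", data=ch.channel_id)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.wavelengths))
        f.attrs["experiment"] = recording.layout.experiment
        f.attrs["subject"] = recording.subject
    recording.schedule.events_df().to_csv(
        path.with_name(path.stem + "_events.tsv"), sep="\t", index=False)
    if recording.ground_truth is not None:
        path.with_name(path.stem + "_groundtruth.json").write_text(
            recording.ground_truth.to_json())
    return path


def read_snirf(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float], str]:
    """Read back OD array (n_ch, 2, T), sample rate, wavelengths, experiment."""
    import h5py

    with h5py.File(path, "r") as f:
        data = f["nirs/data1/dataTimeSeries"][()]
        time = f["nirs/data1/time"][()]
        wavelengths = tuple(f["nirs/probe/wavelengths"][()])
        experiment = f.attrs["experiment"]
    T, m = data.shape
    od = data.reshape(T, m // 2, 2).transpose(1, 2, 0)
    fs = 1.0 / float(np.median(np.diff(time)))
    return od, fs, wavelengths, str(experiment)
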