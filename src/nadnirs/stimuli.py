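"""Artificial-grammar tone stimuli: categories, grammars, lists, and session schedules.

The paradigm uses triplets of frequency-modulated sine tones drawn from six pitch-contour
categories (A rising, B slow wave, C fast wave, D falling, X1 big spike, X2 small spike).
A nonadjacent dependency links the first and third element across a freely varying middle
X element: grammar 1a pairs A with B, 1b pairs C with D; grammar 2 reverses the pairings
(2a: A with D, 2b: C with B). "Incorrect" test triplets instantiate the opposite pairing
of the grammar that was learned (AXD or CXB for a Grammar-1 learner).

Timing constants: each element lasts 1.5 s with 0.25-s gaps, so a triplet lasts 5 s;
target trials hold 2 triplets separated by 1.5 s (11.5 s); baseline trials hold 2, 3 or
4 standard triplets (11.5, 18 or 24.5 s); the learning stream presents 60 standard
triplets separated by 1.5 s (388.5 s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ELEMENT_DURATION = 1.5
INTER_ELEMENT_GAP = 0.25
INTER_TRIPLET_GAP = 1.5
TRIPLET_DURATION = 3 * ELEMENT_DURATION + 2 * INTER_ELEMENT_GAP  # 5.0 s
TARGET_TRIAL_DURATION = 2 * TRIPLET_DURATION + INTER_TRIPLET_GAP  # 11.5 s
N_LEARNING_TRIPLETS = 60
N_TRIALS_PER_CONDITION = 10
BASELINE_DURATIONS = (11.5, 18.0, 24.5)  # = 2, 3, 4 standard triplets
#: draw weights for the jittered baseline durations; short baselines dominate so
#: that a 20-target test phase lasts roughly 7.5-9 minutes
BASELINE_WEIGHTS = (0.7, 0.2, 0.1)

CONTOURS = {
    "A": "rising",
    "B": "slow_wave",
    "C": "fast_wave",
    "D": "falling",
    "X1": "big_spike",
    "X2": "small_spike",
}

#: grammar id -> (first category, third category) of rule-conforming triplets
GRAMMARS = {"1a": ("A", "B"), "1b": ("C", "D"), "2a": ("A", "D"), "2b": ("C", "B")}
#: paired opposite grammar (the pairing an "incorrect" triplet follows)
OPPOSITE_GRAMMAR = {"1a": "2a", "1b": "2b", "2a": "1a", "2b": "1b"}
#: the two grammar families used for counterbalancing
GRAMMAR_FAMILIES = {"1": ("1a", "1b"), "2": ("2a", "2b")}


class StimulusError(ValueError):
    """Raised for invalid category, variant, or pool requests."""


@dataclass(frozen=True)
class ToneCategory:
    name: str
    contour: str
    variants: tuple[float, ...]  # base frequencies, Hz, strictly increasing


def build_variant_table(category_name: str, x_high_encoding: str = "step30") -> ToneCategory:
    """Return the pitch-variant grid of one category.

    A–D hold 10 variants: 500–700 Hz in 50-Hz steps, then 900–1,100 Hz in 50-Hz steps
    (a 200-Hz gap between variants 5 and 6). X1/X2 hold 16 variants: 500–710 Hz in
    30-Hz steps, then a 190-Hz gap to 900 Hz. For the upper X range the printed
    endpoint (1,100 Hz) and the printed step (30 Hz) are mutually inconsistent;
    ``x_high_encoding`` selects ``"step30"`` (900–1,110 Hz, default) or
    ``"endpoint1100"`` (900–1,100 Hz, uneven step 200/7 Hz).
    """
    if category_name not in CONTOURS:
        raise StimulusError(f"unknown tone category {category_name!r}")
    if category_name in "ABCD":
        low = np.arange(500.0, 701.0, 50.0)
        high = np.arange(900.0, 1101.0, 50.0)
    else:
        low = np.arange(500.0, 711.0, 30.0)
        if x_high_encoding == "step30":
            high = 900.0 + 30.0 * np.arange(8)
        elif x_high_encoding == "endpoint1100":
            high = np.linspace(900.0, 1100.0, 8)
        else:
            raise StimulusError(f"unknown x_high_encoding {x_high_encoding!r}")
    variants = tuple(np.concatenate([low, high]).tolist())
    return ToneCategory(category_name, CONTOURS[category_name], variants)


def _contour_frequency(contour: str, f0: float, t: np.ndarray, T: float) -> np.ndarray:
    """Instantaneous-frequency trajectory (Hz) of a contour anchored at base ``f0``.

    Rising/falling are linear glides over ±20 % of the base; slow/fast waves are
    sinusoidal FM at 1 vs 3 cycles per element; spikes are a single Gaussian
    frequency excursion (50 % vs 20 % of base) centred mid-element.
    """
    x = t / T
    if contour == "rising":
        return f0 * (0.8 + 0.4 * x)
    if contour == "falling":
        return f0 * (1.2 - 0.4 * x)
    if contour == "slow_wave":
        return f0 * (1.0 + 0.2 * np.sin(2 * np.pi * 1.0 * x))
    if contour == "fast_wave":
        return f0 * (1.0 + 0.2 * np.sin(2 * np.pi * 3.0 * x))
    if contour == "big_spike":
        return f0 * (1.0 + 0.5 * np.exp(-0.5 * ((x - 0.5) / 0.08) ** 2))
    if contour == "small_spike":
        return f0 * (1.0 + 0.2 * np.exp(-0.5 * ((x - 0.5) / 0.08) ** 2))
    raise StimulusError(f"unknown contour {contour!r}")


def synthesize_element(category: str, variant_index: int, sample_rate: int = 44_100,
                       ramp: float = 0.010) -> np.ndarray:
    """Render one 1.5-s frequency-modulated sine tone.

    ``variant_index`` is 1-based, matching the variant numbering of the stimulus
    tables. Amplitude is normalised to [-1, 1] with raised-cosine on/offset ramps
    (default 10 ms) to avoid clicks.
    """
    if sample_rate < 8000:
        raise StimulusError("sample_rate must be >= 8 kHz")
    cat = build_variant_table(category)
    if not 1 <= variant_index <= len(cat.variants):
        raise StimulusError(
            f"variant {variant_index} invalid for category {category} "
            f"(1..{len(cat.variants)})")
    f0 = cat.variants[variant_index - 1]
    n = int(round(ELEMENT_DURATION * sample_rate))
    t = np.arange(n) / sample_rate
    freq = _contour_frequency(cat.contour, f0, t, ELEMENT_DURATION)
    phase = 2 * np.pi * np.cumsum(freq) / sample_rate
    y = np.sin(phase)
    nr = max(1, int(round(ramp * sample_rate)))
    env = np.ones(n)
    win = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    env[:nr] = win
    env[-nr:] = win[::-1]
    y *= env
    return y / np.max(np.abs(y))


@dataclass(frozen=True)
class Triplet:
    """One grammar sequence: three (category, 1-based variant) elements."""
    elements: tuple[tuple[str, int], tuple[str, int], tuple[str, int]]
    grammar_id: str  # nominal grammar of the list the triplet belongs to
    role: str  # standard | correct | incorrect

    @property
    def duration(self) -> float:
        return TRIPLET_DURATION

    def conforms_to(self, grammar_id: str) -> bool:
        first, third = GRAMMARS[grammar_id]
        return (self.elements[0][0] == first and self.elements[2][0] == third
                and self.elements[1][0] in ("X1", "X2"))

    def check(self) -> None:
        """Raise if the element categories contradict the declared role."""
        expected = (self.grammar_id if self.role in ("standard", "correct")
                    else OPPOSITE_GRAMMAR[self.grammar_id])
        if not self.conforms_to(expected):
            raise StimulusError(
                f"triplet {self.elements} declared {self.role}/{self.grammar_id} "
                f"but does not follow grammar {expected}")

    def spec_string(self) -> str:
        return "+".join(f"{c}{v}" for c, v in self.elements)


@dataclass(frozen=True)
class VariantPool:
    """Partition of each category's variants into familiarisation vs novel halves."""
    familiar: dict[str, tuple[int, ...]]
    novel: dict[str, tuple[int, ...]]

    def indices(self, category: str, role: str) -> tuple[int, ...]:
        table = self.familiar if role == "standard" else self.novel
        if category not in table or not table[category]:
            raise StimulusError(f"empty variant pool for {category} / {role}")
        return table[category]


def default_pool(familiar_half: str = "low") -> VariantPool:
    """Split every category's variants into low/high halves.

    ``familiar_half`` selects which half is heard during learning; test triplets
    use the other (novel) half, so test items never reuse a learned pitch variant.
    """
    fam, nov = {}, {}
    for name in CONTOURS:
        n = len(build_variant_table(name).variants)
        half = n // 2
        low, high = tuple(range(1, half + 1)), tuple(range(half + 1, n + 1))
        if familiar_half == "low":
            fam[name], nov[name] = low, high
        else:
            fam[name], nov[name] = high, low
    return VariantPool(fam, nov)


def make_triplet(grammar_id: str, role: str, pool: VariantPool,
                 rng: np.random.Generator) -> Triplet:
    """Draw one triplet of the requested role under ``grammar_id``.

    Standard and correct triplets follow the grammar's (first, third) pairing;
    incorrect triplets follow the paired opposite grammar. The middle element is
    drawn freely from X1/X2.
    """
    if grammar_id not in GRAMMARS:
        raise StimulusError(f"unknown grammar {grammar_id!r}")
    if role not in ("standard", "correct", "incorrect"):
        raise StimulusError(f"unknown role {role!r}")
    realized = grammar_id if role != "incorrect" else OPPOSITE_GRAMMAR[grammar_id]
    first_cat, third_cat = GRAMMARS[realized]
    x_cat = ("X1", "X2")[rng.integers(2)]
    elems = []
    for cat in (first_cat, x_cat, third_cat):
        idx = pool.indices(cat, role)
        elems.append((cat, int(rng.choice(idx))))
    trip = Triplet(tuple(elems), grammar_id, role)
    trip.check()
    return trip


@dataclass(frozen=True)
class StimulusList:
    list_id: int
    grammar_family: str  # "1" or "2": the family standard+correct triplets follow
    familiar_half: str
    standard: tuple[Triplet, ...]
    correct: tuple[Triplet, ...]
    incorrect: tuple[Triplet, ...]

    def check(self) -> None:
        for t in self.standard + self.correct + self.incorrect:
            t.check()
        learned = {(c, v) for t in self.standard for c, v in t.elements}
        for t in self.correct + self.incorrect:
            reused = {(c, v) for c, v in t.elements} & learned
            if reused:
                raise StimulusError(f"test triplet reuses learned variants {reused}")


def build_stimulus_lists(rng: np.random.Generator,
                         n_standard: int = N_LEARNING_TRIPLETS,
                         n_test: int = 2 * N_TRIALS_PER_CONDITION) -> list[StimulusList]:
    """Create the 4 counterbalanced stimulus lists.

    Lists 1/2 treat Grammar 1 as the learned grammar (incorrect triplets follow
    Grammar 2); lists 3/4 reverse the pairing. Odd lists familiarise on the
    low-frequency variant half, even lists on the high half, so across lists both
    sound pairings and both pitch ranges serve as "correct".
    """
    lists = []
    for list_id, (family, half) in enumerate(
            [("1", "low"), ("1", "high"), ("2", "low"), ("2", "high")], start=1):
        pool = default_pool(half)
        sub_a, sub_b = GRAMMAR_FAMILIES[family]
        def draw(role, n):
            return tuple(
                make_triplet((sub_a, sub_b)[i % 2], role, pool, rng) for i in range(n))
        sl = StimulusList(list_id, family, half, draw("standard", n_standard),
                          draw("correct", n_test), draw("incorrect", n_test))
        sl.check()
        lists.append(sl)
    return lists


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    kind: str  # standard_triplet | correct_trial | incorrect_trial | baseline_trial
    triplets: tuple[Triplet, ...]


@dataclass(frozen=True)
class SessionSchedule:
    experiment: str  # neonate | infant
    list_id: int
    phases: tuple[tuple[str, float, float], ...]  # (name, onset s, duration s)
    events: tuple[Event, ...]

    @property
    def duration(self) -> float:
        name, onset, dur = self.phases[-1]
        return onset + dur

    def phase_span(self, name: str) -> tuple[float, float]:
        for pname, onset, dur in self.phases:
            if pname == name:
                return onset, onset + dur
        raise KeyError(f"phase {name!r} not in schedule")

    def target_trials(self) -> list[Event]:
        return [e for e in self.events if e.kind in ("correct_trial", "incorrect_trial")]

    def events_df(self) -> pd.DataFrame:
        rows = [{
            "onset": e.onset,
            "duration": e.duration,
            "trial_type": e.kind,
            "grammar_id": e.triplets[0].grammar_id if e.triplets else "",
            "stim": ";".join(t.spec_string() for t in e.triplets),
        } for e in self.events]
        return pd.DataFrame(rows)


def _condition_order(rng: np.random.Generator,
                     n_per_condition: int = N_TRIALS_PER_CONDITION,
                     max_run: int = 2) -> list[str]:
    """Pseudorandom Correct/Incorrect order with no run longer than ``max_run``."""
    conds = ["correct_trial"] * n_per_condition + ["incorrect_trial"] * n_per_condition
    while True:
        order = [conds[i] for i in rng.permutation(len(conds))]
        runs = 1
        ok = True
        for a, b in zip(order, order[1:]):
            runs = runs + 1 if a == b else 1
            if runs > max_run:
                ok = False
                break
        if ok:
            return order


def schedule_session(experiment: str, stimulus_list: StimulusList,
                     rng: np.random.Generator,
                     pre_rest: float = 240.0, post_rest: float = 230.0) -> SessionSchedule:
    """Lay out the timed event stream of one experimental session.

    Neonate sessions run Pre-Rest -> Learning -> Test -> Post-Rest; infant sessions
    run Learning -> Test only. The test phase alternates target trials (2 triplets,
    11.5 s) with jittered baseline trials of 2–4 standard triplets (11.5/18/24.5 s),
    opening and closing with a baseline trial so every target is flanked by
    standard-triplet baseline on both sides.
    """
    if experiment not in ("neonate", "infant"):
        raise StimulusError(f"unknown experiment {experiment!r}")
    events: list[Event] = []
    phases: list[tuple[str, float, float]] = []
    t = 0.0
    if experiment == "neonate":
        phases.append(("PreRest", t, pre_rest))
        t += pre_rest

    # Learning: 60 standard triplets, 1.5-s inter-triplet gaps.
    standards = list(stimulus_list.standard)
    learn_onset = t
    for i in range(N_LEARNING_TRIPLETS):
        trip = standards[i % len(standards)]
        events.append(Event(t, TRIPLET_DURATION, "standard_triplet", (trip,)))
        t += TRIPLET_DURATION
        if i < N_LEARNING_TRIPLETS - 1:
            t += INTER_TRIPLET_GAP
    phases.append(("Learning", learn_onset, t - learn_onset))

    # Test: baseline / target alternation.
    test_onset = t
    order = _condition_order(rng)
    pools = {"correct_trial": list(stimulus_list.correct),
             "incorrect_trial": list(stimulus_list.incorrect)}
    cursor = {"correct_trial": 0, "incorrect_trial": 0}

    def baseline_event(start: float) -> Event:
        dur = float(rng.choice(BASELINE_DURATIONS, p=BASELINE_WEIGHTS))
        k = {11.5: 2, 18.0: 3, 24.5: 4}[dur]
        trips = tuple(standards[int(rng.integers(len(standards)))] for _ in range(k))
        return Event(start, dur, "baseline_trial", trips)

    ev = baseline_event(t)
    events.append(ev)
    t += ev.duration
    for cond in order:
        pool = pools[cond]
        i = cursor[cond]
        trips = (pool[i % len(pool)], pool[(i + 1) % len(pool)])
        cursor[cond] += 2
        events.append(Event(t, TARGET_TRIAL_DURATION, cond, trips))
        t += TARGET_TRIAL_DURATION
        ev = baseline_event(t)
        events.append(ev)
        t += ev.duration
    phases.append(("Test", test_onset, t - test_onset))

    if experiment == "neonate":
        phases.append(("PostRest", t, post_rest))
        t += post_rest
    return SessionSchedule(experiment, stimulus_list.list_id,
                           tuple(phases), tuple(events))


# ---------------------------------------------------------------------------
# Audio / event serialization
# ---------------------------------------------------------------------------

def render_event(event: Event, sample_rate: int) -> np.ndarray:
    """Waveform of one event (its triplets with intra-event gaps)."""
    parts = []
    gap_e = np.zeros(int(round(INTER_ELEMENT_GAP * sample_rate)))
    gap_t = np.zeros(int(round(INTER_TRIPLET_GAP * sample_rate)))
    for k, trip in enumerate(event.triplets):
        if k:
            parts.append(gap_t)
        for j, (cat, var) in enumerate(trip.elements):
            if j:
                parts.append(gap_e)
            parts.append(synthesize_element(cat, var, sample_rate))
    return np.concatenate(parts) if parts else np.zeros(0)


def write_session(schedule: SessionSchedule, out_dir: str | Path,
                  sample_rate: int = 44_100, seed: int | None = None,
                  write_audio: bool = True) -> dict[str, Path]:
    """Write one WAV per phase, a BIDS-style events TSV, and a JSON sidecar.

    Rest phases are rendered as silence. Event onsets in the TSV are absolute
    session times in seconds. Returns the paths written.
    """
    from scipy.io import wavfile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if write_audio:
        for name, onset, dur in schedule.phases:
            n = int(round(dur * sample_rate))
            buf = np.zeros(n, dtype=np.float64)
            for ev in schedule.events:
                if onset <= ev.onset < onset + dur:
                    wav = render_event(ev, sample_rate)
                    i0 = int(round((ev.onset - onset) * sample_rate))
                    buf[i0:i0 + len(wav)] = wav[:max(0, n - i0)]
            pcm = np.clip(buf * 32767, -32768, 32767).astype(np.int16)
            p = out / f"{name}.wav"
            wavfile.write(p, sample_rate, pcm)
            paths[f"audio_{name}"] = p
    events_path = out / "events.tsv"
    schedule.events_df().to_csv(events_path, sep="\t", index=False,
                                float_format="%.6f")
    paths["events"] = events_path
    sidecar = {"experiment": schedule.experiment, "list_id": schedule.list_id,
               "seed": seed, "sample_rate": sample_rate,
               "phases": [list(p) for p in schedule.phases]}
    sidecar_path = out / "session.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = sidecar_path
    return paths


def read_events(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the events TSV written by :func:`write_session`."""
    return pd.read_csv(path, sep="\t", keep_default_na=False)
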