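"""Synthetic 2 kHz electrodermal (EDA) and startle-EMG recordings.

Renders per-subject physiological signals from an event timeline with
injectable, condition-dependent effect sizes, so the whole scoring and
statistics pipeline can be exercised without real recordings.  The injected
effect structure mirrors the qualitative findings of real-time observational
fear learning experiments:

* the demonstrator's shock reactions (observational US) evoke large skin
  conductance responses in every observer;
* a CS+ > CS- electrodermal differential in the direct-expression phase
  appears only in contingency-aware observers;
* startle bursts are larger in the direct-expression phase than during
  observation, and larger during CS presentations than fixation only in
  aware observers.

EDA model: tonic level + slow linear drift + Gaussian noise + a sum of
biexponential (Bateman-type) response kernels placed ``scr_latency`` after
each triggering event.  Per-event amplitudes are lognormal around the
condition mean (SCR amplitudes are non-negative and right-skewed) and are
zeroed with probability ``1 - response_prob``; US-locked responses always
occur.  On reinforced trials an additional US-sized response is injected at
CS onset so that CS-anchored scoring of the observational US is exercised.

EMG model: baseline Gaussian noise plus, at each startle probe, an additive
burst of 30-300 Hz band-limited noise under a Hann envelope, starting
``burst_latency`` after probe onset.  Bursts are normalized so that the
rectified-and-smoothed peak (what the startle scorer measures) equals the
intended gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import signal

from .design import (
    CsType,
    DesignConfig,
    EventKind,
    EventTimeline,
    Phase,
    build_timeline,
)

__all__ = [
    "SynthParams",
    "Recording",
    "QuestionnaireAnswers",
    "SubjectData",
    "LIKERT_QUESTIONS",
    "scr_kernel",
    "scr_kernel_peak_time",
    "render_eda",
    "render_emg",
    "render_questionnaire",
    "simulate_subject",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic signal generator.

    Amplitude defaults encode the study conditions the generator emulates:
    US-evoked skin conductance responses (0.8 uS) dominate CS-evoked ones;
    in the direct-expression (DE) phase aware subjects show a CS+ (0.30 uS)
    vs CS- (0.18 uS) differential while unaware subjects respond 0.18 uS to
    both; observational-phase CS responses are 0.15 uS.  Startle burst
    envelope gains are larger in DE (0.14 mV) than OFL (0.10 mV), with
    CS-driven boosts (x1.25 CS+, x1.15 CS-) only in aware subjects.
    """

    fs: float = 2000.0
    # --- EDA
    scr_rise_tau: float = 0.75
    scr_decay_tau: float = 3.0
    scr_latency: float = 1.5
    tonic_level: float = 5.0
    tonic_drift: float = 0.05          # uS per minute
    eda_noise_sd: float = 0.01
    amp_us: float = 0.8
    amp_cs_plus_aware_de: float = 0.30
    amp_cs_minus_aware_de: float = 0.18
    amp_cs_unaware_de: float = 0.18
    amp_cs_ofl: float = 0.15
    response_prob: float = 0.9
    lognormal_amp_cv: float = 0.4
    # --- EMG
    emg_noise_sd: float = 0.01
    burst_gain_ofl: float = 0.10
    burst_gain_de: float = 0.14
    burst_cs_plus_boost_aware_de: float = 1.25
    burst_cs_minus_boost_aware_de: float = 1.15
    burst_latency: float = 0.035
    burst_duration: float = 0.1
    burst_band: tuple[float, float] = (30.0, 300.0)
    # --- cohort
    p_aware: float = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scr_rise_tau <= 0 or self.scr_decay_tau <= 0:
            raise ValueError("SCR time constants must be > 0")
        if self.scr_rise_tau >= self.scr_decay_tau:
            raise ValueError("scr_rise_tau must be < scr_decay_tau")
        amps = (
            self.amp_us, self.amp_cs_plus_aware_de, self.amp_cs_minus_aware_de,
            self.amp_cs_unaware_de, self.amp_cs_ofl,
        )
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be >= 0")
        if self.fs <= 2 * 500.0:
            raise ValueError("fs must exceed 1000 Hz so the EMG band is representable")
        if not (0.0 <= self.p_aware <= 1.0):
            raise ValueError("p_aware must be in [0, 1]")


@dataclass
class Recording:
    """Fixed-rate multi-channel physiological time series for one subject."""

    fs: float
    eda: np.ndarray
    emg: np.ndarray
    subject_id: str
    role: str = "observer"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eda = np.asarray(self.eda, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eda.shape != self.emg.shape:
            raise ValueError("all channels must have equal length")
        if not (np.isfinite(self.eda).all() and np.isfinite(self.emg).all()):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.eda.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


LIKERT_QUESTIONS = ("discomfort", "strength", "naturalness", "empathy", "identification")

#: (min, max, median, IQR) used to sample each post-experiment Likert rating.
_LIKERT_SHAPE = {
    "discomfort": (2, 8, 6, 2),
    "strength": (2, 8, 6, 3),
    "naturalness": (2, 9, 8, 2),
    "empathy": (0, 9, 4, 4),
    "identification": (1, 9, 7, 2),
}


@dataclass
class QuestionnaireAnswers:
    """Post-experiment contingency questionnaire plus demonstration ratings.

    The contingency part progresses from the open-ended rule report, through
    percentage ratings of shock probability per stimulus, to a forced choice
    among CS+, CS- and the fixation cross.
    """

    rule_reported: bool
    rule_stimulus: str | None
    pct_ratings: dict[str, float]
    forced_choice: str
    likert_ratings: dict[str, int]
    subject_id: str = ""

    def __post_init__(self) -> None:
        for v in self.pct_ratings.values():
            if not (0.0 <= v <= 100.0):
                raise ValueError("percentage ratings must be in [0, 100]")
        for v in self.likert_ratings.values():
            if not (0 <= v <= 9):
                raise ValueError("Likert ratings must be in [0, 9]")


@dataclass
class SubjectData:
    """One synthetic observer: timelines, recordings per phase, answers."""

    subject_id: str
    aware: bool
    timelines: dict[Phase, EventTimeline]
    recordings: dict[Phase, Recording]
    answers: QuestionnaireAnswers


# ---------------------------------------------------------------------------
# SCR kernel
# ---------------------------------------------------------------------------

def scr_kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the biexponential kernel maximum (closed form from dh/dt=0)."""
    return math.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)


def scr_kernel(t: np.ndarray | float, rise_tau: float = 0.75,
               decay_tau: float = 3.0) -> np.ndarray:
    """Peak-normalized biexponential SCR shape.

    ``h(t) = (exp(-t/decay_tau) - exp(-t/rise_tau)) / c`` with ``c`` chosen
    so that ``max_t h(t) = 1``; ``h(0) = 0`` and ``h(t<0) = 0``.
    """
    if rise_tau >= decay_tau:
        raise ValueError("rise_tau must be < decay_tau")
    t = np.asarray(t, dtype=float)
    tpk = scr_kernel_peak_time(rise_tau, decay_tau)
    norm = math.exp(-tpk / decay_tau) - math.exp(-tpk / rise_tau)
    out = np.where(t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0) / norm
    return out


# ---------------------------------------------------------------------------
# EDA rendering
# ---------------------------------------------------------------------------

def _lognormal_amp(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean == 0.0:
        return 0.0
    if cv == 0.0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _recording_length(timeline: EventTimeline, fs: float, tail: float = 1.0) -> int:
    return int(round((timeline.duration + tail) * fs))


def _cs_amplitude(params: SynthParams, phase: Phase, cs: CsType, aware: bool) -> float:
    if phase is Phase.OFL:
        return params.amp_cs_ofl
    if not aware:
        return params.amp_cs_unaware_de
    if cs is CsType.CS_PLUS:
        return params.amp_cs_plus_aware_de
    return params.amp_cs_minus_aware_de


def render_eda(
    timeline: EventTimeline,
    params: SynthParams,
    aware: bool,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render the electrodermal channel (uS) for one phase.

    Tonic level + drift + Gaussian noise + event-locked SCR kernels.  Each
    CS onset triggers a response with the condition-dependent mean
    amplitude; every US triggers an ``amp_us``-scale response, and
    reinforced trials additionally receive a US-sized response at CS onset
    (the observer's reaction to watching the shock, which CS-anchored US
    scoring picks up).
    """
    rng = np.random.default_rng(seed)
    fs = params.fs
    n = _recording_length(timeline, fs)
    t_min = np.arange(n) / fs / 60.0
    out = params.tonic_level + params.tonic_drift * t_min
    if params.eda_noise_sd > 0:
        out = out + rng.normal(0.0, params.eda_noise_sd, size=n)

    # responses: (onset seconds, mean amplitude, always fires)
    triggers: list[tuple[float, float, bool]] = []
    for tr in timeline.trials:
        amp = _cs_amplitude(params, timeline.phase, tr.cs_type, aware)
        triggers.append((tr.onset, amp, False))
        if tr.reinforced:
            triggers.append((tr.onset, params.amp_us, True))
            triggers.append((tr.onset + timeline.us_onset_in_cs, params.amp_us, True))

    kernel_span = 8.0 * params.scr_decay_tau
    kt = np.arange(int(round(kernel_span * fs))) / fs
    kernel = scr_kernel(kt, params.scr_rise_tau, params.scr_decay_tau)
    for onset, mean_amp, always in triggers:
        if not always and rng.uniform() > params.response_prob:
            continue
        amp = _lognormal_amp(rng, mean_amp, params.lognormal_amp_cv)
        if amp == 0.0:
            continue
        i0 = int(round((onset + params.scr_latency) * fs))
        i1 = min(i0 + kernel.size, n)
        if i0 >= n:
            continue
        out[i0:i1] += amp * kernel[: i1 - i0]
    return out


# ---------------------------------------------------------------------------
# EMG rendering
# ---------------------------------------------------------------------------

def _burst_shapes(
    n_bursts: int, params: SynthParams, rng: np.random.Generator,
    smoothing_taps: np.ndarray,
) -> np.ndarray:
    """Hann-windowed band-limited noise bursts, each normalized so the peak
    of its rectified-and-smoothed envelope equals 1 (so the startle scorer
    measures exactly the injected gain)."""
    fs = params.fs
    nb = int(round(params.burst_duration * fs))
    pad = nb  # filter transient padding
    white = rng.standard_normal((n_bursts, nb + 2 * pad))
    sos = signal.butter(4, params.burst_band, btype="bandpass", fs=fs, output="sos")
    carriers = signal.sosfiltfilt(sos, white, axis=-1)[:, pad : pad + nb]
    shapes = np.hanning(nb)[None, :] * carriers
    smoothed = signal.oaconvolve(
        np.abs(shapes), smoothing_taps[None, :], mode="same", axes=-1
    )
    peaks = smoothed.max(axis=-1, keepdims=True)
    peaks[peaks <= 0] = 1.0  # degenerate draws stay unnormalized
    return shapes / peaks


def _smoothing_taps(fs: float, cutoff: float = 40.0) -> np.ndarray:
    """The 40 Hz low-pass FIR used by the startle scorer, reused here so the
    burst normalization matches what the scorer will measure."""
    numtaps = 2 * int(round(0.1 * fs)) + 1
    return signal.firwin(numtaps, cutoff, fs=fs)


def render_emg(
    timeline: EventTimeline,
    params: SynthParams,
    aware: bool,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render the startle-EMG channel (mV) for one phase.

    Baseline Gaussian noise everywhere; at each probe an additive burst
    whose envelope gain is phase gain x condition boost x per-trial
    lognormal variability.  Condition boosts apply only in the DE phase of
    aware subjects (CS+ x1.25, CS- x1.15, fixation x1.0); unaware subjects
    and the OFL phase have all boosts equal to 1.
    """
    rng = np.random.default_rng(seed)
    fs = params.fs
    n = _recording_length(timeline, fs)
    out = (
        rng.normal(0.0, params.emg_noise_sd, size=n)
        if params.emg_noise_sd > 0
        else np.zeros(n)
    )
    phase_gain = params.burst_gain_ofl if timeline.phase is Phase.OFL else params.burst_gain_de
    taps = _smoothing_taps(fs)
    probes = timeline.probe_onsets()
    if not probes:
        return out
    shapes = _burst_shapes(len(probes), params, rng, taps)
    for (onset, trial, where), shape in zip(probes, shapes):
        boost = 1.0
        if timeline.phase is Phase.DE and aware and where == "cs":
            boost = (
                params.burst_cs_plus_boost_aware_de
                if trial.cs_type is CsType.CS_PLUS
                else params.burst_cs_minus_boost_aware_de
            )
        gain = phase_gain * boost * _lognormal_amp(rng, 1.0, params.lognormal_amp_cv)
        burst = gain * shape
        i0 = int(round((onset + params.burst_latency) * fs))
        i1 = min(i0 + burst.size, n)
        if i0 >= n:
            continue
        out[i0:i1] += burst[: i1 - i0]
    return out


# ---------------------------------------------------------------------------
# Questionnaire rendering
# ---------------------------------------------------------------------------

def _likert(rng: np.random.Generator) -> dict[str, int]:
    out = {}
    for q, (lo, hi, med, iqr) in _LIKERT_SHAPE.items():
        draw = rng.normal(med, max(iqr, 1) / 1.349)
        out[q] = int(np.clip(round(draw), lo, hi))
    return out


def render_questionnaire(
    aware: bool,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "",
) -> QuestionnaireAnswers:
    """Draw questionnaire answers consistent with the awareness flag.

    Aware subjects pick CS+ in the forced choice and either report the rule
    for CS+ or give CS+ the uniquely highest shock-probability rating (or
    both).  Unaware subjects are drawn from incorrect / inconsistent answer
    patterns, so classification recovers the flag for every seed.
    """
    rng = np.random.default_rng(seed)
    likert = _likert(rng)
    if aware:
        plus = float(rng.integers(60, 101))
        minus = float(rng.integers(0, int(plus) - 9))
        fix = float(rng.integers(0, int(minus) + 1))
        basis = int(rng.integers(3))  # 0: rule only, 1: pct only, 2: both
        return QuestionnaireAnswers(
            rule_reported=basis != 1,
            rule_stimulus="CS_PLUS" if basis != 1 else None,
            pct_ratings={"CS_PLUS": plus, "CS_MINUS": minus, "FIXATION": fix},
            forced_choice="CS_PLUS",
            likert_ratings=likert,
            subject_id=subject_id,
        )
    pattern = int(rng.integers(3))
    if pattern == 0:  # wrong forced choice
        forced = "CS_MINUS" if rng.uniform() < 0.7 else "FIXATION"
        minus = float(rng.integers(40, 91))
        return QuestionnaireAnswers(
            rule_reported=False,
            rule_stimulus=None,
            pct_ratings={"CS_PLUS": float(rng.integers(0, 41)), "CS_MINUS": minus,
                         "FIXATION": float(rng.integers(0, 31))},
            forced_choice=forced,
            likert_ratings=likert,
            subject_id=subject_id,
        )
    if pattern == 1:  # correct forced choice but inconsistent rule + ratings
        minus = float(rng.integers(50, 91))
        return QuestionnaireAnswers(
            rule_reported=True,
            rule_stimulus="CS_MINUS",
            pct_ratings={"CS_PLUS": float(rng.integers(0, int(minus))),
                         "CS_MINUS": minus, "FIXATION": float(rng.integers(0, 31))},
            forced_choice="CS_PLUS",
            likert_ratings=likert,
            subject_id=subject_id,
        )
    # correct forced choice, no rule, tied ratings (no unique maximum)
    tied = float(rng.integers(30, 71))
    return QuestionnaireAnswers(
        rule_reported=False,
        rule_stimulus=None,
        pct_ratings={"CS_PLUS": tied, "CS_MINUS": tied,
                     "FIXATION": float(rng.integers(0, int(tied) + 1))},
        forced_choice="CS_PLUS",
        likert_ratings=likert,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    subject_id: str,
    cfg: DesignConfig,
    params: SynthParams,
    aware: bool,
    seed: int | np.random.SeedSequence,
) -> SubjectData:
    """Render both phases (timelines, EDA, EMG) and answers for one subject."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    kids = ss.spawn(5)
    timelines: dict[Phase, EventTimeline] = {}
    recordings: dict[Phase, Recording] = {}
    tl_ofl = build_timeline(cfg, Phase.OFL, np.random.default_rng(kids[0]))
    tl_de = build_timeline(cfg, Phase.DE, np.random.default_rng(kids[4]))
    rng_eda = np.random.default_rng(kids[1])
    rng_emg = np.random.default_rng(kids[2])
    for phase, tl in ((Phase.OFL, tl_ofl), (Phase.DE, tl_de)):
        eda = render_eda(tl, params, aware, rng_eda)
        emg = render_emg(tl, params, aware, rng_emg)
        timelines[phase] = tl
        recordings[phase] = Recording(
            fs=params.fs, eda=eda, emg=emg, subject_id=subject_id,
            meta={"phase": phase.value, "aware_ground_truth": aware},
        )
    answers = render_questionnaire(aware, np.random.default_rng(kids[3]), subject_id)
    return SubjectData(subject_id, aware, timelines, recordings, answers)


def draw_awareness(
    n_subjects: int,
    params: SynthParams,
    seed: int | np.random.SeedSequence | None,
    n_aware: int | None = None,
) -> list[bool]:
    """Awareness flags for a cohort: Bernoulli(p_aware) draws, or exactly
    *n_aware* aware subjects first when a fixed group split is requested."""
    if n_aware is not None:
        if not (0 <= n_aware <= n_subjects):
            raise ValueError("n_aware out of range")
        return [i < n_aware for i in range(n_subjects)]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    return [bool(rng.uniform() < params.p_aware) for _ in range(n_subjects)]


def iter_cohort(
    n_subjects: int,
    cfg: DesignConfig | None = None,
    params: SynthParams | None = None,
    seed: int | None = None,
    n_aware: int | None = None,
) -> Iterator[SubjectData]:
    """Lazily yield subject bundles; per-subject seeds derive from *seed*."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cfg = cfg or DesignConfig()
    params = params or SynthParams()
    master = np.random.SeedSequence(seed if seed is not None else params.seed)
    aware_ss, subj_ss = master.spawn(2)
    flags = draw_awareness(n_subjects, params, aware_ss, n_aware)
    for i, (aware, child) in enumerate(zip(flags, subj_ss.spawn(n_subjects))):
        yield simulate_subject(f"sub-{i + 1:03d}", cfg, params, aware, child)


def simulate_cohort(
    n_subjects: int,
    cfg: DesignConfig | None = None,
    params: SynthParams | None = None,
    seed: int | None = None,
    n_aware: int | None = None,
    out_dir: str | None = None,
) -> list[SubjectData]:
    """Materialize a cohort; optionally write all per-subject files.

    Identical arguments always produce identical cohorts.  With *out_dir*
    the recordings, events, and questionnaire tables are written in the
    package's tab-separated formats (one subdirectory per subject).
    """
    subjects = list(iter_cohort(n_subjects, cfg, params, seed, n_aware))
    if out_dir is not None:
        from . import io as _io

        _io.write_cohort(subjects, out_dir)
    return subjects
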