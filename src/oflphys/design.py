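"""Experimental-design generation for the two-phase observational fear
learning (OFL) task.

The experiment has an observational learning phase (OFL: the observer
watches a demonstrator undergo differential fear conditioning) followed by a
direct-expression phase (DE: the observer faces the conditioned stimuli
directly, with no shocks).  This module generates the trial sequence and the
full event timeline under the task's constraints:

* pseudo-random CS+/CS- order, no more than ``max_run_length`` identical
  stimuli in a row;
* half of the CS+ trials reinforced with the shock (US), the first and the
  last CS+ always reinforced;
* 9 s CS presentations separated by 10-15 s fixation intervals;
* the US as a train of 5 brief electrical pulses starting 7.5 s after CS
  onset;
* acoustic startle probes in half of the CS presentations (onset 6.0, 6.5 or
  7.0 s after CS onset) and a quarter of the intertrial intervals (onset
  2.0-4.5 s after fixation onset).

All random draws go through a :class:`numpy.random.Generator`; every public
operation is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Phase",
    "CsType",
    "EventKind",
    "DesignConfig",
    "Trial",
    "Event",
    "EventTimeline",
    "DesignError",
    "generate_cs_sequence",
    "assign_reinforcement",
    "assign_probes",
    "build_timeline",
    "us_train_duration",
    "FROZEN_SEQUENCES",
]

#: Resolution (seconds) to which all generated event times are quantized.
#: 1 ms keeps the events file round-trippable at 3 decimals and is finer
#: than any scoring window of interest.
TIME_QUANTUM = 1e-3


class Phase(str, Enum):
    """Task phase: observational learning or direct expression."""

    OFL = "OFL"
    DE = "DE"


class CsType(str, Enum):
    CS_PLUS = "CS_PLUS"
    CS_MINUS = "CS_MINUS"


class EventKind(str, Enum):
    CS_PLUS = "CS_PLUS"
    CS_MINUS = "CS_MINUS"
    FIXATION = "FIXATION"
    US = "US"
    PROBE = "PROBE"


class DesignError(ValueError):
    """Raised when a design constraint set is invalid or infeasible."""


def _quantize(t: float) -> float:
    return round(round(t / TIME_QUANTUM) * TIME_QUANTUM, 3)


@dataclass(frozen=True)
class DesignConfig:
    """All timing / count / ratio constants of the two-phase experiment.

    Defaults reproduce the published task: 24+24 OFL trials, 12+12 DE
    trials, 50% reinforcement, 9 s CS, 10-15 s ITI, US at 7.5 s after CS
    onset (5 x 1 ms pulses, 200 ms inter-pulse latency), probes in half of
    CSs and a quarter of ITIs.
    """

    n_cs_plus_ofl: int = 24
    n_cs_minus_ofl: int = 24
    n_cs_plus_de: int = 12
    n_cs_minus_de: int = 12
    reinforcement_ratio: float = 0.5
    cs_duration: float = 9.0
    iti_range: tuple[float, float] = (10.0, 15.0)
    us_onset_in_cs: float = 7.5
    us_n_pulses: int = 5
    us_pulse_duration: float = 0.001
    us_pulse_latency: float = 0.200
    probe_cs_fraction: float = 0.5
    probe_cs_onsets: tuple[float, ...] = (6.0, 6.5, 7.0)
    probe_iti_fraction: float = 0.25
    probe_iti_onset_range: tuple[float, float] = (2.0, 4.5)
    probe_duration: float = 0.050
    max_run_length: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = (
            self.n_cs_plus_ofl,
            self.n_cs_minus_ofl,
            self.n_cs_plus_de,
            self.n_cs_minus_de,
            self.us_n_pulses,
            self.max_run_length,
        )
        if any(c <= 0 for c in counts):
            raise DesignError("all counts must be > 0")
        if not (0.0 < self.reinforcement_ratio <= 1.0):
            raise DesignError("reinforcement_ratio must be in (0, 1]")
        if self.iti_range[0] > self.iti_range[1]:
            raise DesignError("iti_range must be ordered (low, high)")
        if any(o >= self.cs_duration for o in self.probe_cs_onsets):
            raise DesignError("probe_cs_onsets must all fall before CS offset")
        if self.us_onset_in_cs >= self.cs_duration:
            raise DesignError("us_onset_in_cs must fall before CS offset")
        if not (0.0 <= self.probe_cs_fraction <= 1.0):
            raise DesignError("probe_cs_fraction must be in [0, 1]")
        if not (0.0 <= self.probe_iti_fraction <= 1.0):
            raise DesignError("probe_iti_fraction must be in [0, 1]")

    def n_cs(self, phase: Phase) -> tuple[int, int]:
        """(n CS+, n CS-) for *phase*."""
        if phase is Phase.OFL:
            return self.n_cs_plus_ofl, self.n_cs_minus_ofl
        return self.n_cs_plus_de, self.n_cs_minus_de


@dataclass(frozen=True)
class Trial:
    """One CS presentation followed by its intertrial (fixation) interval.

    ``onset`` is seconds from phase start; all intervals are half-open
    ``[onset, onset + duration)``.  ``probe_onset`` is relative to CS onset,
    ``iti_probe_onset`` relative to fixation onset; either is ``None`` when
    the trial carries no such probe.
    """

    index: int
    phase: Phase
    cs_type: CsType
    onset: float
    reinforced: bool
    iti_duration: float
    probe_onset: float | None = None
    iti_probe_onset: float | None = None

    def __post_init__(self) -> None:
        if self.reinforced and self.cs_type is not CsType.CS_PLUS:
            raise DesignError("only CS+ trials can be reinforced")
        if self.reinforced and self.phase is not Phase.OFL:
            raise DesignError("reinforcement only occurs in the OFL phase")


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    kind: EventKind
    trial_index: int


@dataclass
class EventTimeline:
    """Ordered trials plus the flattened event list for one phase.

    ``lead_in`` is the duration of the initial fixation shown before the
    first CS (it provides a pre-stimulus baseline for the first trial).
    ``events`` is sorted by onset; CS events never overlap; every US event
    lies inside its parent CS+ interval.
    """

    phase: Phase
    trials: list[Trial]
    events: list[Event]
    lead_in: float
    cs_duration: float
    us_onset_in_cs: float

    @property
    def duration(self) -> float:
        """Total phase duration (end of the last fixation interval)."""
        last = self.trials[-1]
        return _quantize(last.onset + self.cs_duration + last.iti_duration)

    def probe_onsets(self) -> list[tuple[float, Trial, str]]:
        """Absolute probe onsets with their parent trial and location.

        Location is ``"cs"`` for probes during the CS and ``"iti"`` for
        probes during the following fixation interval.
        """
        out: list[tuple[float, Trial, str]] = []
        for tr in self.trials:
            if tr.probe_onset is not None:
                out.append((_quantize(tr.onset + tr.probe_onset), tr, "cs"))
            if tr.iti_probe_onset is not None:
                onset = tr.onset + self.cs_duration + tr.iti_probe_onset
                out.append((_quantize(onset), tr, "iti"))
        out.sort(key=lambda item: item[0])
        return out

    def validate(self) -> None:
        onsets = [ev.onset for ev in self.events]
        if onsets != sorted(onsets):
            raise DesignError("events not sorted by onset")
        cs_iv = [
            (ev.onset, ev.onset + ev.duration)
            for ev in self.events
            if ev.kind in (EventKind.CS_PLUS, EventKind.CS_MINUS)
        ]
        for (a0, a1), (b0, b1) in zip(cs_iv, cs_iv[1:]):
            if b0 < a1:
                raise DesignError("overlapping CS events")
        cs_by_trial = {
            ev.trial_index: ev
            for ev in self.events
            if ev.kind in (EventKind.CS_PLUS, EventKind.CS_MINUS)
        }
        for ev in self.events:
            if ev.kind is EventKind.US:
                cs = cs_by_trial[ev.trial_index]
                if not (cs.onset <= ev.onset and ev.onset + ev.duration <= cs.onset + cs.duration):
                    raise DesignError("US event outside its parent CS+ interval")
                if cs.kind is not EventKind.CS_PLUS:
                    raise DesignError("US event attached to a CS- trial")


# ---------------------------------------------------------------------------
# CS sequence generation
# ---------------------------------------------------------------------------

def _completable(n_same: int, n_other: int, run: int, max_run: int,
                 memo: dict) -> bool:
    """Can a valid suffix be built with *n_same* items of the label currently
    on a *run*-long run and *n_other* of the other label?"""
    key = (n_same, n_other, run)
    hit = memo.get(key)
    if hit is not None:
        return hit
    if n_same == 0 and n_other == 0:
        res = True
    else:
        res = False
        if n_same > 0 and run < max_run:
            res = _completable(n_same - 1, n_other, run + 1, max_run, memo)
        if not res and n_other > 0:
            res = _completable(n_other - 1, n_same, 1, max_run, memo)
    memo[key] = res
    return res


def generate_cs_sequence(
    n_plus: int,
    n_minus: int,
    max_run_length: int = 2,
    seed: int | np.random.Generator | None = None,
) -> list[CsType]:
    """Draw a pseudo-random CS order with a bounded run length.

    The sequence contains exactly *n_plus* CS+ and *n_minus* CS- labels and
    never repeats the same label more than *max_run_length* times in a row.
    Construction is sequential: at each position the next label is drawn
    uniformly among the labels that still admit a valid completion, so no
    rejection sampling is needed and infeasible constraint sets fail fast.

    Raises
    ------
    DesignError
        If no sequence satisfies the constraints (e.g. ``n_plus=3,
        n_minus=0, max_run_length=2``).
    """
    if n_plus < 1 or n_minus < 1:
        raise DesignError("need at least one trial of each CS type")
    if max_run_length < 1:
        raise DesignError("max_run_length must be >= 1")
    rng = np.random.default_rng(seed)
    memo: dict = {}
    if not (
        _completable(n_plus - 1, n_minus, 1, max_run_length, memo)
        or _completable(n_minus - 1, n_plus, 1, max_run_length, memo)
    ):
        raise DesignError(
            f"no CS sequence with n_plus={n_plus}, n_minus={n_minus}, "
            f"max_run_length={max_run_length} exists"
        )
    seq: list[CsType] = []
    remaining = {CsType.CS_PLUS: n_plus, CsType.CS_MINUS: n_minus}
    last: CsType | None = None
    run = 0
    for _ in range(n_plus + n_minus):
        options = []
        for label in (CsType.CS_PLUS, CsType.CS_MINUS):
            if remaining[label] == 0:
                continue
            new_run = run + 1 if label is last else 1
            if new_run > max_run_length:
                continue
            other = CsType.CS_MINUS if label is CsType.CS_PLUS else CsType.CS_PLUS
            if _completable(
                remaining[label] - 1, remaining[other], new_run, max_run_length, memo
            ):
                options.append(label)
        if not options:  # pragma: no cover - excluded by feasibility check
            raise DesignError("sequence construction reached a dead end")
        pick = options[int(rng.integers(len(options)))] if len(options) > 1 else options[0]
        seq.append(pick)
        run = run + 1 if pick is last else 1
        last = pick
        remaining[pick] -= 1
    return seq


def assign_reinforcement(
    sequence: Sequence[CsType],
    ratio: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> frozenset[int]:
    """Choose which CS+ trials are reinforced with the shock.

    Exactly ``round(ratio * n_CS+)`` CS+ trials are reinforced (banker's
    rounding, so 24 x 0.5 -> 12 exactly); the first and the last CS+ in the
    sequence are always reinforced; CS- trials never are.  Returns the set
    of reinforced positions in *sequence*.
    """
    plus_idx = [i for i, c in enumerate(sequence) if c is CsType.CS_PLUS]
    if len(plus_idx) < 2:
        raise DesignError("need at least two CS+ trials for first/last reinforcement")
    n_reinforced = round(ratio * len(plus_idx))
    if n_reinforced < 2:
        raise DesignError(
            f"ratio {ratio} yields {n_reinforced} reinforced trials but the "
            "first/last rule requires at least 2"
        )
    rng = np.random.default_rng(seed)
    chosen = {plus_idx[0], plus_idx[-1]}
    middle = np.array(plus_idx[1:-1])
    extra = n_reinforced - 2
    if extra > 0:
        chosen.update(int(i) for i in rng.choice(middle, size=extra, replace=False))
    return frozenset(chosen)


# ---------------------------------------------------------------------------
# Probe assignment
# ---------------------------------------------------------------------------

def _split_half(indices: list[int], n_probed: int, rng: np.random.Generator) -> set[int]:
    if n_probed > len(indices):
        raise DesignError("cannot probe more trials than available")
    picked = rng.choice(np.array(indices), size=n_probed, replace=False)
    return {int(i) for i in picked}


def assign_probes(
    timeline: EventTimeline,
    cfg: DesignConfig,
    seed: int | np.random.Generator | None = None,
) -> EventTimeline:
    """Place startle probes on a timeline.

    CS probes: ``floor(probe_cs_fraction * n_CS)`` trials carry a probe,
    balanced exactly across CS+ and CS-, with onsets drawn from
    ``cfg.probe_cs_onsets``.  Within CS+, probed trials are additionally
    stratified across reinforced and unreinforced subsets so that the
    US-response scoring (which discards probed trials) retains equal trial
    counts per condition.

    ITI probes: ``floor(probe_iti_fraction * n_ITI)`` fixation intervals
    carry a probe with onset uniform in ``cfg.probe_iti_onset_range``; ITI
    probe counts are balanced between the intervals that follow unprobed
    reinforced and unprobed unreinforced CS+ trials, for the same reason.
    The 4.5 s onset cap against the 10 s minimum ITI guarantees probes never
    interfere with the next CS.
    """
    rng = np.random.default_rng(seed)
    trials = list(timeline.trials)
    n_trials = len(trials)
    plus = [t.index for t in trials if t.cs_type is CsType.CS_PLUS]
    minus = [t.index for t in trials if t.cs_type is CsType.CS_MINUS]
    n_cs_probes = math.floor(cfg.probe_cs_fraction * n_trials)
    n_plus_probes = n_cs_probes // 2
    n_minus_probes = n_cs_probes - n_plus_probes

    reinforced = [i for i in plus if trials[i].reinforced]
    unreinforced = [i for i in plus if not trials[i].reinforced]
    probed: set[int] = set()
    if reinforced and unreinforced:
        n_r = n_plus_probes // 2
        n_u = n_plus_probes - n_r
        if n_u > len(unreinforced):  # rebalance if subsets are uneven
            n_u = len(unreinforced)
            n_r = n_plus_probes - n_u
        probed |= _split_half(reinforced, n_r, rng)
        probed |= _split_half(unreinforced, n_u, rng)
    else:
        probed |= _split_half(plus, n_plus_probes, rng)
    probed |= _split_half(minus, n_minus_probes, rng)

    onset_choices = np.array(cfg.probe_cs_onsets)
    cs_probe_onset = {
        i: float(onset_choices[int(rng.integers(len(onset_choices)))]) for i in sorted(probed)
    }

    # --- ITI probes, balanced over the US-scoreable CS+ candidate classes
    n_iti_probes = math.floor(cfg.probe_iti_fraction * n_trials)
    iti_probed = set(
        int(i) for i in rng.choice(np.arange(n_trials), size=n_iti_probes, replace=False)
    )
    cls_r = [i for i in reinforced if i not in probed]
    cls_u = [i for i in unreinforced if i not in probed]
    if cls_r and cls_u:
        iti_probed = _balance_iti_probes(iti_probed, cls_r, cls_u, n_trials, rng)

    lo, hi = cfg.probe_iti_onset_range
    new_trials = []
    for tr in trials:
        kw: dict = {}
        if tr.index in cs_probe_onset:
            kw["probe_onset"] = cs_probe_onset[tr.index]
        if tr.index in iti_probed:
            kw["iti_probe_onset"] = _quantize(rng.uniform(lo, hi))
        new_trials.append(replace(tr, **kw) if kw else tr)
    return _timeline_from_trials(timeline.phase, new_trials, timeline.lead_in, cfg)


def _balance_iti_probes(
    iti_probed: set[int],
    cls_r: list[int],
    cls_u: list[int],
    n_trials: int,
    rng: np.random.Generator,
) -> set[int]:
    """Equalize ITI-probe counts between two trial classes, keeping the total.

    Moves probes between classes (or to unaffiliated trials when parity
    forbids an equal split) until the two classes carry equal counts.
    """
    iti_probed = set(iti_probed)
    other = [i for i in range(n_trials) if i not in cls_r and i not in cls_u]

    def counts() -> tuple[list[int], list[int]]:
        return [i for i in cls_r if i in iti_probed], [i for i in cls_u if i in iti_probed]

    in_r, in_u = counts()
    if (len(in_r) + len(in_u)) % 2 == 1:
        # odd total across the two classes: move one probe out to a free slot
        donor_cls = in_r if len(in_r) >= len(in_u) else in_u
        free = [i for i in other if i not in iti_probed]
        if free:
            iti_probed.discard(donor_cls[int(rng.integers(len(donor_cls)))])
            iti_probed.add(free[int(rng.integers(len(free)))])
    in_r, in_u = counts()
    while len(in_r) != len(in_u):
        src, dst_cls = (in_r, cls_u) if len(in_r) > len(in_u) else (in_u, cls_r)
        free = [i for i in dst_cls if i not in iti_probed]
        iti_probed.discard(src[int(rng.integers(len(src)))])
        iti_probed.add(free[int(rng.integers(len(free)))])
        in_r, in_u = counts()
    return iti_probed


# ---------------------------------------------------------------------------
# Timeline construction
# ---------------------------------------------------------------------------

def us_train_duration(n_pulses: int, pulse_duration: float, latency: float) -> float:
    """Span of the US pulse train in seconds, rounded to 1 decimal.

    Measured from the onset of the first pulse to the offset of the last:
    ``(n_pulses - 1) * latency + pulse_duration``.  The default train
    (5 pulses, 1 ms each, 200 ms latency) spans 0.8 s.
    """
    if n_pulses < 1:
        raise DesignError("n_pulses must be >= 1")
    return round((n_pulses - 1) * latency + pulse_duration, 1)


def _timeline_from_trials(
    phase: Phase, trials: list[Trial], lead_in: float, cfg: DesignConfig
) -> EventTimeline:
    events: list[Event] = [Event(0.0, lead_in, EventKind.FIXATION, -1)]
    us_span = (cfg.us_n_pulses - 1) * cfg.us_pulse_latency + cfg.us_pulse_duration
    for tr in trials:
        kind = EventKind.CS_PLUS if tr.cs_type is CsType.CS_PLUS else EventKind.CS_MINUS
        events.append(Event(tr.onset, cfg.cs_duration, kind, tr.index))
        if tr.reinforced:
            events.append(
                Event(_quantize(tr.onset + cfg.us_onset_in_cs), _quantize(us_span),
                      EventKind.US, tr.index)
            )
        if tr.probe_onset is not None:
            events.append(
                Event(_quantize(tr.onset + tr.probe_onset), cfg.probe_duration,
                      EventKind.PROBE, tr.index)
            )
        fix_onset = _quantize(tr.onset + cfg.cs_duration)
        events.append(Event(fix_onset, tr.iti_duration, EventKind.FIXATION, tr.index))
        if tr.iti_probe_onset is not None:
            events.append(
                Event(_quantize(fix_onset + tr.iti_probe_onset), cfg.probe_duration,
                      EventKind.PROBE, tr.index)
            )
    events.sort(key=lambda ev: (ev.onset, ev.kind.value))
    tl = EventTimeline(
        phase=phase,
        trials=trials,
        events=events,
        lead_in=lead_in,
        cs_duration=cfg.cs_duration,
        us_onset_in_cs=cfg.us_onset_in_cs,
    )
    tl.validate()
    return tl


def build_timeline(
    cfg: DesignConfig,
    phase: Phase | str,
    seed: int | np.random.Generator | None = None,
) -> EventTimeline:
    """Generate the full event timeline for one phase.

    Sequence, reinforcement (OFL only), intertrial intervals and probes are
    drawn from a single seeded generator, so the timeline is reproducible.
    Onsets are absolute seconds from phase start; the phase opens with a
    lead-in fixation interval drawn from the ITI range.
    """
    phase = Phase(phase)
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    n_plus, n_minus = cfg.n_cs(phase)
    seq = generate_cs_sequence(n_plus, n_minus, cfg.max_run_length, rng)
    if phase is Phase.OFL:
        reinforced = assign_reinforcement(seq, cfg.reinforcement_ratio, rng)
    else:
        reinforced = frozenset()
    lo, hi = cfg.iti_range
    lead_in = _quantize(rng.uniform(lo, hi))
    trials: list[Trial] = []
    t = lead_in
    for i, cs in enumerate(seq):
        iti = _quantize(rng.uniform(lo, hi))
        trials.append(
            Trial(
                index=i,
                phase=phase,
                cs_type=cs,
                onset=_quantize(t),
                reinforced=i in reinforced,
                iti_duration=iti,
            )
        )
        t = _quantize(t + cfg.cs_duration + iti)
    timeline = _timeline_from_trials(phase, trials, lead_in, cfg)
    return assign_probes(timeline, cfg, rng)


#: Two frozen CS orders (seeds 1 and 2 of the default generator) kept for
#: bit-exact regression tests, mirroring the two counterbalanced sequences
#: used in practice.  "P" = CS+, "M" = CS-.
FROZEN_SEQUENCES: tuple[str, str] = (
    "PMMPMPPMMPMPPMMPPMPMPPMMPMPPMMPMMPMMPPMPMPPMPPMM",
    "MPPMPPMMPPMPPMMPMMPMPMPMPPMMPPMMPPMPMPMMPMPPMMPM",
)
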