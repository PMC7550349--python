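"""Readers/writers for the package's tab-separated artifacts, pipeline
configuration, and the end-to-end pipeline runner.

All artifacts are plain TSV with a header row and times in seconds:

* recording: ``time  eda  emg`` at a fixed rate, with a JSON sidecar
  carrying the sampling rate, units and subject id;
* events: ``onset  duration  trial_index  phase  kind  reinforced  probe``
  (onsets/durations with 3 decimals; ``probe`` holds the probe onset
  relative to its parent CS or fixation onset on PROBE rows);
* questionnaire answers, awareness labels, trial-score and subject-summary
  tables mirroring the scoring modules' fields.

:func:`run_pipeline` chains simulation, SCR scoring, FPS scoring,
awareness classification and the group statistics, logging input/output
counts and exclusions at every stage and producing identical outputs for a
fixed master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, fps, scr, stats, synth
from .design import (
    CsType,
    DesignConfig,
    Event,
    EventKind,
    EventTimeline,
    Phase,
    Trial,
)
from .fps import FpsCondition, FpsParams
from .scr import ScrCondition, ScrParams
from .synth import QuestionnaireAnswers, Recording, SubjectData, SynthParams

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_answers",
    "write_answers",
    "write_cohort",
    "PipelineConfig",
    "PipelineReport",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger(__name__)

_NA = "n/a"


# ---------------------------------------------------------------------------
# Recording files
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``time  eda  emg`` TSV plus a JSON sidecar (same path + .json)."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t, "eda": rec.eda, "emg": rec.emg})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "fs": rec.fs,
        "units": {"eda": "microsiemens", "emg": "millivolt"},
        "subject_id": rec.subject_id,
        "role": rec.role,
        **rec.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording TSV, validating layout, time axis and sidecar rate."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["time", "eda", "emg"]:
        raise ValueError(f"{path}: header must be 'time\\teda\\temg', got {list(df.columns)}")
    for col in df.columns:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path}: ragged/missing value in column {col!r} at line {bad[0] + 2}")
    t = df["time"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: recording needs at least 2 samples")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise ValueError(f"{path}: time axis is not increasing")
    bad = np.nonzero(np.abs(dt - step) > max(1e-6, 1e-6 * step))[0]
    if bad.size:
        raise ValueError(
            f"{path}: gap or irregular time step at line {int(bad[0]) + 3} "
            f"(dt={dt[bad[0]]:.6f}, expected {step:.6f})"
        )
    fs = 1.0 / step
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    subject_id = path.stem
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        fs_meta = float(meta.pop("fs", fs))
        if abs(fs_meta - fs) > 1e-3 * fs_meta:
            raise ValueError(
                f"{path}: sampling rate {fs:.3f} Hz inferred from the time column "
                f"disagrees with sidecar fs={fs_meta}"
            )
        fs = fs_meta
        subject_id = meta.pop("subject_id", subject_id)
        meta.pop("units", None)
    role = meta.pop("role", "observer")
    return Recording(
        fs=fs, eda=df["eda"].to_numpy(), emg=df["emg"].to_numpy(),
        subject_id=subject_id, role=role, meta=meta,
    )


# ---------------------------------------------------------------------------
# Events files
# ---------------------------------------------------------------------------

def write_events(timeline: EventTimeline, path: str | Path) -> None:
    """Write the flattened event list in the BIDS-events-style layout."""
    reinforced = {tr.index: tr.reinforced for tr in timeline.trials}
    cs_onset = {tr.index: tr.onset for tr in timeline.trials}
    fix_onset = {tr.index: tr.onset + timeline.cs_duration for tr in timeline.trials}
    rows = []
    for ev in timeline.events:
        if ev.kind is EventKind.PROBE:
            anchor = cs_onset[ev.trial_index]
            if ev.onset >= fix_onset[ev.trial_index]:
                anchor = fix_onset[ev.trial_index]
            probe = f"{ev.onset - anchor:.3f}"
        else:
            probe = _NA
        rows.append(
            {
                "onset": f"{ev.onset:.3f}",
                "duration": f"{ev.duration:.3f}",
                "trial_index": ev.trial_index,
                "phase": timeline.phase.value,
                "kind": ev.kind.value,
                "reinforced": int(reinforced.get(ev.trial_index, False)),
                "probe": probe,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> EventTimeline:
    """Reconstruct an :class:`EventTimeline` from an events TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"probe": str})
    expected = ["onset", "duration", "trial_index", "phase", "kind", "reinforced", "probe"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    phase = Phase(df["phase"].iloc[0])
    events: list[Event] = []
    lead_in = 0.0
    cs_rows: dict[int, pd.Series] = {}
    fix_dur: dict[int, float] = {}
    probes: dict[int, dict[str, float]] = {}
    us_rel: float | None = None
    for _, row in df.iterrows():
        idx = int(row["trial_index"])
        kind = EventKind(row["kind"])
        onset = round(float(row["onset"]), 3)
        dur = round(float(row["duration"]), 3)
        events.append(Event(onset, dur, kind, idx))
        if kind is EventKind.FIXATION:
            if idx == -1:
                lead_in = dur
            else:
                fix_dur[idx] = dur
        elif kind in (EventKind.CS_PLUS, EventKind.CS_MINUS):
            cs_rows[idx] = row
        elif kind is EventKind.US and us_rel is None:
            pass  # resolved after CS rows are known
        if kind is EventKind.PROBE:
            probes.setdefault(idx, {})[_probe_location(df, row, cs_rows)] = round(
                float(row["probe"]), 3
            )
    cs_duration = round(float(cs_rows[next(iter(cs_rows))]["duration"]), 3)
    us_onset_in_cs = 7.5
    for ev in events:
        if ev.kind is EventKind.US:
            cs_onset = round(float(cs_rows[ev.trial_index]["onset"]), 3)
            us_onset_in_cs = round(ev.onset - cs_onset, 3)
            break
    trials = []
    for idx in sorted(cs_rows):
        row = cs_rows[idx]
        pr = probes.get(idx, {})
        trials.append(
            Trial(
                index=idx,
                phase=phase,
                cs_type=CsType(row["kind"]),
                onset=round(float(row["onset"]), 3),
                reinforced=bool(int(row["reinforced"])),
                iti_duration=fix_dur[idx],
                probe_onset=pr.get("cs"),
                iti_probe_onset=pr.get("iti"),
            )
        )
    events.sort(key=lambda ev: (ev.onset, ev.kind.value))
    tl = EventTimeline(
        phase=phase, trials=trials, events=events, lead_in=lead_in,
        cs_duration=cs_duration, us_onset_in_cs=us_onset_in_cs,
    )
    tl.validate()
    return tl


def _probe_location(df: pd.DataFrame, probe_row: pd.Series,
                    cs_rows: dict[int, pd.Series]) -> str:
    idx = int(probe_row["trial_index"])
    cs = cs_rows[idx]
    cs_end = float(cs["onset"]) + float(cs["duration"])
    return "cs" if float(probe_row["onset"]) < cs_end else "iti"


# ---------------------------------------------------------------------------
# Questionnaire / label tables
# ---------------------------------------------------------------------------

def write_answers(answers: list[QuestionnaireAnswers], path: str | Path) -> None:
    rows = []
    for a in answers:
        row = {
            "subject_id": a.subject_id,
            "rule_reported": int(a.rule_reported),
            "rule_stimulus": a.rule_stimulus or _NA,
            "forced_choice": a.forced_choice,
        }
        for stim in ("CS_PLUS", "CS_MINUS", "FIXATION"):
            row[f"pct_{stim}"] = a.pct_ratings.get(stim, np.nan)
        for q in synth.LIKERT_QUESTIONS:
            row[f"likert_{q}"] = a.likert_ratings[q]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_answers(path: str | Path) -> list[QuestionnaireAnswers]:
    # keep the literal "n/a" marker out of pandas' default NaN handling
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    out = []
    for _, row in df.iterrows():
        rule = str(row["rule_stimulus"])
        out.append(
            QuestionnaireAnswers(
                rule_reported=bool(int(row["rule_reported"])),
                rule_stimulus=None if rule == _NA else rule,
                pct_ratings={
                    stim: float(row[f"pct_{stim}"])
                    for stim in ("CS_PLUS", "CS_MINUS", "FIXATION")
                    if not pd.isna(row[f"pct_{stim}"])
                },
                forced_choice=str(row["forced_choice"]),
                likert_ratings={q: int(row[f"likert_{q}"]) for q in synth.LIKERT_QUESTIONS},
                subject_id=str(row["subject_id"]),
            )
        )
    return out


def write_labels(labels: list[behavior.ContingencyLabel], path: str | Path) -> None:
    pd.DataFrame(
        [{"subject": l.subject_id, "aware": int(l.aware), "basis": l.basis} for l in labels]
    ).to_csv(path, sep="\t", index=False)


def write_cohort(subjects: list[SubjectData], out_dir: str | Path) -> None:
    """Write per-subject recordings and events plus the cohort answers table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in subjects:
        sdir = out / sub.subject_id
        sdir.mkdir(exist_ok=True)
        for phase in (Phase.OFL, Phase.DE):
            tag = phase.value.lower()
            write_events(sub.timelines[phase], sdir / f"{sub.subject_id}_{tag}_events.tsv")
            write_recording(sub.recordings[phase], sdir / f"{sub.subject_id}_{tag}_recording.tsv")
    write_answers([s.answers for s in subjects], out / "answers.tsv")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

def _from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    """Everything one end-to-end synthetic run needs."""

    n_subjects: int = 35
    seed: int = 0
    n_aware: int | None = None
    design: DesignConfig = field(default_factory=DesignConfig)
    synth: SynthParams = field(default_factory=SynthParams)
    scr: ScrParams = field(default_factory=ScrParams)
    fps: FpsParams = field(default_factory=FpsParams)
    out_dir: str | None = None
    write_recordings: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sections = {
            "design": DesignConfig, "synth": SynthParams,
            "scr": ScrParams, "fps": FpsParams,
        }
        kwargs: dict = {}
        for key, val in raw.items():
            if key in sections:
                kwargs[key] = _from_dict(sections[key], val or {})
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineReport:
    """Aggregated tables, statistics and bookkeeping of one pipeline run."""

    n_subjects: int
    labels: list[behavior.ContingencyLabel]
    scr_subjects: list[scr.ScrSubjectScores]
    fps_subjects: list[fps.FpsSubjectScores]
    scr_table: pd.DataFrame
    fps_table: pd.DataFrame
    likert_summary: pd.DataFrame
    results: dict[str, stats.StatResult | list[stats.StatResult]]
    notes: list[str]

    @property
    def n_scr_included(self) -> int:
        return sum(1 for s in self.scr_subjects if not s.excluded)

    @property
    def n_fps_included(self) -> int:
        return sum(1 for s in self.fps_subjects if not s.excluded)

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for key, res in self.results.items():
            for r in res if isinstance(res, list) else [res]:
                row = r.as_row()
                row["analysis"] = key
                rows.append(row)
        return pd.DataFrame(rows)


def _score_subject_scr(sub: SubjectData, params: ScrParams) -> scr.ScrSubjectScores:
    # Scoring runs on the decomposition's decimated grid: the phasic
    # component has sub-hertz bandwidth, so window extrema there match the
    # full-rate values to a fraction of a percent at a fraction of the cost.
    phasic = {}
    fd = None
    for phase, rec in sub.recordings.items():
        _, ph, fd = scr._decompose_decimated(rec.eda, rec.fs, params.decomposition, params)
        phasic[phase] = ph
    trials = scr.score_all_trials(phasic, fd, sub.timelines, params)
    return scr.summarize_subject(trials, params, sub.subject_id)


def _score_subject_fps(
    sub: SubjectData, params: FpsParams
) -> tuple[list[fps.FpsTrialScore], np.ndarray]:
    trials: list[fps.FpsTrialScore] = []
    for phase, rec in sub.recordings.items():
        trials.extend(fps.score_probe_trials(rec.emg, rec.fs, sub.timelines[phase], params))
    rms = np.array([t.baseline_rms for t in trials])
    return trials, rms


def _long_table(
    subject_scores: list, labels: dict[str, bool], conditions: list
) -> pd.DataFrame:
    rows = []
    for ss in subject_scores:
        if ss.excluded:
            continue
        for cond in conditions:
            if cond in ss.condition_means:
                rows.append(
                    {
                        "subject_id": ss.subject_id,
                        "group": "aware" if labels[ss.subject_id] else "unaware",
                        "condition": cond.value,
                        "value": ss.condition_means[cond],
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Simulate, score, classify and analyze one synthetic cohort.

    Stages: simulate -> SCR scoring -> FPS scoring -> awareness
    classification -> group statistics.  Every exclusion is logged with its
    reason; analyses whose prerequisites fail (e.g. all subjects excluded,
    or a contingency group with fewer than two subjects) are skipped with an
    explicit note instead of erroring.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    notes: list[str] = []
    labels: list[behavior.ContingencyLabel] = []
    scr_subjects: list[scr.ScrSubjectScores] = []
    fps_trials_by_subject: dict[str, list[fps.FpsTrialScore]] = {}
    rms_by_subject: dict[str, np.ndarray] = {}
    answers: list[QuestionnaireAnswers] = []

    subject_iter = synth.iter_cohort(
        config.n_subjects, config.design, config.synth, config.seed, config.n_aware
    )
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    for sub in subject_iter:
        sid = sub.subject_id
        try:
            scr_subjects.append(_score_subject_scr(sub, config.scr))
            trials, rms = _score_subject_fps(sub, config.fps)
            fps_trials_by_subject[sid] = trials
            rms_by_subject[sid] = rms
            labels.append(behavior.classify_contingency(sub.answers))
            answers.append(sub.answers)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at subject {sid}: {exc}") from exc
        if out and config.write_recordings:
            write_cohort([sub], out / "cohort")
    logger.info("simulated and scored %d subjects", len(labels))

    noisy = fps.flag_noisy_subjects(rms_by_subject, config.fps)
    fps_subjects = [
        fps.summarize_subject_fps(trials, config.fps, sid, noisy=sid in noisy)
        for sid, trials in fps_trials_by_subject.items()
    ]
    for s in scr_subjects:
        if s.excluded:
            notes.append(f"SCR exclusion: {s.subject_id} ({s.n_nonzero_de} nonzero DE responses)")
    for s in fps_subjects:
        if s.excluded:
            notes.append(f"FPS exclusion: {s.subject_id} ({s.exclusion_reason})")

    aware_by_id = {l.subject_id: l.aware for l in labels}
    scr_table = _long_table(scr_subjects, aware_by_id, list(ScrCondition))
    fps_table = _long_table(fps_subjects, aware_by_id, list(FpsCondition))
    results: dict[str, stats.StatResult | list[stats.StatResult]] = {}

    _analyze_scr(scr_table, results, notes)
    _analyze_fps(fps_table, results, notes)

    likert_summary = behavior.summarize_likert(answers, labels)
    try:
        kw = []
        for q in synth.LIKERT_QUESTIONS:
            aware_vals = [a.likert_ratings[q] for a in answers if aware_by_id[a.subject_id]]
            unaware_vals = [a.likert_ratings[q] for a in answers if not aware_by_id[a.subject_id]]
            kw.append(stats.kruskal_wallis([aware_vals, unaware_vals], name=q))
        results["likert_kruskal_wallis"] = kw
    except ValueError as exc:
        notes.append(f"Likert comparison skipped: {exc}")

    report = PipelineReport(
        n_subjects=config.n_subjects,
        labels=labels,
        scr_subjects=scr_subjects,
        fps_subjects=fps_subjects,
        scr_table=scr_table,
        fps_table=fps_table,
        likert_summary=likert_summary,
        results=results,
        notes=notes,
    )
    if out:
        write_report(report, out)
    return report


def _pivot(table: pd.DataFrame, conds: list[str]) -> pd.DataFrame:
    sub = table[table["condition"].isin(conds)]
    return sub.pivot(index="subject_id", columns="condition", values="value").dropna()


def _analyze_scr(table: pd.DataFrame, results: dict, notes: list[str]) -> None:
    if table.empty:
        notes.append("SCR analysis skipped: all subjects excluded")
        return
    us = _pivot(table, [ScrCondition.OBS_US.value, ScrCondition.OBS_NO_US.value])
    if len(us) >= 2:
        results["scr_us_vs_nous"] = stats.paired_t(
            us[ScrCondition.OBS_US.value], us[ScrCondition.OBS_NO_US.value],
            name="obs US vs obs noUS",
        )
    cs_conds = [
        ScrCondition.OBS_CS_PLUS.value, ScrCondition.OBS_CS_MINUS.value,
        ScrCondition.DIR_CS_PLUS.value, ScrCondition.DIR_CS_MINUS.value,
    ]
    cs = table[table["condition"].isin(cs_conds)].copy()
    cs["stimulus"] = np.where(cs["condition"].str.contains("PLUS"), "CS_PLUS", "CS_MINUS")
    cs["phase"] = np.where(cs["condition"].str.startswith("obs"), "OFL", "DE")
    try:
        results["scr_rm_stimulus_phase"] = stats.rm_anova(
            cs, dv="value", within=["stimulus", "phase"], subject="subject_id",
        )
    except ValueError as exc:
        notes.append(f"SCR rm-ANOVA skipped: {exc}")
    de = table[table["condition"].isin(
        [ScrCondition.DIR_CS_PLUS.value, ScrCondition.DIR_CS_MINUS.value]
    )].copy()
    de["stimulus"] = np.where(de["condition"].str.contains("PLUS"), "CS_PLUS", "CS_MINUS")
    try:
        results["scr_mixed_de"] = stats.mixed_anova(
            de, dv="value", within="stimulus", between="group", subject="subject_id",
        )
        results["scr_posthoc"] = stats.bonferroni_posthoc(
            de,
            [
                stats.Contrast("paired", ScrCondition.DIR_CS_PLUS.value,
                               ScrCondition.DIR_CS_MINUS.value, group="aware",
                               name="aware: dir CS+ vs dir CS-"),
                stats.Contrast("paired", ScrCondition.DIR_CS_PLUS.value,
                               ScrCondition.DIR_CS_MINUS.value, group="unaware",
                               name="unaware: dir CS+ vs dir CS-"),
                stats.Contrast("between", "aware", "unaware",
                               condition=ScrCondition.DIR_CS_PLUS.value,
                               name="dir CS+: aware vs unaware"),
                stats.Contrast("between", "aware", "unaware",
                               condition=ScrCondition.DIR_CS_MINUS.value,
                               name="dir CS-: aware vs unaware"),
            ],
        )
    except ValueError as exc:
        notes.append(f"SCR mixed ANOVA skipped: {exc}")


def _analyze_fps(table: pd.DataFrame, results: dict, notes: list[str]) -> None:
    if table.empty:
        notes.append("FPS analysis skipped: all subjects excluded")
        return
    all_conds = [c.value for c in FpsCondition]
    full = table[table["condition"].isin(all_conds)].copy()
    full["stimulus"] = full["condition"].str.replace(r"^(obs|dir)_", "", regex=True)
    full["phase"] = np.where(full["condition"].str.startswith("obs"), "OFL", "DE")
    try:
        results["fps_rm_stimulus_phase"] = stats.rm_anova(
            full, dv="value", within=["stimulus", "phase"], subject="subject_id",
        )
    except ValueError as exc:
        notes.append(f"FPS rm-ANOVA skipped: {exc}")
    phase_means = full.groupby(["subject_id", "phase"])["value"].mean().unstack().dropna()
    if len(phase_means) >= 2:
        results["fps_de_vs_ofl"] = stats.paired_t(
            phase_means["DE"], phase_means["OFL"], name="DE vs OFL phase mean",
        )
    de = table[table["condition"].isin(
        [FpsCondition.DIR_CS_PLUS.value, FpsCondition.DIR_CS_MINUS.value,
         FpsCondition.DIR_FIX.value]
    )].copy()
    de["stimulus"] = de["condition"].str.replace("dir_", "", regex=False)
    try:
        results["fps_mixed_de"] = stats.mixed_anova(
            de, dv="value", within="stimulus", between="group", subject="subject_id",
        )
    except ValueError as exc:
        notes.append(f"FPS mixed ANOVA skipped: {exc}")
    try:
        results["fps_posthoc_all"] = stats.bonferroni_posthoc(
            de,
            [
                stats.Contrast("paired", FpsCondition.DIR_CS_PLUS.value,
                               FpsCondition.DIR_FIX.value, name="dir CS+ vs dir fix"),
                stats.Contrast("paired", FpsCondition.DIR_CS_MINUS.value,
                               FpsCondition.DIR_FIX.value, name="dir CS- vs dir fix"),
            ],
        )
        results["fps_posthoc_groups"] = stats.bonferroni_posthoc(
            de,
            [
                stats.Contrast("paired", FpsCondition.DIR_CS_PLUS.value,
                               FpsCondition.DIR_FIX.value, group="aware",
                               name="aware: dir CS+ vs dir fix"),
                stats.Contrast("paired", FpsCondition.DIR_CS_MINUS.value,
                               FpsCondition.DIR_FIX.value, group="aware",
                               name="aware: dir CS- vs dir fix"),
                stats.Contrast("paired", FpsCondition.DIR_CS_PLUS.value,
                               FpsCondition.DIR_FIX.value, group="unaware",
                               name="unaware: dir CS+ vs dir fix"),
                stats.Contrast("paired", FpsCondition.DIR_CS_MINUS.value,
                               FpsCondition.DIR_FIX.value, group="unaware",
                               name="unaware: dir CS- vs dir fix"),
            ],
        )
    except ValueError as exc:
        notes.append(f"FPS post-hocs skipped: {exc}")


def write_report(report: PipelineReport, out_dir: str | Path) -> None:
    """Write result tables, subject summaries, labels and notes as TSV/text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.results_frame().to_csv(out / "stat_results.tsv", sep="\t", index=False,
                                  float_format="%.6g")
    report.scr_table.to_csv(out / "scr_condition_means.tsv", sep="\t", index=False,
                            float_format="%.6g")
    report.fps_table.to_csv(out / "fps_condition_means.tsv", sep="\t", index=False,
                            float_format="%.6g")
    report.likert_summary.to_csv(out / "likert_summary.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    write_labels(report.labels, out / "labels.tsv")
    scr_rows = [
        {
            "subject": s.subject_id, "scr_max": s.scr_max,
            "excluded": int(s.excluded), "n_nonzero_de": s.n_nonzero_de,
            **{c.value: s.condition_means.get(c, np.nan) for c in ScrCondition},
        }
        for s in report.scr_subjects
    ]
    pd.DataFrame(scr_rows).to_csv(out / "scr_subjects.tsv", sep="\t", index=False,
                                  float_format="%.6g")
    fps_rows = [
        {
            "subject": s.subject_id, "excluded": int(s.excluded),
            "exclusion_reason": s.exclusion_reason,
            "n_nonzero_total": s.n_nonzero_total,
            **{c.value: s.condition_means.get(c, np.nan) for c in FpsCondition},
        }
        for s in report.fps_subjects
    ]
    pd.DataFrame(fps_rows).to_csv(out / "fps_subjects.tsv", sep="\t", index=False,
                                  float_format="%.6g")
    (out / "notes.log").write_text(
        "\n".join(report.notes) + ("\n" if report.notes else "")
    )
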