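# oflphys

Psychophysiology pipeline for **observational fear learning (OFL)**
experiments: a participant (the *observer*) watches a friend (the
*demonstrator*) undergo differential fear conditioning — one colored square
(CS+) is probabilistically paired with an uncomfortable electric shock (US),
another (CS−) is always safe — and is then exposed to the same stimuli
directly (*direct expression*, DE) with no shocks. Learning is read out from
two autonomic channels recorded at 2 kHz from the observer:

* **Skin conductance responses (SCR).** Electrodermal activity is decomposed
  into tonic and phasic components (sparse-driver deconvolution against a
  biexponential kernel, cvxEDA-style convex program); each trial is scored
  trough-to-peak, `max(phasic, [0, 6) s after onset) − mean(phasic, 2 s
  before onset)`, with amplitudes < 0.2 μS treated as no response, and
  normalized within subjects as `log(1 + SCR/SCRmax)`.
* **Fear-potentiated startle (FPS).** Orbicularis-oculi EMG responses to
  acoustic startle probes are band-pass filtered (28–500 Hz, 4th-order
  Butterworth), rectified, smoothed (40 Hz FIR), scored as the 20–120 ms
  peak minus the −100–0 ms baseline, and T-score normalized within
  participants (mean 50, sd 10).

Observers are classified as **contingency-aware** when their forced-choice
questionnaire answer names the CS+ and is consistent with their earlier
answers (rule report or highest shock-probability rating). Group analyses —
paired *t* tests, repeated-measures and mixed-design ANOVAs with partial
η², Bonferroni post-hocs, Kruskal–Wallis on ratings — test the signature
pattern: a CS+ > CS− differential only in aware observers, and startle
potentiation in the DE phase.

The package is exercisable end to end with **no external data**: the
`design` module generates the two-phase timeline under the task's
constraints (24+24 OFL / 12+12 DE trials, 50 % reinforcement with first and
last CS+ always reinforced, no more than two identical stimuli in a row,
9 s CS, 10–15 s ITI, US as five 1 ms pulses at 200 ms latency starting
7.5 s after CS onset, probes in half the CSs and a quarter of the ITIs),
and the `synth` module renders per-subject EDA/EMG recordings with
injectable condition effects plus matching questionnaire answers.

## Worked example

```python
from oflphys.io import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(n_subjects=35, seed=1))
print(sum(l.aware for l in report.labels), "of", report.n_subjects, "aware")
inter = {r.name: r for r in report.results["scr_mixed_de"]}["Interaction"]
print(f"SCR stimulus x contingency: F({inter.df[0]:.0f}, {inter.df[1]:.0f}) "
      f"= {inter.statistic:.2f}, p = {inter.p:.2g}, eta_p^2 = {inter.effect_size:.2f}")
de = report.results["fps_de_vs_ofl"]
print(f"FPS DE vs OFL: t({de.df:.0f}) = {de.statistic:.2f}, d = {de.effect_size:.2f}")
```

prints (seed 1):

```
14 of 35 aware
SCR stimulus x contingency: F(1, 30) = 73.19, p = 1.5e-09, eta_p^2 = 0.71
FPS DE vs OFL: t(34) = 26.30, d = 4.45
```

i.e. 14 of the 35 synthetic observers are classified contingency-aware, the
stimulus × contingency interaction on direct-expression SCRs is detected
(aware observers respond more to CS+ than CS−, unaware observers do not
differentiate), and startle is strongly potentiated in the direct-expression
phase relative to observation.

The same stages are available as shell commands (`oflphys simulate-design`,
`simulate-cohort`, `score-scr`, `score-fps`, `classify`, `analyze`, `run`),
all operating on plain tab-separated files.

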