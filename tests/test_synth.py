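"""Synthetic EDA/EMG rendering and questionnaire generation."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from oflphys import behavior, fps, scr
from oflphys.design import CsType, DesignConfig, Phase, build_timeline
from oflphys.synth import (
    SynthParams,
    draw_awareness,
    render_eda,
    render_emg,
    render_questionnaire,
    scr_kernel,
    scr_kernel_peak_time,
    simulate_cohort,
    simulate_subject,
)
from conftest import make_manual_timeline


def quiet_params(**kw) -> SynthParams:
    base = dict(eda_noise_sd=0.0, tonic_drift=0.0, lognormal_amp_cv=0.0,
                response_prob=1.0, emg_noise_sd=0.0)
    base.update(kw)
    return SynthParams(**base)


class TestKernel:
    def test_zero_at_origin_and_unit_peak(self):
        t = np.linspace(0, 30, 60001)
        h = scr_kernel(t, 0.75, 3.0)
        assert h[0] == 0.0
        assert np.max(h) <= 1.0 + 1e-12
        assert np.max(h) == pytest.approx(1.0, abs=1e-6)
        assert scr_kernel(scr_kernel_peak_time(0.75, 3.0), 0.75, 3.0) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_peak_time_matches_closed_form(self):
        rise, decay = 0.75, 3.0
        t = np.linspace(0, 10, 200001)
        h = scr_kernel(t, rise, decay)
        t_star = math.log(decay / rise) * rise * decay / (decay - rise)
        assert t_star == pytest.approx(1.3863 * 0.75 * 3.0 / 2.25, rel=1e-3)
        assert t[np.argmax(h)] == pytest.approx(t_star, abs=1e-3)
        assert scr_kernel_peak_time(rise, decay) == pytest.approx(t_star)

    def test_invalid_taus(self):
        with pytest.raises(ValueError):
            scr_kernel(1.0, 3.0, 0.75)
        with pytest.raises(ValueError):
            SynthParams(scr_rise_tau=3.0, scr_decay_tau=0.75)


class TestRenderEda:
    def test_pure_tonic_ramp_when_everything_zero(self, one_trial_timeline):
        params = quiet_params(
            amp_us=0.0, amp_cs_plus_aware_de=0.0, amp_cs_minus_aware_de=0.0,
            amp_cs_unaware_de=0.0, amp_cs_ofl=0.0, tonic_drift=0.05,
        )
        eda = render_eda(one_trial_timeline, params, aware=True, seed=0)
        t_min = np.arange(eda.size) / params.fs / 60.0
        assert np.allclose(eda, params.tonic_level + 0.05 * t_min, atol=1e-12)

    def test_single_event_amplitude_exact(self, one_trial_timeline):
        a = 0.37
        params = quiet_params(amp_cs_unaware_de=a)
        eda = render_eda(one_trial_timeline, params, aware=False, seed=0)
        # tolerance reflects sampling of the kernel peak on the 0.5 ms grid
        assert np.max(eda) - params.tonic_level == pytest.approx(a, abs=1e-7)

    def test_superposition_of_event_subsets(self):
        params = quiet_params(amp_cs_unaware_de=0.4)
        # all three timelines span the same 61 s so responses are never cut
        tl_a = make_manual_timeline([{"onset": 12.0, "iti_duration": 40.0}])
        tl_b = make_manual_timeline(
            [{"onset": 12.0, "iti_duration": 19.0}, {"onset": 40.0}]
        )
        only_b = make_manual_timeline([{"onset": 40.0}])
        eda_ab = render_eda(tl_b, params, aware=False, seed=0)
        eda_a = render_eda(tl_a, params, aware=False, seed=0)
        eda_bb = render_eda(only_b, params, aware=False, seed=0)
        assert eda_a.size == eda_bb.size == eda_ab.size
        summed = eda_a + eda_bb - params.tonic_level
        assert np.allclose(summed, eda_ab, atol=1e-9)

    def test_eda_strictly_positive_default_params(self, default_cfg, default_params):
        tl = build_timeline(default_cfg, Phase.DE, seed=0)
        for seed in range(20):
            assert np.all(render_eda(tl, default_params, aware=True, seed=seed) > 0)

    def test_scored_amplitude_tracks_injected_amplitude(self):
        """With noise off, scoring recovers injected amplitudes to ~10%."""
        cfg = DesignConfig()
        tl = build_timeline(cfg, Phase.DE, seed=9)
        for inj in (0.3, 0.6, 1.2):
            params = quiet_params(
                amp_cs_plus_aware_de=inj, amp_cs_minus_aware_de=inj,
                eda_noise_sd=0.0,
            )
            eda = render_eda(tl, params, aware=True, seed=1)
            tonic, phasic = scr.decompose_eda(eda, params.fs, "convex_sparse")
            amps = [scr.score_trial(phasic, params.fs, t.onset) for t in tl.trials]
            slope = np.mean(amps) / inj
            assert 0.9 <= slope <= 1.1

    def test_aware_subjects_show_cs_differential_after_scoring(self, default_cfg):
        """DE-phase CS+ mean exceeds CS- mean in nearly all aware subjects."""
        params = SynthParams()
        sp = scr.ScrParams()
        wins = 0
        n_sub = 60
        ss = np.random.SeedSequence(2024)
        for child in ss.spawn(n_sub):
            rng = np.random.default_rng(child)
            tl = build_timeline(default_cfg, Phase.DE, rng)
            eda = render_eda(tl, params, True, rng)
            _, phasic, fd = scr._decompose_decimated(eda, params.fs, "convex_sparse", sp)
            plus, minus = [], []
            for t in tl.trials:
                amp = scr.score_trial(phasic, fd, t.onset, sp)
                (plus if t.cs_type is CsType.CS_PLUS else minus).append(amp)
            wins += np.mean(plus) > np.mean(minus)
        assert wins >= 0.9 * n_sub


class TestRenderEmg:
    def test_zero_gain_leaves_baseline_statistics(self):
        tl = make_manual_timeline([{"onset": 12.0, "probe_onset": 6.0}])
        params = SynthParams(burst_gain_ofl=0.0, burst_gain_de=0.0, emg_noise_sd=0.02)
        emg = render_emg(tl, params, aware=True, seed=5)
        assert np.var(emg) == pytest.approx(0.02 ** 2, rel=0.05)

    def test_single_burst_score_matches_gain(self):
        tl = make_manual_timeline([{"onset": 12.0, "probe_onset": 6.0}])
        gain = 0.14
        params = quiet_params()
        emg = render_emg(tl, params, aware=False, seed=8)
        sm = fps.preprocess_emg(emg, params.fs)
        score = fps.score_startle(sm, params.fs, 18.0)
        assert score == pytest.approx(gain, rel=0.05)

    def test_de_startle_exceeds_ofl_across_subjects(self, default_cfg):
        params = SynthParams()
        fp = fps.FpsParams()
        wins = 0
        n_sub = 40
        ss = np.random.SeedSequence(77)
        for child in ss.spawn(n_sub):
            rng = np.random.default_rng(child)
            means = {}
            for phase in (Phase.OFL, Phase.DE):
                tl = build_timeline(default_cfg, phase, rng)
                emg = render_emg(tl, params, False, rng)
                scores = fps.score_probe_trials(emg, params.fs, tl, fp)
                means[phase] = np.mean([t.raw_magnitude for t in scores])
            wins += means[Phase.DE] > means[Phase.OFL]
        assert wins >= 0.9 * n_sub


class TestQuestionnaire:
    def test_aware_answers_classify_aware(self):
        for seed in range(200):
            ans = render_questionnaire(True, seed=seed)
            assert behavior.classify_contingency(ans).aware

    def test_unaware_answers_classify_unaware(self):
        for seed in range(200):
            ans = render_questionnaire(False, seed=seed)
            assert not behavior.classify_contingency(ans).aware

    def test_awareness_counts_binomial(self):
        """Awareness draws over many cohorts follow Binomial(35, p_aware)."""
        params = SynthParams()
        counts = [
            sum(draw_awareness(35, params, seed)) for seed in range(1000)
        ]
        binom = sps.binom(35, params.p_aware)
        cuts = [-0.5, 10.5, 12.5, 14.5, 16.5, 18.5, 35.5]
        obs = np.histogram(counts, bins=cuts)[0]
        exp = np.diff([binom.cdf(c) for c in cuts]) * len(counts)
        stat = sps.chisquare(obs, exp * obs.sum() / exp.sum())
        assert stat.pvalue > 0.01


class TestCohort:
    def test_cohort_reproducible(self, tiny_cfg):
        a = simulate_cohort(2, tiny_cfg, SynthParams(), seed=31)
        b = simulate_cohort(2, tiny_cfg, SynthParams(), seed=31)
        for sa, sb in zip(a, b):
            assert sa.aware == sb.aware
            for phase in (Phase.OFL, Phase.DE):
                assert np.array_equal(sa.recordings[phase].eda, sb.recordings[phase].eda)
                assert np.array_equal(sa.recordings[phase].emg, sb.recordings[phase].emg)
            assert sa.answers == sb.answers

    def test_zero_noise_cohort_deterministic_signal(self, tiny_cfg):
        params = quiet_params()
        subs = simulate_cohort(2, tiny_cfg, params, seed=3)
        for sub in subs:
            eda = sub.recordings[Phase.DE].eda
            assert np.isfinite(eda).all()
            assert np.all(eda >= params.tonic_level - 1e-12)
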