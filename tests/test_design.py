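"""Trial-sequence, reinforcement, probe and timeline generation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from oflphys.design import (
    FROZEN_SEQUENCES,
    CsType,
    DesignConfig,
    DesignError,
    EventKind,
    Phase,
    assign_probes,
    assign_reinforcement,
    build_timeline,
    generate_cs_sequence,
    us_train_duration,
)


def as_str(seq):
    return "".join("P" if c is CsType.CS_PLUS else "M" for c in seq)


def max_run(seq):
    return max(len(list(g)) for _, g in itertools.groupby(seq))


class TestCsSequence:
    @pytest.mark.parametrize("n_plus,n_minus", [(24, 24), (1, 1), (12, 12), (10, 20)])
    def test_counts_and_run_limit(self, n_plus, n_minus):
        seq = generate_cs_sequence(n_plus, n_minus, 2, seed=7)
        assert sum(c is CsType.CS_PLUS for c in seq) == n_plus
        assert sum(c is CsType.CS_MINUS for c in seq) == n_minus
        assert max_run(seq) <= 2

    def test_deterministic_for_seed(self):
        a = generate_cs_sequence(24, 24, 2, seed=5)
        b = generate_cs_sequence(24, 24, 2, seed=5)
        assert a == b

    def test_frozen_sequences_regression(self):
        assert as_str(generate_cs_sequence(24, 24, 2, seed=1)) == FROZEN_SEQUENCES[0]
        assert as_str(generate_cs_sequence(24, 24, 2, seed=2)) == FROZEN_SEQUENCES[1]

    def test_emitted_sequences_are_exactly_the_valid_set(self):
        """Every generated (3,3) order is in the brute-force valid set, and
        the generator can reach more than one of them."""
        valid = {
            "".join(s)
            for s in itertools.permutations("PPPMMM")
            if max_run(s) <= 2
        }
        seen = set()
        for seed in range(300):
            s = as_str(generate_cs_sequence(3, 3, 2, seed=seed))
            assert s in valid
            seen.add(s)
        assert len(seen) > 1

    @pytest.mark.parametrize("n_plus,n_minus,max_run_length", [(5, 1, 2), (3, 1, 1), (10, 3, 2)])
    def test_infeasible_raises(self, n_plus, n_minus, max_run_length):
        with pytest.raises(DesignError):
            generate_cs_sequence(n_plus, n_minus, max_run_length, seed=0)

    def test_mass_generation_respects_all_constraints(self):
        for seed in range(1000):
            seq = generate_cs_sequence(24, 24, 2, seed=seed)
            assert sum(c is CsType.CS_PLUS for c in seq) == 24
            assert max_run(seq) <= 2


class TestReinforcement:
    def test_default_design_reinforces_half_with_endpoints(self):
        seq = generate_cs_sequence(24, 24, 2, seed=3)
        chosen = assign_reinforcement(seq, 0.5, seed=3)
        assert len(chosen) == 12
        plus_idx = [i for i, c in enumerate(seq) if c is CsType.CS_PLUS]
        assert plus_idx[0] in chosen and plus_idx[-1] in chosen
        assert all(seq[i] is CsType.CS_PLUS for i in chosen)

    def test_two_cs_plus_full_ratio(self):
        seq = [CsType.CS_PLUS, CsType.CS_MINUS, CsType.CS_PLUS]
        assert assign_reinforcement(seq, 1.0, seed=0) == frozenset({0, 2})

    def test_four_cs_plus_half_ratio_forced_to_endpoints(self):
        seq = [CsType.CS_PLUS, CsType.CS_MINUS] * 4
        plus_idx = [0, 2, 4, 6]
        for seed in range(50):
            chosen = assign_reinforcement(seq, 0.5, seed=seed)
            assert chosen == frozenset({plus_idx[0], plus_idx[-1]})

    def test_bankers_rounding_of_count(self):
        seq = [CsType.CS_PLUS] * 10 + [CsType.CS_MINUS]
        # 10 * 0.25 = 2.5 rounds to 2 (ties to even)
        assert len(assign_reinforcement(seq, 0.25, seed=1)) == 2

    def test_too_few_reinforced_raises(self):
        seq = [CsType.CS_PLUS] * 24 + [CsType.CS_MINUS]
        with pytest.raises(DesignError):
            assign_reinforcement(seq, 0.04, seed=0)


class TestProbes:
    def test_ofl_probe_counts_balanced(self, default_cfg):
        tl = build_timeline(default_cfg, Phase.OFL, seed=11)
        cs_probed = [t for t in tl.trials if t.probe_onset is not None]
        assert len(cs_probed) == 24
        assert sum(t.cs_type is CsType.CS_PLUS for t in cs_probed) == 12
        assert sum(t.cs_type is CsType.CS_MINUS for t in cs_probed) == 12
        # stratified across reinforced/unreinforced CS+
        plus = [t for t in cs_probed if t.cs_type is CsType.CS_PLUS]
        assert sum(t.reinforced for t in plus) == 6
        assert len([t for t in tl.trials if t.iti_probe_onset is not None]) == 12

    def test_probe_onsets_from_allowed_sets(self, default_cfg):
        for seed in range(10):
            tl = build_timeline(default_cfg, Phase.OFL, seed=seed)
            for t in tl.trials:
                if t.probe_onset is not None:
                    assert t.probe_onset in default_cfg.probe_cs_onsets
                if t.iti_probe_onset is not None:
                    lo, hi = default_cfg.probe_iti_onset_range
                    assert lo <= t.iti_probe_onset <= hi

    def test_zero_probe_fraction(self):
        cfg = DesignConfig(probe_cs_fraction=0.0, probe_iti_fraction=0.0)
        tl = build_timeline(cfg, Phase.OFL, seed=2)
        assert all(t.probe_onset is None and t.iti_probe_onset is None for t in tl.trials)

    def test_us_scoreable_classes_balanced(self, default_cfg):
        """Probe stratification leaves equal numbers of probe-free
        reinforced and unreinforced CS+ trials."""
        for seed in range(10):
            tl = build_timeline(default_cfg, Phase.OFL, seed=seed)
            free = [
                t for t in tl.trials
                if t.cs_type is CsType.CS_PLUS
                and t.probe_onset is None and t.iti_probe_onset is None
            ]
            n_r = sum(t.reinforced for t in free)
            assert n_r == len(free) - n_r


class TestTimeline:
    def test_de_phase_composition(self, default_cfg):
        tl = build_timeline(default_cfg, Phase.DE, seed=4)
        assert sum(t.cs_type is CsType.CS_PLUS for t in tl.trials) == 12
        assert sum(t.cs_type is CsType.CS_MINUS for t in tl.trials) == 12
        assert not any(ev.kind is EventKind.US for ev in tl.events)
        assert not any(t.reinforced for t in tl.trials)

    def test_us_onset_inside_parent_cs(self, default_cfg):
        tl = build_timeline(default_cfg, Phase.OFL, seed=4)
        cs_onsets = {t.index: t.onset for t in tl.trials}
        us_events = [ev for ev in tl.events if ev.kind is EventKind.US]
        assert len(us_events) == 12
        for ev in us_events:
            assert ev.onset == pytest.approx(cs_onsets[ev.trial_index] + 7.5, abs=1e-9)

    def test_repeatable_under_seed(self, default_cfg):
        a = build_timeline(default_cfg, Phase.OFL, seed=123)
        b = build_timeline(default_cfg, Phase.OFL, seed=123)
        assert a.trials == b.trials and a.events == b.events

    def test_iti_durations_uniform(self, default_cfg):
        itis = []
        for seed in range(110):
            tl = build_timeline(default_cfg, Phase.OFL, seed=seed)
            itis.extend(t.iti_duration for t in tl.trials)
        assert len(itis) >= 5000
        stat = sps.kstest(itis, sps.uniform(loc=10.0, scale=5.0).cdf)
        assert stat.pvalue > 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(DesignError):
            DesignConfig(reinforcement_ratio=0.0)
        with pytest.raises(DesignError):
            DesignConfig(iti_range=(15.0, 10.0))
        with pytest.raises(DesignError):
            DesignConfig(probe_cs_onsets=(6.0, 9.5))
        with pytest.raises(DesignError):
            DesignConfig(us_onset_in_cs=9.0)


@pytest.mark.parametrize(
    "n,dur,lat,expected",
    [(5, 0.001, 0.200, 0.8), (1, 0.001, 0.123, 0.0), (3, 0.001, 0.100, 0.2)],
)
def test_us_train_duration(n, dur, lat, expected):
    assert us_train_duration(n, dur, lat) == pytest.approx(expected)
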