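import numpy as np
import pytest

from oflphys.design import (
    CsType,
    DesignConfig,
    Phase,
    Trial,
    _timeline_from_trials,
)
from oflphys.synth import SynthParams


@pytest.fixture(scope="session")
def default_cfg() -> DesignConfig:
    return DesignConfig()


@pytest.fixture(scope="session")
def default_params() -> SynthParams:
    return SynthParams()


@pytest.fixture(scope="session")
def tiny_cfg() -> DesignConfig:
    """A 2+2-trial direct-expression design for fast IO/CLI tests."""
    return DesignConfig(
        n_cs_plus_ofl=2, n_cs_minus_ofl=2, n_cs_plus_de=2, n_cs_minus_de=2,
        reinforcement_ratio=1.0,
    )


def make_manual_timeline(
    specs: list[dict],
    phase: Phase = Phase.DE,
    cfg: DesignConfig | None = None,
    lead_in: float = 12.0,
):
    """Build a timeline from explicit trial specs (onset, cs_type, ...)."""
    cfg = cfg or DesignConfig()
    trials = [
        Trial(
            index=i,
            phase=phase,
            cs_type=s.get("cs_type", CsType.CS_MINUS),
            onset=s["onset"],
            reinforced=s.get("reinforced", False),
            iti_duration=s.get("iti_duration", 12.0),
            probe_onset=s.get("probe_onset"),
            iti_probe_onset=s.get("iti_probe_onset"),
        )
        for i, s in enumerate(specs)
    ]
    return _timeline_from_trials(phase, trials, lead_in, cfg)


@pytest.fixture(scope="session")
def one_trial_timeline():
    return make_manual_timeline([{"onset": 12.0}])
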