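import numpy as np
import pytest

from synergait import default_body, default_muscles, load_preset


@pytest.fixture(scope="session")
def body():
    return default_body()


@pytest.fixture(scope="session")
def muscles():
    return default_muscles()


@pytest.fixture(scope="session")
def walking_preset():
    return load_preset("walking_1.6")


@pytest.fixture(scope="session")
def running_preset():
    return load_preset("running_1.6")


@pytest.fixture(scope="session")
def lagrangian_oracle(body):
    """Independent symbolic EOM oracle (slow to build; shared per session)."""
    from .oracles import build_lagrangian_oracle

    return build_lagrangian_oracle(body)


@pytest.fixture(scope="session")
def walking_record(body, muscles, walking_preset):
    """One smoke-resolution walking run shared by the acceptance tests,
    launched from the preset's shipped limit-cycle state."""
    from synergait.skeleton_dynamics import simulate

    return simulate(
        body, muscles, walking_preset.pulses, walking_preset.regulator,
        duration=12.0, dt=1e-4, y0=walking_preset.launch,
        meta={"preset": "walking_1.6"},
    )


@pytest.fixture(scope="session")
def running_record(body, muscles, running_preset):
    from synergait.skeleton_dynamics import simulate

    return simulate(
        body, muscles, running_preset.pulses, running_preset.regulator,
        duration=10.0, dt=1e-4, y0=running_preset.launch,
        meta={"preset": "running_1.6"},
    )
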