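import pytest

from tamoxsim import build_default_model, default_design, default_network, run_arm

#: fixed seed for every stochastic test in the suite
SUITE_SEED = 1234


@pytest.fixture(scope="session")
def template():
    return default_network()


@pytest.fixture(scope="session")
def model():
    """Default calibrated model, shared across the suite (read-only)."""
    return build_default_model()


@pytest.fixture(scope="session")
def design(model):
    return default_design(seed=SUITE_SEED, n=1000)


@pytest.fixture(scope="session")
def arm_records(model, design):
    """Lazily computed per-arm trough records, cached for the session."""
    cache = {}

    def get(arm_id):
        if arm_id not in cache:
            arm = next(a for a in design.arms if a.arm_id == arm_id)
            cache[arm_id] = run_arm(arm, model)
        return cache[arm_id]

    return get
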