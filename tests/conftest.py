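import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

import operantfp as ofp

# Desk-scale end-to-end conditions: three short single-drug-period sessions
# with an injection-locked transient of known amplitude whose peak lands
# 0.2 s after the injection.
E2E_AMPLITUDE = 0.05  # dF/F units
E2E_LATENCY = 0.2  # s
E2E_WINDOW = (5.0, 5.0)
E2E_N_SESSIONS = 3


def e2e_templates(i: int):
    session = ofp.SessionTemplate(
        periods=(("drug", 300.0),),
        np1_rate_drug=0.15,
        seed=100 + i,
    )
    photometry = ofp.PhotometryTemplate(
        blocks=((0.0, 300.0),),
        event_locked=(("inj1", E2E_LATENCY, E2E_AMPLITUDE),),
        seed=200 + i,
    )
    return session, photometry


@pytest.fixture(scope="session")
def cfg():
    return ofp.load_config()


@pytest.fixture(scope="session")
def e2e_root(tmp_path_factory):
    """Three simulated session folders plus their ground truths."""
    root = tmp_path_factory.mktemp("sessions")
    truths = {}
    for i in range(E2E_N_SESSIONS):
        st, pt = e2e_templates(i)
        name = f"s{i:02d}"
        truths[name] = ofp.make_session_dir(root / name, st, pt)
    return root, truths
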