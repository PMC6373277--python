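import pytest
from hypothesis import HealthCheck, settings

from sle_trio.cohort import simulate_cohort
from sle_trio.config import preset
from sle_trio.workflow import run_analysis

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(preset("tiny", seed=7))


@pytest.fixture(scope="session")
def paper_analysis():
    """Full analysis of one paper-like 71-family cohort."""
    return run_analysis(preset("paper_like", seed=3))


@pytest.fixture(scope="session")
def recovery_run():
    """One large (500-family) cohort analysis for recovery-style checks."""
    cfg = preset("paper_like", seed=2).replace(n_families=500, n_reference=2000)
    return run_analysis(cfg)
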