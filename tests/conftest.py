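import pytest
from hypothesis import settings

from continence_ce.params import base_case_parameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ps():
    """Prepared base-case parameter set (shared, treated as read-only)."""
    return base_case_parameters()


@pytest.fixture(scope="session")
def base_results(ps):
    from continence_ce.economics import per_patient_results

    return per_patient_results(ps, prepared=True)
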