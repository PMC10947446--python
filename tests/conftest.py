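import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_experiment():
    """One complete synthetic experiment shared by read-only tests."""
    import pamksea as pk

    params = pk.SimulationParams(seed=7)
    scores, truth, fc, ksmap = pk.run_pipeline(params, n_active=3, delta=1.0)
    return {"params": params, "scores": scores, "truth": truth, "fc": fc, "ksmap": ksmap}
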