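import time

import pytest
from hypothesis import HealthCheck, settings

from rgpscan.pipeline import run_pipeline
from rgpscan.simulate import (
    default_config,
    generate_genome_set,
    shared_sites_config,
    worked_example_config,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

_quiet = lambda msg: None  # noqa: E731


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default four-genome synthetic set (seed 1)."""
    gset, truth = generate_genome_set(default_config(seed=1))
    t0 = time.perf_counter()
    result = run_pipeline(gset, seed=1, log=_quiet)
    runtime = time.perf_counter() - t0
    return {"gset": gset, "truth": truth, "result": result, "runtime": runtime}


@pytest.fixture(scope="session")
def worked_run():
    """Pipeline on the synthetic stand-in for the worked example."""
    gset, truth = generate_genome_set(worked_example_config())
    result = run_pipeline(gset, log=_quiet)
    return {"gset": gset, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def shared_sites_run():
    """Pipeline on the small three-shared-site genome set."""
    gset, truth = generate_genome_set(shared_sites_config())
    result = run_pipeline(gset, log=_quiet)
    return {"gset": gset, "truth": truth, "result": result}
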