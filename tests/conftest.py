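import warnings

import pytest

from paleograss.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast four-genome simulation used by several unit tests."""
    cfg = SimulationConfig(n_proto=3, genes_per_chrom=40, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The full default simulation analysed end to end (expensive; shared)."""
    from paleograss.pipeline import run_default_analysis

    import time

    scratch = tmp_path_factory.mktemp("default_ds")
    t0 = time.monotonic()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result, sim, metrics = run_default_analysis(seed=0, scratch=str(scratch))
    metrics["elapsed_s"] = time.monotonic() - t0
    return result, sim, metrics
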