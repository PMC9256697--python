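import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctc_concord.io_core import RunConfig
from ctc_concord import pipeline
from ctc_concord import simulate as sim

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def tiny_genome():
    """Small synthetic genome (2 chromosomes x 50 kb) with planted k-mers."""
    config = sim.SimConfig(n_chroms=2, chrom_length=50_000, n_kmer_sites=6)
    rng = np.random.default_rng(123)
    return sim.generate_genome(config, rng)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default three-patient scenario bundle, simulated and analyzed once.

    Shared by the end-to-end tests; seed fixed so results are reproducible.
    """
    root = tmp_path_factory.mktemp("bundle")
    data_dir = root / "data"
    out_dir = root / "out"
    truths, genome = sim.simulate_run(sim.default_sim_config(), seed=11,
                                      outdir=data_dir)
    cfg = RunConfig(rng_seed=11)
    results = pipeline.run_all(data_dir, cfg, out_dir,
                               reference=genome.sequences())
    return {
        "data_dir": data_dir,
        "out_dir": out_dir,
        "results": results,
        "truths": truths,
        "genome": genome,
        "cfg": cfg,
    }
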