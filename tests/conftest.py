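import numpy as np
import pytest

from polvtx.genome import GenomeIndex
from polvtx.simulate import SimulationConfig, simulate_all


@pytest.fixture
def genome():
    return GenomeIndex({"chr1": 1000, "chr2": 800})


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_sim_config(seed: int = 7, **overrides) -> SimulationConfig:
    """Desk-scale config for unit tests (full default scale is exercised
    by the acceptance suite)."""
    defaults = dict(
        seed=seed,
        chrom_lengths={"chr1": 300_000, "chr2": 300_000},
        n_genes=40,
        n_peaks=60,
        reads_per_peak={"wt_ip": 30.0, "mut_ip": 15.0, "gro": 30.0},
        ip_background_reads=1000,
        n_control_reads=300,
        n_dmrs=12,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One small simulated input bundle shared across unit tests."""
    outdir = tmp_path_factory.mktemp("simulated")
    cfg = small_sim_config()
    truth = simulate_all(cfg, outdir)
    return {"config": cfg, "dir": outdir, "truth": truth}
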