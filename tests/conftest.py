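import numpy as np
import pytest

from silopt.codon_usage import human_codon_usage
from silopt.simulate import SimulationConfig, simulate_cds, simulate_cohort


@pytest.fixture(scope="session")
def human_table():
    return human_codon_usage()


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read/resolve/score tests."""
    config = SimulationConfig(
        seed=11,
        n_genes=40,
        n_samples=50,
        mutations_per_sample=60,
        cds_length_range=(80, 200),
    )
    rng = config.rng()
    cds, genes = simulate_cds(config, rng=rng)
    maf, timing, truth = simulate_cohort(config, cds, genes, rng=rng)
    return {
        "config": config,
        "cds": cds,
        "genes": genes,
        "maf": maf,
        "timing": timing,
        "truth": truth,
        "samples": truth.attrs["samples"],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
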