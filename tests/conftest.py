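import numpy as np
import pandas as pd
import pytest

import cmuquant as cq


@pytest.fixture(scope="session")
def builtin_classification():
    return cq.load_builtin_classification()


@pytest.fixture(scope="session")
def spike_spec():
    return cq.SpikeInSpec(
        {
            "Truepera radiovictrix": 0.1,
            "Imtechella halotolerans": 0.2,
            "Allobacillus halotolerans": 0.4,
        }
    )


@pytest.fixture(scope="session")
def recovery_config():
    """Desk-scale community used for sequencing-recovery checks.

    Small and light enough (about 6 ng of community DNA) that every species
    above the 1e4-cell reporting threshold receives thousands of reads at
    depth 1e6, keeping multinomial sampling error well inside 0.05 log10.
    """
    return cq.SimulationConfig(
        n_species=30,
        n_samples_per_group=4,
        base_log10_mean=4.2,
        base_log10_sd=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def simulated_truth(recovery_config):
    return cq.simulate_community(recovery_config)


@pytest.fixture(scope="session")
def simulated_dataset(recovery_config):
    truth = cq.simulate_community(recovery_config)
    profiles = cq.simulate_sequencing(truth, depth=1_000_000, seed=11)
    return truth, profiles


@pytest.fixture()
def tiny_cmu_table():
    """4+4 samples x 3 taxa CMU table with a clear group-2 enrichment."""
    rng = np.random.default_rng(5)
    taxa = ["Fusobacterium nucleatum", "Rothia dentocariosa", "Prevotella loescheii"]
    samples = [f"h{i}" for i in range(4)] + [f"g{i}" for i in range(4)]
    base = np.array([1e3, 1e7, 1e3])
    rows = []
    for i, s in enumerate(samples):
        shift = np.array([30.0, 1.0, 30.0]) if s.startswith("g") else 1.0
        rows.append(base * shift * rng.lognormal(0, 0.1, 3))
    table = pd.DataFrame(rows, index=samples, columns=taxa)
    groups = pd.Series(
        {s: ("gingivitis" if s.startswith("g") else "healthy") for s in samples}
    )
    return table, groups
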