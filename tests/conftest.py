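import warnings

import numpy as np
import pytest

from coexpipe import quantify, syndata


@pytest.fixture(scope="session")
def three_module_sim():
    """A well-separated three-module time course with one extra DE gene."""
    cfg = syndata.SimulationConfig(
        n_genes=300,
        modules=[
            syndata.ModuleSpec(size=40, profile=(0, 2.5, 2.5), within_noise_sd=0.1),
            syndata.ModuleSpec(size=40, profile=(0, -2.5, -2.5), within_noise_sd=0.1),
            syndata.ModuleSpec(size=40, profile=(0, 0, 3), within_noise_sd=0.1),
        ],
        de_genes=[syndata.DeSpec(gene_index=200, comparison=(0, 1), log2_fc=3)],
        seed=42,
    )
    counts, truth = syndata.simulate_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def small_counts():
    """Hand-sized count matrix with friendly RPKM values."""
    return quantify.CountMatrix(
        gene_ids=["g1", "g2", "g3"],
        lengths=[1000, 2000, 500],
        counts=np.array([[10, 20, 40], [0, 4, 8], [100, 100, 100]]),
        sample_labels=["0h", "2h", "4h"],
        library_sizes=[1_000_000, 1_000_000, 1_000_000],
    )


@pytest.fixture(autouse=True)
def _quiet_short_profile_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="Pearson correlation over only"
        )
        yield
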