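from __future__ import annotations

import numpy as np
import pytest

from tdgtool.dream_sim import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small noiseless single-replicate DREAM experiment (40 target sites)."""
    cfg = SimConfig(
        seed=1,
        n_contigs=1,
        target_sites_per_contig=40,
        coverage_mean=100.0,
        error_rate=0.0,
        n_replicates=1,
    )
    outdir = tmp_path_factory.mktemp("small_bundle")
    return simulate_experiment(cfg, outdir)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
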