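import numpy as np
import pytest

from tefam.simulate import ChimeraSpec, SimConfig, simulate_genomes


@pytest.fixture(scope="session")
def small_sim():
    """One-species simulation shared by read-only tests."""
    cfg = SimConfig(seed=123, n_species=1, contig_length=80_000,
                    n_background_genes=10, n_paralog_families=5,
                    genes_per_family=(2, 3), p_te_near_paralog=0.8,
                    p_te_background=0.1,
                    chimera=ChimeraSpec(postfusion_rate=0.05))
    return simulate_genomes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))
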