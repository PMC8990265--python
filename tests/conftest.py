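import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from svscan.simulate import (
    SimConfig,
    generate_genome_pair,
    simulate_population,
    simulate_reads,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Genome pair + population truth without reads (fast, reused across modules)."""
    cfg = SimConfig(seed=11, n_chrom=2, chrom_len=150_000, n_sv=60, snp_rate=1e-3,
                    n_wild=8, n_cult=8, n_selected_sv=6, depth=5)
    genome_a, genome_b, truth, blocks = generate_genome_pair(cfg)
    truth = simulate_population(truth, cfg)
    return cfg, genome_a, genome_b, truth, blocks


@pytest.fixture(scope="session")
def read_dataset(tmp_path_factory):
    """A 20x read simulation over a 1-chromosome toy genome, with truth SAMs."""
    cfg = SimConfig(seed=5, n_chrom=1, chrom_len=50_000, n_sv=20, snp_rate=5e-4,
                    n_wild=4, n_cult=4, n_selected_sv=2, depth=20, error_rate=0.01)
    genome_a, genome_b, truth, _ = generate_genome_pair(cfg)
    truth = simulate_population(truth, cfg)
    out = tmp_path_factory.mktemp("reads20x")
    manifest = simulate_reads(truth, genome_a, genome_b, cfg, out)
    return cfg, genome_a, genome_b, truth, manifest


def make_matrix_from_truth(truth):
    """Truth genotypes wrapped as a GenotypeMatrix (no read noise)."""
    from svscan.models import GenotypeMatrix

    return GenotypeMatrix(truth.sv_genotypes, truth.groups)


@pytest.fixture()
def two_group_labels():
    accs = [f"W{i:02d}" for i in range(28)] + [f"C{i:02d}" for i in range(32)]
    return pd.Series(["wild"] * 28 + ["cultivated"] * 32, index=accs, name="group")
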