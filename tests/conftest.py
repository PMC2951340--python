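import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from neighborscan.genome_io import GeneRecord
from neighborscan.synthetic_data import SyntheticConfig, simulate_genome


def make_genes(positions, chrom="chr1", species="sp", length=200):
    """Genes centered at the given midpoints (bp)."""
    return [
        GeneRecord(f"g{i}", species, chrom, int(p - length / 2), int(p + length / 2))
        for i, p in enumerate(positions)
    ]


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic genome shared by read-only tests."""
    return simulate_genome(SyntheticConfig(), seed=7)


@pytest.fixture(scope="session")
def small_config():
    """A reduced genome for end-to-end CLI runs."""
    from neighborscan.synthetic_data import PlantedCluster

    return SyntheticConfig(
        n_chromosomes=2,
        chrom_length=10_000_000,
        n_genes=1500,
        n_terms=20,
        planted=[
            PlantedCluster("chr1", 100, 50, "T01", 0.6, high_orthology=True),
            PlantedCluster("chr2", 300, 50, "T02", 0.6),
        ],
    )
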