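import numpy as np
import pytest

from creseq.records import GenomicInterval, Peak, TranscriptRecord
from creseq.simulate import SimulationConfig, simulate_study

#: fixed seed for every stochastic fixture in the suite
SEED = 7


@pytest.fixture(scope="session")
def default_sim():
    """One synthetic study under the standard design."""
    return simulate_study(SimulationConfig(seed=SEED))


@pytest.fixture(scope="session")
def uncoupled_sim():
    """Negative control: expression independent of occupancy."""
    return simulate_study(SimulationConfig(seed=SEED), couple_expression=False)


@pytest.fixture(scope="session")
def many_sites_sim():
    """A large planted-site set for motif-recovery statistics (n >= 2000)."""
    config = SimulationConfig(
        seed=SEED,
        n_chroms=2,
        chrom_length=3_000_000,
        n_genes=50,
        n_intergenic_sites=2_000,
        background_rate=0.001,  # reads are irrelevant here; keep it light
    )
    return simulate_study(config)


@pytest.fixture(scope="session")
def promoter_sim():
    """Every gene carries a promoter site: TSS-distance statistics at n=500."""
    config = SimulationConfig(
        seed=SEED,
        n_chroms=2,
        chrom_length=5_000_000,
        n_genes=500,
        occupied_gene_fraction=1.0,
        n_intergenic_sites=0,
        background_rate=0.001,
        n_direct_targets=10,
        n_nondirect_deregulated=12,
    )
    return simulate_study(config)


@pytest.fixture
def toy_transcripts():
    return [
        TranscriptRecord("NM_001", "GeneA", "chr1", "+", 10_000, 15_000),
        TranscriptRecord("NM_002", "GeneB", "chr1", "-", 16_000, 20_001),
        TranscriptRecord("NM_003", "GeneC", "chr1", "+", 40_000, 80_000),
        TranscriptRecord("NM_004", "GeneD", "chr2", "+", 5_000, 9_000),
    ]


def make_peak(chrom, start, end, summit=None, n_reads=None):
    if summit is None:
        summit = (start + end) // 2
    return Peak(
        interval=GenomicInterval(chrom, start, end), summit=summit, n_reads=n_reads
    )


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
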