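import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from structatlas.intervals import GeneModel, GenomicInterval
from structatlas.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_config():
    """Small but fully featured generator config used across tests."""
    return SyntheticConfig(
        seed=3, lattice_shape=(10, 8, 6), n_coarse_regions=4,
        n_fine_regions=12,
        n_probes_per_group={"utr_structured": 12, "utr_unstructured": 12,
                            "ncrna_structured": 4, "ncrna_unstructured": 4},
        n_genes=8, genome_length=80_000, n_interaction_pairs=12)


def random_gene_models(rng, n_genes: int, chrom_len: int = 10_000,
                       chrom: str = "chr1") -> list[GeneModel]:
    """Random non-overlapping gene models with UTR/CDS/intron parts."""
    genes = []
    cursor = int(rng.integers(0, 50))
    kinds_cycle = ["five_utr", "cds", "intron", "cds", "three_utr"]
    for k in range(n_genes):
        strand = "+" if rng.integers(2) else "-"
        parts = []
        for kind in kinds_cycle if strand == "+" else kinds_cycle[::-1]:
            ln = int(rng.integers(10, 120))
            if cursor + ln >= chrom_len:
                break
            parts.append((GenomicInterval(chrom, cursor, cursor + ln, strand),
                          kind))
            cursor += ln
        cursor += int(rng.integers(20, 200))
        if parts:
            genes.append(GeneModel(f"g{k}", parts))
        if cursor >= chrom_len - 300:
            break
    return genes


def random_interval(rng, chrom_len: int = 10_000, max_len: int = 300,
                    chrom: str = "chr1", strand: str = ".") -> GenomicInterval:
    start = int(rng.integers(0, chrom_len - max_len))
    return GenomicInterval(chrom, start,
                           start + int(rng.integers(1, max_len)), strand)
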