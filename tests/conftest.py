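import numpy as np
import pytest

from evorepair.genome import GeneModel, Genome
from evorepair.synthetic_data import SimulationConfig, gen_genome


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    """Small deterministic genome shared by read-only tests."""
    return gen_genome(n_genes=40, seed=11)


@pytest.fixture(scope="session")
def null_genome() -> Genome:
    """Genome at the study-layout scale used by the convergence suites."""
    return gen_genome(n_genes=200, seed=7)


@pytest.fixture()
def plus_gene() -> tuple[Genome, GeneModel]:
    """Hand-built single-gene genome on the + strand with a known CDS.

    CDS is ATG GAA CCC TGA at 1-based positions 601..612 so codon 2 (GAA,
    Glu) sits at 604..606.
    """
    flank5 = "A" * 600
    cds = "ATGGAACCCTGA"
    contig = flank5 + cds + "T" * 1200
    gene = GeneModel(
        gene_id="g1", chrom="chr1", strand="+", cds_start=601, cds_end=612,
        cds_sequence=cds,
    )
    return Genome(contigs={"chr1": contig}, genes=[gene]), gene


def make_variant_frame(rows):
    """Rows of (population, chrom, pos, ref, alt, fraction) -> variant table."""
    import pandas as pd

    return pd.DataFrame(
        rows, columns=["population", "chrom", "pos", "ref", "alt", "fraction"]
    )


@pytest.fixture()
def null_config() -> SimulationConfig:
    return SimulationConfig(
        seed=0,
        n_populations_per_condition=12,
        conditions=("0.25", "0.5", "2", "8"),
        genotypes=("mutant",),
        per_base_rate=1e-5,
    )
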