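"""Shared fixtures: tiny hand-built genomes and cached simulations."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from microsynteny.genome_io import GeneModel, GenomeAnnotation
from microsynteny.synthetic_data import (
    SimulationConfig,
    paperlike_config,
    simulate_scenario,
)


def make_gene(
    gene_id: str,
    start: int,
    cds: str,
    chromosome: str = "chr1",
    strand: str = "+",
    species: str = "sp",
) -> GeneModel:
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return GeneModel(
        gene_id=gene_id,
        species_id=species,
        chromosome=chromosome,
        start=start,
        end=start + len(cds) - 1,
        strand=strand,
        cds=cds,
        protein=prot,
    )


def make_annotation(genes, species: str = "sp", chrom_len: int = 10_000_000):
    chroms = {g.chromosome for g in genes}
    return GenomeAnnotation(
        species_id=species,
        chromosomes={c: chrom_len for c in chroms},
        genes=list(genes),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_scenario():
    """Two species, one planted duplication - fast enough for unit tests."""
    from microsynteny.synthetic_data import SimEvent

    cfg = SimulationConfig(
        seed=11,
        species=("aa", "bb"),
        divergence_times=(30.0,),
        n_chromosomes=2,
        genes_per_chromosome=16,
        mean_gene_length=300,
        intergenic_mean=8_000,
        anchors=(("chr1", 7),),
        events=(
            SimEvent(
                "segmental_duplication", 20.0, ("bb",), "chr1", 4, 7,
                dest_chromosome="chr2", dest_index=8,
            ),
        ),
    )
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def paper_scenario():
    """The standard preset used across recovery tests (one simulation)."""
    return simulate_scenario(paperlike_config(1))
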