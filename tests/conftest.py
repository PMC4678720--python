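"""Shared fixtures: tiny hand-built genomes and a session-scoped synthetic
dataset so the expensive generation/featurization happens once."""

from __future__ import annotations

import numpy as np
import pytest

from irescan import features as F
from irescan import synthetic as S
from irescan.genome_io import GeneModel, OrganismAssembly


@pytest.fixture
def toy_assembly() -> OrganismAssembly:
    rng = np.random.default_rng(42)
    chrom = "".join(rng.choice(list("ACGT"), size=400))
    return OrganismAssembly(organism_id="toy", chromosomes={"chr1": chrom})


@pytest.fixture
def toy_gene() -> GeneModel:
    return GeneModel(
        gene_id="g1", organism_id="toy", chromosome="chr1",
        strand="+", cds_start=101, cds_end=220,
    )


@pytest.fixture(scope="session")
def synthetic_data() -> S.SyntheticGenomes:
    return S.generate_genomes(S.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def synthetic_features(synthetic_data):
    return F.compute_feature_table(
        synthetic_data.assemblies, synthetic_data.genes, synthetic_data.orthologs
    )
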