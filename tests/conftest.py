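import numpy as np
import pandas as pd
import pytest

from vaccpav import SimulationParams, generate_truth
from vaccpav.io import GeneModel, GenomeAnnotation


@pytest.fixture(scope="session")
def toy_presence() -> pd.DataFrame:
    """N=3 accessions, five orthogroups with occupancies 3, 2, 1, 2, 1."""
    return pd.DataFrame(
        {
            "A": [1, 1, 1, 0, 0],
            "B": [1, 1, 0, 1, 1],
            "C": [1, 0, 0, 1, 0],
        },
        index=[f"OG{i}" for i in range(5)],
        dtype=bool,
    )


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(
        n_accessions=5, n_orthogroups=400, core_fraction=0.5, seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_params):
    return generate_truth(small_params)


def make_gene(gene_id, start, end, cds=None, seq_id="chr1", strand="+"):
    return GeneModel(
        gene_id=gene_id,
        seq_id=seq_id,
        start=start,
        end=end,
        strand=strand,
        cds_segments=tuple(cds) if cds else ((start, end),),
    )


@pytest.fixture
def tiny_annotations():
    """Two accessions, two genes each, on a shared coordinate frame."""
    a = GenomeAnnotation(
        "A",
        [make_gene("g1", 1_000, 2_000), make_gene("g2", 50_000, 51_000)],
    )
    b = GenomeAnnotation(
        "B",
        [make_gene("h1", 1_100, 2_100), make_gene("h2", 50_200, 51_200)],
    )
    return {"A": a, "B": b}
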