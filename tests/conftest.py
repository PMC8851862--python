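import logging

import pytest

from unipseudo.pipeline import PipelineConfig, PipelineData, run_stages
from unipseudo.simulate import standard_benchmark

logging.getLogger("unipseudo").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_benchmark():
    """60 genes, 12 planted losses, 12 artifacts, divergence 0.05, seed 7."""
    return standard_benchmark(seed=7, n_genes=60, n_lost=12, n_artifacts=12)


@pytest.fixture(scope="session")
def small_data(small_benchmark):
    b = small_benchmark
    return PipelineData(
        genes=b.reference.genes,
        query_assembly=b.query.assembly,
        synteny={s.gene_id: s.query for s in b.query.synteny},
        support=b.support,
    )


@pytest.fixture(scope="session")
def small_run(small_data):
    """Pipeline run through the filter cascade on the small benchmark."""
    cfg = PipelineConfig(seed=7, relax_gate=False)
    return run_stages(small_data, cfg, upto="filter")
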