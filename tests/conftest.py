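import numpy as np
import pytest

import grnformer as gf
from grnformer.synthetic import default_gene_table


@pytest.fixture(scope="session")
def small_grn():
    genes = [f"G{j:05d}" for j in range(30)]
    return gf.PlantedGRN.random(genes, edge_prob=0.08, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_grn):
    cfg = gf.SyntheticConfig(
        n_cells=400, n_genes=60, n_groups=4, mean_depth=600, seed=7
    )
    return gf.generate_dataset(cfg, small_grn)


@pytest.fixture(scope="session")
def small_vocab(small_dataset):
    table = default_gene_table(small_dataset.gene_ids, seed=7)
    return gf.GeneVocabulary.from_gene_table(table, d=32, seed=7)


@pytest.fixture(scope="session")
def small_ontology():
    return gf.make_ontology(4, 2, seed=7)


@pytest.fixture(scope="session")
def small_model(small_vocab, small_ontology):
    cfg = gf.ModelConfig(
        n_layers=2, n_heads=2, d=32, context_size=60, classes=("cell_type",)
    )
    return gf.Model(cfg, small_vocab, {"cell_type": small_ontology}, seed=7)
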