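import dendropy
import numpy as np
import pytest

from polyrekit import simgenome as sg

SPECIES_TREE_5 = \
    "(((sal:10,lsp:10)wgt_clade:5,pgr:15)lythraceae:10,egr:25)root;"
SPECIES_TREE_3 = "((sal:10,lsp:10)wgt_clade:5,pgr:15)root;"


def species_tree(newick=SPECIES_TREE_3):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return sg.SimConfig(seed=11, n_anc_chromosomes=8, n_anc_genes=400)


@pytest.fixture
def small_history(small_config):
    return sg.simulate_wgt_genomes(small_config)
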