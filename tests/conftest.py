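import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gwgen.network import load_candidate_network, load_expression
from gwgen.synthetic import GeneratorConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """Scaled-down study conditions for fast fixtures (same noise model)."""
    return GeneratorConfig(
        n_tf=4, n_protein=10, n_gene=8, n_lncrna=4, n_mirna=4,
        n_samples=100,
        n_drugs=40, n_targets=25, n_drug_features=30, n_target_features=40,
        n_pairs=300, margin=0.6, seed=7,
    )


TOY_NODES = """id\tsymbol\tnode_class
p1\tP1\tprotein
p2\tP2\tprotein
tf1\tTF1\tTF
r1\tR1\treceptor
g1\tG1\tgene
l1\tL1\tlncRNA
m1\tM1\tmiRNA
"""

TOY_PPI = """source\ttarget
p1\tp2
p1\tr1
p2\ttf1
tf1\tr1
"""

TOY_GRN = """source\ttarget
tf1\tg1
tf1\tl1
l1\tg1
m1\tg1
m1\tl1
"""


@pytest.fixture
def toy_network_files(tmp_path):
    """7 typed nodes, 4 PPI pairs, 5 regulations (hand-countable)."""
    nodes = tmp_path / "nodes.tsv"
    ppi = tmp_path / "ppi.tsv"
    grn = tmp_path / "grn.tsv"
    nodes.write_text(TOY_NODES)
    ppi.write_text(TOY_PPI)
    grn.write_text(TOY_GRN)
    return nodes, ppi, grn


@pytest.fixture
def toy_network(toy_network_files):
    nodes, ppi, grn = toy_network_files
    return load_candidate_network(ppi, grn, nodes)


@pytest.fixture
def toy_expression(tmp_path):
    """3-node x 4-sample expression matrix with two groups."""
    rng = np.random.default_rng(3)
    expr = pd.DataFrame(
        rng.uniform(1, 3, size=(3, 4)),
        index=["a", "b", "c"],
        columns=["s1", "s2", "s3", "s4"],
    )
    mat = tmp_path / "expr.tsv"
    labels = tmp_path / "labels.tsv"
    expr.to_csv(mat, sep="\t", index_label="node")
    labels.write_text(
        "sample\tgroup\ns1\tcontrol\ns2\tcontrol\ns3\tcase\ns4\tcase\n"
    )
    return mat, labels, expr


@pytest.fixture
def toy_dataset(toy_expression):
    mat, labels, _ = toy_expression
    return load_expression(mat, labels)
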