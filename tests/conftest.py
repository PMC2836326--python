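import numpy as np
import pandas as pd
import pytest

from mitophylo import synthgen
from mitophylo.alignment import PartitionedAlignment
from mitophylo.synthgen import BirthDeathParams, ExtinctLineageError


def surviving_bd_tree(params: BirthDeathParams, seed: int):
    """Birth-death replicate conditioned on survival (redraw on extinction)."""
    for k in range(200):
        try:
            return synthgen.simulate_bd_tree(params, seed + 100_000 * (k + 1))
        except ExtinctLineageError:
            continue
    raise RuntimeError("no surviving replicate found")


def random_tree(n_tips: int, seed: int, depth: float = 1.0):
    """Random ultrametric topology rescaled to the given root depth."""
    tree = surviving_bd_tree(BirthDeathParams(b=1.0, d=0.0, t_max=50.0,
                                              n_target=n_tips), seed)
    scale = depth / tree.seed_node.age
    for nd in tree:
        if nd.edge.length is not None:
            nd.edge.length *= scale
        if getattr(nd, "age", None) is not None:
            nd.age *= scale
    return tree


def flat_alignment(taxa, matrix, label="codon1", gene="g1"):
    matrix = np.asarray(matrix, dtype="<U1")
    n = matrix.shape[1]
    return PartitionedAlignment(list(taxa), matrix,
                                np.array([label] * n, dtype=object),
                                np.array([gene] * n, dtype=object))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_dataset():
    """A 6-taxon, 5-partition simulated dataset (deterministic)."""
    bd = BirthDeathParams(b=0.06, d=0.0, t_max=300.0, n_target=6)
    return synthgen.make_dataset(
        17, bd=bd,
        lengths={"codon1": 250, "codon2": 250, "codon3": 250, "rRNA": 150, "tRNA": 100},
        missing_taxa_fraction=0.0)


@pytest.fixture
def parasitism_trait():
    return pd.Series({"a": 0, "b": 1, "c": 2, "d": 0, "e": 3})
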