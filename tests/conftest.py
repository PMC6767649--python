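import numpy as np
import pytest

from tryptome import synthetic_data as sd


@pytest.fixture(scope="session")
def simspec():
    return sd.SimSpec(seed=11)


@pytest.fixture(scope="session")
def hit_bundle(simspec, tmp_path_factory):
    """Synthetic domtblout + planted architecture truth, generated once."""
    out = tmp_path_factory.mktemp("hits")
    path, truth = sd.gen_domain_hits(simspec, out / "hits.domtblout")
    return path, truth


@pytest.fixture(scope="session")
def gff_bundle(simspec, tmp_path_factory):
    out = tmp_path_factory.mktemp("gff")
    path, truth = sd.gen_gff(simspec, out / "genes.gff3")
    return path, truth


@pytest.fixture(scope="session")
def cell_bundle(simspec, tmp_path_factory):
    out = tmp_path_factory.mktemp("cells")
    path, truth = sd.gen_cell_matrix(simspec, out / "cells.tsv")
    return path, truth


def random_binary_newick(rng: np.random.Generator, n_leaves: int, prefix: str = "t") -> str:
    """Random join-order binary newick over labelled leaves (test utility)."""
    nodes = [f"{prefix}{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
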