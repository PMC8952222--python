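import numpy as np
import pytest

from coevscreen.core_io import DistanceMatrix, Msa, PhyloTree


@pytest.fixture
def toy_msa() -> Msa:
    return Msa(
        "toy",
        [
            ("sp1", "ACDEFGHIKLMN"),
            ("sp2", "ACDEFGHIKLMN"),
            ("sp3", "ACDEYGHIKLMN"),
        ],
    )


@pytest.fixture
def four_taxon_tree() -> PhyloTree:
    return PhyloTree.from_newick("((A:1,B:2):1,C:3,D:4);")


def random_binary_tree(n_leaves: int, rng: np.random.Generator):
    """A random binary tree as (newick string, patristic DistanceMatrix)."""
    from coevscreen.core_io import patristic_distances

    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = [f"{l}:{rng.uniform(0.1, 2.0):.6f}" for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    newick = "(" + ",".join(nodes) + ");"  # unrooted trifurcation at the root
    tree = PhyloTree.from_newick(newick)
    return tree, patristic_distances(tree)
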