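import random as pyrandom

import numpy as np
import pytest
from dendropy.model import birthdeath

from paleophylo.phylogeny import Phylogeny
from paleophylo.synthetic import SyntheticScenario, generate


def make_random_tree(n_tips: int, seed: int, depth: float = 10.0) -> Phylogeny:
    """Random ultrametric tree with positive branch lengths and fixed depth."""
    rng = pyrandom.Random(seed)
    t = birthdeath.birth_death_tree(birth_rate=1.0, death_rate=0.0,
                                    num_extant_tips=n_tips, rng=rng)
    ext = rng.expovariate(2.0) + 0.05
    t.seed_node.edge.length = None  # stem edge would distort the height
    for k, leaf in enumerate(t.leaf_node_iter()):
        leaf.taxon.label = f"t{k + 1}"
        leaf.edge.length += ext
    h = max(leaf.distance_from_root() for leaf in t.leaf_node_iter())
    for e in t.preorder_edge_iter():
        if e.length is not None:
            e.length *= depth / h
    return Phylogeny(t)


@pytest.fixture
def tree_factory():
    return make_random_tree


def gls_oracle(tree: Phylogeny, tip_values: dict) -> np.ndarray:
    """Brute-force GLS ancestral states from the full BM covariance matrix."""
    y = np.array([tip_values[n] for n in tree.tip_names])
    V = tree.vcv()
    Vi = np.linalg.inv(V)
    one = np.ones(len(y))
    mu = float(one @ Vi @ y) / float(one @ Vi @ one)
    est = np.empty(tree.n_nodes)
    for node in range(tree.n_nodes):
        a = np.array([tree.shared_path(node, tid) for tid in tree.tip_ids])
        est[node] = mu + a @ Vi @ (y - mu)
    return est


def path_length_oracle(tree: Phylogeny, name_a: str, name_b: str) -> float:
    """Independent recursive path length via dendropy parent chains."""
    def chain(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    nd_a = tree.nodes[tree.tip_id(name_a)]
    nd_b = tree.nodes[tree.tip_id(name_b)]
    anc_a = chain(nd_a)
    anc_b = chain(nd_b)
    shared = next(n for n in anc_a if n in anc_b)

    def climb(node, stop):
        total = 0.0
        while node is not stop:
            total += node.edge.length
            node = node.parent_node
        return total

    return climb(nd_a, shared) + climb(nd_b, shared)


@pytest.fixture(scope="session")
def small_bundle():
    """Compact synthetic scenario shared across tests (read-only)."""
    return generate(SyntheticScenario(seed=7, n_points=500, n_slices=21,
                                      n_species=5))
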