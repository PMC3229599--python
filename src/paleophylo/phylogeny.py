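"""Rooted, time-calibrated phylogenies (thin wrapper over dendropy).

Branch lengths are in millions of years (My).  Node *depth* is time before
present: tips of an ultrametric tree sit at depth 0 and the root at the crown
age.  Depths drive the along-branch envelope interpolation, so ultrametricity
is required wherever time lookups are used.
"""

from __future__ import annotations

import io as _io

import dendropy
import numpy as np

MY_PER_KY = 1.0 / 1000.0


class Phylogeny:
    """Indexed view of a rooted dendropy tree with branch lengths.

    Nodes get stable integer ids in preorder (root = 0).  Tip nodes keep
    their taxon labels.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        root = tree.seed_node
        if len(root.child_nodes()) < 2:
            raise ValueError("tree must be rooted with >= 2 children at the root")
        nodes = list(tree.preorder_node_iter())
        self.nodes = nodes
        self.node_id = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.branch_length = np.full(n, np.nan)  # edge above each node; NaN at root
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise ValueError("every non-root branch must have a length")
                if nd.edge.length < 0:
                    raise ValueError("branch lengths must be >= 0")
                p = self.node_id[id(nd.parent_node)]
                self.parent[i] = p
                self.branch_length[i] = float(nd.edge.length)
                self.children[p].append(i)
        for i, nd in enumerate(nodes):
            if nd.is_internal() and len(self.children[i]) < 2 and i != 0:
                raise ValueError("internal nodes must have >= 2 children")
        # distance from root
        self.root_distance = np.zeros(n)
        for i in range(1, n):
            self.root_distance[i] = self.root_distance[self.parent[i]] + self.branch_length[i]
        self.tip_ids = np.array([i for i, nd in enumerate(nodes) if nd.is_leaf()], dtype=int)
        self.tip_names = [nodes[i].taxon.label if nodes[i].taxon is not None else f"tip{i}"
                          for i in self.tip_ids]
        if len(set(self.tip_names)) != len(self.tip_names):
            raise ValueError("tip names must be unique")
        self._tip_index = {name: i for name, i in zip(self.tip_names, self.tip_ids)}
        self.height = float(self.root_distance[self.tip_ids].max())
        #: time before present of each node (My); tips ~0 when ultrametric
        self.depth = self.height - self.root_distance

    # ------------------------------------------------------------------ basic
    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def tip_id(self, name: str) -> int:
        try:
            return self._tip_index[name]
        except KeyError:
            raise KeyError(f"unknown tip name: {name}") from None

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = self.depth[self.tip_ids]
        return bool(np.all(np.abs(depths) <= tol * max(self.height, 1.0)))

    def ancestors(self, node: int) -> list[int]:
        """Node ids from `node`'s parent up to the root."""
        out = []
        i = self.parent[node]
        while i != -1:
            out.append(i)
            i = self.parent[i]
        return out

    def mrca(self, a: int, b: int) -> int:
        anc_a = set([a] + self.ancestors(a))
        i = b
        while i not in anc_a:
            i = self.parent[i]
        return i

    def path_length(self, name_a: str, name_b: str) -> float:
        """Sum of branch lengths on the path between two tips (My)."""
        i, j = self.tip_id(name_a), self.tip_id(name_b)
        m = self.mrca(i, j)
        return float(self.root_distance[i] + self.root_distance[j]
                     - 2.0 * self.root_distance[m])

    def shared_path(self, a: int, b: int) -> float:
        """Root-to-MRCA distance — the Brownian-motion covariance scale."""
        return float(self.root_distance[self.mrca(a, b)])

    def vcv(self) -> np.ndarray:
        """Brownian-motion tip covariance matrix (shared path lengths)."""
        k = self.n_tips
        out = np.zeros((k, k))
        for ai in range(k):
            for bi in range(ai, k):
                s = self.shared_path(self.tip_ids[ai], self.tip_ids[bi])
                out[ai, bi] = out[bi, ai] = s
        return out

    def retain_tips(self, names) -> "Phylogeny":
        """Subtree spanning the named tips (unifurcations suppressed)."""
        names = list(names)
        unknown = [n for n in names if n not in self._tip_index]
        if unknown:
            raise KeyError(f"unknown tip name(s): {unknown}")
        if len(names) < 2:
            raise ValueError("need at least 2 tips to retain")
        sub = self._tree.extract_tree_with_taxa_labels(labels=names)
        sub.seed_node.edge.length = None
        return Phylogeny(sub)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny."""
    try:
        tree = dendropy.Tree.get(
            file=_io.StringIO(text), schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())
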