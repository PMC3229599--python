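"""Ancestral climate-envelope reconstruction under Brownian motion.

Each envelope bound (one variable, min or max side) is treated as a
continuous trait evolving by Brownian motion on the time-calibrated tree.
The most-likely values at internal nodes are the generalized least squares
estimates implied by the BM covariance (shared path length from the root).
They are computed here by solving the equivalent weighted-average linear
system: at the joint maximum of the BM likelihood every internal node value
is the branch-length-weighted mean of its neighbours, with tip values fixed.

The envelope anywhere *along* a branch is the linear interpolation between
the values at the branch's two ends, scaled by position along the branch —
so a terminal lineage's envelope drifts linearly from its parent node's
reconstruction to its modern tip value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .envelopes import BioclimEnvelope
from .phylogeny import MY_PER_KY, Phylogeny

logger = logging.getLogger(__name__)


@dataclass
class TraitReconstruction:
    """Tip values plus most-likely internal-node values for one trait."""

    trait: tuple          # (variable code, "min" | "max") or any hashable tag
    tree: Phylogeny
    tip_values: dict      # tip name -> value (untouched input)
    node_values: np.ndarray  # (n_nodes,) value at every node (tips included)

    def value_at_node(self, node: int) -> float:
        return float(self.node_values[node])

    def value_along_lineage(self, lineage: str, time_kya: float) -> float:
        """Trait value at `time_kya` before present on the lineage's root path.

        Finds the branch of the tip-to-root path spanning that depth and
        interpolates linearly between the values at the branch's ends.
        """
        t_my = time_kya * MY_PER_KY
        tree = self.tree
        node = tree.tip_id(lineage)
        if t_my < tree.depth[node] - 1e-12:
            raise ValueError("time predates the tip (tree must be ultrametric)")
        while tree.parent[node] != -1 and tree.depth[tree.parent[node]] < t_my:
            node = tree.parent[node]
        parent = tree.parent[node]
        d_child = tree.depth[node]
        if abs(t_my - d_child) <= 1e-12 or parent == -1:
            if parent == -1 and t_my > d_child + 1e-12:
                raise ValueError(
                    f"time {time_kya} kya predates the root ({d_child * 1000:g} kya)")
            return float(self.node_values[node])
        d_parent = tree.depth[parent]
        frac = (t_my - d_child) / (d_parent - d_child)
        return float((1.0 - frac) * self.node_values[node]
                     + frac * self.node_values[parent])


def ancestral_reconstruct(tree: Phylogeny, tip_values: Mapping[str, float],
                          trait=("trait", "value")) -> TraitReconstruction:
    """Most-likely (GLS/BM) values at every internal node for one trait.

    Solves the weighted-Laplacian system in which each internal node's value
    is the 1/branch-length weighted average of its neighbours' values; the
    solution coincides with the GLS estimates built from the full BM
    covariance matrix.
    """
    missing = [name for name in tree.tip_names if name not in tip_values]
    if missing:
        raise ValueError(f"tip(s) without a trait value: {missing}")
    vals = {tree.tip_id(name): float(tip_values[name]) for name in tree.tip_names}
    for v in vals.values():
        if not np.isfinite(v):
            raise ValueError("tip trait values must be finite")

    internal = [i for i in range(tree.n_nodes) if i not in vals]
    pos = {node: row for row, node in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for row, node in enumerate(internal):
        neighbours = []
        if tree.parent[node] != -1:
            neighbours.append((tree.parent[node], tree.branch_length[node]))
        for c in tree.children[node]:
            neighbours.append((c, tree.branch_length[c]))
        for nb, ell in neighbours:
            if not ell > 0:
                raise ValueError("branch lengths on reconstruction paths must be > 0")
            wgt = 1.0 / ell
            A[row, row] += wgt
            if nb in pos:
                A[row, pos[nb]] -= wgt
            else:
                b[row] += wgt * vals[nb]
    solution = np.linalg.solve(A, b)

    node_values = np.empty(tree.n_nodes)
    for node, v in vals.items():
        node_values[node] = v
    for row, node in enumerate(internal):
        node_values[node] = solution[row]
    return TraitReconstruction(trait=trait, tree=tree,
                               tip_values=dict(tip_values),
                               node_values=node_values)


class EnvelopeReconstruction:
    """All 2 × n_variables trait reconstructions for a set of tip envelopes."""

    def __init__(self, tree: Phylogeny, traits: dict, percentile_pair=(5.0, 95.0),
                 codes: tuple[str, ...] = ()):
        self.tree = tree
        self.traits = traits            # (code, side) -> TraitReconstruction
        self.percentile_pair = percentile_pair
        self.codes = codes

    def envelope_at(self, lineage: str, time_kya: float) -> BioclimEnvelope:
        """Rectilinear envelope of a lineage at a past time.

        Because min and max bounds evolve independently, a reconstructed
        lower bound can exceed its upper bound; both are then collapsed to
        their midpoint (logged).
        """
        lower = np.empty(len(self.codes))
        upper = np.empty(len(self.codes))
        for j, code in enumerate(self.codes):
            lower[j] = self.traits[(code, "min")].value_along_lineage(lineage, time_kya)
            upper[j] = self.traits[(code, "max")].value_along_lineage(lineage, time_kya)
        crossed = lower > upper
        if np.any(crossed):
            mid = 0.5 * (lower[crossed] + upper[crossed])
            logger.warning("reconstructed min > max for %d variable(s) of %s at "
                           "%g kya; collapsed to midpoints", int(crossed.sum()),
                           lineage, time_kya)
            lower[crossed] = upper[crossed] = mid
        return BioclimEnvelope.from_bounds(lower, upper, *self.percentile_pair)


def reconstruct_all(tree: Phylogeny, tip_envelopes: Mapping[str, BioclimEnvelope],
                    codes: tuple[str, ...]) -> EnvelopeReconstruction:
    """Reconstruct every (variable, side) bound trait across the tree."""
    missing = [n for n in tree.tip_names if n not in tip_envelopes]
    if missing:
        raise ValueError(f"tip(s) without an envelope: {missing}")
    pairs = {(env.percentile_low, env.percentile_high)
             for env in tip_envelopes.values()}
    sizes = {env.n_features_in_ for env in tip_envelopes.values()}
    if len(pairs) > 1 or len(sizes) > 1 or sizes != {len(codes)}:
        raise ValueError("tip envelopes must share one registry and percentile pair")
    traits = {}
    for j, code in enumerate(codes):
        for side, attr in (("min", "lower_"), ("max", "upper_")):
            tips = {name: float(getattr(env, attr)[j])
                    for name, env in tip_envelopes.items()}
            traits[(code, side)] = ancestral_reconstruct(tree, tips, trait=(code, side))
    return EnvelopeReconstruction(tree, traits, tuple(pairs)[0], tuple(codes))
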