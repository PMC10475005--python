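"""Stochastic feature gain and loss along a fixed tree, and exact expectations.

Discrete features arise along branches as a Poisson process at rate ``r`` per
lineage per unit time; each feature, once present, is lost from a lineage at
rate ``nu`` per feature.  At a speciation the current feature set is copied to
both daughter lineages; every gain creates a globally novel feature.  On a
single path of length ``l`` starting empty, the feature count is Poisson with
mean (r/nu)(1 - exp(-nu*l)) -- the classic constant-birth linear-death law --
and the total feature diversity over the leaves of any fixed tree started
empty is likewise Poisson.

`evolve_features` is a per-edge Gillespie simulation of this process (waiting
times Exponential(r + k*nu), gain with probability r/(r+k*nu), loss evicting a
uniformly chosen current feature).  `expected_fd_tree` computes the exact
expected feature diversity among leaves surviving a field-of-bullets event,
for an arbitrary tree, by a survival-probability recursion over nodes.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .trees import PhyloTree

__all__ = [
    "FeatureParams",
    "LeafFeatures",
    "evolve_features",
    "fd_of_run",
    "singleton_count",
    "expected_fd_tree",
]


@dataclass(frozen=True)
class FeatureParams:
    """Feature-evolution rates: gain ``r`` (per lineage-time), loss ``nu``
    (per feature-time), and ``f0`` features present at the top of the stem."""

    r: float
    nu: float
    f0: int = 0

    def __post_init__(self) -> None:
        if self.r < 0 or self.nu < 0:
            raise ValueError("rates r and nu must be >= 0")
        if not (isinstance(self.f0, (int, np.integer)) and self.f0 >= 0):
            raise ValueError("f0 must be a nonnegative integer")


@dataclass(frozen=True)
class LeafFeatures:
    """Realised feature sets at the extant leaves of one simulation run."""

    features: Mapping[str, frozenset[str]]
    next_feature_index: int

    def union(self, leaves: Iterable[str] | None = None) -> frozenset[str]:
        labels = list(self.features) if leaves is None else list(leaves)
        unknown = set(labels) - set(self.features)
        if unknown:
            raise KeyError(f"unknown leaf label(s): {sorted(unknown)}")
        out: set[str] = set()
        for lb in labels:
            out.update(self.features[lb])
        return frozenset(out)


def _sorted_children(node):
    """Children ordered by their smallest descendant leaf label.

    Fixes the traversal (hence the RNG stream) independently of how the tree
    object happened to be built.
    """
    def key(c):
        if c.is_leaf():
            return c.taxon.label
        return min(lf.taxon.label for lf in c.leaf_iter())

    return sorted(node.child_nodes(), key=key)


def evolve_features(tree: PhyloTree, params: FeatureParams, seed: int) -> LeafFeatures:
    """Simulate feature gain/loss along every edge; return extant-leaf sets.

    Pre-order edge traversal with inherited state: each edge starts from its
    parent's end-state (the stem starts with ``f0`` root features, identifiers
    prefixed ``root``); along an edge with ``k`` current features the next
    event arrives after Exponential(r + k*nu) time and is a gain with
    probability r/(r+k*nu) (a new unique feature, identifiers ``g0, g1, ...``
    in order of creation) or else removes one uniformly chosen current
    feature.  A loss may evict a feature gained earlier on the same edge.
    Features on extinct lineages evolve identically but never reach the
    output.  Deterministic for a fixed seed.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    r, nu = params.r, params.nu
    rng = np.random.default_rng(seed)
    counter = 0
    out: dict[str, frozenset[str]] = {}

    def walk(node, inherited: list[str]) -> None:
        nonlocal counter
        current = list(inherited)
        length = node.edge.length or 0.0
        pos = 0.0
        while True:
            k = len(current)
            rate = r + k * nu
            if rate <= 0.0:
                break
            pos += rng.exponential(1.0 / rate)
            if pos > length:
                break
            if rng.random() < r / rate:
                current.append(f"g{counter}")
                counter += 1
            else:
                victim = int(rng.integers(k))
                current[victim] = current[-1]
                current.pop()
        if node.is_leaf():
            if node.extant:
                out[node.taxon.label] = frozenset(current)
        else:
            for child in _sorted_children(node):
                walk(child, current)

    root_features = [f"root{i}" for i in range(params.f0)]
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000 + 10 * len(tree.leaf_labels())))
    try:
        walk(tree.tree.seed_node, root_features)
    finally:
        sys.setrecursionlimit(old)
    return LeafFeatures(features=out, next_feature_index=counter)


def fd_of_run(
    leaf_features: LeafFeatures, survivors: Iterable[str] | None = None
) -> int:
    """Distinct features (unit richness) among the chosen extant leaves."""
    return len(leaf_features.union(survivors))


def singleton_count(leaf_features: LeafFeatures) -> int:
    """Features carried by exactly one extant leaf."""
    counts: dict[str, int] = {}
    for fs in leaf_features.features.values():
        for f in fs:
            counts[f] = counts.get(f, 0) + 1
    return sum(1 for c in counts.values() if c == 1)


# ---------------------------------------------------------------------------
# exact expectations on a fixed tree
# ---------------------------------------------------------------------------


def _gain_mass(r: float, nu: float, length: float) -> float:
    """Expected number of features gained on an edge of this length that are
    still present at its lower end: (r/nu)(1 - exp(-nu*l)), -> r*l as nu->0."""
    if nu == 0.0:
        return r * length
    return (r / nu) * -np.expm1(-nu * length)


def _decay(nu: float, length: float) -> float:
    return 1.0 if nu == 0.0 else float(np.exp(-nu * length))


def expected_fd_tree(
    tree: PhyloTree, params: FeatureParams, s: float = 1.0
) -> float:
    """Exact E[FD] among extant leaves surviving a field-of-bullets event.

    Let q(v) be the probability that a single feature present at node v is
    still present in at least one surviving extant leaf below v:

        q(extant leaf)  = s
        q(extinct leaf) = 0
        q(internal v)   = 1 - prod_children (1 - exp(-nu * l_c) q(c)).

    By thinning the gain process on each edge, features gained on edge e and
    surviving to its lower end number (r/nu)(1 - exp(-nu*l_e)) in expectation,
    each independently reaching a surviving leaf with probability q(bottom(e));
    so

        E[FD] = sum_e (r/nu)(1-exp(-nu*l_e)) q(bottom(e))
                + f0 * exp(-nu*l_stem) * q(root),

    the stem treated as an edge whose gained features, and the f0 root
    features, must first survive to the stem's lower end.  nu=0 uses the
    analytic limits (r*l and decay 1).
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0,1], got {s}")
    r, nu = params.r, params.nu

    q: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            q[node] = s if node.extant else 0.0
        else:
            miss = 1.0
            for c in node.child_nodes():
                miss *= 1.0 - _decay(nu, c.edge.length or 0.0) * q[c]
            q[node] = 1.0 - miss

    total = 0.0
    for node in tree.tree.preorder_node_iter():
        total += _gain_mass(r, nu, node.edge.length or 0.0) * q[node]
    seed = tree.tree.seed_node
    total += params.f0 * _decay(nu, seed.edge.length or 0.0) * q[seed]
    return float(total)
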