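"""Rooted binary trees with a stem edge: newick I/O, birth-death simulation, pruning.

Trees are time-calibrated: branch lengths are temporal durations, the root sits
at the bottom of a *stem edge* whose top marks time 0, and every leaf of a
surviving lineage ("extant" leaf) sits at time ``age``.  Extinct lineages end
at leaves strictly above the present; they are kept in the structure (an honest
forward simulation produces them) but excluded from diversity computations.

The container is a :class:`dendropy.Tree`; the stem edge is the seed node's
edge length.  A one-leaf tree is a single (leaf) seed node whose edge is the
stem.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "BDParams",
    "PhyloTree",
    "read_newick",
    "write_newick",
    "simulate_bd_tree",
    "prune_fob",
    "sample_survivors",
    "restrict_to_leaves",
]

#: absolute tolerance used when deciding whether a leaf lies at the present
ULTRAMETRIC_TOL = 1e-9


@dataclass(frozen=True)
class BDParams:
    """Linear birth-death rates: speciation ``lam`` and extinction ``mu``.

    Rates are per lineage per unit time.  ``lam > 0`` and ``mu >= 0`` always;
    asymptotic quantities additionally need the supercritical regime
    ``lam > mu`` and raise otherwise (checked where used, not here).
    """

    lam: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"speciation rate lam must be > 0, got {self.lam}")
        if self.mu < 0:
            raise ValueError(f"extinction rate mu must be >= 0, got {self.mu}")

    @property
    def net_rate(self) -> float:
        return self.lam - self.mu

    def require_supercritical(self) -> None:
        if not self.lam > self.mu:
            raise ValueError(
                f"operation requires lam > mu, got lam={self.lam}, mu={self.mu}"
            )


class PhyloTree:
    """A rooted binary time tree with a stem edge and extant-leaf flags.

    Parameters
    ----------
    tree:
        A dendropy tree.  The seed node's edge length is the stem length
        (``None`` is read as 0).  Every internal node must have exactly two
        children; the only exception is a one-leaf tree whose seed node is the
        leaf itself.
    age:
        Total time from the top of the stem to the present.  If omitted, the
        maximum root-to-leaf depth is used.  Leaves whose depth equals the age
        (within :data:`ULTRAMETRIC_TOL`) are flagged extant.
    """

    def __init__(self, tree: dendropy.Tree, age: float | None = None):
        self.tree = tree
        self._validate_shape()
        depths = self._compute_depths()
        if age is None:
            age = max(depths[lf] for lf in self.tree.leaf_node_iter())
        self.age = float(age)
        for leaf in self.tree.leaf_node_iter():
            leaf.extant = abs(depths[leaf] - self.age) <= ULTRAMETRIC_TOL
        self._depths = depths

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | os.PathLike, age: float | None = None) -> "PhyloTree":
        return read_newick(source, age=age)

    # -- validation and basic geometry ------------------------------------

    def _validate_shape(self) -> None:
        for node in self.tree.preorder_node_iter():
            nc = len(node.child_nodes())
            if node is self.tree.seed_node:
                if nc not in (0, 2):
                    raise ValueError(
                        f"root below the stem must be a leaf or binary, has {nc} children"
                    )
            elif nc not in (0, 2):
                path = self._node_path(node)
                raise ValueError(f"non-binary node ({nc} children) at {path}")
            if node.edge.length is None:
                node.edge.length = 0.0 if node is self.tree.seed_node else None
            if node.edge.length is None:
                path = self._node_path(node)
                raise ValueError(f"missing branch length at {path}")
            if node.edge.length < 0:
                path = self._node_path(node)
                raise ValueError(f"negative branch length at {path}")
        labels = [lf.taxon.label if lf.taxon else None for lf in self.tree.leaf_node_iter()]
        if any(lb is None for lb in labels):
            raise ValueError("every leaf must be labelled")
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")

    def _node_path(self, node) -> str:
        leaves = [lf.taxon.label for lf in node.leaf_iter() if lf.taxon]
        return "MRCA(" + ",".join(sorted(leaves)[:4]) + ")" if leaves else "<internal>"

    def _compute_depths(self) -> dict:
        depths = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            depths[node] = (depths[parent] if parent else 0.0) + (node.edge.length or 0.0)
        return depths

    # -- accessors ---------------------------------------------------------

    @property
    def stem_length(self) -> float:
        return float(self.tree.seed_node.edge.length or 0.0)

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def extant_leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter() if lf.extant]

    @property
    def n_extant(self) -> int:
        return len(self.extant_leaf_labels())

    def depth_of(self, label: str) -> float:
        """Root-to-leaf path length (stem included) for a leaf label."""
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return self._depths[lf]
        raise KeyError(f"unknown leaf label {label!r}")

    def leaf_depths(self) -> dict[str, float]:
        return {lf.taxon.label: self._depths[lf] for lf in self.tree.leaf_node_iter()}

    def total_branch_length(self) -> float:
        """Sum of all branch lengths, stem included, extinct lineages included."""
        return sum(nd.edge.length or 0.0 for nd in self.tree.preorder_node_iter())

    def pd_of(self, labels) -> float:
        """Rooted phylogenetic diversity of a leaf subset.

        Sum of branch lengths on the union of root-to-leaf paths, the stem
        included (it lies on every such path).
        """
        want = set(labels)
        known = set(self.leaf_labels())
        unknown = want - known
        if unknown:
            raise KeyError(f"unknown leaf label(s): {sorted(unknown)}")
        if not want:
            return 0.0
        total = 0.0
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node._on_path = node.taxon.label in want
            else:
                node._on_path = any(c._on_path for c in node.child_nodes())
            if node._on_path:
                total += node.edge.length or 0.0
        return total

    # -- newick ------------------------------------------------------------

    def as_newick(self) -> str:
        return write_newick(self)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick())


def _collapse_unary_top(tree: dendropy.Tree) -> None:
    """Merge a unary chain above the first branching node into the stem."""
    seed = tree.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        child.edge.length = (child.edge.length or 0.0) + (seed.edge.length or 0.0)
        seed.remove_child(child)
        child.parent_node = None
        tree.seed_node = child
        seed = child


def read_newick(source: str | os.PathLike, age: float | None = None) -> PhyloTree:
    """Parse newick text or a file path into a :class:`PhyloTree`.

    The trailing root branch length is the stem; unary wrappers above the
    first branching node are collapsed into the stem (path lengths are
    preserved exactly).  Extant flags are recovered from leaf depth vs age.
    """
    text = None
    if isinstance(source, (str,)) and ("(" in source or ";" in source):
        text = source
    elif os.path.exists(os.fspath(source)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    _collapse_unary_top(tree)
    return PhyloTree(tree, age=age)


def write_newick(ptree: PhyloTree) -> str:
    out = ptree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    return out.strip() + "\n"


# ---------------------------------------------------------------------------
# forward birth-death simulation
# ---------------------------------------------------------------------------


def simulate_bd_tree(
    bd: BDParams,
    age: float,
    seed: int,
    tip_filter: tuple[int, int] | None = None,
    require_survival: bool = True,
    max_attempts: int = 10**6,
) -> PhyloTree:
    """Simulate a birth-death tree forward in time from a single lineage.

    Lineages split at rate ``bd.lam`` and die at rate ``bd.mu``.  The stem
    edge runs from time 0 to the first speciation (or to ``age`` for a
    single surviving lineage).  Extinct subtrees are retained, with extant
    flags marking leaves at the present.

    Parameters
    ----------
    tip_filter:
        ``(lo, hi)`` inclusive range of *extant* tip counts; realisations are
        rejection-sampled until the count falls in the range.
    require_survival:
        When True (default) the tree is conditioned on >= 1 extant tip.  Set
        False to obtain the unconditioned process (a fully extinct
        realisation is then returned as-is, with zero extant tips).
    max_attempts:
        Cap on rejection attempts; exceeded -> RuntimeError.
    """
    if age <= 0:
        raise ValueError("age must be > 0")
    lo, hi = tip_filter if tip_filter is not None else (None, None)
    rng = np.random.default_rng(seed)
    p_birth = bd.lam / (bd.lam + bd.mu)
    total_rate_per_lineage = bd.lam + bd.mu

    for attempt in range(1, max_attempts + 1):
        # lightweight skeleton: each lineage is [parent_idx, birth_time,
        # death_time_or_None, child0, child1, extant]
        nodes = [[-1, 0.0, None, None, None, False]]
        alive = [0]
        t = 0.0
        aborted = False
        while alive:
            n = len(alive)
            t += rng.exponential(1.0 / (n * total_rate_per_lineage))
            if t >= age:
                break
            i = int(rng.integers(n))
            idx = alive[i]
            alive[i] = alive[-1]
            alive.pop()
            nodes[idx][2] = t
            if rng.random() < p_birth:
                for k in (3, 4):
                    nodes[idx][k] = len(nodes)
                    nodes.append([idx, t, None, None, None, False])
                    alive.append(len(nodes) - 1)
                # pure-birth counts never decrease: reject early once over cap
                if hi is not None and bd.mu == 0.0 and len(alive) > hi:
                    aborted = True
                    break
            # else: death -- lineage closed at time t, stays a leaf
        if aborted:
            continue
        for idx in alive:
            nodes[idx][2] = age
            nodes[idx][5] = True
        n_extant = len(alive)
        if require_survival and n_extant == 0:
            continue
        if lo is not None and not (lo <= n_extant <= hi):
            continue
        return _skeleton_to_tree(nodes, age)
    raise RuntimeError(
        f"tip filter {tip_filter} not attained in {max_attempts} attempts"
    )


def _skeleton_to_tree(nodes: list, age: float) -> PhyloTree:
    taxa = dendropy.TaxonNamespace()
    dnodes = [dendropy.Node() for _ in nodes]
    n_extant = 0
    n_extinct = 0
    for i, (parent, t0, t1, c0, c1, extant) in enumerate(nodes):
        dnodes[i].edge.length = t1 - t0
        if c0 is not None:
            dnodes[i].add_child(dnodes[c0])
            dnodes[i].add_child(dnodes[c1])
        else:
            if extant:
                n_extant += 1
                label = f"t{n_extant}"
            else:
                n_extinct += 1
                label = f"x{n_extinct}"
            dnodes[i].taxon = dendropy.Taxon(label=label)
            taxa.add_taxon(dnodes[i].taxon)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = dnodes[0]
    return PhyloTree(tree, age=age)


# ---------------------------------------------------------------------------
# field-of-bullets pruning
# ---------------------------------------------------------------------------


def sample_survivors(
    labels,
    s: float,
    mode: str = "bernoulli",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> frozenset:
    """Draw the set of surviving labels under a field-of-bullets event.

    ``bernoulli``: each label survives independently with probability s.
    ``fixed-fraction``: exactly round(s*n) labels survive (s is the survival
    fraction; rounding is half-away-from-zero), chosen uniformly.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"survival probability s must be in [0,1], got {s}")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or an rng) is required for sampling")
        rng = np.random.default_rng(seed)
    labels = sorted(labels)
    n = len(labels)
    if mode == "bernoulli":
        keep = rng.random(n) < s
        return frozenset(lb for lb, k in zip(labels, keep) if k)
    if mode == "fixed-fraction":
        k = int(np.floor(s * n + 0.5))
        if k == 0:
            return frozenset()
        idx = rng.choice(n, size=k, replace=False)
        return frozenset(labels[i] for i in idx)
    raise ValueError(f"unknown pruning mode {mode!r}")


def prune_fob(
    ptree: PhyloTree,
    s: float,
    mode: str = "bernoulli",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Apply a field-of-bullets extinction event and prune the tree.

    Returns ``(pruned_tree, survivors)``.  The pruned tree keeps only the
    surviving extant leaves; unary nodes created by the removal are suppressed
    by concatenating branch lengths (the stem may therefore lengthen), so
    every surviving leaf keeps its root-to-leaf path length.  An empty
    survivor set yields ``(None, frozenset())``.
    """
    extant = ptree.extant_leaf_labels()
    if not extant:
        raise ValueError("tree has no extant leaves to prune")
    survivors = sample_survivors(extant, s, mode=mode, seed=seed, rng=rng)
    if not survivors:
        return None, survivors
    return restrict_to_leaves(ptree, survivors), survivors


def restrict_to_leaves(ptree: PhyloTree, keep) -> PhyloTree:
    """Tree restricted to a leaf subset, unary nodes suppressed, lengths kept."""
    keep = set(keep)
    known = set(ptree.leaf_labels())
    unknown = keep - known
    if unknown:
        raise KeyError(f"unknown leaf label(s): {sorted(unknown)}")
    taxa = dendropy.TaxonNamespace()

    def build(node):
        if node.is_leaf():
            if node.taxon.label not in keep:
                return None
            new = dendropy.Node()
            new.edge.length = node.edge.length or 0.0
            new.taxon = dendropy.Taxon(label=node.taxon.label)
            taxa.add_taxon(new.taxon)
            return new
        kept = [b for b in (build(c) for c in node.child_nodes()) if b is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].edge.length += node.edge.length or 0.0
            return kept[0]
        new = dendropy.Node()
        new.edge.length = node.edge.length or 0.0
        for c in kept:
            new.add_child(c)
        return new

    root = build(ptree.tree.seed_node)
    if root is None:
        raise ValueError("leaf subset is empty")
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return PhyloTree(tree, age=ptree.age)
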