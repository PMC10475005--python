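"""Shared fixtures: small assignments, random ultrametric trees, oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from featdiv import FeatureAssignment, SurvivalProfile, feature_diversity, read_newick


def enumerate_expected_phi(assignment: FeatureAssignment, profile: SurvivalProfile) -> float:
    """Brute-force E[FD(survivors)/FD(all)] by summing over all 2^n outcomes."""
    species = assignment.species
    total = assignment.fd()
    expected = 0.0
    for fates in itertools.product((0, 1), repeat=len(species)):
        p = 1.0
        survivors = []
        for x, alive in zip(species, fates):
            sx = profile.prob(x)
            p *= sx if alive else 1.0 - sx
            if alive:
                survivors.append(x)
        if p > 0.0:
            expected += p * feature_diversity(assignment, survivors) / total
    return expected


def random_assignment(rng: np.random.Generator, n_species: int = 5,
                      n_features: int = 6, unit_richness: bool = False) -> FeatureAssignment:
    feats = [f"f{i}" for i in range(n_features)]
    features_of = {}
    for i in range(n_species):
        k = int(rng.integers(0, n_features + 1))
        features_of[f"s{i}"] = rng.choice(feats, size=k, replace=False).tolist()
    if not any(features_of.values()):  # keep total FD positive
        features_of["s0"] = [feats[0]]
    richness = None if unit_richness else {
        f: float(rng.uniform(0.2, 3.0)) for f in feats
    }
    return FeatureAssignment.build(features_of, richness)


def random_ultrametric_newick(rng: np.random.Generator, n_leaves: int,
                              age: float = 1.0) -> str:
    """Random ultrametric rooted binary tree with a positive stem edge."""
    stem = float(rng.uniform(0.05, 0.3)) * age
    height = age - stem
    counter = itertools.count(1)

    def build(n: int, h: float) -> str:
        if n == 1:
            return f"t{next(counter)}:{h:.12g}"
        k = int(rng.integers(1, n))
        u = float(rng.uniform(0.0, h))  # height of this internal node's children
        left = build(k, u)
        right = build(n - k, u)
        return f"({left},{right}):{h - u:.12g}"

    if n_leaves == 1:
        return f"t1:{age:.12g};"
    k = int(rng.integers(1, n_leaves))
    u = float(rng.uniform(0.0, height))
    return f"({build(k, u)},{build(n_leaves - k, u)}):{stem + height - u:.12g};"


def caterpillar_with_long_pendant(n: int, ell: float = 2.0):
    """Height-2*ell tree: one leaf on a pendant edge of length ell, the other
    n-1 leaves on pendant edges of length 1/n hanging from a zero-length comb.

    The shared root path of the short leaves is long, so the surviving
    fraction of feature diversity keeps fluctuating no matter how large n is.
    """
    assert n >= 3 and ell > 1.0 / n
    short = 1.0 / n
    sub = f"s1:{short:.12g}"
    for i in range(2, n - 1):
        sub = f"({sub},s{i}:{short:.12g}):0"
    sub = f"({sub},s{n - 1}:{short:.12g}):{ell - short:.12g}"
    return read_newick(f"(long:{ell:.12g},{sub}):{ell:.12g};")


@pytest.fixture
def rng():
    return np.random.default_rng(20230902)


@pytest.fixture
def t2_tree():
    """Two-leaf tree: stem 0.7, pendant edges 1.5."""
    return read_newick("(a:1.5,b:1.5):0.7;")
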