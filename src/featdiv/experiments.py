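"""End-to-end simulation study: theory curves, pruning replicates, SD summary.

The study conditions mirror the reference simulation protocol: 500 pure-birth
trees (lam = 0.055, mu = 0, age 100, filtered to 250 extant tips) and 500
birth-death trees (lam = 0.11, mu = 0.088, age 100, 250-300 extant tips);
features evolved with gain rate r = 0.3 and loss rates nu/lam in
{0, 0.5, 1, 2, 10}; a fixed-fraction extinction event retaining a proportion
s of tips for s on a 0.05..0.95 grid; the realised surviving fraction of
feature diversity recorded per replicate.  The replicate count and the tip
window are exposed so scaled-down runs stay on the same protocol.

Seeding: a master seed feeds ``numpy.random.SeedSequence``; replicate i draws
its child sequence by spawn index, and within a replicate the tree, each
feature-evolution run and each pruning draw consume consecutive entries of
``generate_state`` -- a documented counter scheme making every table
byte-reproducible from the master seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .trees import BDParams, simulate_bd_tree, sample_survivors
from .gainloss import FeatureParams, evolve_features, fd_of_run
from .bdtheory import DerivedRatios, phi_pd, phi_fd_limit

__all__ = [
    "ExperimentConfig",
    "run_phi_curves",
    "run_pruning_experiment",
    "run_sd_summary",
]

_DEFAULT_NU_GRID = (0.0, 0.5, 1.0, 2.0, 10.0)
_DEFAULT_S_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass(frozen=True)
class ExperimentConfig:
    """One tree scenario plus the feature/extinction grids and seeds."""

    name: str
    lam: float
    mu: float
    age: float
    tips_min: int
    tips_max: int
    r: float = 0.3
    nu_over_lambda: tuple[float, ...] = _DEFAULT_NU_GRID
    s_grid: tuple[float, ...] = _DEFAULT_S_GRID
    n_replicates: int = 500
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(not 0.0 < s < 1.0 for s in self.s_grid):
            raise ValueError("s grid must lie strictly inside (0,1)")
        if self.tips_min > self.tips_max or self.tips_min < 1:
            raise ValueError("bad tip filter range")

    @classmethod
    def yule(cls, n_replicates: int = 500, master_seed: int = 0,
             tip_window: int = 0, **kw) -> "ExperimentConfig":
        """Pure-birth scenario; ``tip_window`` widens the 250-tip filter to
        250 +/- tip_window (rejection cost drops roughly linearly)."""
        return cls(name="yule", lam=0.055, mu=0.0, age=100.0,
                   tips_min=250 - tip_window, tips_max=250 + tip_window,
                   n_replicates=n_replicates, master_seed=master_seed, **kw)

    @classmethod
    def birth_death(cls, n_replicates: int = 500, master_seed: int = 0,
                    **kw) -> "ExperimentConfig":
        return cls(name="birth_death", lam=0.11, mu=0.088, age=100.0,
                   tips_min=250, tips_max=300,
                   n_replicates=n_replicates, master_seed=master_seed, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def _replicate_seeds(config: ExperimentConfig):
    """Deterministic per-replicate integer seeds (< 2**31)."""
    root = np.random.SeedSequence(config.master_seed)
    children = root.spawn(config.n_replicates)
    n_nu = len(config.nu_over_lambda)
    n_s = len(config.s_grid)
    per_rep = 1 + n_nu * (1 + n_s)
    for child in children:
        state = child.generate_state(per_rep, dtype=np.uint64) & 0x7FFFFFFF
        yield [int(v) for v in state]


def run_phi_curves(
    rho1: float,
    nu_over_lambda=_DEFAULT_NU_GRID,
    s_grid=_DEFAULT_S_GRID,
) -> pd.DataFrame:
    """Theory curves: the large-t surviving-FD fraction for each loss ratio.

    Columns ``nu_over_lambda, s, phi``; the nu = 0 row is the phylogenetic
    diversity curve (the two coincide there), and curves decrease pointwise
    toward s as nu/lam grows.
    """
    rows = []
    for r2 in nu_over_lambda:
        for s in s_grid:
            if r2 == 0.0:
                phi = phi_pd(rho1, float(s))
            else:
                phi = phi_fd_limit(DerivedRatios(rho1=rho1, rho2=float(r2)), float(s))
            rows.append({"nu_over_lambda": r2, "s": float(s), "phi": phi})
    return pd.DataFrame(rows)


def run_pruning_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate trees, evolve features, prune, record surviving-FD fractions.

    One row per (replicate, nu/lam, s): the realised
    FD(survivors)/FD(all extant) with unit richness, fixed-fraction pruning
    retaining round(s*n) tips.  Byte-reproducible from the master seed.
    """
    bd = BDParams(lam=config.lam, mu=config.mu)
    rows = []
    for rep, seeds in enumerate(_replicate_seeds(config)):
        it = iter(seeds)
        tree_seed = next(it)
        try:
            tree = simulate_bd_tree(
                bd, config.age, seed=tree_seed,
                tip_filter=(config.tips_min, config.tips_max),
            )
        except RuntimeError as err:
            raise RuntimeError(f"replicate {rep}: {err}") from err
        extant = tree.extant_leaf_labels()
        for r2 in config.nu_over_lambda:
            fp = FeatureParams(r=config.r, nu=r2 * config.lam)
            lf = evolve_features(tree, fp, seed=next(it))
            total = fd_of_run(lf)
            for s in config.s_grid:
                survivors = sample_survivors(
                    extant, float(s), mode="fixed-fraction", seed=next(it)
                )
                frac = fd_of_run(lf, survivors) / total if total > 0 else np.nan
                rows.append({
                    "replicate": rep,
                    "nu_over_lambda": r2,
                    "s": float(s),
                    "fraction": frac,
                })
    return pd.DataFrame(rows)


def run_sd_summary(fractions: pd.DataFrame, name: str = "") -> pd.DataFrame:
    """Across-replicate SD of the surviving fraction at each s, averaged
    over the s grid.  Columns ``scenario, nu_over_lambda, mean_sd``."""
    sd = (
        fractions.groupby(["nu_over_lambda", "s"])["fraction"]
        .std(ddof=1)
        .reset_index()
    )
    out = (
        sd.groupby("nu_over_lambda")["fraction"].mean().reset_index()
        .rename(columns={"fraction": "mean_sd"})
    )
    out.insert(0, "scenario", name)
    return out
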