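"""Calibration experiments for the package's permutation statistics.

These functions run the simulation studies that anchor the statistics to
their defining behaviour: the D statistic averages 0 for traits generated
under the Brownian threshold model and 1 for randomly assigned traits; the
NRI permutation test holds its nominal type-I error on neutral samples;
and state-selective retention in browsed plots produces the
browsed-clustered / unbrowsed-neutral NRI pattern.  They are used by the
test suite and by the reproduction script, and are exported for anyone who
wants to re-run the calibrations at other design points.
"""

from __future__ import annotations

import numpy as np

from ._seeds import spawn_rng
from .nri import nri, nri_by_treatment_year
from .signal_tests import d_statistic
from .simulate import (
    SimulationConfig,
    assemble_communities,
    simulate_brownian_trait,
    simulate_two_clade_tree,
    simulate_yule_tree,
    threshold_binarize,
)

__all__ = [
    "d_statistic_calibration",
    "nri_type_one_error",
    "clade_filter_recovery",
]


def d_statistic_calibration(
    mode: str,
    n_replicates: int = 200,
    n_tips: int = 50,
    prevalence: int = 25,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """D statistics of traits generated under a known model.

    ``mode="brownian_threshold"`` evolves a Brownian character (sigma^2 = 1)
    on a fresh pure-birth tree per replicate and thresholds it at
    ``prevalence`` tips; ``mode="random"`` assigns state 1 to ``prevalence``
    uniformly chosen tips.  Returns the array of D values; their mean is
    the calibration quantity (0 and 1 respectively).
    """
    if mode not in ("brownian_threshold", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    out = np.empty(n_replicates)
    for i in range(n_replicates):
        tree = simulate_yule_tree(n_tips, 1.0, rng=spawn_rng(seed, "tree", mode, i))
        if mode == "brownian_threshold":
            liability = simulate_brownian_trait(
                tree, 1.0, rng=spawn_rng(seed, "bm", i)
            )
            trait = threshold_binarize(
                liability, prevalence, rng=spawn_rng(seed, "thr", i)
            )
        else:
            rng = spawn_rng(seed, "rand", i)
            ones = rng.choice(n_tips, size=prevalence, replace=False)
            vec = np.zeros(n_tips, dtype=int)
            vec[ones] = 1
            trait = dict(zip(tree.tip_labels, vec.tolist()))
        result = d_statistic(
            tree, trait, n_perm=n_perm,
            seed=int(spawn_rng(seed, "dstat", mode, i).integers(2**31)),
        )
        out[i] = result.D
    return out


def nri_type_one_error(
    n_replicates: int = 1000,
    n_pool: int = 24,
    n_members: int = 8,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of neutral random samples rejected at level ``alpha``.

    Members are drawn uniformly from the pool, i.e. exactly the null the
    permutation test assumes, so the fraction estimates the type-I error.
    """
    tree = simulate_yule_tree(n_pool, 1.0, rng=spawn_rng(seed, "pool-tree"))
    dist = tree.cophenetic_matrix()
    labels = np.array(tree.tip_labels)
    hits = 0
    for i in range(n_replicates):
        rng = spawn_rng(seed, "neutral", i)
        members = labels[rng.choice(n_pool, size=n_members, replace=False)]
        r = nri(members, dist, n_perm=n_perm, seed=int(rng.integers(2**31)))
        hits += r.p_clustering <= alpha
    return hits / n_replicates


def clade_filter_recovery(
    n_replicates: int = 100,
    n_per_clade: int = 10,
    base_occupancy: float = 0.3,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates recovering the browsing signature.

    Each replicate builds a deep two-clade pool, assembles one survey year
    in which browsed (control) plots retain only the tolerant clade, and
    scores a success when the browsed pooled community is significantly
    clustered (NRI > 0, p <= alpha) while the unbrowsed one is not.
    """
    successes = 0
    for i in range(n_replicates):
        tree, trait = simulate_two_clade_tree(
            n_per_clade, rng=spawn_rng(seed, "clade-tree", i)
        )
        cfg = SimulationConfig(
            n_species=2 * n_per_clade,
            years=(2006,),
            mk_n_states=2,
            base_occupancy=base_occupancy,
            threshold_prevalence=n_per_clade,
            master_seed=int(spawn_rng(seed, "assembly", i).integers(2**31)),
        )
        panel, _ = assemble_communities(tree, trait, {0: 1.0, 1: 0.0}, cfg)
        table = nri_by_treatment_year(
            panel, tree, n_perm=n_perm,
            seed=int(spawn_rng(seed, "nri", i).integers(2**31)),
        ).set_index("treatment")
        browsed, unbrowsed = table.loc["control"], table.loc["exclosure"]
        ok = (
            np.isfinite(browsed.nri)
            and browsed.nri > 0
            and browsed.p_clustering <= alpha
            and not (
                np.isfinite(unbrowsed.nri)
                and unbrowsed.nri > 0
                and unbrowsed.p_clustering <= alpha
            )
        )
        successes += bool(ok)
    return successes / n_replicates
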