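"""Phylogenetic signal tests for browse-vulnerability traits.

Two complementary tests are provided:

* **Fritz & Purvis' D** for binary traits (e.g. pollination mode).  The
  observed statistic is the sum of sister-clade differences of the 0/1
  character, with nodal values estimated tip-to-root by equal-weight
  averaging of daughter values (branch lengths ignored).  It is scaled
  between two permutation nulls — random tip shuffles (D = 1 on average)
  and a Brownian threshold model matched to the observed prevalence
  (D = 0 on average) — so D < 0 indicates strong conservatism and D > 1
  overdispersion.

* A **parsimony-score permutation test** for multistate traits (e.g.
  browse type).  The observed statistic is the minimum number of state
  transitions on the tree (Fitch parsimony, with Hartigan's generalisation
  at polytomies so the count stays minimal); the null distribution comes
  from permuting the tip states, and the p-value is the fraction of
  permutations whose score is less than or equal to the observed score.

Both tests ignore branch lengths except for the Brownian null, which
simulates Brownian motion along the actual branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np

from .simulate import brownian_tip_matrix, threshold_columns
from .trees import PhyloTree

__all__ = [
    "DStatResult",
    "ParsimonySignalResult",
    "fitch_parsimony_score",
    "parsimony_signal_test",
    "sister_clade_difference_sum",
    "d_scale",
    "d_statistic",
]

_MAX_STATES = 16  # bitmask width used by the parsimony sweep


@dataclass(frozen=True)
class DStatResult:
    """Fritz & Purvis D with its two permutation nulls.

    ``D = (d_obs - mean_d_brownian) / (mean_d_random - mean_d_brownian)``;
    p-values are two-tailed with add-one permutation ranks.
    """

    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    p_random: float
    p_brownian: float
    n_perm: int
    seed: int | None
    degenerate: bool = False


@dataclass(frozen=True)
class ParsimonySignalResult:
    """Observed parsimony steps against the tip-permutation null.

    ``p_value = (#{null <= observed} + 1) / (n_perm + 1)``; the null
    summary reports the mean and the 2.5 % / 97.5 % quantiles.
    """

    observed_steps: int
    null_mean: float
    null_q025: float
    null_q975: float
    p_value: float
    n_perm: int
    seed: int | None
    degenerate: bool = False


# --------------------------------------------------------------------- #
# encoding helpers


def _tip_vector(tree: PhyloTree, mapping: Mapping[str, object]) -> list:
    missing = [t for t in tree.tip_labels if t not in mapping]
    if missing:
        raise KeyError(f"trait state missing for tips: {', '.join(missing)}")
    return [mapping[t] for t in tree.tip_labels]


def _encode_states(raw: list) -> tuple[np.ndarray, int]:
    alphabet = sorted(set(raw), key=repr)
    if len(alphabet) > _MAX_STATES:
        raise ValueError(f"at most {_MAX_STATES} states supported, got {len(alphabet)}")
    code = {s: i for i, s in enumerate(alphabet)}
    return np.array([code[s] for s in raw], dtype=np.int64), len(alphabet)


# --------------------------------------------------------------------- #
# parsimony


def _parsimony_scores(tree: PhyloTree, states: np.ndarray, n_states: int) -> np.ndarray:
    """Minimum transition counts for each column of ``states``.

    ``states`` has shape (n_tips, m) with integer codes in [0, n_states).
    Postorder Fitch/Hartigan sweep with state sets as bitmasks; at a node
    with ``c`` children the cost contribution is ``c - K`` where ``K`` is
    the largest number of children whose preferred sets share a state.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.int64))
    if states.shape[0] != tree.n_tips:
        raise ValueError("state matrix rows must match tree tips")
    m = states.shape[1]
    vsets = np.zeros((tree.n_nodes, m), dtype=np.uint32)
    vsets[tree.tip_ids] = (np.uint32(1) << states.astype(np.uint32))
    steps = np.zeros(m, dtype=np.int64)
    for v in range(tree.n_nodes):
        ch = tree.children[v]
        if len(ch) == 0:
            continue
        counts = np.zeros((n_states, m), dtype=np.int64)
        for c in ch:
            for s in range(n_states):
                counts[s] += (vsets[c] >> np.uint32(s)) & np.uint32(1)
        k_max = counts.max(axis=0)
        steps += len(ch) - k_max
        v_new = np.zeros(m, dtype=np.uint32)
        for s in range(n_states):
            v_new |= (counts[s] == k_max).astype(np.uint32) << np.uint32(s)
        vsets[v] = v_new
    return steps


def fitch_parsimony_score(
    tree: PhyloTree, trait: Mapping[str, Hashable]
) -> int:
    """Minimum number of state transitions of ``trait`` on the tree.

    States are unordered and branch lengths are ignored.  At polytomies
    the Hartigan generalisation of the Fitch pass is used, so the count is
    the true minimum on the tree as given.
    """
    codes, k = _encode_states(_tip_vector(tree, trait))
    return int(_parsimony_scores(tree, codes[:, None], k)[0])


def parsimony_signal_test(
    tree: PhyloTree,
    trait: Mapping[str, Hashable],
    n_perm: int = 1000,
    seed: int | None = None,
) -> ParsimonySignalResult:
    """Tip-state permutation test of phylogenetic signal in a multistate trait.

    The multiset of states is preserved: the null shuffles the observed
    states across all tips.  A constant trait is degenerate (observed and
    every null score are 0, hence p = 1).
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    codes, k = _encode_states(_tip_vector(tree, trait))
    observed = int(_parsimony_scores(tree, codes[:, None], k)[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1).T
    null = _parsimony_scores(tree, perms, k)
    p = (np.count_nonzero(null <= observed) + 1) / (n_perm + 1)
    return ParsimonySignalResult(
        observed_steps=observed,
        null_mean=float(null.mean()),
        null_q025=float(np.quantile(null, 0.025)),
        null_q975=float(np.quantile(null, 0.975)),
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        degenerate=(k == 1),
    )


# --------------------------------------------------------------------- #
# Fritz & Purvis D


def _d_sums(tree: PhyloTree, tip_values: np.ndarray) -> np.ndarray:
    """Sister-clade difference sums for each column of ``tip_values``.

    Nodal values are estimated tip-to-root as the unweighted mean of
    daughter values; the statistic is the sum over internal nodes of all
    pairwise absolute differences between daughter values (the pairwise
    sum generalises the two-daughter case at polytomies).
    """
    tip_values = np.atleast_2d(np.asarray(tip_values, dtype=float))
    if tip_values.shape[0] != tree.n_tips:
        raise ValueError("tip value rows must match tree tips")
    m = tip_values.shape[1]
    vals = np.zeros((tree.n_nodes, m))
    vals[tree.tip_ids] = tip_values
    d = np.zeros(m)
    for v in range(tree.n_nodes):
        ch = tree.children[v]
        if len(ch) == 0:
            continue
        cv = vals[ch]
        vals[v] = cv.mean(axis=0)
        for a in range(len(ch)):
            for b in range(a + 1, len(ch)):
                d += np.abs(cv[a] - cv[b])
    return d


def sister_clade_difference_sum(
    tree: PhyloTree, tip_values: Mapping[str, float]
) -> float:
    """The d statistic of a real-valued character (branch lengths ignored)."""
    vec = np.array(_tip_vector(tree, tip_values), dtype=float)
    return float(_d_sums(tree, vec[:, None])[0])


def d_scale(d_obs: float, mean_d_random: float, mean_d_brownian: float) -> float:
    """Scale an observed d sum between its two null means.

    Returns 1 when ``d_obs`` equals the random-null mean, 0 when it equals
    the Brownian-null mean, NaN when the two means coincide (degenerate
    scaling).
    """
    denom = mean_d_random - mean_d_brownian
    if denom == 0:
        return float("nan")
    return float((d_obs - mean_d_brownian) / denom)


def _two_tailed_rank_p(null: np.ndarray, obs: float, n_perm: int) -> float:
    p_low = (np.count_nonzero(null <= obs) + 1) / (n_perm + 1)
    p_high = (np.count_nonzero(null >= obs) + 1) / (n_perm + 1)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def d_statistic(
    tree: PhyloTree,
    trait: Mapping[str, int],
    n_perm: int = 1000,
    seed: int | None = None,
) -> DStatResult:
    """Fritz & Purvis' D for a binary trait.

    The random null shuffles the observed 0/1 states across tips
    (prevalence preserved); the Brownian null simulates Brownian motion
    (sigma^2 = 1) along the branch lengths and thresholds each realisation
    at the observed minority-state count.  Because the d sum is invariant
    under complementing the trait and Brownian motion is sign-symmetric,
    thresholding at ``min(k, n - k)`` is distributionally identical to
    prevalence-matching and makes the whole result exactly invariant to
    swapping the 0/1 coding.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    raw = _tip_vector(tree, trait)
    bad = sorted({v for v in raw if v not in (0, 1)}, key=repr)
    if bad:
        raise ValueError(f"binary trait must be coded 0/1, found: {bad}")
    vec = np.array(raw, dtype=np.int64)
    n = vec.size
    k = int(vec.sum())
    if k == 0 or k == n:
        raise ValueError("binary trait must have both states present")

    d_obs = float(_d_sums(tree, vec[:, None].astype(float))[0])
    rng = np.random.default_rng(seed)

    shuffled = rng.permuted(np.tile(vec, (n_perm, 1)), axis=1).T.astype(float)
    d_random = _d_sums(tree, shuffled)

    bm = brownian_tip_matrix(tree, 1.0, n_perm, rng)
    binarized = threshold_columns(bm, min(k, n - k), rng).astype(float)
    d_brownian = _d_sums(tree, binarized)

    mean_r = float(d_random.mean())
    mean_b = float(d_brownian.mean())
    value = d_scale(d_obs, mean_r, mean_b)
    return DStatResult(
        d_obs=d_obs,
        mean_d_random=mean_r,
        mean_d_brownian=mean_b,
        D=value,
        p_random=_two_tailed_rank_p(d_random, d_obs, n_perm),
        p_brownian=_two_tailed_rank_p(d_brownian, d_obs, n_perm),
        n_perm=n_perm,
        seed=seed,
        degenerate=not np.isfinite(value),
    )
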