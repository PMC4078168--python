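"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: distances by
explicit node-to-root path walks, parsimony by exhaustive enumeration of
internal-state assignments, the d sum by a plain recursion, and null MPDs
by literally shuffling tip labels.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from phylobrowse.diversity import CoverPanel
from phylobrowse.trees import DistanceMatrix, PhyloTree


def root_path(tree: PhyloTree, v: int) -> list[int]:
    path = []
    while v != tree.root:
        path.append(v)
        v = int(tree.parent[v])
    return path


def patristic_oracle(tree: PhyloTree) -> np.ndarray:
    """Pairwise distances via symmetric differences of root paths."""
    n = tree.n_tips
    out = np.zeros((n, n))
    paths = [set(root_path(tree, int(t))) for t in tree.tip_ids]
    for i in range(n):
        for j in range(i + 1, n):
            edges = paths[i] ^ paths[j]
            d = sum(tree.edge_lengths[e] for e in edges)
            out[i, j] = out[j, i] = d
    return out


def exhaustive_parsimony(tree: PhyloTree, tip_states: dict[str, int], n_states: int) -> int:
    """Minimum transitions by brute force over all internal assignments."""
    state = {int(t): tip_states[lab] for t, lab in zip(tree.tip_ids, tree.tip_labels)}
    internal = [v for v in range(tree.n_nodes) if len(tree.children[v]) > 0]
    best = None
    for combo in itertools.product(range(n_states), repeat=len(internal)):
        assign = dict(state)
        assign.update(zip(internal, combo))
        cost = sum(
            assign[v] != assign[int(tree.parent[v])]
            for v in range(tree.n_nodes)
            if v != tree.root
        )
        best = cost if best is None else min(best, cost)
    return int(best)


def recursive_d_sum(tree: PhyloTree, values: dict[str, float]) -> float:
    """Sister-clade difference sum by direct recursion."""
    tip_value = {int(t): float(values[lab]) for t, lab in zip(tree.tip_ids, tree.tip_labels)}

    def walk(v: int) -> tuple[float, float]:  # (node value, subtree d sum)
        ch = tree.children[v]
        if len(ch) == 0:
            return tip_value[v], 0.0
        vals, d = [], 0.0
        for c in ch:
            cv, cd = walk(int(c))
            vals.append(cv)
            d += cd
        for a in range(len(vals)):
            for b in range(a + 1, len(vals)):
                d += abs(vals[a] - vals[b])
        return float(np.mean(vals)), d

    return walk(tree.root)[1]


def mpd_oracle(members: list[str], dist: DistanceMatrix) -> float:
    idx = [dist.index(m) for m in members]
    total, pairs = 0.0, 0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            total += dist.values[idx[a], idx[b]]
            pairs += 1
    return total / pairs


def label_shuffle_null_mpds(
    dist: DistanceMatrix, members: list[str], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null MPDs by literally shuffling tip labels on the phylogeny."""
    idx = np.array([dist.index(m) for m in members])
    m = len(idx)
    out = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(dist.taxa))
        moved = perm[idx]
        out[i] = dist.values[np.ix_(moved, moved)].sum() / (m * (m - 1))
    return out


def make_panel(entries: list[tuple], plots: list[tuple]) -> CoverPanel:
    """Panel from (plot_id, year, species, cover) and (plot_id, site_id, treatment)."""
    cover = pd.DataFrame(entries, columns=["plot_id", "year", "species", "cover"])
    meta = pd.DataFrame(plots, columns=["plot_id", "site_id", "treatment"])
    return CoverPanel(cover, meta)


def paired_plots(n_sites: int = 4) -> list[tuple]:
    out = []
    for s in range(1, n_sites + 1):
        out.append((f"s{s}_ex", f"site{s}", "exclosure"))
        out.append((f"s{s}_co", f"site{s}", "control"))
    return out


def balanced_newick(depth: int) -> str:
    """Fully balanced binary tree with unit branch lengths and 2**depth tips."""
    counter = itertools.count(1)

    def build(d: int) -> str:
        if d == 0:
            return f"t{next(counter)}:1"
        return f"({build(d - 1)},{build(d - 1)}):1"

    inner = f"({build(depth - 1)},{build(depth - 1)})"
    return inner + ";"
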