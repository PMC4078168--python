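"""Rooted phylogenies: parsing, validation, patristic distances, pruning.

Every statistic in this package consumes one of the two containers defined
here.  :class:`PhyloTree` stores a rooted tree (polytomies allowed) in
postorder arrays: node ``i``'s children all have indices ``< i`` and the
root is the last node, which makes the trait-evolution and parsimony
recursions simple vectorised sweeps.  :class:`DistanceMatrix` holds the
patristic (cophenetic) distances between all pairs of tips, the substrate
for mean pairwise distance and the net relatedness index.

Branch lengths are kept exactly as parsed.  A missing branch length is
stored as NaN and only rejected by the operations that actually need
lengths (patristic distances, Brownian simulation); parsimony and the
sister-clade difference sum ignore lengths by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "DistanceMatrix",
    "NewickParseError",
    "TreeValidationError",
    "UltrametricityWarning",
    "parse_newick",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree (or a tree query) violates a structural invariant."""


class UltrametricityWarning(UserWarning):
    """Emitted when a tree with complete branch lengths is not ultrametric.

    Ultrametricity is never enforced: none of the metrics in this package
    require it, but a strongly non-ultrametric tree where one is expected
    usually indicates an un-smoothed input.
    """


def _scan_newick_syntax(text: str) -> None:
    stack: list[int] = []
    for i, ch in enumerate(text):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise NewickParseError(f"unmatched ')' at character {i}")
            stack.pop()
    if stack:
        raise NewickParseError(f"unmatched '(' at character {stack[-1]}")
    if ";" not in text:
        raise NewickParseError("missing terminating ';'")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric patristic distance matrix over an ordered set of tips."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.taxa):
            raise ValueError("distance matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in distance matrix")
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.taxa)})

    def index(self, label: str) -> int:
        try:
            return self._index[label]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"taxon not in distance matrix: {label!r}") from None

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = tuple(labels)
        idx = np.array([self.index(t) for t in labels], dtype=np.intp)
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])


class PhyloTree:
    """Rooted phylogeny with named tips, stored in postorder arrays.

    Parameters
    ----------
    children : sequence of int sequences
        Child indices per node; empty for tips.  Node order must be a
        postorder (children before parents, root last).
    edge_lengths : array-like of float
        Length of the edge above each node; NaN for the root and for
        missing lengths.
    labels : sequence of str or None
        Tip labels (``None`` for internal nodes).
    """

    def __init__(
        self,
        children: Sequence[Sequence[int]],
        edge_lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        n = len(children)
        if not (n == len(edge_lengths) == len(labels)):
            raise TreeValidationError("children/edge_lengths/labels length mismatch")
        self.children: tuple[np.ndarray, ...] = tuple(
            np.asarray(c, dtype=np.intp) for c in children
        )
        self.edge_lengths = np.asarray(edge_lengths, dtype=float)
        self.labels: tuple[str | None, ...] = tuple(labels)

        parent = np.full(n, -1, dtype=np.intp)
        for v, ch in enumerate(self.children):
            for c in ch:
                if c >= v:
                    raise TreeValidationError("node order is not a postorder")
                if parent[c] != -1:
                    raise TreeValidationError(f"node {c} has more than one parent")
                parent[c] = v
        if n and np.count_nonzero(parent == -1) != 1:
            raise TreeValidationError("tree must have exactly one root")
        self.parent = parent

        self.tip_ids = np.array(
            [v for v in range(n) if len(self.children[v]) == 0], dtype=np.intp
        )
        tip_labels = []
        for v in self.tip_ids:
            lab = self.labels[v]
            if lab is None or not str(lab).strip():
                raise TreeValidationError(f"tip node {v} has an empty label")
            tip_labels.append(str(lab).strip())
        self.tip_labels: tuple[str, ...] = tuple(tip_labels)
        if len(self.tip_labels) < 2:
            raise TreeValidationError(
                f"tree must have at least 2 tips (got {len(self.tip_labels)})"
            )
        seen: set[str] = set()
        for lab in self.tip_labels:
            if lab in seen:
                raise TreeValidationError(f"duplicate tip label: {lab!r}")
            seen.add(lab)

        finite = np.isfinite(self.edge_lengths)
        if np.any(self.edge_lengths[finite] < 0):
            raise TreeValidationError("negative branch length")

    # ------------------------------------------------------------------ #
    # basic queries

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def internal_ids(self) -> np.ndarray:
        return np.array(
            [v for v in range(self.n_nodes) if len(self.children[v]) > 0],
            dtype=np.intp,
        )

    @property
    def has_branch_lengths(self) -> bool:
        """True when every non-root edge has a finite length."""
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return bool(np.all(np.isfinite(self.edge_lengths[mask])))

    def require_branch_lengths(self, operation: str) -> None:
        if not self.has_branch_lengths:
            missing = [
                v for v in range(self.n_nodes)
                if v != self.root and not np.isfinite(self.edge_lengths[v])
            ]
            raise TreeValidationError(
                f"{operation} requires branch lengths on every edge; "
                f"missing on {len(missing)} edge(s)"
            )

    def node_depths(self) -> np.ndarray:
        """Distance of every node from the root (requires branch lengths)."""
        self.require_branch_lengths("node_depths")
        depth = np.zeros(self.n_nodes)
        for v in range(self.n_nodes - 2, -1, -1):  # parents first
            depth[v] = depth[self.parent[v]] + self.edge_lengths[v]
        return depth

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        if not self.has_branch_lengths:
            return False
        d = self.node_depths()[self.tip_ids]
        top = float(d.max())
        return bool(top == 0.0 or (top - d.min()) <= rel_tol * top)

    # ------------------------------------------------------------------ #
    # construction

    @classmethod
    def from_nested(cls, nested) -> "PhyloTree":
        """Build from nested ``(label, length, children)`` tuples.

        ``label`` is ``None`` for internal nodes, ``length`` is ``None``
        for the root or a missing length, ``children`` is a (possibly
        empty) list of nested tuples.
        """
        children_out: list[list[int]] = []
        lengths_out: list[float] = []
        labels_out: list[str | None] = []

        def emit(node) -> int:
            label, length, kids = node
            kid_ids = [emit(k) for k in kids]
            children_out.append(kid_ids)
            lengths_out.append(np.nan if length is None else float(length))
            labels_out.append(label)
            return len(children_out) - 1

        emit(nested)
        return cls(children_out, lengths_out, labels_out)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    @classmethod
    def _from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        children, lengths, labels = [], [], []
        root = nodes[-1]
        for n in nodes:
            children.append([index[id(c)] for c in n.child_nodes()])
            if n is root:
                lengths.append(np.nan)
            else:
                lengths.append(np.nan if n.edge.length is None else float(n.edge.length))
            if n.is_leaf():
                lab = n.taxon.label if n.taxon is not None else n.label
                if lab is None or not str(lab).strip():
                    raise TreeValidationError("unlabeled tip in Newick input")
                labels.append(str(lab).strip())
            else:
                labels.append(None)
        return cls(children, lengths, labels)

    # ------------------------------------------------------------------ #
    # output

    def to_newick(self, precision: int = 12) -> str:
        """Serialise to Newick; branch lengths at 12 significant digits."""

        def render(v: int) -> str:
            ch = self.children[v]
            if len(ch) == 0:
                s = str(self.labels[v])
            else:
                s = "(" + ",".join(render(int(c)) for c in ch) + ")"
            length = self.edge_lengths[v]
            if v != self.root and np.isfinite(length):
                s += f":{length:.{precision}g}"
            return s

        return render(self.root) + ";"

    # ------------------------------------------------------------------ #
    # distances and pruning

    def cophenetic_matrix(self) -> DistanceMatrix:
        """Patristic distances between all pairs of tips.

        ``d[i, j]`` is the sum of branch lengths on the path between tips
        ``i`` and ``j``; taxa are ordered as in :attr:`tip_labels`.
        """
        self.require_branch_lengths("cophenetic_matrix")
        depth = self.node_depths()
        ntips = self.n_tips
        tip_row = np.full(self.n_nodes, -1, dtype=np.intp)
        tip_row[self.tip_ids] = np.arange(ntips)
        tip_depth = depth[self.tip_ids]

        D = np.zeros((ntips, ntips))
        tipsets: list[np.ndarray | None] = [None] * self.n_nodes
        for v in range(self.n_nodes):
            ch = self.children[v]
            if len(ch) == 0:
                tipsets[v] = np.array([tip_row[v]], dtype=np.intp)
                continue
            sets = [tipsets[int(c)] for c in ch]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    ra, rb = sets[a], sets[b]
                    block = tip_depth[ra][:, None] + tip_depth[rb][None, :] - 2.0 * depth[v]
                    D[np.ix_(ra, rb)] = block
                    D[np.ix_(rb, ra)] = block.T
            tipsets[v] = np.concatenate(sets)
        return DistanceMatrix(self.tip_labels, D)

    def prune_to_taxa(self, keep: Iterable[str]) -> "PhyloTree":
        """Induced subtree on ``keep``; patristic distances are preserved.

        Internal nodes left with a single child are collapsed and their
        branch lengths summed, so the pruned cophenetic matrix equals the
        corresponding submatrix of the full one.
        """
        keep_set = {str(s).strip() for s in keep}
        missing = sorted(keep_set - set(self.tip_labels))
        if missing:
            raise TreeValidationError(
                "taxa not in tree: " + ", ".join(missing)
            )
        if len(keep_set) < 2:
            raise TreeValidationError("prune_to_taxa needs at least 2 taxa")

        class _Sub:
            __slots__ = ("label", "length", "children")

            def __init__(self, label, length, children):
                self.label = label
                self.length = length
                self.children = children

        reps: list[_Sub | None] = [None] * self.n_nodes
        for v in range(self.n_nodes):
            ch = self.children[v]
            length = self.edge_lengths[v]
            if len(ch) == 0:
                if self.labels[v] is not None and str(self.labels[v]).strip() in keep_set:
                    reps[v] = _Sub(self.labels[v], length, [])
                continue
            subs = [reps[int(c)] for c in ch if reps[int(c)] is not None]
            if not subs:
                continue
            if len(subs) == 1 and v != self.root:
                # collapse the pass-through node into its single survivor
                child = subs[0]
                child.length = child.length + length
                reps[v] = child
            else:
                reps[v] = _Sub(None, length, subs)

        root_rep = reps[self.root]
        assert root_rep is not None
        while len(root_rep.children) == 1:
            root_rep = root_rep.children[0]
        root_rep.length = np.nan  # the root pendant edge carries no information

        def to_nested(sub: "_Sub"):
            length = None if not np.isfinite(sub.length) else float(sub.length)
            return (sub.label, length, [to_nested(c) for c in sub.children])

        return PhyloTree.from_nested(to_nested(root_rep))


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick tree.

    Polytomies are accepted; branch lengths are preserved exactly as
    written.  Malformed parenthesis structure raises
    :class:`NewickParseError` naming the character offset; duplicate or
    empty tip labels raise :class:`TreeValidationError`.
    """
    _scan_newick_syntax(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except (TreeValidationError, NewickParseError):
        raise
    except Exception as exc:  # dendropy raises several error types
        msg = str(exc)
        if "Duplicate taxon labels" in msg:
            dup = msg.rsplit(":", 1)[-1].strip()
            raise TreeValidationError(f"duplicate tip label: {dup!r}") from exc
        raise NewickParseError(f"could not parse Newick: {msg}") from exc
    tree = PhyloTree._from_dendropy(dtree)
    if tree.has_branch_lengths and not tree.is_ultrametric():
        warnings.warn(
            "input tree is not ultrametric (checked at relative tolerance 1e-6)",
            UltrametricityWarning,
            stacklevel=2,
        )
    return tree
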