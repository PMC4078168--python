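"""Synthetic trees, traits, communities and transect records.

The generator emulates the statistical structure of a paired deer-exclosure
vegetation survey: an ultrametric species-pool phylogeny (pure-birth), a
binary trait evolved under a Brownian threshold model (the pollination-mode
analogue), a multistate trait with clade-level conservatism evolved under
an equal-rates Markov chain (the browse-type analogue), and paired
exclosure/control plots in which browsed (control) plots retain each
species with a probability that depends on its trait state — herbivory as
a biotic filter on presence.  Realised covers are written out as integer
centimetre line-intercept segments, the raw format the cover pipeline
consumes.

Determinism: every cell of the design draws from its own labelled stream
derived from the master seed (see :mod:`phylobrowse._seeds`), so outputs
are byte-identical for a given configuration regardless of iteration order
and remain coupled when a single parameter (e.g. one retention
probability) is varied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._seeds import spawn_rng
from .diversity import CoverPanel, TransectRecord
from .trees import PhyloTree, TreeValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_yule_tree",
    "simulate_brownian_trait",
    "brownian_tip_matrix",
    "threshold_binarize",
    "threshold_columns",
    "simulate_mk_trait",
    "assemble_communities",
    "default_retention",
    "simulate_dataset",
]

#: Browse-type state names used when writing synthetic trait tables.
BROWSE_STATE_NAMES = ("grass", "sedge", "woody", "broadleaf_forb", "fern", "lycopod")
POLLINATION_STATE_NAMES = ("abiotic", "biotic")  # codes 0 and 1


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and model parameters for the synthetic survey.

    Defaults reproduce the field design the analysis assumes: a 36-species
    site pool, 4 sites each holding one exclosure and one adjacent control
    plot, 3 transects of 500 cm per plot, and six survey years (2007 is
    absent from the data, not from the logic).
    """

    n_species: int = 36
    birth_rate: float = 1.0
    bm_sigma2: float = 1.0
    threshold_prevalence: int = 18
    mk_n_states: int = 6
    mk_rate: float = 0.15
    retention: Mapping[int, float] | None = None
    n_sites: int = 4
    transects_per_plot: int = 3
    transect_cm: int = 500
    years: tuple[int, ...] = (2006, 2008, 2009, 2010, 2011, 2012)
    base_occupancy: float = 0.6
    cover_meanlog: float = 1.2
    cover_sdlog: float = 0.8
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if not (0 < self.threshold_prevalence < self.n_species):
            raise ValueError("threshold_prevalence must be in (0, n_species)")
        if not (0.0 <= self.base_occupancy <= 1.0):
            raise ValueError("base_occupancy must be in [0, 1]")
        if self.retention is not None:
            bad = {s: p for s, p in self.retention.items() if not 0.0 <= p <= 1.0}
            if bad:
                raise ValueError(f"retention probabilities outside [0, 1]: {bad}")

    @property
    def transect_total_cm(self) -> int:
        return self.transects_per_plot * self.transect_cm


def default_retention(n_states: int) -> dict[int, float]:
    """Strong state-selective browsing: state 0 (the graminoid analogue)
    is fully retained in browsed plots, all other states mostly removed."""
    return {s: (1.0 if s == 0 else 0.15) for s in range(n_states)}


# --------------------------------------------------------------------- #
# tree simulation


def simulate_yule_tree(
    n_species: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PhyloTree:
    """Ultrametric pure-birth tree with ``n_species`` tips.

    Waiting times between successive speciations are exponential with rate
    ``k * birth_rate`` for ``k`` extant lineages; after the pool reaches
    ``n_species`` lineages the tree is extended by one further exponential
    waiting time so the youngest tips have positive pendant edges.  Tips
    are labelled ``sp0001 ...`` left to right.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    # node records: {"birth": t, "children": [ids], "split": t or None}
    nodes = [
        {"birth": 0.0, "children": [1, 2], "split": 0.0},
        {"birth": 0.0, "children": [], "split": None},
        {"birth": 0.0, "children": [], "split": None},
    ]
    active = [1, 2]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        v = active[i]
        left = {"birth": t, "children": [], "split": None}
        right = {"birth": t, "children": [], "split": None}
        nodes.append(left)
        nodes.append(right)
        lid, rid = len(nodes) - 2, len(nodes) - 1
        nodes[v]["children"] = [lid, rid]
        nodes[v]["split"] = t
        active[i] = lid
        active.append(rid)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))

    width = max(4, len(str(n_species)))
    counter = [0]

    def nested(v: int, is_root: bool):
        nd = nodes[v]
        if nd["children"]:
            kids = [nested(c, False) for c in nd["children"]]
            length = None if is_root else nd["split"] - nd["birth"]
            return (None, length, kids)
        counter[0] += 1
        return (f"sp{counter[0]:0{width}d}", t_end - nd["birth"], [])

    return PhyloTree.from_nested(nested(0, True))


def _to_nested(tree: PhyloTree, v: int, prefix: str, drop_length: bool):
    label = tree.labels[v]
    if label is not None:
        label = prefix + str(label)
    length = tree.edge_lengths[v]
    length = None if (drop_length or not np.isfinite(length)) else float(length)
    kids = [_to_nested(tree, int(c), prefix, False) for c in tree.children[v]]
    return (label if not kids else None, length, kids)


def simulate_two_clade_tree(
    n_per_clade: int,
    birth_rate: float = 1.0,
    stem_length: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PhyloTree, dict[str, int]]:
    """Deep two-clade species pool and its clade-membership trait.

    Two independent pure-birth subtrees are joined at the root by stems of
    at least ``stem_length`` (stretched so the whole tree is ultrametric).
    Returns the tree and a 0/1 trait marking which clade each tip belongs
    to — the canonical substrate for clade-selective filtering scenarios.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    subs = [
        simulate_yule_tree(n_per_clade, birth_rate, rng=rng) for _ in range(2)
    ]
    heights = [float(s.node_depths()[s.tip_ids].max()) for s in subs]
    top = max(heights)
    nested_kids = []
    for i, (sub, h) in enumerate(zip(subs, heights)):
        label, _, kids = _to_nested(sub, sub.root, "AB"[i] + "_", True)
        nested_kids.append((label, stem_length + (top - h), kids))
    tree = PhyloTree.from_nested((None, None, nested_kids))
    trait = {lab: (0 if lab.startswith("A_") else 1) for lab in tree.tip_labels}
    return tree, trait


# --------------------------------------------------------------------- #
# trait simulation


def brownian_tip_matrix(
    tree: PhyloTree, sigma2: float, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """``(n_tips, n_draws)`` independent Brownian realisations on the tree.

    Root value 0; each child's value adds a Normal(0, sigma2 * branch
    length) increment.  Rows follow ``tree.tip_labels``.
    """
    tree.require_branch_lengths("Brownian simulation")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    n = tree.n_nodes
    vals = np.zeros((n, n_draws))
    for v in range(n - 2, -1, -1):  # parents (higher index) first
        scale = np.sqrt(sigma2 * tree.edge_lengths[v])
        vals[v] = vals[tree.parent[v]] + rng.standard_normal(n_draws) * scale
    return vals[tree.tip_ids]


def simulate_brownian_trait(
    tree: PhyloTree,
    sigma2: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """One Brownian-motion realisation, as a species -> value mapping."""
    if rng is None:
        rng = np.random.default_rng(seed)
    col = brownian_tip_matrix(tree, sigma2, 1, rng)[:, 0]
    return dict(zip(tree.tip_labels, col.tolist()))


def threshold_columns(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-column top-``k`` indicator of ``x`` (ties broken by seeded jitter)."""
    if not (0 < k < x.shape[0]):
        raise ValueError(f"prevalence k must be in (0, {x.shape[0]}), got {k}")
    span = float(np.ptp(x)) if x.size else 0.0
    jitter = rng.random(x.shape) * 1e-9 * (span + 1.0)
    top = np.argpartition(-(x + jitter), k - 1, axis=0)[:k]
    out = np.zeros(x.shape, dtype=np.int8)
    np.put_along_axis(out, top, 1, axis=0)
    return out


def threshold_binarize(
    values: Mapping[str, float],
    prevalence: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Binary trait from a continuous one: the ``prevalence`` largest
    values become state 1, the rest state 0 (the threshold model)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = list(values.keys())
    x = np.array([values[s] for s in labels], dtype=float)[:, None]
    b = threshold_columns(x, prevalence, rng)[:, 0]
    return {s: int(v) for s, v in zip(labels, b)}


def simulate_mk_trait(
    tree: PhyloTree,
    n_states: int,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Multistate trait under the equal-rates Markov (Mk) model.

    The root state is uniform; along each branch of length ``t`` change
    events arrive as a Poisson process with rate ``rate`` and each event
    jumps to a uniformly chosen different state.  Low rates on deep trees
    give clade-conserved characters (the browse-type situation).
    """
    tree.require_branch_lengths("Mk simulation")
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = tree.n_nodes
    states = np.zeros(n, dtype=np.int64)
    states[tree.root] = rng.integers(n_states)
    for v in range(n - 2, -1, -1):
        s = states[tree.parent[v]]
        n_events = rng.poisson(rate * tree.edge_lengths[v])
        for _ in range(int(n_events)):
            jump = int(rng.integers(n_states - 1))
            s = jump if jump < s else jump + 1
        states[v] = s
    return {lab: int(states[tip]) for lab, tip in zip(tree.tip_labels, tree.tip_ids)}


# --------------------------------------------------------------------- #
# community assembly


def _split_segments(
    target_cm: int,
    n_transects: int,
    transect_cm: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Split a per-plot intercept total into (transect_id, cm) pieces.

    The total is cut into 1-3 random integer pieces placed on random
    transects; a transect never receives more than ``transect_cm`` of one
    species (excess spills onto the next transect with room).
    """
    max_pieces = min(3, target_cm)
    n_pieces = int(rng.integers(1, max_pieces + 1))
    if n_pieces > 1:
        cuts = np.sort(rng.choice(target_cm - 1, size=n_pieces - 1, replace=False)) + 1
        lengths = np.diff(np.concatenate(([0], cuts, [target_cm]))).tolist()
    else:
        lengths = [target_cm]
    used = dict.fromkeys(range(1, n_transects + 1), 0)
    placed: list[tuple[int, int]] = []
    for piece in lengths:
        tid = int(rng.integers(1, n_transects + 1))
        remaining = int(piece)
        for offset in range(n_transects):
            t = (tid - 1 + offset) % n_transects + 1
            room = transect_cm - used[t]
            if room <= 0:
                continue
            take = min(room, remaining)
            used[t] += take
            placed.append((t, take))
            remaining -= take
            if remaining == 0:
                break
        if remaining > 0:  # cannot happen while target <= total tape length
            raise ValueError("intercept target exceeds total tape length")
    return placed


def assemble_communities(
    tree: PhyloTree,
    susceptibility_trait: Mapping[str, int],
    retention: Mapping[int, float],
    config: SimulationConfig,
    seed: int | None = None,
    return_targets: bool = False,
):
    """Paired exclosure/control panel under state-selective browsing.

    In every year and site, each pool species occurs in the exclosure plot
    with probability ``base_occupancy``; in the paired control (browsed)
    plot the probability is additionally multiplied by
    ``retention[state]``.  Present species receive a log-normal percent
    cover (capped at 100) realised as integer-centimetre intercept
    segments whose sums reproduce the cover value to 1 cm.

    Returns ``(panel, records)``; with ``return_targets=True`` also a dict
    ``(plot_id, year, species) -> intended percent cover``.
    """
    master = config.master_seed if seed is None else seed
    species = tree.tip_labels
    missing = [s for s in species if s not in susceptibility_trait]
    if missing:
        raise TreeValidationError(f"trait missing for species: {', '.join(missing)}")
    states = {s: susceptibility_trait[s] for s in species}
    absent = sorted(set(states.values()) - set(retention.keys()))
    if absent:
        raise ValueError(f"retention undefined for states: {absent}")

    records: list[TransectRecord] = []
    targets: dict[tuple[str, int, str], float] = {}
    for year in config.years:
        for site in range(1, config.n_sites + 1):
            site_id = f"site{site}"
            for treatment in ("exclosure", "control"):
                plot_id = f"{site_id}_{'ex' if treatment == 'exclosure' else 'co'}"
                for sp in species:
                    r = spawn_rng(master, "plot", year, site, treatment, sp)
                    u = r.random()
                    raw = float(np.exp(r.normal(config.cover_meanlog, config.cover_sdlog)))
                    p = config.base_occupancy
                    if treatment == "control":
                        p *= retention[states[sp]]
                    if u >= p:
                        continue
                    cover_pct = min(raw, 100.0)
                    target_cm = max(1, round(cover_pct * config.transect_total_cm / 100.0))
                    targets[(plot_id, year, sp)] = 100.0 * target_cm / config.transect_total_cm
                    for tid, cm in _split_segments(
                        target_cm, config.transects_per_plot, config.transect_cm, r
                    ):
                        records.append(
                            TransectRecord(
                                plot_id=plot_id,
                                site_id=site_id,
                                treatment=treatment,
                                year=year,
                                transect_id=tid,
                                species=sp,
                                intercept_cm=cm,
                            )
                        )
    panel = CoverPanel.from_transect_records(
        records, config.transect_total_cm, config.transect_cm
    )
    if return_targets:
        return panel, records, targets
    return panel, records


# --------------------------------------------------------------------- #
# whole datasets


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete synthetic survey: tree, traits, panel and raw records."""

    config: SimulationConfig
    tree: PhyloTree
    liability: dict[str, float]          # Brownian values behind the binary trait
    pollination: dict[str, int]          # 0 = abiotic, 1 = biotic
    browse_state: dict[str, int]         # Mk states, 0 = browse-tolerant analogue
    retention: dict[int, float]
    panel: CoverPanel
    records: list[TransectRecord]

    def trait_tables(self) -> dict[str, dict[str, str]]:
        """Named trait tables in the CSV dialect of the pipeline."""
        return {
            "pollination_mode": {
                s: POLLINATION_STATE_NAMES[v] for s, v in self.pollination.items()
            },
            "browse_type": {
                s: BROWSE_STATE_NAMES[v % len(BROWSE_STATE_NAMES)]
                for s, v in self.browse_state.items()
            },
        }


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate every input of the analysis chain from one configuration."""
    seed = config.master_seed
    tree = simulate_yule_tree(
        config.n_species, config.birth_rate, rng=spawn_rng(seed, "tree")
    )
    liability = simulate_brownian_trait(
        tree, config.bm_sigma2, rng=spawn_rng(seed, "bm")
    )
    pollination = threshold_binarize(
        liability, config.threshold_prevalence, rng=spawn_rng(seed, "threshold")
    )
    browse = simulate_mk_trait(
        tree, config.mk_n_states, config.mk_rate, rng=spawn_rng(seed, "mk")
    )
    retention = dict(
        config.retention
        if config.retention is not None
        else default_retention(config.mk_n_states)
    )
    panel, records = assemble_communities(tree, browse, retention, config, seed=seed)
    return SyntheticDataset(
        config=config,
        tree=tree,
        liability=liability,
        pollination=pollination,
        browse_state=browse,
        retention=retention,
        panel=panel,
        records=records,
    )
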