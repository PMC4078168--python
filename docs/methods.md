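# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `phylobrowse`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Study design assumed

The package targets paired-exclosure line-intercept surveys: each site
holds one fenced plot (treatment `exclosure`) and one adjacent unfenced
plot (`control`), each sampled by three permanent 500 cm transects, in
several years. Percent cover of species *i* in a plot is
100·Σnᵢ/1500, the intercepted centimetres summed over occurrences and
transects; pooling a treatment's four plots divides the summed
centimetres by 6000, which is identical to averaging the four per-plot
covers (the implementation averages). Because different species can
overhang the same tape segment, a plot's summed cover may exceed 100 %;
a *single* species' cover cannot, and the validator enforces both this
and the per-transect tape length. Year coverage is data, not logic: the
pipeline iterates over whatever years the input holds.

## Diversity metrics

Species richness is the count of species with positive cover. The
Shannon–Wiener index uses natural logarithms (H′ in nats), computed via
`scipy.stats.entropy` on cover-proportional abundances with zero-cover
species excluded; H′ is undefined (an error, not 0) for an empty
community. The logarithm base is a convention choice; tests pin the
closed forms H′(1 species) = 0 and H′(S equal species) = ln S.

## Patristic distances and the tree container

Trees are parsed from Newick by dendropy, validated (unique non-empty tip
labels, ≥ 2 tips, non-negative branch lengths, single root), and
flattened to postorder arrays so that every traversal in the package is a
simple index sweep. Missing branch lengths are stored as NaN and rejected
only by operations that need lengths (patristic distances, Brownian
simulation); parsimony and the sister-clade difference sum ignore lengths
by construction. Ultrametricity is checked at relative tolerance 1e-6 and
reported as a warning, never enforced — none of the metrics require it.
Polytomies are accepted everywhere and never resolved; the statistics are
defined on the tree as given. Tip-label joins between tree, cover and
trait tables are exact and case-sensitive after trimming surrounding
whitespace. Pruning builds the induced subtree, collapsing pass-through
nodes and summing their branch lengths, so pruned patristic distances
equal the corresponding submatrix of the full cophenetic matrix
(oracle-tested). Newick output renders branch lengths at 12 significant
digits, which round-trips the double-precision values the parser stores.

## MPD and the net relatedness index

MPD is the unweighted mean patristic distance over all unordered pairs of
a community's species — presence-based, because the index is meant to
measure relatedness of the surviving species *set*; abundance weighting
is deliberately not offered. The NRI null shuffles all tip labels on the
phylogeny; for MPD this is equivalent to drawing the same number of
species uniformly from the pool, and the implementation uses the draw
form for speed (the test suite checks the equivalence against a literal
label shuffle). The species pool is the full tip set of the supplied
tree, mirroring a site-specific phylogeny. With the null mean and
standard deviation (ddof = 1) over `n_perm` draws (default 999),

    NRI = -(MPD_obs - mean_null) / sd_null,

so communities of close relatives score positive. The primary p-value is
one-tailed for clustering, p = (#{null ≤ obs} + 1)/(n_perm + 1); a
two-tailed companion doubles the smaller tail. The add-one estimator
avoids zero p-values. A null with (numerically) zero spread — e.g. the
community is the whole pool — sets a `degenerate` flag and reports NRI as
NaN with the rank-based p only. In treatment × year tables, each cell's
seed derives from the master seed plus the sorted member set, so two
cells holding identical communities report identical results while
distinct communities get independent streams.

## Phylogenetic signal

**Fritz & Purvis' D (binary traits).** Nodal values are estimated
tip-to-root as the unweighted mean of daughter values, branch lengths
ignored; the observed statistic d_obs sums, over internal nodes, all
pairwise absolute differences between daughter values (the pairwise sum
generalises the two-daughter case at polytomies). Two nulls, each with
`n_perm` (default 1000) draws, bracket it:

* *random*: the observed 0/1 states shuffled across tips (prevalence
  preserved);
* *Brownian threshold*: Brownian motion with σ² = 1 simulated along the
  branch lengths, each realisation thresholded so its top-ranked tips
  carry state 1.

D = (d_obs − mean_brownian)/(mean_random − mean_brownian), so D ≈ 1 for
phylogenetically random traits, D ≈ 0 for Brownian-threshold traits, and
D < 0 for strong conservatism; p-values against each null are two-tailed
add-one permutation ranks. The Brownian null thresholds at the
*minority*-state count min(k, n−k): the d sum is invariant under
complementing the trait and Brownian motion is sign-symmetric, so this is
distributionally identical to prevalence matching while making the whole
result bit-identical under 0/1 recoding. Threshold ties (measure-zero for
Brownian values, but possible in user input) are broken by seeded uniform
jitter. The estimator's acceptance surface is its calibration, not
numeric agreement with any other implementation: over 200 fifty-tip
pure-birth trees the mean D must lie within ±0.1 of 0 (threshold-Brownian
generation) and of 1 (random generation); both are recomputed by
`scripts/acceptance.py`.

**Parsimony permutation test (multistate traits).** The observed
statistic is the minimum number of state transitions on the tree, by the
Fitch dynamic program with Hartigan's generalisation at polytomies (cost
at a node with c children is c − K, where K is the largest number of
children whose preferred state sets share a state); this is the true
minimum on multifurcating trees and is verified against exhaustive
enumeration on small instances. The null permutes the observed states
across all tips (multiset preserved), and
p = (#{null ≤ observed} + 1)/(n_perm + 1); the null summary reports the
mean and 2.5 %/97.5 % quantiles. A constant character is degenerate:
observed and all null scores are 0, hence p = 1. Because the statistic is
integer-valued with heavy ties, permutation p-values are *conservative*
at any fixed level: on 30-tip trees with 6 states the realised
rejection rate of neutral characters at nominal 0.05 is ≈ 0.02–0.035.
The test suite therefore asserts validity (rejection ≤ 0.07) and
non-degeneracy rather than exact uniformity, while the continuous-MPD
NRI test is held to the full 0.05 ± 0.02 band.

## DBSI

DBSI(species, year) = ΣC_e/(ΣC_e + ΣC_c), with the sums over all
exclosure and all control plots of that year. It is invariant to
rescaling a year's covers, maps to 1 − DBSI when treatment labels are
swapped, and hits 1 (or 0) exactly when the control (or exclosure) sum is
zero. A species-year absent from both treatments is 0/0 and is *undefined*
— excluded from the across-year mean rather than coerced. The reported
value per species is the unweighted mean over defined years, sorted
ascending (least to most susceptible). The rarity filter defaults to
"positive cover in ≥ 2 distinct plots, either treatment, in ≥ 2 years";
because published descriptions of such filters vary between
plots-of-either-treatment and exclosures-only readings, both thresholds
and the treatment restriction are configurable and the filter only flags,
never silently drops, species in the output table.

## Synthetic data generator

The generator emulates the survey's statistical structure, not its
botany:

* **Species pool**: a pure-birth (Yule) tree, default 36 tips at rate 1,
  extended by a final exponential wait so the youngest tips have positive
  pendant edges; ultrametric by construction. Mean tree height is
  oracle-tested against the analytic pure-birth expectation.
* **Binary trait**: Brownian motion (σ² = 1) thresholded at a fixed
  prevalence (default 18/36) — the generating model under which D is
  calibrated to 0.
* **Multistate trait**: equal-rates Mk with default 6 states at rate 0.15
  per unit branch length — low enough for clade-level conservatism, the
  situation the parsimony test targets. State 0 plays the browse-tolerant
  (graminoid-like) role.
* **Communities**: in every year and site, each pool species enters the
  exclosure plot with probability `base_occupancy` (default 0.6); the
  paired control plot multiplies that by a per-state retention
  probability (default 1.0 for state 0, 0.15 otherwise — strong,
  state-selective browsing). Browsing is modelled as presence thinning
  because every downstream statistic (richness, NRI, DBSI) operates on
  presence or summed cover. Present species draw a log-normal percent
  cover (meanlog 1.2, sdlog 0.8, capped at 100; the analysis only depends
  on presence structure, so the abundance law is a convenience choice)
  realised as 1–3 integer-centimetre segments on random transects, never
  exceeding 500 cm per transect, so records re-aggregate to the intended
  cover within one centimetre of tape (100/1500 ≈ 0.067 % cover).
* **Determinism**: every stochastic cell draws from a labelled stream
  derived from the master seed (SeedSequence over CRC-32-hashed labels),
  so outputs are byte-identical regardless of iteration order, and
  realisations stay coupled when one retention value is varied — which
  is also what makes the filter-monotonicity property testable pathwise.
* **Two-clade scenario**: `simulate_two_clade_tree` joins two pure-birth
  subtrees with long stems (ultrametric) and returns the clade-membership
  trait; with retention 1 for one clade and ≈ 0 for the other it
  reproduces the qualitative browsing signature (browsed pooled
  communities clustered with positive NRI, unbrowsed neutral, browsed
  MPD depressed), and the recovery rate of that signature over 100
  seeded replicates is an acceptance check (≥ 90 %). For such scenarios
  `base_occupancy` ≈ 0.3 keeps the pooled exclosure community a proper
  subset of the pool; near-saturated pools degenerate the NRI null.

What the generator does **not** emulate: real abundance dynamics and
between-year autocorrelation (years are independent draws), spatial
structure within transects, cover *reduction* without extirpation,
observation error in species identification, and the deep, unbalanced
shape of a real vascular-plant phylogeny — a Yule pool understates the
MPD contrast a real graminoid-dominated browsed community shows. Passing
tests therefore demonstrate correctness and calibration of the
statistics, not field effect sizes.

## Pipeline

`run_pipeline` validates the configuration before any computation (fail
fast: missing trait tables with signal tests requested, unknown test
kinds, neither-or-both input blocks), assembles the panel from transect
records, a cover table or the synthetic generator, and runs the stages in
order: per-plot diversity (richness, H′, MPD), per-treatment-year NRI,
trait signal tests (tips without trait states are pruned with a logged
warning), rarity filter and DBSI. Species present in cover but absent
from the tree are an error by default (`missing_species: drop` logs and
drops instead). Treatment comparison is descriptive — means over
plot-years and percent differences 100·(ex − co)/ex — leaving model-based
inference (e.g. mixed models with site effects) to external tools via the
tidy CSVs. Reports are byte-identical under a fixed configuration; all
derived seeds, permutation counts and a configuration hash are recorded
in the metadata.

## Problem sizes in the test and acceptance suites

Calibration and oracle runs use 50-tip trees × 200 replicates × 1000
permutations (D), 24-tip pools × 1000 replicates × 999 permutations (NRI
type-I), 500 instances of ≤ 7 tips × ≤ 3 states (exhaustive parsimony),
and 100 replicates of the 20-species two-clade recovery scenario — sizes
at which the targeted properties are statistically resolvable while the
whole suite completes in well under a minute of the calibration-heavy
paths; Monte-Carlo oracles with fixed seeds use 2–3 standard-error
tolerances.
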