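# phylobrowse

Phylogenetic community analysis of selective herbivory for paired
deer-exclosure vegetation surveys.

Chronic browsing by overabundant white-tailed deer does more than thin the
forest understorey: because browse tolerance and attractiveness to deer
(growth form, pollination mode) are phylogenetically heritable, browsing
acts as a *biotic filter* that strips whole branches from the community's
evolutionary tree. Detecting that filter requires comparing fenced
(exclosure) and adjacent browsed (control) plots not just in how many
species they hold, but in how *related* the survivors are. `phylobrowse`
implements the full analysis chain for such surveys, plus a synthetic-data
generator so every stage can be exercised and calibrated without field
data.

## What it computes

Given a rooted phylogeny of the site's species pool (Newick), line-intercept
transect records (or a percent-cover table) for paired exclosure/control
plots over several years, and a trait table:

1. **Cover and species diversity** — percent cover per species and plot,
   cover<sub>i</sub> = 100·Σnᵢ/1500 for three 500 cm transects; species
   richness *SR*; Shannon–Wiener *H′* = −Σ pᵢ ln pᵢ with cover as
   abundance.
2. **Phylogenetic diversity and community structure** — mean pairwise
   patristic distance MPD over each community, and the net relatedness
   index against a 999-permutation tip-shuffle null,
   NRI = −(MPD_obs − mean MPD_null)/sd MPD_null, with permutation p-values
   (r+1)/(n+1). Positive NRI = phylogenetic clustering, the signature of a
   shared heritable filter.
3. **Phylogenetic signal of browse-vulnerability traits** — Fritz & Purvis'
   *D* for binary traits (scaled so E[*D*] = 1 under random tip assignment
   and E[*D*] = 0 under a Brownian threshold model; *D* < 0 = strong
   conservatism), and a Fitch/Hartigan parsimony-score permutation test for
   multistate traits (p = fraction of 1000 tip-state permutations needing
   no more steps than the observed character).
4. **Deer-browsing susceptibility index** — per species and year,
   DBSI = ΣC_e/(ΣC_e + ΣC_c) over exclosure (C_e) and control (C_c)
   covers: 1 = found only inside exclosures (browse-dependent), 0 = only
   outside; reported as the mean over defined years after a configurable
   rarity filter.

The synthetic module generates all inputs with the structure the analysis
assumes: ultrametric pure-birth species pools, Brownian-threshold binary
traits, clade-conserved Mk multistate traits, and paired communities in
which browsed plots retain species with state-dependent probabilities,
realised down to integer-centimetre transect segments.

## Worked example

A 36-species pool split into a browse-tolerant clade (A) and a
browse-susceptible clade (B); browsed plots retain clade-B species with
probability 0.2:

```python
from phylobrowse import (SimulationConfig, assemble_communities, d_statistic,
                         mean_dbsi, nri_by_treatment_year)
from phylobrowse.simulate import simulate_two_clade_tree

tree, clade = simulate_two_clade_tree(18, seed=7)
config = SimulationConfig(n_species=36, years=(2006, 2008, 2009),
                          base_occupancy=0.35, master_seed=7)
panel, _ = assemble_communities(tree, clade, {0: 1.0, 1: 0.2}, config)

table = nri_by_treatment_year(panel, tree, n_perm=999, seed=7)
print(table[["treatment", "year", "n_species", "mpd_obs", "nri",
             "p_clustering"]].round(3).to_string(index=False))
```

```
treatment  year  n_species  mpd_obs    nri  p_clustering
exclosure  2006         24    6.747 -1.271         0.923
exclosure  2008         30    6.663 -0.771         0.755
exclosure  2009         33    6.594  0.823         0.206
  control  2006         19    5.362  8.082         0.001
  control  2008         20    6.080  3.766         0.004
  control  2009         23    6.220  3.495         0.006
```

Browsed (control) communities are strongly clustered in every year —
large positive NRI, p ≤ 0.006 — while exclosure communities are
indistinguishable from random draws of the pool: the filter signature.
The trait driving the filter is itself phylogenetically conserved,

```python
signal = d_statistic(tree, clade, n_perm=1000, seed=7)
print(f"D = {signal.D:.3f}  (p vs random null = {signal.p_random:.3f})")
```

```
D = -0.787  (p vs random null = 0.002)
```

and the susceptibility index ranks species from browse-tolerant to
exclosure-dependent (`mean_dbsi(panel)`): the least susceptible species
score ≈ 0.3 while every heavily filtered clade-B species scores 1.0.

The same chain runs from the shell: `phylobrowse simulate` writes a
synthetic dataset (tree.nwk, transects.csv, cover.csv, traits.csv),
`phylobrowse run --config config.yaml --out-dir out` executes the full
pipeline (diversity, NRI, signal tests, DBSI → CSVs + report.json), and
`phylobrowse nri|signal|dbsi` run single stages on prepared files.

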