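"""Synthetic trees, traits and community assembly."""

import numpy as np
import pytest

from phylobrowse import (
    SimulationConfig,
    assemble_communities,
    compute_cover,
    simulate_brownian_trait,
    simulate_dataset,
    simulate_mk_trait,
    simulate_yule_tree,
    threshold_binarize,
)
from phylobrowse.simulate import (
    brownian_tip_matrix,
    default_retention,
    simulate_two_clade_tree,
)
from phylobrowse._seeds import spawn_rng
from phylobrowse import fitch_parsimony_score, parsimony_signal_test, species_richness


class TestYuleTree:
    def test_two_species_is_an_ultrametric_cherry(self):
        tree = simulate_yule_tree(2, 1.0, seed=0)
        assert tree.n_tips == 2
        assert len(tree.children[tree.root]) == 2
        assert tree.is_ultrametric()

    def test_fifty_species_ultrametric_by_construction(self):
        tree = simulate_yule_tree(50, 1.0, seed=3)
        depths = tree.node_depths()[tree.tip_ids]
        assert np.allclose(depths, depths[0], rtol=1e-9)
        assert tree.tip_labels[0] == "sp0001"

    def test_deterministic_per_seed(self):
        a = simulate_yule_tree(20, 1.0, seed=5).to_newick()
        b = simulate_yule_tree(20, 1.0, seed=5).to_newick()
        assert a == b

    def test_mean_height_matches_pure_birth_expectation(self):
        # time to go from 2 to n lineages is a sum of Exp(k*b) waits, plus
        # one final Exp(n*b) extension: E[H] = (sum_{k=2}^{n-1} 1/k + 1/n)/b
        n, b, reps = 20, 2.0, 3000
        expected = (sum(1.0 / k for k in range(2, n)) + 1.0 / n) / b
        rng = np.random.default_rng(17)
        heights = []
        for _ in range(reps):
            tree = simulate_yule_tree(n, b, rng=rng)
            heights.append(tree.node_depths()[tree.tip_ids].max())
        heights = np.array(heights)
        se = heights.std(ddof=1) / np.sqrt(reps)
        assert abs(heights.mean() - expected) < 3 * se


class TestBrownianTrait:
    def test_zero_variance_is_identically_zero(self, basic_tree):
        values = simulate_brownian_trait(basic_tree, 0.0, seed=0)
        assert all(v == 0.0 for v in values.values())

    def test_cherry_difference_variance(self):
        # tips A and B at depth 1 from their ancestor: Var(A - B) = 2*sigma2*t
        from phylobrowse import parse_newick

        tree = parse_newick("((A:1,B:1):1,C:2);")
        x = brownian_tip_matrix(tree, 1.7, 10_000, np.random.default_rng(4))
        ia, ib = tree.tip_labels.index("A"), tree.tip_labels.index("B")
        var = np.var(x[ia] - x[ib], ddof=1)
        assert var == pytest.approx(2 * 1.7 * 1.0, rel=0.05)

    def test_tip_covariance_equals_shared_path_length(self):
        from phylobrowse import parse_newick

        tree = parse_newick("((A:1,B:1):1,C:2);")
        x = brownian_tip_matrix(tree, 1.0, 10_000, np.random.default_rng(5))
        ia, ib = tree.tip_labels.index("A"), tree.tip_labels.index("B")
        cov = np.cov(x[ia], x[ib], ddof=1)[0, 1]
        assert cov == pytest.approx(1.0, abs=0.07)  # shared stem length 1
        ic = tree.tip_labels.index("C")
        assert np.cov(x[ia], x[ic], ddof=1)[0, 1] == pytest.approx(0.0, abs=0.07)

    def test_missing_branch_lengths_rejected(self):
        from phylobrowse import parse_newick
        from phylobrowse.trees import TreeValidationError

        tree = parse_newick("((A,B),C);")
        with pytest.raises(TreeValidationError, match="branch lengths"):
            simulate_brownian_trait(tree, 1.0, seed=0)


class TestThresholdBinarize:
    def test_prevalence_is_exact(self, yule50):
        values = simulate_brownian_trait(yule50, 1.0, seed=1)
        for k in (1, 10, 49):
            trait = threshold_binarize(values, k, seed=0)
            assert sum(trait.values()) == k

    def test_degenerate_prevalence_rejected(self, yule50):
        values = simulate_brownian_trait(yule50, 1.0, seed=1)
        with pytest.raises(ValueError, match="prevalence"):
            threshold_binarize(values, 50, seed=0)

    def test_all_tied_values_still_hit_prevalence(self):
        values = {f"sp{i}": 0.0 for i in range(10)}
        trait = threshold_binarize(values, 4, seed=2)
        assert sum(trait.values()) == 4


class TestMkTrait:
    def test_zero_rate_is_constant_with_zero_steps(self, yule50):
        trait = simulate_mk_trait(yule50, 4, 0.0, seed=0)
        assert len(set(trait.values())) == 1
        assert fitch_parsimony_score(yule50, trait) == 0

    def test_high_rate_limit_states_near_uniform(self):
        counts = np.zeros(3)
        for i in range(60):
            tree = simulate_yule_tree(20, 1.0, rng=spawn_rng(8, "t", i))
            trait = simulate_mk_trait(tree, 3, 50.0, rng=spawn_rng(8, "mk", i))
            for s in trait.values():
                counts[s] += 1
        freqs = counts / counts.sum()
        assert np.all(np.abs(freqs - 1 / 3) < 0.05)

    def test_low_rate_on_deep_split_tree_is_detected_as_signal(self):
        # conditioned on the character being parsimony-informative (every
        # observed state on >= 2 tips): constant or singleton-variant draws
        # carry nothing a permutation test could detect
        hits = informative = 0
        for i in range(100):
            tree, _ = simulate_two_clade_tree(
                8, birth_rate=10.0, stem_length=20.0, rng=spawn_rng(9, "t", i)
            )
            trait = simulate_mk_trait(tree, 3, 0.08, rng=spawn_rng(9, "mk", i))
            vals = list(trait.values())
            counts = {s: vals.count(s) for s in set(vals)}
            if len(counts) == 1 or min(counts.values()) < 2:
                continue
            informative += 1
            r = parsimony_signal_test(tree, trait, n_perm=499, seed=i)
            hits += r.p_value <= 0.05
        assert informative >= 30
        assert hits >= 0.9 * informative


class TestAssembleCommunities:
    def small_config(self, **kw):
        defaults = dict(
            n_species=12, years=(2006, 2008), master_seed=0, mk_n_states=3,
            threshold_prevalence=6,
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_round_trip_records_reproduce_cover_to_one_centimetre(self):
        cfg = self.small_config()
        tree = simulate_yule_tree(cfg.n_species, seed=1)
        trait = simulate_mk_trait(tree, 3, 0.2, seed=2)
        panel, records, targets = assemble_communities(
            tree, trait, {0: 1.0, 1: 0.5, 2: 0.1}, cfg, seed=4, return_targets=True
        )
        bound = 100.0 / cfg.transect_total_cm
        for (plot, year, sp), want in targets.items():
            got = float(panel.plot_cover(plot, year).get(sp, 0.0))
            assert abs(got - want) <= bound
        # and aggregating the raw records again gives the panel exactly
        by_plot = {}
        for r in records:
            by_plot.setdefault((r.plot_id, r.year), []).append(r)
        for (plot, year), recs in by_plot.items():
            cover = compute_cover(recs, cfg.transect_total_cm, cfg.transect_cm)
            stored = panel.plot_cover(plot, year).to_dict()
            assert cover == pytest.approx(stored)

    def test_byte_identical_reruns(self):
        cfg = self.small_config()
        tree = simulate_yule_tree(cfg.n_species, seed=1)
        trait = simulate_mk_trait(tree, 3, 0.2, seed=2)
        ret = {0: 1.0, 1: 0.5, 2: 0.1}
        p1, r1 = assemble_communities(tree, trait, ret, cfg, seed=4)
        p2, r2 = assemble_communities(tree, trait, ret, cfg, seed=4)
        assert r1 == r2
        assert p1.cover.equals(p2.cover)

    def test_neutral_retention_makes_treatments_exchangeable(self):
        # with retention == 1 everywhere the richness difference between
        # paired treatments is centred on zero
        diffs = []
        for i in range(200):
            cfg = self.small_config(
                n_species=8, years=(2006,), master_seed=i, threshold_prevalence=4
            )
            tree = simulate_yule_tree(cfg.n_species, rng=spawn_rng(5, "t", i))
            trait = simulate_mk_trait(tree, 3, 0.2, rng=spawn_rng(5, "mk", i))
            panel, _ = assemble_communities(
                tree, trait, {0: 1.0, 1: 1.0, 2: 1.0}, cfg, seed=i
            )
            rich = {
                t: species_richness(panel.pooled_cover(t, 2006))
                for t in ("exclosure", "control")
            }
            diffs.append(rich["exclosure"] - rich["control"])
        diffs = np.array(diffs, dtype=float)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2.5 * se + 1e-9

    def test_filter_monotonicity_along_retention_grid(self):
        # same seed couples realisations, so lowering one state's retention
        # can only remove that state's cover in browsed plots
        cfg = self.small_config()
        tree = simulate_yule_tree(cfg.n_species, seed=1)
        trait = simulate_mk_trait(tree, 3, 0.2, seed=2)
        state1 = [sp for sp, s in trait.items() if s == 1]
        prev = None
        for r1 in (1.0, 0.7, 0.4, 0.1, 0.0):
            panel, _ = assemble_communities(
                tree, trait, {0: 1.0, 1: r1, 2: 0.5}, cfg, seed=4
            )
            pooled = panel.pooled_cover("control", 2006)
            total = float(pooled.reindex(state1, fill_value=0.0).sum())
            if prev is not None:
                assert total <= prev + 1e-12
            prev = total

    def test_clade_filter_produces_browsed_clustering_pattern(self):
        from phylobrowse import mpd, nri

        tree, trait = simulate_two_clade_tree(10, seed=6)
        cfg = SimulationConfig(n_species=20, years=(2006,), master_seed=6, mk_n_states=2)
        panel, _ = assemble_communities(tree, trait, {0: 1.0, 1: 0.0}, cfg, seed=6)
        dist = tree.cophenetic_matrix()
        browsed = panel.species_present("control", 2006)
        unbrowsed = panel.species_present("exclosure", 2006)
        assert set(browsed) <= {sp for sp, s in trait.items() if s == 0}
        assert mpd(browsed, dist) < mpd(unbrowsed, dist)
        r = nri(browsed, dist, n_perm=999, seed=1)
        assert r.nri > 0 and r.p_clustering <= 0.05


class TestSimulateDataset:
    def test_full_dataset_is_deterministic_and_coherent(self):
        cfg = SimulationConfig(
            n_species=10, years=(2006, 2008), master_seed=3, threshold_prevalence=5
        )
        ds1 = simulate_dataset(cfg)
        ds2 = simulate_dataset(cfg)
        assert ds1.tree.to_newick() == ds2.tree.to_newick()
        assert ds1.records == ds2.records
        assert ds1.pollination == ds2.pollination
        assert sum(ds1.pollination.values()) == cfg.threshold_prevalence
        assert set(ds1.panel.species) <= set(ds1.tree.tip_labels)
        tables = ds1.trait_tables()
        assert set(tables) == {"pollination_mode", "browse_type"}

    def test_default_retention_favours_state_zero(self):
        ret = default_retention(6)
        assert ret[0] == 1.0
        assert all(ret[s] < 1.0 for s in range(1, 6))
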