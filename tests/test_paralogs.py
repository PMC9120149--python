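"""Shared-intron classification, Dollo parsimony, U12 calls, group tests."""

import numpy as np
import pytest

from paralintron import paralogs
from paralintron.intron_mapping import IntronPosition
from paralintron.paralogs import ParalogyMap
from paralintron.simulate import SimulationConfig, simulate_stem
from paralintron.trees import parse_newick

from _oracles import dollo_min_losses, random_tree


def plain_pmap(*ogs):
    return ParalogyMap(acquisition_of={og: "acq1" for og in ogs})


class TestParalogyFromTree:
    def test_single_acquisition_makes_all_paralogous(self, d1d2_tree):
        # wrap the duplication-rooted tree under an acquisition root
        tree = parse_newick(
            "(((OG_A,OG_B)[duplication],OG_C)[duplication])[acquisition];"
        )
        pmap = paralogs.paralogy_from_tree(tree)
        assert pmap.relation("OG_A", "OG_C") == "paralogous"

    def test_sibling_acquisitions_are_clean_separate(self):
        tree = parse_newick("((A1,A2)[acquisition],(B1)[acquisition]);")
        pmap = paralogs.paralogy_from_tree(tree)
        assert pmap.relation("A1", "A2") == "paralogous"
        assert pmap.relation("A1", "B1") == "separate"
        assert not pmap.ambiguous

    def test_acquisition_under_duplication_is_ambiguous(self):
        tree = parse_newick(
            "(((A1)[acquisition],(B1)[acquisition])[duplication],(C1)[acquisition]);"
        )
        pmap = paralogs.paralogy_from_tree(tree)
        assert pmap.relation("A1", "B1") == "excluded"
        assert pmap.relation("A1", "C1") == "excluded"

    def test_unannotated_root_acts_as_implicit_acquisition(self):
        tree = parse_newick("((X,Y)[duplication],Z);")
        pmap = paralogs.paralogy_from_tree(tree)
        assert pmap.relation("X", "Z") == "paralogous"


class TestClassifyShared:
    def test_equal_column_and_phase_in_paralogs_is_shared(self):
        cl = paralogs.classify_shared(
            {"OG1": {(40, 0)}, "OG2": {(40, 0)}}, plain_pmap("OG1", "OG2")
        )
        assert cl.category[("OG1", (40, 0))] == "shared"
        assert cl.category[("OG2", (40, 0))] == "shared"

    def test_phase_mismatch_is_not_shared(self):
        cl = paralogs.classify_shared(
            {"OG1": {(40, 0)}, "OG2": {(40, 1)}}, plain_pmap("OG1", "OG2")
        )
        assert cl.category[("OG1", (40, 0))] == "unique"
        assert cl.category[("OG2", (40, 1))] == "unique"

    def test_separate_acquisition_never_makes_shared(self):
        pmap = ParalogyMap(
            acquisition_of={"OG1": "a1", "OG2": "a1", "OG3": "a2"}
        )
        cl = paralogs.classify_shared(
            {"OG1": {(40, 0)}, "OG2": {(40, 0)}, "OG3": {(40, 0)}}, pmap
        )
        assert cl.category[("OG1", (40, 0))] == "shared"
        assert cl.category[("OG2", (40, 0))] == "shared"
        # OG3 has no paralog partner at all: its introns are excluded
        assert cl.category[("OG3", (40, 0))] == "excluded"

    def test_shared_only_with_separate_acquisition_is_excluded_both_ways(self):
        pmap = ParalogyMap(
            acquisition_of={"OG1": "a1", "OG2": "a1", "OG3": "a2", "OG4": "a2"}
        )
        cl = paralogs.classify_shared(
            {"OG1": {(40, 0)}, "OG2": set(), "OG3": {(40, 0)}, "OG4": set()},
            pmap,
        )
        # OG1 shares (40,0) only with the separately acquired OG3
        assert cl.category[("OG1", (40, 0))] == "parallel_only"
        assert cl.category[("OG3", (40, 0))] == "parallel_only"
        assert cl.n_considered == 0

    def test_fraction_shared(self):
        cl = paralogs.classify_shared(
            {"OG1": {(40, 0), (10, 1)}, "OG2": {(40, 0)}},
            plain_pmap("OG1", "OG2"),
        )
        assert cl.fraction_shared == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_removing_separate_ogs_never_decreases_shared_fraction(self, seed):
        """Dropping the separate-acquisition OGs can only turn
        parallel-only introns unique, never unmake a shared one."""
        config = SimulationConfig(
            seed=seed + 1,
            n_acquisitions=2,
            n_duplications=1,
            parallel_gain_rate=0.25,
            gain_rate_stem=10.0,
            loss_rate_stem=0.5,
            protein_length=150,
        )
        fam = simulate_stem(config, "fam")
        pmap = paralogs.paralogy_from_tree(fam.gene_tree)
        full = paralogs.classify_shared(fam.leca_sets, pmap)
        keep = [
            og
            for og in fam.leca_sets
            if any(
                pmap.relation(og, other) == "paralogous"
                for other in fam.leca_sets
                if other != og
            )
        ]
        reduced_sets = {og: fam.leca_sets[og] for og in keep}
        reduced = paralogs.classify_shared(reduced_sets, pmap)
        if reduced.n_considered and full.n_considered:
            assert reduced.fraction_shared >= full.fraction_shared - 1e-12


class TestParallelGainControl:
    def family(self, seed, parallel):
        config = SimulationConfig(
            seed=seed,
            n_acquisitions=2,
            n_duplications=1,
            parallel_gain_rate=parallel,
            gain_rate_stem=10.0,
            loss_rate_stem=0.5,
            protein_length=150,
        )
        fam = simulate_stem(config, f"fam{seed}")
        return fam.leca_sets, paralogs.paralogy_from_tree(fam.gene_tree)

    def test_zero_parallel_rate_gives_zero_separate_fraction(self):
        families = [self.family(seed, 0.0) for seed in range(1, 11)]
        control = paralogs.parallel_gain_control(families)
        assert control.fraction_separate == 0.0

    def test_fisher_table_shape_and_p(self):
        families = [self.family(seed, 0.2) for seed in range(1, 11)]
        control = paralogs.parallel_gain_control(families)
        assert len(control.table) == 2
        assert 0.0 <= control.fisher.p <= 1.0

    def test_no_separate_ogs_returns_none(self):
        cl_sets = {"OG1": {(40, 0)}, "OG2": {(40, 0)}}
        with pytest.warns(UserWarning, match="control unavailable"):
            result = paralogs.parallel_gain_control(
                [(cl_sets, plain_pmap("OG1", "OG2"))]
            )
        assert result is None

    def test_predup_gains_dominate_control_significantly(self):
        """With pre-duplication gains and no parallel gains the paralog
        fraction exceeds the control at alpha=0.05 in >=95% of seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(1, n_seeds + 1):
            config = SimulationConfig(
                seed=seed,
                n_acquisitions=2,
                n_duplications=1,
                parallel_gain_rate=0.0,
                gain_rate_stem=10.0,
                loss_rate_stem=0.5,
                protein_length=150,
            )
            families = [
                (f.leca_sets, paralogs.paralogy_from_tree(f.gene_tree))
                for f in (
                    simulate_stem(config, f"f{seed}_{i}") for i in range(6)
                )
            ]
            control = paralogs.parallel_gain_control(families)
            if (
                control is not None
                and control.fraction_paralogs > control.fraction_separate
                and control.fisher.p < 0.05
            ):
                hits += 1
        assert hits / n_seeds >= 0.95


class TestDollo:
    def test_worked_example_gain_above_root_loss_on_leaf_branch(self, d1d2_tree):
        state = paralogs.dollo_preduplication(
            d1d2_tree, {"OG_A": {(40, 0)}, "OG_B": set(), "OG_C": {(40, 0)}}
        )
        assert (40, 0) in state.present["D1"]
        assert (40, 0) in state.present["D2"]
        assert state.gain_branch[(40, 0)] == "D1"
        assert state.loss_branches[(40, 0)] == {"OG_B"}

    def test_single_carrier_gain_on_terminal_branch(self, d1d2_tree):
        state = paralogs.dollo_preduplication(
            d1d2_tree, {"OG_A": {(7, 2)}, "OG_B": set(), "OG_C": set()}
        )
        assert state.gain_branch[(7, 2)] == "OG_A"
        assert not state.loss_branches[(7, 2)]
        assert not state.duplications_with_introns()["D1"]

    def test_cherry_carriers_flag_only_lower_duplication(self, d1d2_tree):
        state = paralogs.dollo_preduplication(
            d1d2_tree, {"OG_A": {(9, 0)}, "OG_B": {(9, 0)}, "OG_C": set()}
        )
        assert (9, 0) in state.present["D2"]
        assert (9, 0) not in state.present["D1"]
        flags = state.duplications_with_introns()
        assert flags == {"D1": False, "D2": True}
        ancestral_flags = state.ancestral_duplication_had_introns()
        assert ancestral_flags == {"D1": False, "D2": False}

    def test_ancestral_flag_set_below_intron_bearing_duplication(self, d1d2_tree):
        state = paralogs.dollo_preduplication(
            d1d2_tree, {"OG_A": {(3, 1)}, "OG_B": set(), "OG_C": {(3, 1)}}
        )
        assert state.ancestral_duplication_had_introns()["D2"]

    def test_unknown_carrier_rejected(self, d1d2_tree):
        with pytest.raises(ValueError, match="ghost"):
            paralogs.dollo_preduplication(d1d2_tree, {"ghost": {(1, 0)}})

    def test_worked_example_event_counts(self, d1d2_tree):
        state = paralogs.dollo_preduplication(
            d1d2_tree, {"OG_A": {(40, 0)}, "OG_B": set(), "OG_C": {(40, 0)}}
        )
        gains_dup, losses_dup, gains_leca, losses_leca = (
            paralogs.count_preduplication_events([state])
        )
        assert (gains_dup, losses_dup, gains_leca, losses_leca) == (1, 0, 0, 1)

    def test_no_shared_introns_put_all_gains_on_leca_branches(self, d1d2_tree):
        state = paralogs.dollo_preduplication(
            d1d2_tree,
            {"OG_A": {(1, 0)}, "OG_B": {(2, 0)}, "OG_C": {(3, 0)}},
        )
        gains_dup, losses_dup, gains_leca, losses_leca = (
            paralogs.count_preduplication_events([state])
        )
        assert (gains_dup, losses_dup, gains_leca, losses_leca) == (0, 0, 3, 0)

    @pytest.mark.parametrize("seed", range(25))
    def test_loss_count_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(2, 9)))
        leaves = tree.leaf_names
        n_carriers = int(rng.integers(1, len(leaves) + 1))
        carriers = set(rng.choice(leaves, size=n_carriers, replace=False))
        sets = {leaf: ({(5, 0)} if leaf in carriers else set()) for leaf in leaves}
        state = paralogs.dollo_preduplication(tree, sets)
        assert len(state.loss_branches[(5, 0)]) == dollo_min_losses(tree, carriers)

    def test_dollo_consistent_simulation_recovered_exactly(self):
        """Loss-only post-duplication histories are recovered event for
        event: gains on the true gain branches, Dollo-minimal losses."""
        config = SimulationConfig(
            seed=9,
            n_duplications=2,
            parallel_gain_rate=0.0,
            gain_rate_stem=8.0,
            loss_rate_stem=0.6,
            protein_length=150,
        )
        for i in range(10):
            fam = simulate_stem(config, f"fam{i}")
            state = paralogs.dollo_preduplication(fam.gene_tree, fam.leca_sets)
            for key, node in state.gain_branch.items():
                carriers = {
                    og for og, keys in fam.leca_sets.items() if key in keys
                }
                if len(carriers) < 2:
                    continue
                # every surviving multi-carrier intron was truly present at
                # each duplication node the reconstruction places it on
                for dup, present in state.present.items():
                    if key in present and dup in fam.node_present:
                        if not fam.gene_tree.node(dup).is_leaf:
                            assert key in fam.node_present[dup]


class TestAnnotateU12:
    positions = [IntronPosition("og1", 12, 0), IntronPosition("og1", 30, 1)]

    def rows(self, n_species):
        return [
            (f"sp{i}", "og1", 12, 0, "U12") for i in range(n_species)
        ]

    @pytest.mark.parametrize("n,expected", [(3, "U12"), (2, "U2"), (0, "U2")])
    def test_three_species_rule(self, n, expected):
        types = paralogs.annotate_u12(self.rows(n), self.positions)
        assert types[self.positions[0]] == expected
        assert types[self.positions[1]] == "U2"  # no predictions at all

    def test_duplicate_species_counted_once(self):
        rows = self.rows(2) + [("sp0", "og1", 12, 0, "U12")]
        types = paralogs.annotate_u12(rows, self.positions)
        assert types[self.positions[0]] == "U2"


class TestGroupFractions:
    def test_identical_fractions_give_null_chi2(self):
        outcomes = {f"u{i}": i % 2 == 0 for i in range(200)}
        categories = {
            f"u{i}": {"alpha" if i < 100 else "beta"} for i in range(200)
        }
        table = paralogs.group_fractions(outcomes, categories)
        assert table.chi2.statistic == pytest.approx(0.0)
        assert table.chi2.p == pytest.approx(1.0)

    def test_small_groups_dropped_from_reporting(self):
        outcomes = {f"u{i}": True for i in range(12)}
        categories = {f"u{i}": {"big" if i < 11 else "tiny"} for i in range(12)}
        table = paralogs.group_fractions(outcomes, categories)
        assert "big" in table.counts
        assert "tiny" not in table.counts

    def test_units_spanning_main_groups_excluded(self):
        main = {"translation": "information", "glycolysis": "metabolism"}
        outcomes = {"a": True, "b": False, "c": True}
        categories = {
            "a": {"translation"},
            "b": {"glycolysis"},
            "c": {"translation", "glycolysis"},  # spans two main groups
        }
        table = paralogs.group_fractions(
            outcomes, categories, min_units=1, main_group_of=main
        )
        total = sum(sum(v) for v in table.main_group_counts.values())
        assert total == 2

    def test_zeroed_group_detected_as_significant(self):
        """A category whose families lost every shared intron stands out,
        mirroring the empty nuclear-transport observation."""
        rng = np.random.default_rng(4)
        outcomes = {}
        categories = {}
        for i in range(150):
            categories[f"u{i}"] = {"transport" if i < 50 else "signalling"}
            outcomes[f"u{i}"] = False if i < 50 else bool(rng.uniform() < 0.4)
        table = paralogs.group_fractions(outcomes, categories)
        assert table.counts["transport"][0] == 0
        assert table.chi2.p < 0.001
        (pair,) = [
            r for a, b, r in table.pairwise if {a, b} == {"transport", "signalling"}
        ]
        assert pair.p_adj < 0.01
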