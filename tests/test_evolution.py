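import dendropy
import numpy as np
import pytest

import ciliaprofile as cp
from ciliaprofile.evolution import discretize_fraction

from _oracles import exhaustive_dollo_min, random_binary_newick


def newick_tree(text):
    return dendropy.Tree.get(data=text, schema="newick")


class TestDolloLossCounting:
    def test_all_present_no_losses(self):
        tree = newick_tree("((A,B),(C,D));")
        report = cp.count_independent_losses(
            tree, {s: True for s in "ABCD"}
        )
        assert report.total_losses == 0
        assert report.loss_edges == []

    def test_four_leaf_hand_example(self):
        # B lost alone; C and D lost together as one clade: two events
        tree = newick_tree("((A,B),(C,D));")
        trait = {"A": True, "B": False, "C": False, "D": False}
        report = cp.count_independent_losses(tree, trait)
        assert report.total_losses == 2
        assert sorted(sorted(e) for e in report.loss_edges) == [["B"], ["C", "D"]]

    def test_missing_trait_rejected(self):
        tree = newick_tree("(A,B);")
        with pytest.raises(ValueError, match="missing"):
            cp.count_independent_losses(tree, {"A": True})

    def test_per_group_attribution_sums_to_total(self):
        tree = newick_tree("((A,B),(C,D));")
        trait = {"A": True, "B": False, "C": False, "D": False}
        ann = [
            cp.SpeciesAnnotation("A", "opisthokonta", True, True),
            cp.SpeciesAnnotation("B", "opisthokonta", False, False),
            cp.SpeciesAnnotation("C", "alveolata", False, False),
            cp.SpeciesAnnotation("D", "alveolata", False, False),
        ]
        report = cp.count_independent_losses(tree, trait, ann)
        assert report.per_group_losses == {"opisthokonta": 1, "alveolata": 1}

    def test_equals_exhaustive_minimum_on_random_trees(self, rng):
        # Dollo count must equal the exhaustive minimal edge cover on
        # random binary trees up to 10 leaves with random trait states
        for _ in range(40):
            n = int(rng.integers(2, 11))
            labels = [f"t{i}" for i in range(n)]
            tree = newick_tree(random_binary_newick(labels, rng))
            trait = {lb: bool(rng.integers(2)) for lb in labels}
            if not any(trait.values()):
                trait[labels[0]] = True  # keep the root-present premise
            report = cp.count_independent_losses(tree, trait)
            assert report.total_losses == exhaustive_dollo_min(tree, trait)
            # loss clades are disjoint: no double counting
            all_leaves = [s for e in report.loss_edges for s in e]
            assert len(all_leaves) == len(set(all_leaves))

    def test_invariant_under_child_rotation(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 9))
            labels = [f"t{i}" for i in range(n)]
            newick = random_binary_newick(labels, rng)
            tree = newick_tree(newick)
            trait = {lb: bool(rng.integers(2)) for lb in labels}
            trait[labels[0]] = True
            base = cp.count_independent_losses(tree, trait).total_losses
            rotated = newick_tree(newick)
            for node in rotated.preorder_node_iter():
                children = node.child_nodes()
                if len(children) == 2:
                    node.set_child_nodes(children[::-1])
            assert cp.count_independent_losses(rotated, trait).total_losses == base

    def test_multifurcation_merging_absent_siblings_preserves_count(self):
        # collapsing an internal edge that does not separate absent leaves
        # from each other leaves the count unchanged
        multi = newick_tree("(A,B,C,(D,E));")
        refined = newick_tree("((A,B),C,(D,E));")  # groups present A with lost B
        trait = {"A": True, "B": False, "C": False, "D": True, "E": False}
        a = cp.count_independent_losses(multi, trait).total_losses
        b = cp.count_independent_losses(refined, trait).total_losses
        assert a == b == 3  # B, C and E remain three separate loss events

    def test_simulated_trait_gives_configured_loss_count(self, small_sim):
        matrix, truth, annotations = small_sim
        tree = cp.eukaryote_subtree(truth, annotations)
        trait = {
            a.species_id: a.is_ciliated
            for a in annotations if a.major_group != "prokaryote"
        }
        report = cp.count_independent_losses(tree, trait, annotations)
        assert report.total_losses == 3  # config.n_cilium_losses


class TestLossPatternClassification:
    def test_thresholds_as_printed(self):
        # strict inequalities: > 2/3 high, > 1/3 mid, else low
        assert discretize_fraction(1.0) == "high"
        assert discretize_fraction(0.5) == "mid"
        assert discretize_fraction(0.2) == "low"
        assert discretize_fraction(2 / 3) == "mid"  # boundary point
        assert discretize_fraction(1 / 3) == "low"  # boundary point

    @pytest.fixture
    def toy_matrix(self):
        # 3 species x 5 genes in 2 categories engineered to give catA
        # fractions 1.0 / 0.5 / 0.0 and catB fractions 1.0 / 1.0 / 1/3
        values = np.array([
            [1, 1, 0],
            [1, 0, 0],
            [1, 1, 1],
            [1, 1, 0],
            [1, 1, 0],
        ])
        matrix = cp.ProfileMatrix(
            ["a1", "a2", "b1", "b2", "b3"], ["s1", "s2", "s3"], values
        )
        cats = {"a1": "catA", "a2": "catA", "b1": "catB", "b2": "catB", "b3": "catB"}
        return matrix, cats

    def test_fraction_discretization_per_species(self, toy_matrix):
        matrix, cats = toy_matrix
        patterns, n = cp.classify_loss_patterns(matrix, cats)
        states = {p.species_id: p.states() for p in patterns}
        assert states["s1"] == {"catA": "high", "catB": "high"}
        assert states["s2"] == {"catA": "mid", "catB": "high"}
        assert states["s3"] == {"catA": "low", "catB": "low"}
        assert n == 3

    def test_all_present_species_is_all_high(self, toy_matrix):
        matrix, cats = toy_matrix
        patterns, _ = cp.classify_loss_patterns(matrix, cats, species_list=["s1"])
        assert set(patterns[0].states().values()) == {"high"}

    def test_empty_category_rejected(self, toy_matrix):
        matrix, cats = toy_matrix
        cats = dict(cats, missing_gene="catC")  # gene absent from matrix
        with pytest.raises(ValueError, match="catC"):
            cp.classify_loss_patterns(matrix, cats)

    def test_pattern_count_bounds(self, small_sim):
        matrix, truth, annotations = small_sim
        cats = {g: "cil" for g in truth.module_members("cil")}
        patterns, n = cp.classify_loss_patterns(matrix, cats)
        assert n <= 3 ** 1
        assert n <= len(matrix.species_ids)


class TestFunctionPrediction:
    def test_below_half_ciliated_gives_no_prediction(self, toy_annotations):
        # present in 3 of 8 ciliated genomes
        row = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        pred = cp.predict_gene_function("g", row, toy_annotations)
        assert pred.call == "no_prediction"
        assert pred.conservation_fraction == pytest.approx(3 / 8)

    def test_present_everywhere_including_nonmotile_is_biogenesis(self, toy_annotations):
        row = [1, 1, 1, 1, 1, 0, 1, 1, 1, 0, 0, 0]
        pred = cp.predict_gene_function("g", row, toy_annotations)
        assert pred.call == "biogenesis"

    def test_absent_only_from_nonmotile_ciliated_is_motility(self, toy_annotations):
        # sp02/sp03 carry immotile cilia; absence there + broad presence in
        # motile-ciliated genomes is the motility footprint
        row = [1, 1, 0, 0, 1, 0, 1, 1, 1, 0, 0, 0]
        pred = cp.predict_gene_function("g", row, toy_annotations)
        assert pred.call == "motility"

    def test_rule_truth_table_on_constructed_profiles(self, toy_annotations):
        # exhaustively check the decision rule against its definition over
        # all 2^8 presence patterns on the ciliated genomes
        ciliated_idx = [i for i, a in enumerate(toy_annotations) if a.is_ciliated]
        nonmotile_idx = [
            i for i, a in enumerate(toy_annotations)
            if a.is_ciliated and not a.has_motile_cilia
        ]
        motile_idx = [i for i, a in enumerate(toy_annotations) if a.has_motile_cilia]
        for bits in range(2 ** len(ciliated_idx)):
            row = np.zeros(len(toy_annotations), dtype=int)
            for k, i in enumerate(ciliated_idx):
                row[i] = (bits >> k) & 1
            pred = cp.predict_gene_function("g", row, toy_annotations)
            frac = row[ciliated_idx].mean()
            if frac < 0.5:
                expected = "no_prediction"
            elif not row[nonmotile_idx].any() and row[motile_idx].mean() >= 0.5:
                expected = "motility"
            else:
                expected = "biogenesis"
            assert pred.call == expected

    def test_monotone_in_ciliated_presence(self, toy_annotations):
        # adding the gene to one more ciliated genome never downgrades a
        # biogenesis call to no_prediction
        row = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        assert cp.predict_gene_function("g", row, toy_annotations).call == "biogenesis"
        for i, a in enumerate(toy_annotations):
            if a.is_ciliated and row[i] == 0:
                grown = row.copy()
                grown[i] = 1
                assert (
                    cp.predict_gene_function("g", grown, toy_annotations).call
                    != "no_prediction"
                )

    def test_zero_ciliated_species_rejected(self):
        ann = [cp.SpeciesAnnotation("x", "prokaryote", False, False)]
        with pytest.raises(ValueError, match="ciliated"):
            cp.predict_gene_function("g", [1], ann)


class TestUniversallyConservedGenes:
    def test_single_ciliated_absence_excludes(self, toy_annotations):
        values = np.ones((1, 12), dtype=int)
        values[0, [5, 9, 10, 11]] = 0  # absent from nonciliated + prokaryotes
        values[0, 7] = 0  # one ciliated absence disqualifies
        matrix = cp.ProfileMatrix(["g1"], [a.species_id for a in toy_annotations], values)
        assert cp.universally_conserved_genes(matrix, toy_annotations) == []

    def test_planted_universal_genes_recovered_exactly(self, small_sim):
        matrix, truth, annotations = small_sim
        # noise-free: exactly the ciliary-module genes (plus any background
        # gene that happens to mirror the ciliated state) are universal
        universal = set(cp.universally_conserved_genes(matrix, annotations))
        assert truth.module_members("cil") <= universal
        ann = {a.species_id: a for a in annotations}
        for g in universal:
            row = matrix.row(g)
            for j, s in enumerate(matrix.species_ids):
                if ann[s].is_ciliated:
                    assert row[j] == 1
                elif ann[s].major_group != "prokaryote":
                    assert row[j] == 0

    def test_prokaryote_presence_does_not_disqualify(self, toy_annotations):
        values = np.ones((1, 12), dtype=int)
        values[0, [5, 9]] = 0       # absent from nonciliated eukaryotes
        # prokaryote columns 10, 11 stay 1: ignored by the definition
        matrix = cp.ProfileMatrix(["g1"], [a.species_id for a in toy_annotations], values)
        assert cp.universally_conserved_genes(matrix, toy_annotations) == ["g1"]
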