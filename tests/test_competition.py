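"""Patristic distances, the Gaussian competition kernel, and Nz."""

from io import StringIO

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nichepart import (
    CompetitionKernel,
    alpha,
    effective_abundance,
    patristic_distances,
    simulate_census_and_tree,
)
from nichepart.competition import seasonal_competition_table
from nichepart.errors import CoverageError, TreeError


def census_of(rows):
    return pd.DataFrame(rows, columns=["species", "season", "abundance"])


def networkx_patristic_oracle(newick):
    """Independent path-walk: tree as a graph, distances by shortest path."""
    tree = dendropy.Tree.get(
        file=StringIO(newick), schema="newick", preserve_underscores=True
    )
    g = nx.Graph()
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            g.add_edge(id(node), id(child), weight=child.edge.length)
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    labels = sorted(leaves)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, leaves[labels[i]])
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = lengths[leaves[labels[j]]]
    return labels, D / D.max()


class TestPatristicDistances:
    def test_three_leaf_path_sums(self):
        d = patristic_distances("((A:1,B:1):1,C:2);")
        assert d.normalization == pytest.approx(4.0)  # raw d(A,C) = 4
        assert d.distance("A", "B") == pytest.approx(0.5)
        assert d.distance("A", "C") == pytest.approx(1.0)
        assert d.distance("B", "C") == pytest.approx(1.0)

    def test_metric_axioms_and_range(self):
        _, newick = simulate_census_and_tree(12, seed=0)
        d = patristic_distances(newick)
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.allclose(np.diag(d.matrix), 0.0)
        assert d.matrix.min() >= 0.0
        assert d.matrix.max() == pytest.approx(1.0)

    def test_matches_independent_path_oracle_on_random_trees(self):
        for seed in range(20):
            _, newick = simulate_census_and_tree(3 + seed % 8, seed=seed)
            d = patristic_distances(newick)
            labels, D_oracle = networkx_patristic_oracle(newick)
            assert tuple(labels) == d.species
            assert np.allclose(d.matrix, D_oracle, atol=1e-9)

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            patristic_distances("((A:1,A:1):1,C:2);")

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(TreeError):
            patristic_distances("((A,B),C);")

    def test_too_few_leaves_rejected(self):
        with pytest.raises(TreeError):
            patristic_distances("(A:1);")


class TestAlphaKernel:
    def test_conspecific_weight_is_one(self):
        assert alpha(0.0, CompetitionKernel()) == 1.0

    def test_maximal_distance_default_kernel(self):
        assert alpha(1.0, CompetitionKernel(0.05)) == pytest.approx(np.exp(-10))

    def test_strictly_decreasing(self):
        k = CompetitionKernel(0.05)
        d = np.linspace(0, 1, 50)
        w = alpha(d, k)
        assert np.all(np.diff(w) < 0)

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            CompetitionKernel(0.0)


class TestEffectiveAbundance:
    TREE = "((A:1,B:1):1,C:2);"

    def test_single_species_self_term_only(self):
        d = patristic_distances("(A:1,B:1);")
        census = census_of([("A", "breeding", 100.0)])
        nz = effective_abundance(census, d, CompetitionKernel(), "A", "breeding")
        assert nz == pytest.approx(100.0)

    def test_two_species_hand_computation(self):
        d = patristic_distances("(A:1,B:1);")  # normalised d(A,B) = 1
        census = census_of([("A", "breeding", 100.0), ("B", "breeding", 100.0)])
        nz = effective_abundance(census, d, CompetitionKernel(0.05), "A", "breeding")
        assert nz == pytest.approx(100.0 + 100.0 * np.exp(-10.0))

    def test_self_term_floor(self):
        d = patristic_distances(self.TREE)
        census = census_of(
            [("A", "breeding", 50.0), ("B", "breeding", 10.0), ("C", "breeding", 5.0)]
        )
        nz = effective_abundance(census, d, CompetitionKernel(), "A", "breeding")
        assert nz >= 50.0

    def test_linearity_in_abundance(self):
        d = patristic_distances(self.TREE)
        rows = [("A", "breeding", 50.0), ("B", "breeding", 10.0),
                ("C", "breeding", 5.0)]
        nz1 = effective_abundance(census_of(rows), d, CompetitionKernel(),
                                  "A", "breeding")
        doubled = [(s, se, 2 * a) for s, se, a in rows]
        nz2 = effective_abundance(census_of(doubled), d, CompetitionKernel(),
                                  "A", "breeding")
        assert nz2 == pytest.approx(2 * nz1)

    def test_identical_phylogeny_sums_all_abundance(self):
        # kernel weight -> 1 as sigma2 -> infinity mimics d = 0 for all pairs
        d = patristic_distances(self.TREE)
        rows = [("A", "breeding", 50.0), ("B", "breeding", 10.0),
                ("C", "breeding", 5.0)]
        nz = effective_abundance(census_of(rows), d, CompetitionKernel(1e12),
                                 "A", "breeding")
        assert nz == pytest.approx(65.0, rel=1e-6)

    def test_species_absent_that_season_contribute_zero(self):
        d = patristic_distances(self.TREE)
        census = census_of(
            [("A", "breeding", 50.0), ("B", "non_breeding", 10.0)]
        )
        nz = effective_abundance(census, d, CompetitionKernel(), "A", "breeding")
        assert nz == pytest.approx(50.0)

    def test_census_species_missing_from_tree_rejected(self):
        d = patristic_distances(self.TREE)
        census = census_of([("A", "breeding", 1.0), ("Z", "breeding", 1.0)])
        with pytest.raises(CoverageError, match="Z"):
            effective_abundance(census, d, CompetitionKernel(), "A", "breeding")

    def test_multi_year_census_averaged_within_season(self):
        d = patristic_distances("(A:1,B:1);")
        census = pd.DataFrame(
            [("A", "breeding", 2020, 100.0), ("A", "breeding", 2021, 200.0)],
            columns=["species", "season", "year", "abundance"],
        )
        nz = effective_abundance(census, d, CompetitionKernel(), "A", "breeding")
        assert nz == pytest.approx(150.0)

    def test_seasonal_table_reports_percent_increase(self):
        census, newick = simulate_census_and_tree(8, seed=6)
        d = patristic_distances(newick)
        table = seasonal_competition_table(
            census, d, CompetitionKernel(), [d.species[0], d.species[1]]
        )
        # generator inflates breeding abundances, so Nz must rise in breeding
        assert (table["percent_increase_breeding"] > 0).all()
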