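"""Unit and oracle tests for the bipartition screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dichoscreen.screen import (
    Bipartition,
    GeneSplitScore,
    ProportionTable,
    ScoreParams,
    ScreenConfig,
    binarize_and_tabulate,
    enumerate_bipartitions,
    score_gene_split,
    screen_all,
    top_genes,
)

from conftest import GROUP8, make_adata, random_table


# ---------------------------------------------------------------- bipartitions

@pytest.mark.parametrize("n_groups", range(2, 11))
def test_bipartition_count(n_groups):
    groups = [f"g{i}" for i in range(n_groups)]
    assert len(enumerate_bipartitions(groups)) == 2**n_groups - 2


def test_two_groups_both_orientations():
    splits = enumerate_bipartitions(["A", "B"])
    assert splits == [
        Bipartition(("A",), ("B",)),
        Bipartition(("B",), ("A",)),
    ]


def test_four_groups_complements_and_uniqueness():
    splits = enumerate_bipartitions(["A", "B", "C", "D"])
    assert len(splits) == 14
    assert len(set(splits)) == 14
    as_sets = {(frozenset(s.subset_1), frozenset(s.subset_2)) for s in splits}
    for s1, s2 in as_sets:
        assert (s2, s1) in as_sets  # every split's complement is present


def test_trivial_splits_excluded_and_errors():
    for s in enumerate_bipartitions(["A", "B", "C"]):
        assert s.subset_1 and s.subset_2
    with pytest.raises(ValueError):
        enumerate_bipartitions(["A"])
    with pytest.raises(ValueError):
        enumerate_bipartitions(["A", "A"])


def test_bipartition_invariants():
    with pytest.raises(ValueError):
        Bipartition(("A",), ("A", "B"))
    with pytest.raises(ValueError):
        Bipartition((), ("A",))


# ---------------------------------------------------------------- scoring

def test_score_perfect_dichotomy_hand_value():
    # one group fully expressing vs one fully silent, at default offsets:
    # log2(0.9) - log2(0.02)
    s = score_gene_split({"A": 1.0, "B": 0.0}, Bipartition(("A",), ("B",)))
    assert s == pytest.approx(math.log2(0.9) - math.log2(0.02), abs=1e-12)
    assert s == pytest.approx(5.4919, abs=1e-4)


@pytest.mark.parametrize(
    "prop,expect_inf",
    [(0.05, True), (0.0999, True), (0.1, True), (0.1001, False), (0.5, False)],
)
def test_penalty_boundary_at_ten_percent(prop, expect_inf):
    """A subset_1 group expressing in <=10% of cells forces the minimal score."""
    s = score_gene_split({"A": prop, "B": 0.0}, Bipartition(("A",), ("B",)))
    assert (s == float("-inf")) is expect_inf


def test_score_group_mismatch_errors():
    with pytest.raises(ValueError, match="missing"):
        score_gene_split({"A": 0.5}, Bipartition(("A",), ("B",)))


def test_score_equal_weight_per_group():
    # subset means weight each group by 1/|S|, independent of cell counts
    s = score_gene_split(
        {"A": 0.9, "B": 0.5, "C": 0.1}, Bipartition(("A", "B"), ("C",))
    )
    expected = (math.log2(-1 + 0.9 + 0.9) + math.log2(-1 + 0.9 + 0.5)) / 2 - math.log2(
        0.02 + 0.1
    )
    assert s == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- tabulation

def test_binarize_direct_counts():
    counts = [[0], [1], [2], [0]]
    adata = make_adata(counts, ["G1"] * 4, genes=["g"])
    table = binarize_and_tabulate(adata)
    assert table.num_expr.loc["g", "G1"] == 2
    assert table.prop.loc["g", "G1"] == 0.5


def test_binarize_all_zero_gene():
    counts = np.zeros((6, 2), dtype=int)
    counts[:, 1] = 1
    adata = make_adata(counts, ["G1"] * 3 + ["G2"] * 3)
    table = binarize_and_tabulate(adata)
    assert (table.prop.loc["g0"] == 0).all()
    assert (table.prop.loc["g1"] == 1).all()


def test_binarize_matches_per_cell_loop():
    rng = np.random.default_rng(5)
    counts = rng.poisson(0.7, size=(50, 12))
    groups = rng.choice(["G1", "G2", "G3"], size=50)
    adata = make_adata(counts, groups)
    table = binarize_and_tabulate(adata)
    for j in range(12):
        for g in ["G1", "G2", "G3"]:
            expected = sum(
                1 for i in range(50) if groups[i] == g and counts[i, j] >= 1
            )
            assert table.num_expr.loc[f"g{j}", g] == expected
            n = (groups == g).sum()
            assert table.prop.loc[f"g{j}", g] * n == pytest.approx(expected)


def test_binarize_unlabeled_cell_errors():
    adata = make_adata([[1], [2]], ["G1", None])
    with pytest.raises(ValueError, match="unlabeled"):
        binarize_and_tabulate(adata)


# ---------------------------------------------------------------- screen_all

def brute_force_screen(table, params=ScoreParams()):
    out = {}
    for split in enumerate_bipartitions(table.groups):
        for gene in table.genes:
            out[(gene, split)] = score_gene_split(table.prop.loc[gene], split, params)
    return out


def test_screen_all_shape_and_oracle():
    """Vectorized screen equals the naive per-gene/per-split loop."""
    rng = np.random.default_rng(42)
    table = random_table(rng, n_genes=200)
    # ensure some all-zero and all-one genes are present
    table.num_expr.iloc[0] = 0
    table.num_expr.iloc[1] = table.ncells.to_numpy()
    table = ProportionTable(table.num_expr, table.ncells)

    scores = screen_all(table)
    assert len(scores) == 200 * 254
    oracle = brute_force_screen(table)
    for s in scores:
        expected = oracle[(s.gene, s.split)]
        if math.isinf(expected):
            assert s.score == float("-inf")
        else:
            assert s.score == pytest.approx(expected, abs=1e-9)


def test_screen_all_empty_gene_set():
    table = ProportionTable(
        pd.DataFrame(columns=["A", "B"], dtype=int), pd.Series({"A": 3, "B": 4})
    )
    assert screen_all(table) == []


def test_constant_prop_gene_finite_scores_vary_only_with_split_shape():
    # a gene at identical proportion everywhere: the score depends only
    # on the split through the (constant) per-side means, so all finite
    # scores are equal
    table = ProportionTable(
        pd.DataFrame({g: [50] for g in ["A", "B", "C"]}, index=["g"]),
        pd.Series({"A": 100, "B": 100, "C": 100}),
    )
    finite = {round(s.score, 12) for s in screen_all(table) if math.isfinite(s.score)}
    assert len(finite) == 1


# ---------------------------------------------------------------- ranking

def test_top_genes_dedup_keeps_best_split():
    x = Bipartition(("A",), ("B",))
    y = Bipartition(("B",), ("A",))
    scores = [GeneSplitScore("geneA", x, 5.0, 0.9), GeneSplitScore("geneA", y, 4.0, 0.8)]
    ranked = top_genes(scores, ScreenConfig(top_k=10))
    assert len(ranked) == 1
    assert ranked[0].split == x


def test_top_genes_all_minus_inf_empty():
    x = Bipartition(("A",), ("B",))
    scores = [GeneSplitScore("g1", x, float("-inf")), GeneSplitScore("g2", x, float("-inf"))]
    assert top_genes(scores) == []


def test_top_genes_matches_sort_then_dedup_oracle():
    rng = np.random.default_rng(9)
    table = random_table(rng, n_genes=500)
    scores = screen_all(table)
    ranked = top_genes(scores, ScreenConfig(top_k=100), group_order=table.groups)

    # oracle: per gene take max finite score over splits, sort descending
    best = {}
    for s in scores:
        if s.gene not in best or s.score > best[s.gene]:
            best[s.gene] = s.score
    finite = {g: v for g, v in best.items() if math.isfinite(v)}
    expected_order = sorted(finite.items(), key=lambda kv: -kv[1])[:100]
    assert len(ranked) == len(expected_order)
    for got, (gene, score) in zip(ranked, expected_order):
        assert got.score == pytest.approx(score, abs=1e-12)
    # set of genes agrees even where scores tie
    assert {s.gene for s in ranked} == {g for g, _ in expected_order}


def test_minus_inf_never_outranks_finite():
    x = Bipartition(("A",), ("B",))
    scores = [
        GeneSplitScore("dead", x, float("-inf")),
        GeneSplitScore("alive", x, -100.0),
    ]
    ranked = top_genes(scores, ScreenConfig(top_k=5))
    assert [s.gene for s in ranked] == ["alive"]


# ---------------------------------------------------------------- properties

def test_monotonicity_in_proportions():
    """Finite scores rise with subset_1 proportions and fall with
    subset_2 proportions."""
    rng = np.random.default_rng(123)
    params = ScoreParams()
    split = Bipartition(("A", "B"), ("C", "D"))
    for _ in range(300):
        props = {
            "A": rng.uniform(0.15, 1.0),
            "B": rng.uniform(0.15, 1.0),
            "C": rng.uniform(0.0, 1.0),
            "D": rng.uniform(0.0, 1.0),
        }
        base = score_gene_split(props, split, params)
        up = dict(props, A=min(1.0, props["A"] + 0.05))
        assert score_gene_split(up, split, params) >= base
        worse = dict(props, C=min(1.0, props["C"] + 0.05))
        if worse["C"] > props["C"]:
            assert score_gene_split(worse, split, params) < base


def test_group_permutation_equivariance():
    """Relabeling the group order changes split encodings but not any
    gene's best score or best split as a set pair."""
    rng = np.random.default_rng(321)
    for _ in range(30):
        table = random_table(rng, n_genes=10)
        perm = list(rng.permutation(table.groups))
        permuted = ProportionTable(table.num_expr[perm], table.ncells[perm])

        def best_by_gene(t):
            ranked = top_genes(
                screen_all(t), ScreenConfig(top_k=10**9, dedup=True), group_order=t.groups
            )
            return {
                s.gene: (s.score, frozenset(s.split.subset_1), frozenset(s.split.subset_2))
                for s in ranked
            }

        a, b = best_by_gene(table), best_by_gene(permuted)
        assert set(a) == set(b)
        for gene in a:
            assert a[gene][0] == pytest.approx(b[gene][0], abs=1e-12)
            assert a[gene][1:] == b[gene][1:]
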