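"""Genotype comparison statistics: scores, ECDF, Mann-Whitney."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fivepdecay import compare
from fivepdecay.compare import (
    ScoreTable,
    cumulative_summary,
    genotype_score,
    median_increment,
    rank_for_go,
    subset_shift_test,
)


def _lt(values: dict[str, float], ratio="uSvsdS", passing=None):
    genes = sorted(values)
    passing = passing if passing is not None else {g: True for g in genes}
    return pd.DataFrame(
        {ratio: [values[g] for g in genes], f"{ratio}_pass": [passing[g] for g in genes]},
        index=pd.Index(genes, name="gene_id"),
    )


def exact_mannwhitney(x, y):
    """Exhaustive enumeration of the U null distribution (no ties)."""
    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)

    def ustat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in set(idx)]
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    us = [ustat(c) for c in combinations(range(n), n1)]
    p_le = sum(u <= u_obs for u in us) / len(us)
    p_ge = sum(u >= u_obs for u in us) / len(us)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def test_identical_tables_score_zero():
    lt = _lt({"A": 0.5, "B": -1.0})
    st_ = genotype_score(lt, lt)
    assert (st_.scores == 0).all()


def test_score_is_log2_fold_change_of_raw_ratios():
    # mutant uS/dS = 4, wt uS/dS = 2 -> score log2(4/2) = 1
    mut, wt = _lt({"A": np.log2(4)}), _lt({"A": np.log2(2)})
    assert genotype_score(mut, wt).scores["A"] == pytest.approx(1.0)


def test_score_restricted_to_genes_passing_in_both():
    mut = _lt({"A": 1.0, "B": 2.0}, passing={"A": True, "B": False})
    wt = _lt({"A": 0.0, "B": 0.0})
    assert list(genotype_score(mut, wt).scores.index) == ["A"]


def test_score_antisymmetric_under_strain_swap():
    rng = np.random.default_rng(0)
    vals1 = {f"G{i}": v for i, v in enumerate(rng.normal(size=30))}
    vals2 = {f"G{i}": v for i, v in enumerate(rng.normal(size=30))}
    a, b = _lt(vals1), _lt(vals2)
    fwd, rev = genotype_score(a, b).scores, genotype_score(b, a).scores
    pd.testing.assert_series_equal(fwd, -rev)


def test_empty_intersection_raises():
    mut = _lt({"A": 1.0}, passing={"A": False})
    with pytest.raises(ValueError):
        genotype_score(mut, _lt({"A": 0.0}))


def test_ecdf_singleton():
    s = cumulative_summary([1.0])
    assert list(s.support) == [1.0] and list(s.ecdf) == [1.0] and s.median == 1.0


def test_median_midpoint_rule():
    assert cumulative_summary([1, 2, 3, 4]).median == pytest.approx(2.5)


def test_ecdf_nondecreasing_ends_at_one():
    rng = np.random.default_rng(1)
    s = cumulative_summary(rng.normal(size=200))
    assert np.all(np.diff(s.ecdf) >= 0) and s.ecdf[-1] == pytest.approx(1.0)
    assert s.support[0] <= s.median <= s.support[-1]


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    vals=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=40),
    c=st.floats(-10, 10, allow_nan=False),
)
def test_delta_median_translation_equivariance(vals, c):
    base = cumulative_summary(vals)
    shifted = cumulative_summary([v + c for v in vals])
    assert shifted.delta_median(base) == pytest.approx(c, abs=1e-9)


def test_median_increment_translation():
    rng = np.random.default_rng(2)
    vals = {f"G{i}": v for i, v in enumerate(rng.normal(size=50))}
    wt = _lt(vals)
    mut = _lt({g: v + 0.7 for g, v in vals.items()})
    assert median_increment(mut, wt) == pytest.approx(0.7)
    assert median_increment(wt, wt) == 0.0


def test_median_increment_differs_from_median_score_for_skewed_data():
    """Δmedian != median of per-gene differences in general (asymmetry)."""
    wt_vals = {"A": 0.0, "B": 0.0, "C": 0.0}
    mut_vals = {"A": 0.0, "B": 0.1, "C": 10.0}
    mut, wt = _lt(mut_vals), _lt(wt_vals)
    dm = median_increment(mut, wt)
    med_score = float(np.median(genotype_score(mut, wt).scores))
    assert dm == pytest.approx(0.1) and med_score == pytest.approx(0.1)
    # a counterexample where they diverge
    wt_vals = {"A": 0.0, "B": 1.0, "C": 2.0}
    mut_vals = {"A": 2.0, "B": 3.0, "C": 0.0}
    dm = median_increment(_lt(mut_vals), _lt(wt_vals))
    med_score = float(np.median(genotype_score(_lt(mut_vals), _lt(wt_vals)).scores))
    assert dm == pytest.approx(1.0) and med_score == pytest.approx(2.0)


def _scores(values: dict[str, float]) -> ScoreTable:
    return ScoreTable(scores=pd.Series(values).sort_index(), ratio_name="uSvsdS")


def test_mannwhitney_exact_matches_enumeration_small_case():
    res = subset_shift_test(_scores({"a": 3, "b": 4, "c": 5, "d": 1, "e": 2}), {"a", "b", "c"})
    u, p = exact_mannwhitney([3, 4, 5], [1, 2])
    assert res.method == "exact"
    assert res.u_statistic == u == 6
    assert res.p_value == pytest.approx(p) == pytest.approx(0.2)


def test_mannwhitney_exact_matches_enumeration_random_splits():
    rng = np.random.default_rng(3)
    for trial in range(5):
        vals = rng.permutation(np.arange(1.0, 9.0))  # distinct, no ties
        for n1 in (2, 3, 4):
            genes = [f"g{i}" for i in range(8)]
            table = _scores(dict(zip(genes, vals)))
            subset = set(genes[:n1])
            res = subset_shift_test(table, subset)
            u, p = exact_mannwhitney(vals[:n1], vals[n1:])
            assert res.method == "exact"
            assert res.u_statistic == pytest.approx(u)
            assert res.p_value == pytest.approx(p, abs=1e-12)


def test_mannwhitney_identical_constant_groups():
    res = subset_shift_test(_scores({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}), {"a", "b"})
    assert res.p_value == 1.0 and res.method == "exact"


def test_mannwhitney_rank_invariance_under_monotone_transform():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=60)
    genes = [f"g{i}" for i in range(60)]
    subset = set(genes[:20])
    base = subset_shift_test(_scores(dict(zip(genes, vals))), subset)
    trans = subset_shift_test(_scores(dict(zip(genes, np.exp(vals)))), subset)
    assert base.p_value == pytest.approx(trans.p_value)
    assert base.u_statistic == trans.u_statistic


def test_mannwhitney_degenerate_groups_raise():
    with pytest.raises(ValueError):
        subset_shift_test(_scores({"a": 1.0, "b": 2.0}), {"a", "b"})
    with pytest.raises(ValueError):
        subset_shift_test(_scores({"a": 1.0, "b": 2.0}), set())


def test_rank_for_go_ordering_and_invariance():
    table = _scores({"A": 1.0, "B": 2.0, "C": 2.0})
    ranked = rank_for_go(table)
    assert list(ranked["gene_id"]) == ["B", "C", "A"]  # ties by gene_id
    shuffled = ScoreTable(scores=table.scores.sample(frac=1, random_state=0), ratio_name="uSvsdS")
    pd.testing.assert_frame_equal(rank_for_go(shuffled), ranked)


def test_rank_for_go_singleton():
    ranked = rank_for_go(_scores({"only": 0.5}))
    assert len(ranked) == 1 and ranked.loc[0, "gene_id"] == "only"


def test_gene_set_loader(tmp_path):
    path = tmp_path / "set.txt"
    path.write_text("# comment\nG1\n\nG2\n")
    assert compare.load_gene_set(path) == ["G1", "G2"]
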