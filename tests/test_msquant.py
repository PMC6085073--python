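"""MS quantification, normalization and the enrichment funnel."""

import numpy as np
import pandas as pd
import pytest

from fivepdecay import msquant
from fivepdecay.msquant import (
    AbundanceSet,
    PeptideTable,
    combine_count_sets,
    count_mw_quant,
    enrichment_test,
    median_normalize,
    top3_quant,
)
from fivepdecay.synthetic_data import simulate_ms_dataset


def make_table(rows, mw=None):
    df = pd.DataFrame(
        rows,
        columns=["protein_id", "strain", "replicate", "gel_set", "peptide_id", "intensity", "confident"],
    )
    proteins = sorted(df["protein_id"].unique())
    mw = mw or {p: 50.0 for p in proteins}
    return PeptideTable(df, pd.Series(mw))


def _rows(protein, strain, rep, intensities, gel="remainder", confident=True):
    return [
        (protein, strain, rep, gel, f"{protein}_p{i}", inten, confident)
        for i, inten in enumerate(intensities)
    ]


def test_top3_mean_of_three_largest():
    tbl = make_table(_rows("P1", "GPD1", 1, [8, 4, 2, 1]))
    aset = top3_quant(tbl)
    assert aset.values.loc[0, "abundance"] == pytest.approx(np.log2((8 + 4 + 2) / 3))


def test_top3_with_fewer_than_three_flagged_by_count():
    tbl = make_table(_rows("P1", "GPD1", 1, [8, 4]))
    row = top3_quant(tbl).values.iloc[0]
    assert row["abundance"] == pytest.approx(np.log2(6.0)) and row["n_peptides"] == 2


def test_top3_homogeneity_under_global_rescaling():
    rows = _rows("P1", "GPD1", 1, [8, 4, 2, 1]) + _rows("P2", "GPD1", 1, [5, 3])
    tbl = make_table(rows)
    scaled = make_table([r[:5] + (r[5] * 16,) + r[6:] for r in rows])
    a, b = top3_quant(tbl).values, top3_quant(scaled).values
    np.testing.assert_allclose(b["abundance"], a["abundance"] + 4.0)


def test_unconfident_peptides_excluded():
    tbl = make_table(_rows("P1", "GPD1", 1, [8]) + _rows("P2", "GPD1", 1, [9], confident=False))
    assert list(top3_quant(tbl).values["protein_id"]) == ["P1"]


def test_count_mw_definition():
    tbl = make_table(_rows("P1", "GPD1", 1, list(range(1, 11))), mw={"P1": 50.0})
    row = count_mw_quant(tbl).values.iloc[0]
    assert row["abundance"] == pytest.approx(np.log2(10 / 50))


def test_count_mw_equal_counts_mw_ratio_two_gives_unit_difference():
    rows = _rows("P1", "GPD1", 1, [1, 1, 1]) + _rows("P2", "GPD1", 1, [9, 9, 9])
    tbl = make_table(rows, mw={"P1": 25.0, "P2": 50.0})
    vals = count_mw_quant(tbl).values.set_index("protein_id")["abundance"]
    assert vals["P1"] - vals["P2"] == pytest.approx(1.0)


def test_median_normalize_centres_each_set():
    rows = (
        _rows("P1", "GPD1", 1, [2.0])
        + _rows("P2", "GPD1", 1, [4.0])
        + _rows("P3", "GPD1", 1, [8.0])
    )
    aset = median_normalize(top3_quant(make_table(rows)))
    vals = aset.values.set_index("protein_id")["abundance"]
    assert vals["P2"] == pytest.approx(0.0)
    assert vals["P1"] == pytest.approx(-1.0) and vals["P3"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        median_normalize(aset)  # double normalization


def test_median_normalize_invariant_to_per_set_constant():
    rng = np.random.default_rng(0)
    rows = []
    for p in range(6):
        rows += _rows(f"P{p}", "GPD1", 1, list(rng.uniform(1, 100, size=4)))
    tbl = make_table(rows)
    base = median_normalize(top3_quant(tbl)).values["abundance"]
    scaled_tbl = make_table([r[:5] + (r[5] * 7.3,) + r[6:] for r in rows])
    scaled = median_normalize(top3_quant(scaled_tbl)).values["abundance"]
    np.testing.assert_allclose(base, scaled, atol=1e-12)


def test_combine_count_sets_averages_and_passes_singletons():
    bait = make_table(_rows("P1", "GPD1", 1, [1], gel="bait"))
    rem = make_table(
        _rows("P1", "GPD1", 1, [1]) + _rows("P2", "GPD1", 1, [1, 1])
    )
    a = AbundanceSet(count_mw_quant(bait).values.assign(abundance=1.0), "count_mw", True)
    b_vals = count_mw_quant(rem).values
    b_vals.loc[b_vals["protein_id"] == "P1", "abundance"] = 3.0
    b_vals.loc[b_vals["protein_id"] == "P2", "abundance"] = -0.5
    b = AbundanceSet(b_vals, "count_mw", True)
    combined = combine_count_sets(a, b).values.set_index("protein_id")["abundance"]
    assert combined["P1"] == pytest.approx(2.0)  # mean of 1 and 3
    assert combined["P2"] == pytest.approx(-0.5)  # remainder only
    with pytest.raises(ValueError):
        combine_count_sets(a, AbundanceSet(top3_quant(rem).values, "top3", True))


def textbook_t(x, y):
    """Equal-variance two-sample t, straight from the pooled-variance formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), n1 + n2 - 2)
    return t, p


def _norm_aset(values):
    df = pd.DataFrame(values, columns=["protein_id", "strain", "replicate", "abundance"])
    df["gel_set"] = "combined"
    df["n_peptides"] = 3
    return AbundanceSet(df, method="count_mw", normalized=True)


def test_enrichment_test_matches_textbook_t_to_1e12():
    rng = np.random.default_rng(1)
    tagged = rng.normal(2.0, 0.5, size=3)
    untagged = rng.normal(0.0, 0.5, size=3)
    rows = [("P1", "GPD1", r + 1, v) for r, v in enumerate(tagged)]
    rows += [("P1", "untagged", r + 1, v) for r, v in enumerate(untagged)]
    res = enrichment_test(_norm_aset(rows), "GPD1").iloc[0]
    t_ref, p_ref = textbook_t(tagged, untagged)
    assert res["t_stat"] == pytest.approx(t_ref, abs=1e-12)
    assert res["p_value"] == pytest.approx(p_ref, abs=1e-12)
    assert res["mean_log2_ratio"] == pytest.approx(tagged.mean() - untagged.mean())


def test_enrichment_identical_groups_t_zero_p_one():
    rows = [("P1", "GPD1", r, v) for r, v in [(1, 1.0), (2, 2.0), (3, 3.0)]]
    rows += [("P1", "untagged", r, v) for r, v in [(1, 1.0), (2, 2.0), (3, 3.0)]]
    res = enrichment_test(_norm_aset(rows), "GPD1").iloc[0]
    assert res["t_stat"] == pytest.approx(0.0) and res["p_value"] == pytest.approx(1.0)


def test_single_replicate_excluded():
    rows = [("P1", "GPD1", 1, 5.0)] + [("P1", "untagged", r, 0.0) for r in (1, 2, 3)]
    assert enrichment_test(_norm_aset(rows), "GPD1").empty


def test_absent_from_untagged_uses_imputed_floor():
    rows = [("P1", "GPD1", r, 4.0 + 0.1 * r) for r in (1, 2, 3)]
    rows += [("P2", "untagged", r, float(r)) for r in (1, 2, 3)]  # background
    res = enrichment_test(_norm_aset(rows), "GPD1").iloc[0]
    assert bool(res["imputed"])
    floor = np.quantile([1.0, 2.0, 3.0], 0.05)
    assert res["mean_log2_ratio"] == pytest.approx(np.mean([4.1, 4.2, 4.3]) - floor)


def test_funnel_monotone_in_tagged_intensity():
    """Scaling a preferential protein's tagged intensities up keeps it preferential."""
    tbl, enriched = simulate_ms_dataset(n_proteins=80, n_enriched=4, seed=5)
    base = msquant.run_enrichment_funnel(tbl)
    hit = sorted(set(base.preferential) & set(enriched))[0]
    pep = tbl.peptides.copy()
    mask = (pep["protein_id"] == hit) & pep["strain"].isin(["GPD1", "STL1"])
    pep.loc[mask, "intensity"] *= 4.0
    boosted = msquant.run_enrichment_funnel(PeptideTable(pep, tbl.protein_mw))
    assert hit in boosted.preferential


def test_threshold_excludes_subthreshold_control_ratio():
    """log2 ratio of 1.4 vs a control strain fails the >1.5 preferential cut."""
    results = pd.DataFrame(
        [
            # protein Q: strong vs untagged in both osmo strains,
            # but only 1.4 log2 above the ASH1 strain
            ("Q", "GPD1", "m", 3, 3, 3.0, 0.0, 3.0, 10.0, 1e-4, False),
            ("Q", "STL1", "m", 3, 3, 3.0, 0.0, 3.0, 10.0, 1e-4, False),
            ("Q", "ASH1", "m", 3, 3, 1.6, 0.0, 1.6, 5.0, 1e-3, False),
            ("Q", "HYP2", "m", 3, 3, 0.0, 0.0, 0.0, 0.0, 1.0, False),
        ],
        columns=[
            "protein_id", "strain", "method", "n_tagged", "n_untagged",
            "mean_tagged", "mean_untagged", "mean_log2_ratio", "t_stat", "p_value", "imputed",
        ],
    )
    out = msquant.preferential_filter(results)
    assert out.preferential == []
    # raising the margin above 1.5 flips it
    results.loc[results["strain"] == "ASH1", "mean_tagged"] = 1.4
    results.loc[results["strain"] == "HYP2", "mean_tagged"] = 0.0
    out2 = msquant.preferential_filter(results)
    assert out2.preferential == ["Q"]


def test_null_dataset_yields_no_preferential_hits():
    tbl, _ = simulate_ms_dataset(n_proteins=120, n_enriched=0, effect_log2=0.0, seed=7)
    res = msquant.run_enrichment_funnel(tbl)
    assert len(res.preferential) <= 2  # type-I only


def test_ms_simulator_deterministic():
    a, ea = simulate_ms_dataset(n_proteins=40, n_enriched=3, seed=9)
    b, eb = simulate_ms_dataset(n_proteins=40, n_enriched=3, seed=9)
    assert ea == eb
    pd.testing.assert_frame_equal(a.peptides, b.peptides)


def test_peptide_table_tsv_round_trip(tmp_path):
    tbl, _ = simulate_ms_dataset(n_proteins=15, n_enriched=2, seed=11)
    p, m = tmp_path / "pep.tsv", tmp_path / "mw.tsv"
    tbl.to_tsv(p, m)
    back = PeptideTable.from_tsv(p, m)
    pd.testing.assert_frame_equal(back.peptides, tbl.peptides)
    np.testing.assert_allclose(back.protein_mw.to_numpy(), tbl.protein_mw.to_numpy())
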