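"""Label-free proteomics enrichment funnel for MS2 RNP pull-downs.

Peptide-level output of a spectral search (protein assignment, >=95%
confidence flags, chromatographic intensities) is turned into protein
abundances by two label-free methods: the mean intensity of the top three
peptides, and peptide count divided by molecular weight (an emPAI-like
index).  Each sample yields four quantitative sets (two gel fractions x
two methods); all are log2-transformed and median-centred per set, the
two count-based sets are combined, and the intensity-based sets are kept
separate.  Proteins quantified in at least two of three replicates are
tested against the untagged-bait control with an equal-variance Student's
t-test, deliberately without multiple-testing correction (candidates are
validated by orthogonal experiments downstream).  The funnel then flags
proteins reproducibly enriched over the untagged strain (>2-fold,
p<0.05) and proteins preferentially bound by the osmostress mRNAs
(significant in both osmo-mRNA strains and >3-fold, i.e. log2 ratio
>1.5, over the untagged strain and both control-mRNA strains).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideTable",
    "AbundanceSet",
    "top3_quant",
    "count_mw_quant",
    "median_normalize",
    "combine_count_sets",
    "quantify_all",
    "enrichment_test",
    "preferential_filter",
    "run_enrichment_funnel",
    "EnrichmentResult",
]

PEPTIDE_COLUMNS = ["protein_id", "strain", "replicate", "gel_set", "peptide_id", "intensity", "confident"]


@dataclass
class PeptideTable:
    """Peptide-level MS records plus protein molecular weights (kDa)."""

    peptides: pd.DataFrame
    protein_mw: pd.Series  # index protein_id, kDa

    def __post_init__(self) -> None:
        missing = set(PEPTIDE_COLUMNS) - set(self.peptides.columns)
        if missing:
            raise ValueError(f"peptide table missing columns {sorted(missing)}")
        if (self.peptides["intensity"] < 0).any():
            raise ValueError("negative peptide intensity")
        if (self.protein_mw <= 0).any():
            raise ValueError("molecular weights must be positive")

    @classmethod
    def from_tsv(cls, peptides_path: str | Path, mw_path: str | Path) -> "PeptideTable":
        pep = pd.read_csv(peptides_path, sep="\t", dtype={"protein_id": str, "strain": str, "gel_set": str})
        mw = pd.read_csv(mw_path, sep="\t", dtype={"protein_id": str}).set_index("protein_id")["mw_kda"]
        return cls(pep, mw)

    def to_tsv(self, peptides_path: str | Path, mw_path: str | Path) -> None:
        self.peptides.to_csv(peptides_path, sep="\t", index=False)
        self.protein_mw.rename("mw_kda").rename_axis("protein_id").reset_index().to_csv(
            mw_path, sep="\t", index=False
        )


_SAMPLE_KEY = ["strain", "replicate", "gel_set"]


@dataclass
class AbundanceSet:
    """Per (protein, sample, gel fraction) log2 abundances for one method."""

    values: pd.DataFrame  # protein_id, strain, replicate, gel_set, abundance, n_peptides
    method: str  # "top3" or "count_mw"
    normalized: bool = False

    def __post_init__(self) -> None:
        key = ["protein_id"] + _SAMPLE_KEY
        if self.values.duplicated(key).any():
            raise ValueError("duplicate (protein, sample, gel_set) rows in abundance set")


def _confident(tbl: PeptideTable) -> pd.DataFrame:
    pep = tbl.peptides
    return pep[pep["confident"] & (pep["intensity"] > 0)]


def top3_quant(tbl: PeptideTable) -> AbundanceSet:
    """log2 of the mean intensity of each protein's three most intense peptides.

    Proteins with fewer than three confident peptides in a sample use the
    mean of what is available (flagged via ``n_peptides``); proteins with
    none are absent, not zero.
    """
    pep = _confident(tbl)
    key = ["protein_id"] + _SAMPLE_KEY
    top = pep.sort_values("intensity", ascending=False).groupby(key, sort=True).head(3)
    agg = top.groupby(key, sort=True)["intensity"].agg(["mean", "size"]).reset_index()
    agg["abundance"] = np.log2(agg["mean"])
    agg = agg.rename(columns={"size": "n_peptides"}).drop(columns="mean")
    return AbundanceSet(values=agg, method="top3")


def count_mw_quant(tbl: PeptideTable) -> AbundanceSet:
    """log2(confident peptide count / molecular weight), an emPAI-like index."""
    pep = _confident(tbl)
    key = ["protein_id"] + _SAMPLE_KEY
    agg = pep.groupby(key, sort=True).size().rename("n_peptides").reset_index()
    mw = tbl.protein_mw.reindex(agg["protein_id"]).to_numpy()
    if np.isnan(mw).any():
        missing = sorted(set(agg.loc[np.isnan(mw), "protein_id"]))
        raise ValueError(f"no molecular weight for proteins {missing[:5]}...")
    agg["abundance"] = np.log2(agg["n_peptides"] / mw)
    return AbundanceSet(values=agg, method="count_mw")


def median_normalize(aset: AbundanceSet) -> AbundanceSet:
    """Centre each (sample, gel fraction) set on its median abundance."""
    if aset.normalized:
        raise ValueError("abundance set already normalized")
    if len(aset.values) == 0:
        raise ValueError("cannot normalize an empty abundance set")
    vals = aset.values.copy()
    vals["abundance"] = vals["abundance"] - vals.groupby(_SAMPLE_KEY)["abundance"].transform("median")
    return AbundanceSet(values=vals, method=aset.method, normalized=True)


def combine_count_sets(bait: AbundanceSet, remainder: AbundanceSet) -> AbundanceSet:
    """Average the two normalized count-based gel-fraction sets per protein/sample."""
    for a in (bait, remainder):
        if a.method != "count_mw":
            raise ValueError(f"combine_count_sets expects count_mw sets, got {a.method}")
        if not a.normalized:
            raise ValueError("normalize before combining")
    both = pd.concat([bait.values, remainder.values], ignore_index=True)
    key = ["protein_id", "strain", "replicate"]
    agg = both.groupby(key, sort=True).agg(
        abundance=("abundance", "mean"), n_peptides=("n_peptides", "sum")
    ).reset_index()
    agg["gel_set"] = "combined"
    return AbundanceSet(values=agg, method="count_mw", normalized=True)


def quantify_all(tbl: PeptideTable) -> dict[str, AbundanceSet]:
    """The full quantification layer: three normalized sets per dataset.

    Returns {"top3_bait", "top3_remainder", "count_combined"}; intensity
    sets are kept per gel fraction, count sets are combined.
    """
    top3 = median_normalize(top3_quant(tbl))
    counts = median_normalize(count_mw_quant(tbl))

    def _split(aset: AbundanceSet, gel: str) -> AbundanceSet:
        return AbundanceSet(
            values=aset.values[aset.values["gel_set"] == gel].reset_index(drop=True),
            method=aset.method,
            normalized=True,
        )

    out = {
        "top3_bait": _split(top3, "bait"),
        "top3_remainder": _split(top3, "remainder"),
        "count_combined": combine_count_sets(_split(counts, "bait"), _split(counts, "remainder")),
    }
    return out


def _pivot(aset: AbundanceSet) -> pd.DataFrame:
    """(protein, strain) x replicate abundance matrix."""
    return aset.values.pivot_table(
        index=["protein_id", "strain"], columns="replicate", values="abundance", aggfunc="mean"
    )


def enrichment_test(
    aset: AbundanceSet,
    tagged_strain: str,
    untagged_strain: str = "untagged",
    min_reps: int = 2,
    equal_var: bool = True,
    impute_quantile: float = 0.05,
    method_label: str | None = None,
) -> pd.DataFrame:
    """Per-protein tagged-vs-untagged enrichment on normalized abundances.

    Proteins with fewer than ``min_reps`` replicate values in the tagged
    strain are excluded.  When the untagged strain also has >= ``min_reps``
    values a two-sample Student's t-test (equal variance by default) is
    run; proteins absent (or nearly absent) from the untagged control are
    compared against a floor imputed at the ``impute_quantile`` of all
    untagged abundances in the set, flagged ``imputed``.  No
    multiple-testing correction is applied, by design.
    """
    if not aset.normalized:
        raise ValueError("run median_normalize before testing")
    mat = _pivot(aset)
    strains = mat.index.get_level_values("strain")
    if tagged_strain not in set(strains):
        raise ValueError(f"strain {tagged_strain!r} absent from abundance set")
    untagged_all = aset.values.loc[aset.values["strain"] == untagged_strain, "abundance"]
    floor = float(untagged_all.quantile(impute_quantile)) if len(untagged_all) else 0.0

    rows = []
    tagged_mat = mat.xs(tagged_strain, level="strain")
    for protein, trow in tagged_mat.iterrows():
        tvals = trow.dropna().to_numpy()
        if len(tvals) < min_reps:
            continue
        try:
            uvals = mat.loc[(protein, untagged_strain)].dropna().to_numpy()
        except KeyError:
            uvals = np.array([])
        imputed = len(uvals) < min_reps
        if imputed:
            ref = max(float(np.mean(uvals)), floor) if len(uvals) else floor
            t_stat, p = stats.ttest_1samp(tvals, ref)
            mean_untagged = ref
        else:
            t_stat, p = stats.ttest_ind(tvals, uvals, equal_var=equal_var)
            mean_untagged = float(np.mean(uvals))
        rows.append(
            {
                "protein_id": protein,
                "strain": tagged_strain,
                "method": method_label or aset.method,
                "n_tagged": len(tvals),
                "n_untagged": len(uvals),
                "mean_tagged": float(np.mean(tvals)),
                "mean_untagged": mean_untagged,
                "mean_log2_ratio": float(np.mean(tvals)) - mean_untagged,
                "t_stat": float(t_stat),
                "p_value": float(p),
                "imputed": imputed,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    """Funnel output: per-protein/strain/method tests plus the final flags."""

    tests: pd.DataFrame
    flags: pd.DataFrame  # index protein_id; reproducibly_enriched_<strain>, preferential
    preferential: list[str] = field(default_factory=list)


def preferential_filter(
    results: pd.DataFrame,
    osmo_strains: tuple[str, str] = ("GPD1", "STL1"),
    control_strains: tuple[str, ...] = ("ASH1", "HYP2"),
    p_thresh: float = 0.05,
    repro_log2: float = 1.0,
    pref_log2: float = 1.5,
    method_mode: str = "either",
    floors: dict[str, float] | None = None,
) -> EnrichmentResult:
    """Apply the funnel's reproducible and preferential enrichment criteria.

    ``results`` concatenates ``enrichment_test`` output over all tagged
    strains and quantification methods.  A protein is reproducibly
    enriched in a strain if any method gives mean log2 ratio >
    ``repro_log2`` (2-fold) with p < ``p_thresh``.  It is preferential if,
    within one method ("either", default) or every method ("both"), both
    osmo-mRNA strains are significant with log2 ratio > ``pref_log2``
    (3-fold) over the untagged strain AND over each control-mRNA strain.
    Proteins undetected in a control strain compare against that method's
    imputed floor (``floors``), or the untagged reference when no floor is
    given.
    """
    needed = set(osmo_strains) | set(control_strains)
    have = set(results["strain"])
    if not needed <= have:
        raise ValueError(f"missing strains in results: {sorted(needed - have)}")
    floors = floors or {}
    proteins = sorted(set(results["protein_id"]))
    methods = sorted(set(results["method"]))
    idx = results.set_index(["protein_id", "strain", "method"]).sort_index()

    def _get(protein: str, strain: str, method: str, col: str):
        try:
            return idx.loc[(protein, strain, method), col]
        except KeyError:
            return np.nan

    flags = pd.DataFrame(index=pd.Index(proteins, name="protein_id"))
    for strain in sorted(have):
        col = []
        for protein in proteins:
            ok = False
            for method in methods:
                ratio = _get(protein, strain, method, "mean_log2_ratio")
                p = _get(protein, strain, method, "p_value")
                if np.isfinite(ratio) and np.isfinite(p) and ratio > repro_log2 and p < p_thresh:
                    ok = True
                    break
            col.append(ok)
        flags[f"reproducibly_enriched_{strain}"] = col

    pref = []
    for protein in proteins:
        per_method = []
        for method in methods:
            ok = True
            for strain in osmo_strains:
                ratio = _get(protein, strain, method, "mean_log2_ratio")
                p = _get(protein, strain, method, "p_value")
                if not (np.isfinite(ratio) and np.isfinite(p) and ratio > pref_log2 and p < p_thresh):
                    ok = False
                    break
                mean_osmo = _get(protein, strain, method, "mean_tagged")
                for ctrl in control_strains:
                    mean_ctrl = _get(protein, ctrl, method, "mean_tagged")
                    if not np.isfinite(mean_ctrl):
                        mean_ctrl = floors.get(method, _get(protein, strain, method, "mean_untagged"))
                    if not (mean_osmo - mean_ctrl > pref_log2):
                        ok = False
                        break
                if not ok:
                    break
            per_method.append(ok)
        pref.append(any(per_method) if method_mode == "either" else all(per_method))
    flags["preferential"] = pref
    preferential = [p for p, f in zip(proteins, pref) if f]
    return EnrichmentResult(tests=results, flags=flags, preferential=preferential)


def run_enrichment_funnel(
    tbl: PeptideTable,
    tagged_strains: tuple[str, ...] = ("GPD1", "STL1", "ASH1", "HYP2"),
    untagged_strain: str = "untagged",
    osmo_strains: tuple[str, str] = ("GPD1", "STL1"),
    control_strains: tuple[str, ...] = ("ASH1", "HYP2"),
    min_reps: int = 2,
    p_thresh: float = 0.05,
    repro_log2: float = 1.0,
    pref_log2: float = 1.5,
    method_mode: str = "either",
    equal_var: bool = True,
) -> EnrichmentResult:
    """End-to-end funnel: quantify, normalize, combine, test, filter."""
    sets = quantify_all(tbl)
    all_tests = []
    floors = {}
    for label, aset in sets.items():
        untagged_vals = aset.values.loc[aset.values["strain"] == untagged_strain, "abundance"]
        floors[label] = float(untagged_vals.quantile(0.05)) if len(untagged_vals) else 0.0
        for strain in tagged_strains:
            all_tests.append(
                enrichment_test(
                    aset,
                    tagged_strain=strain,
                    untagged_strain=untagged_strain,
                    min_reps=min_reps,
                    equal_var=equal_var,
                    method_label=label,
                )
            )
    results = pd.concat(all_tests, ignore_index=True)
    return preferential_filter(
        results,
        osmo_strains=osmo_strains,
        control_strains=control_strains,
        p_thresh=p_thresh,
        repro_log2=repro_log2,
        pref_log2=pref_log2,
        method_mode=method_mode,
        floors=floors,
    )
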