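"""Genotype/condition comparison of 5'-UTR ribosome loading.

Per-gene scores quantify how much more 5'P protection a mutant shows in
the 5'UTR than wild type: score = log2 loading ratio (mutant) - log2
loading ratio (wt), i.e. the log2 fold change of the raw window ratios.
Distribution summaries (ECDF, median increments) and a Mann-Whitney U
test against a gene subset (e.g. osmotic-stress-responsive transcripts)
ask whether specific gene sets shift more than the bulk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreTable",
    "DistributionSummary",
    "MannWhitneyResult",
    "genotype_score",
    "cumulative_summary",
    "median_increment",
    "subset_shift_test",
    "rank_for_go",
    "load_gene_set",
]


@dataclass
class ScoreTable:
    """Per-gene mutant-vs-wt score for one loading ratio.

    Defined only on genes passing the read filter in BOTH strains.
    """

    scores: pd.Series  # index gene_id, float values
    ratio_name: str
    strain_pair: tuple[str, str] = ("mutant", "wt")
    condition: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        df = self.scores.rename("score").to_frame()
        df.index.name = "gene_id"
        return df


@dataclass
class DistributionSummary:
    """Right-continuous ECDF plus median of a score distribution."""

    support: np.ndarray  # sorted unique values
    ecdf: np.ndarray  # P(X <= support[i]), nondecreasing, ends at 1
    median: float
    n: int

    def delta_median(self, reference: "DistributionSummary") -> float:
        return self.median - reference.median


@dataclass
class MannWhitneyResult:
    u_statistic: float
    n1: int
    n2: int
    p_value: float
    method: str  # "exact" or "normal-approx"
    alternative: str = "two-sided"


def _common_passing(lt_mut: pd.DataFrame, lt_wt: pd.DataFrame, ratio_name: str) -> pd.Index:
    if ratio_name not in lt_mut.columns or ratio_name not in lt_wt.columns:
        raise KeyError(f"ratio {ratio_name!r} not present in both loading tables")
    mut_pass = lt_mut.index[lt_mut[f"{ratio_name}_pass"]]
    wt_pass = lt_wt.index[lt_wt[f"{ratio_name}_pass"]]
    common = mut_pass.intersection(wt_pass)
    if len(common) == 0:
        raise ValueError("no gene passes the filter in both strains")
    return common


def genotype_score(
    lt_mut: pd.DataFrame,
    lt_wt: pd.DataFrame,
    ratio_name: str = "uSvsdS",
    strain_pair: tuple[str, str] = ("mutant", "wt"),
    condition: str = "",
) -> ScoreTable:
    """Per-gene score = loading(mutant) - loading(wt) on the common passing set.

    Equals log2 of the fold change of the raw window ratios, so a score of
    1.0 means twice as much relative 5'UTR protection in the mutant.
    """
    common = _common_passing(lt_mut, lt_wt, ratio_name)
    scores = (lt_mut.loc[common, ratio_name] - lt_wt.loc[common, ratio_name]).sort_index()
    return ScoreTable(scores=scores, ratio_name=ratio_name, strain_pair=strain_pair, condition=condition)


def cumulative_summary(values: Iterable[float]) -> DistributionSummary:
    """ECDF and median of a non-empty collection of scores.

    The median follows the standard midpoint convention (mean of the two
    central order statistics for even n).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cumulative_summary requires non-empty input")
    if np.isnan(arr).any():
        raise ValueError("NaN in scores; filter before summarizing")
    support, counts = np.unique(arr, return_counts=True)
    ecdf = np.cumsum(counts) / arr.size
    return DistributionSummary(support=support, ecdf=ecdf, median=float(np.median(arr)), n=arr.size)


def median_increment(
    lt_mut: pd.DataFrame, lt_wt: pd.DataFrame, ratio_name: str = "uSvsdS"
) -> float:
    """Difference of loading-ratio medians, mutant minus wt, on the common passing set.

    This is the increment of the cumulative-distribution medians; it equals
    the median of per-gene scores only for symmetric distributions, so the
    two are reported separately.
    """
    common = _common_passing(lt_mut, lt_wt, ratio_name)
    return float(
        np.median(lt_mut.loc[common, ratio_name]) - np.median(lt_wt.loc[common, ratio_name])
    )


def subset_shift_test(
    scores: ScoreTable,
    subset: Iterable[str],
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> MannWhitneyResult:
    """Mann-Whitney U test: scores of ``subset`` genes vs all other scored genes.

    Uses the exact null distribution when the smaller group has at most
    ``exact_max_n`` members and there are no ties, otherwise the normal
    approximation with tie and continuity corrections.  U is reported for
    the subset group.
    """
    subset = set(subset)
    s = scores.scores
    in_subset = s.index.isin(subset)
    x = s[in_subset].to_numpy()
    y = s[~in_subset].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("subset and complement must both be non-empty within the score table")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # zero rank variance: no evidence of any shift
        return MannWhitneyResult(
            u_statistic=len(x) * len(y) / 2.0, n1=len(x), n2=len(y),
            p_value=1.0, method="exact", alternative=alternative,
        )
    has_ties = len(np.unique(pooled)) < len(x) + len(y)
    if min(len(x), len(y)) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        n1=len(x),
        n2=len(y),
        p_value=float(res.pvalue),
        method="exact" if method == "exact" else "normal-approx",
        alternative=alternative,
    )


def rank_for_go(scores: ScoreTable) -> pd.DataFrame:
    """Genes ranked by descending score, ties broken by gene_id.

    The 2-column output (gene_id, score) feeds external GO enrichment
    tools; enrichment itself is out of scope.
    """
    if scores.n_genes == 0:
        raise ValueError("empty score table")
    df = scores.to_frame().reset_index()
    df = df.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def load_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and #-comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
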