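#!/usr/bin/env python
"""Mutant-vs-wt 5'UTR ribosome accumulation and the OSR subset test.

Computes per-gene scores (log2 fold change of the uSvsdS loading ratio),
the increment of the cumulative-distribution medians, a ranked gene list
for external GO tools, and the Mann-Whitney test asking whether
osmostress-responsive (OSR) transcripts shift more than the bulk.
"""

import json
from pathlib import Path

import pandas as pd

from fivepdecay import compare

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "compare"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lt = {
        label: pd.read_csv(BASE / "windows" / f"loading_{label}.tsv", sep="\t", index_col=0)
        for label in ("wt", "mutant", "mutant_osr")
    }
    osr = compare.load_gene_set(BASE / "degradome" / "osr_genes.txt")

    summary = {}
    for label in ("mutant", "mutant_osr"):
        scores = compare.genotype_score(lt[label], lt["wt"], "uSvsdS", strain_pair=(label, "wt"))
        scores.to_frame().to_csv(OUT / f"scores_{label}.tsv", sep="\t")
        compare.rank_for_go(scores).to_csv(OUT / f"ranked_{label}.tsv", sep="\t", index=False)
        dm = compare.median_increment(lt[label], lt["wt"], "uSvsdS")
        mw = compare.subset_shift_test(scores, osr)
        summary[label] = {
            "n_genes": scores.n_genes,
            "delta_median_uSvsdS": dm,
            "osr_mann_whitney": {"U": mw.u_statistic, "n_osr": mw.n1, "n_rest": mw.n2,
                                 "p_value": mw.p_value, "method": mw.method},
        }
        print(f"{label} vs wt: {scores.n_genes} genes scored, Δmedian = {dm:+.3f}, "
              f"OSR Mann-Whitney p = {mw.p_value:.2e}")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
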