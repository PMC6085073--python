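#!/usr/bin/env python
"""MS2 RNP pull-down proteomics: spiked simulation through the Table-2-style funnel.

Simulates peptide tables for four MS2L-tagged mRNA strains plus an
untagged control, with ten proteins truly enriched on the two osmo-mRNA
baits, then runs the label-free funnel (top-3 and count/MW quantification,
median normalization, >=2-replicate Student's t-tests, 2-fold and 3-fold
filters) and reports how many spiked proteins it recovers.
"""

from pathlib import Path

from fivepdecay import msquant
from fivepdecay.synthetic_data import simulate_ms_dataset

SEED = 20180914
OUT = Path(__file__).resolve().parent.parent / "results" / "msquant"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tbl, enriched = simulate_ms_dataset(
        n_proteins=500, n_enriched=10, n_replicates=3, effect_log2=3.0, seed=SEED
    )
    result = msquant.run_enrichment_funnel(tbl)
    result.tests.to_csv(OUT / "enrichment_tests.tsv", sep="\t", index=False)
    result.flags.to_csv(OUT / "enrichment_flags.tsv", sep="\t")
    (OUT / "preferential.txt").write_text("\n".join(result.preferential) + "\n")
    (OUT / "spiked_truth.txt").write_text("\n".join(enriched) + "\n")

    for strain in ("GPD1", "STL1", "ASH1", "HYP2"):
        n = int(result.flags[f"reproducibly_enriched_{strain}"].sum())
        print(f"reproducibly enriched (>2-fold, p<0.05) vs untagged in {strain}-MS2L: {n}")
    tp = set(result.preferential) & set(enriched)
    fp = set(result.preferential) - set(enriched)
    print(f"preferential on osmo-mRNAs (>3-fold in both, vs untagged and controls): "
          f"{len(result.preferential)} proteins; {len(tp)}/10 spiked recovered, "
          f"{len(fp)} false positive(s)")


if __name__ == "__main__":
    main()
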