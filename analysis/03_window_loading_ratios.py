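#!/usr/bin/env python
"""Window counts and 5'UTR loading ratios per library.

Counts 5'P reads in the 45-nt windows around the start (uS/dS/ddS) and
stop (uE/dE) codons, applies the >=20-read filter, and writes per-gene
log2 loading ratios for each simulated library.
"""

from pathlib import Path

from fivepdecay import reads, windows
from fivepdecay.annotation import load_transcript_models

BASE = Path(__file__).resolve().parent.parent / "results" / "degradome"
OUT = BASE.parent / "windows"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    txs = load_transcript_models(BASE / "transcripts.tsv", dialect="tsv")
    scheme = windows.WindowScheme()
    scheme.to_json(OUT / "scheme.json")
    for label in ("wt", "mutant", "mutant_osr"):
        cov = reads.CoverageTable.from_tsv(BASE / f"coverage_{label}.tsv", txs)
        wct = windows.window_counts(cov, txs, scheme)
        lt = windows.loading_ratios(wct, scheme)
        wct.join(lt).to_csv(OUT / f"loading_{label}.tsv", sep="\t")
        n_pass = int(lt["uSvsdS_pass"].sum())
        print(
            f"{label}: {n_pass}/{len(lt)} genes pass the {scheme.min_reads}-read uSvsdS filter; "
            f"median uSvsdS = {lt['uSvsdS'].median():+.3f}"
        )


if __name__ == "__main__":
    main()
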