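"""UMI handling, PCR deduplication and 5'P coverage tables.

5P-Seq libraries tag each captured molecule with a random unique molecular
identifier (UMI) before amplification; reads sharing the same 5' mapping
site and UMI are PCR copies of one molecule and are collapsed.  Surviving
5' end positions are tallied per transcript into a CoverageTable, raw or
scaled to reads per million (rpm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptSet, start_offset, stop_offset

logger = logging.getLogger(__name__)

__all__ = [
    "RawReadLibrary",
    "CoverageTable",
    "encode_umi",
    "decode_umi",
    "extract_umi",
    "extract_umis_fastq",
    "dedup_reads",
    "fivep_counts",
    "rpm_normalize",
    "load_reads_tsv",
    "load_bed_fivep",
    "load_sam_fivep",
]

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


def encode_umi(umi: str) -> int:
    """Pack an ACGT UMI into a base-4 integer."""
    code = 0
    for b in umi:
        code = code * 4 + _BASE_CODE[b]
    return code


def decode_umi(code: int, umi_len: int) -> str:
    out = []
    for _ in range(umi_len):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _decode_umi_array(codes: np.ndarray, umi_len: int) -> np.ndarray:
    """Vectorised integer->string UMI decoding."""
    n = len(codes)
    letters = np.empty((n, umi_len), dtype="U1")
    base = np.asarray(list(_BASES))
    c = codes.astype(np.int64).copy()
    for j in range(umi_len - 1, -1, -1):
        letters[:, j] = base[c % 4]
        c //= 4
    return letters.view(f"U{umi_len}").ravel() if umi_len else np.full(n, "", dtype="U1")


class RawReadLibrary:
    """5'P read records: (gene, 0-based transcript 5' position, UMI).

    Stored columnar (gene codes, positions, base-4-encoded UMIs) so that
    deduplication and counting stay vectorised.
    """

    def __init__(
        self,
        genes: Sequence[str],
        gene_idx: np.ndarray,
        pos: np.ndarray,
        umi: np.ndarray,
        umi_len: int,
    ) -> None:
        self.genes = list(genes)
        self.gene_idx = np.asarray(gene_idx, dtype=np.int64)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.umi = np.asarray(umi, dtype=np.int64)
        if not (len(self.gene_idx) == len(self.pos) == len(self.umi)):
            raise ValueError("column length mismatch")
        self.umi_len = int(umi_len)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, str]], umi_len: int | None = None
    ) -> "RawReadLibrary":
        genes: list[str] = []
        index: dict[str, int] = {}
        gi, pos, umi = [], [], []
        lens = set()
        for gene, p, u in records:
            if gene not in index:
                index[gene] = len(genes)
                genes.append(gene)
            gi.append(index[gene])
            pos.append(int(p))
            umi.append(encode_umi(u))
            lens.add(len(u))
        if umi_len is None:
            if len(lens) > 1:
                raise ValueError(f"non-uniform UMI lengths {sorted(lens)}")
            umi_len = lens.pop() if lens else 0
        elif lens - {umi_len}:
            raise ValueError(f"UMI lengths {sorted(lens)} != declared {umi_len}")
        return cls(genes, np.array(gi, dtype=np.int64), np.array(pos, dtype=np.int64),
                   np.array(umi, dtype=np.int64), umi_len)

    def __len__(self) -> int:
        return len(self.pos)

    def gene_ids(self) -> np.ndarray:
        return np.asarray(self.genes, dtype=object)[self.gene_idx]

    def umi_strings(self) -> np.ndarray:
        return _decode_umi_array(self.umi, self.umi_len)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids(),
                "five_prime_pos": self.pos,
                "umi": self.umi_strings(),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_reads_tsv(path: str | Path) -> RawReadLibrary:
    """Read a (gene_id, five_prime_pos, umi) TSV written by ``to_tsv``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "umi": str})
    return RawReadLibrary.from_records(
        zip(df["gene_id"], df["five_prime_pos"], df["umi"])
    )


def extract_umi(read: str, umi_len: int = 8) -> tuple[str, str]:
    """Split a raw read into its leading UMI and the alignable remainder.

    The first ``umi_len`` bases are the molecular identifier; at least one
    base must remain for alignment.
    """
    if len(read) <= umi_len:
        raise ValueError(f"read of length {len(read)} too short for umi_len={umi_len}")
    return read[:umi_len], read[umi_len:]


def extract_umis_fastq(
    in_fastq: str | Path, out_fastq: str | Path, umi_len: int = 8
) -> tuple[int, int]:
    """Trim leading UMIs off a FASTQ, appending each UMI to the read name.

    Writes umi_tools-style names (``<name>_<umi>``) so the UMI survives
    alignment.  Returns (n_written, n_skipped_too_short).
    """
    from Bio import SeqIO

    written = skipped = 0
    with open(out_fastq, "w") as out:
        for rec in SeqIO.parse(str(in_fastq), "fastq"):
            seq = str(rec.seq)
            if len(seq) <= umi_len:
                skipped += 1
                continue
            umi, rest = extract_umi(seq, umi_len)
            quals = rec.letter_annotations["phred_quality"][umi_len:]
            out.write(f"@{rec.id}_{umi}\n{rest}\n+\n")
            out.write("".join(chr(q + 33) for q in quals) + "\n")
            written += 1
    if skipped:
        logger.info("extract_umis_fastq: skipped %d reads shorter than %d+1 nt", skipped, umi_len)
    return written, skipped


def dedup_reads(lib: RawReadLibrary) -> RawReadLibrary:
    """Collapse PCR duplicates: one record per (gene, 5' site, UMI).

    Idempotent; output order is sorted by (gene, position, UMI).
    """
    if len(lib) == 0:
        return RawReadLibrary(lib.genes, lib.gene_idx, lib.pos, lib.umi, lib.umi_len)
    stacked = np.stack([lib.gene_idx, lib.pos, lib.umi], axis=1)
    uniq = np.unique(stacked, axis=0)
    return RawReadLibrary(lib.genes, uniq[:, 0], uniq[:, 1], uniq[:, 2], lib.umi_len)


@dataclass
class CoverageTable:
    """Per-gene 5'P end counts over transcript positions.

    ``counts[gene]`` is a dense vector of length ``tx_length``; scale is
    "raw" (integers summing to ``library_size``) or "rpm".
    """

    counts: dict[str, np.ndarray]
    library_size: int
    scale: str = "raw"
    n_dropped: int = 0

    def total(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def to_frame(self, txs: TranscriptSet, keep_zeros: bool = False) -> pd.DataFrame:
        rows = []
        for gene, vec in self.counts.items():
            tx = txs[gene]
            positions = np.arange(len(vec))
            mask = np.ones(len(vec), bool) if keep_zeros else vec > 0
            for p, c in zip(positions[mask], vec[mask]):
                rows.append(
                    (gene, int(p), start_offset(tx, int(p)), stop_offset(tx, int(p)), c)
                )
        return pd.DataFrame(
            rows, columns=["gene_id", "position", "offset_from_start", "offset_from_stop", "count"]
        )

    def to_tsv(self, path: str | Path, txs: TranscriptSet) -> None:
        with open(path, "w") as fh:
            fh.write(f"# scale={self.scale}\tlibrary_size={self.library_size}\n")
            self.to_frame(txs).to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, txs: TranscriptSet) -> "CoverageTable":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                item.split("=") for item in header.lstrip("# ").strip().split("\t")
            )
            df = pd.read_csv(fh, sep="\t", dtype={"gene_id": str})
        counts = {g: np.zeros(txs[g].tx_length) for g in txs.gene_ids}
        for gene, pos, c in zip(df["gene_id"], df["position"], df["count"]):
            counts[gene][int(pos)] += c
        return cls(counts, library_size=int(meta["library_size"]), scale=meta["scale"])


def fivep_counts(lib: RawReadLibrary, txs: TranscriptSet) -> CoverageTable:
    """Tally deduplicated 5'P end positions per gene.

    Reads on genes absent from the annotation, or at positions outside the
    transcript, are dropped and counted in ``n_dropped``.
    """
    gene_ids = txs.gene_ids
    lengths = np.array([txs[g].tx_length for g in gene_ids], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # remap library gene codes onto the annotation's gene order
    remap = np.array([gene_pos.get(g, -1) for g in lib.genes], dtype=np.int64)
    if len(lib) == 0:
        counts = {g: np.zeros(l, dtype=np.float64) for g, l in zip(gene_ids, lengths)}
        return CoverageTable(counts, library_size=0)
    gi = remap[lib.gene_idx]
    known = gi >= 0
    in_range = np.zeros(len(lib), dtype=bool)
    in_range[known] = (lib.pos[known] >= 0) & (lib.pos[known] < lengths[gi[known]])
    keep = known & in_range
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("fivep_counts: dropped %d reads (unknown gene or out of range)", n_dropped)

    flat = offsets[gi[keep]] + lib.pos[keep]
    binned = np.bincount(flat, minlength=int(offsets[-1])).astype(np.float64)
    counts = {
        g: binned[offsets[i] : offsets[i + 1]] for i, g in enumerate(gene_ids)
    }
    return CoverageTable(counts, library_size=int(keep.sum()), n_dropped=n_dropped)


def rpm_normalize(cov: CoverageTable) -> CoverageTable:
    """Scale raw counts to reads per million of the deduplicated library."""
    if cov.scale != "raw":
        raise ValueError(f"expected raw coverage, got scale={cov.scale!r}")
    if cov.library_size == 0:
        raise ValueError("cannot rpm-normalize an empty library")
    factor = 1e6 / cov.library_size
    return CoverageTable(
        {g: v * factor for g, v in cov.counts.items()},
        library_size=cov.library_size,
        scale="rpm",
        n_dropped=cov.n_dropped,
    )


def load_bed_fivep(path: str | Path) -> RawReadLibrary:
    """Read transcript-space BED6 5'-end intervals (name column = UMI)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    return RawReadLibrary.from_records(zip(df["chrom"], df["start"], df["name"]))


def load_sam_fivep(
    path: str | Path,
    txs: TranscriptSet,
    mapq_min: int = 1,
    umi_sep: str = "_",
) -> RawReadLibrary:
    """Extract 5'P positions from aligned reads (SAM/BAM).

    Primary alignments with MAPQ >= ``mapq_min`` only; the UMI is taken
    from the read name after the last ``umi_sep`` (umi_tools convention).
    The biological 5' end is the leftmost reference base for forward
    alignments and the rightmost for reverse alignments, projected through
    the transcript layouts (minus-strand genes flip orientation).
    """
    import pysam

    if not txs.layouts:
        raise ValueError("TranscriptSet has no genomic layouts; load from GTF/GFF3")
    by_chrom: dict[str, list] = {}
    for gid, layout in txs.layouts.items():
        by_chrom.setdefault(layout.chrom, []).append(layout)

    records: list[tuple[str, int, str]] = []
    dropped = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for aln in fh:
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.mapping_quality < mapq_min
            ):
                dropped += 1
                continue
            g5 = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            read_strand = "-" if aln.is_reverse else "+"
            umi = aln.query_name.rsplit(umi_sep, 1)[-1]
            hit = None
            for layout in by_chrom.get(aln.reference_name, []):
                if layout.strand != read_strand:
                    continue
                tpos = layout.genomic_to_transcript(g5)
                if tpos is not None:
                    hit = (layout.gene_id, tpos, umi)
                    break
            if hit is None:
                dropped += 1
                continue
            records.append(hit)
    if dropped:
        logger.info("load_sam_fivep: dropped %d alignments", dropped)
    return RawReadLibrary.from_records(records)
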