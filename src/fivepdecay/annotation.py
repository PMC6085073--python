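"""Transcript coordinate model and annotation I/O.

Every downstream analysis (coverage, metagene profiles, window counts)
anchors positions to the start or stop codon of a transcript.  This module
defines that single coordinate convention:

* transcript positions are 0-based, 5' -> 3';
* ``start_offset`` 0 is the first nucleotide of the start codon, so the
  canonical initiation-paused 5'P end sits at offset -14;
* ``stop_offset`` 0 is the first nucleotide of the stop codon, so the
  termination-paused 5'P end sits at offset -17;
* the CDS length includes the stop codon.

Annotations are read from Ensembl-dialect GTF/GFF3 (1-based inclusive
genomic coordinates, strand-aware, exons concatenated in transcript
orientation) or from a simple 4-column TSV of region lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "TranscriptLayout",
    "TranscriptSet",
    "AnnotationError",
    "AnnotationFormatError",
    "EmptyAnnotationError",
    "load_transcript_models",
    "start_offset",
    "stop_offset",
]


class AnnotationError(ValueError):
    """Base class for annotation problems."""


class AnnotationFormatError(AnnotationError):
    """The annotation file could not be parsed in the requested dialect."""


class EmptyAnnotationError(AnnotationError):
    """No transcript in the file satisfied the model invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """Per-gene coordinate frame: 5'UTR / CDS (stop-inclusive) / 3'UTR.

    Invariants: region lengths sum to ``tx_length``; the CDS is at least
    two codons (start + stop) and a multiple of 3.
    """

    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise AnnotationError("gene_id must be non-empty")
        for name in ("utr5_len", "cds_len", "utr3_len"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise AnnotationError(f"{self.gene_id}: {name} must be a nonnegative integer, got {v!r}")
        if self.cds_len < 6:
            raise AnnotationError(f"{self.gene_id}: cds_len {self.cds_len} < 6")
        if self.cds_len % 3 != 0:
            raise AnnotationError(f"{self.gene_id}: cds_len {self.cds_len} not a multiple of 3")

    @property
    def tx_length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def start_pos(self) -> int:
        """Transcript position of the first nucleotide of the start codon."""
        return self.utr5_len

    @property
    def stop_pos(self) -> int:
        """Transcript position of the first nucleotide of the stop codon."""
        return self.utr5_len + self.cds_len - 3


def start_offset(tx: TranscriptModel, tx_pos: int) -> int:
    """Offset of ``tx_pos`` relative to the first nucleotide of the start codon.

    Negative offsets lie in the 5'UTR; the initiation-paused ribosome leaves
    its 5'P boundary at offset -14.
    """
    if not 0 <= tx_pos < tx.tx_length:
        raise AnnotationError(f"{tx.gene_id}: position {tx_pos} outside [0, {tx.tx_length})")
    return tx_pos - tx.utr5_len


def stop_offset(tx: TranscriptModel, tx_pos: int) -> int:
    """Offset of ``tx_pos`` relative to the first nucleotide of the stop codon."""
    if not 0 <= tx_pos < tx.tx_length:
        raise AnnotationError(f"{tx.gene_id}: position {tx_pos} outside [0, {tx.tx_length})")
    return tx_pos - tx.stop_pos


@dataclass
class TranscriptLayout:
    """Genomic placement of a transcript: chrom, strand and exon blocks.

    Exons are (start, end) 1-based inclusive genomic intervals in genomic
    order.  Transcript coordinates concatenate the exons in transcript
    orientation (reversed for minus-strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tx_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a 0-based genomic position to a 0-based transcript position.

        Returns None if the position falls outside every exon.
        """
        g1 = gpos + 1
        acc = 0
        exons = self.exons if self.strand == "+" else list(reversed(self.exons))
        for s, e in exons:
            if s <= g1 <= e:
                if self.strand == "+":
                    return acc + (g1 - s)
                return acc + (e - g1)
            acc += e - s + 1
        return None


class TranscriptSet:
    """Mapping of gene_id -> TranscriptModel, optionally with genomic layouts."""

    def __init__(
        self,
        records: Mapping[str, TranscriptModel] | None = None,
        layouts: Mapping[str, TranscriptLayout] | None = None,
    ) -> None:
        self.records: dict[str, TranscriptModel] = dict(records or {})
        self.layouts: dict[str, TranscriptLayout] = dict(layouts or {})

    def add(self, tx: TranscriptModel, layout: TranscriptLayout | None = None) -> None:
        if tx.gene_id in self.records:
            raise AnnotationError(f"duplicate gene_id {tx.gene_id}")
        self.records[tx.gene_id] = tx
        if layout is not None:
            self.layouts[tx.gene_id] = layout

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.records.values())

    def __getitem__(self, gene_id: str) -> TranscriptModel:
        return self.records[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TranscriptSet) and self.records == other.records

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [t.gene_id for t in self],
                "utr5_len": [t.utr5_len for t in self],
                "cds_len": [t.cds_len for t in self],
                "utr3_len": [t.utr3_len for t in self],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gtf",):
        return "gtf"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    if suffix in (".tsv", ".txt", ".csv"):
        return "tsv"
    raise AnnotationFormatError(f"cannot infer annotation dialect from {path.name}")


def load_transcript_models(
    path: str | Path,
    dialect: str | None = None,
    transcript_choice: str = "first",
) -> TranscriptSet:
    """Load transcript models from a GTF/GFF3 or length-table TSV.

    Transcripts violating the model invariants are skipped with a logged
    reason.  When a gene has several transcripts, one is kept according to
    ``transcript_choice`` ("first" in file order, or "longest").

    Raises AnnotationFormatError for unparseable input and
    EmptyAnnotationError if no transcript survives validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "tsv":
        return _load_tsv(path)
    if dialect in ("gtf", "gff3"):
        return _load_gxf(path, dialect, transcript_choice)
    raise AnnotationFormatError(f"unknown dialect {dialect!r}")


def _load_tsv(path: Path) -> TranscriptSet:
    try:
        df = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise AnnotationFormatError(f"cannot parse {path}: {exc}") from exc
    required = {"gene_id", "utr5_len", "cds_len", "utr3_len"}
    if not required.issubset(df.columns):
        raise AnnotationFormatError(
            f"{path}: TSV dialect requires columns {sorted(required)}, got {list(df.columns)}"
        )
    txs = TranscriptSet()
    for row in df.itertuples(index=False):
        try:
            txs.add(
                TranscriptModel(
                    gene_id=str(row.gene_id).strip(),
                    utr5_len=int(row.utr5_len),
                    cds_len=int(row.cds_len),
                    utr3_len=int(row.utr3_len),
                )
            )
        except (AnnotationError, TypeError) as exc:
            logger.warning("skipping transcript: %s", exc)
    if len(txs) == 0:
        raise EmptyAnnotationError(f"{path}: no valid transcripts")
    return txs


def _load_gxf(path: Path, dialect: str, transcript_choice: str) -> TranscriptSet:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise AnnotationFormatError(f"cannot parse {path} as {dialect}: {exc}") from exc

    # Group exon / CDS / stop_codon features by transcript id; this copes
    # with minimal GTFs lacking explicit transcript records.
    groups: dict[str, dict[str, list]] = {}
    order: list[str] = []
    gene_of: dict[str, str] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        if dialect == "gtf":
            tid = feat.attributes.get("transcript_id", [None])[0]
            gid = feat.attributes.get("gene_id", [tid])[0]
        else:
            parents = feat.attributes.get("Parent", [None])
            tid = parents[0]
            gid = feat.attributes.get("gene_id", [tid])[0]
        if tid is None:
            logger.warning("skipping %s feature without transcript id", feat.featuretype)
            continue
        if tid not in groups:
            groups[tid] = {"exon": [], "CDS": [], "stop_codon": []}
            order.append(tid)
            gene_of[tid] = gid or tid
        groups[tid][feat.featuretype].append(feat)

    if not groups:
        raise AnnotationFormatError(f"{path}: no exon/CDS features found")

    candidates: dict[str, list[tuple[TranscriptModel, TranscriptLayout]]] = {}
    for tid in order:
        feats = groups[tid]
        if not feats["exon"] or not feats["CDS"]:
            logger.warning("skipping %s: missing exon or CDS features", tid)
            continue
        try:
            model, layout = _assemble_transcript(tid, gene_of[tid], feats)
        except AnnotationError as exc:
            logger.warning("skipping %s: %s", tid, exc)
            continue
        candidates.setdefault(gene_of[tid], []).append((model, layout))

    txs = TranscriptSet()
    for gid, cands in candidates.items():
        if transcript_choice == "longest":
            model, layout = max(cands, key=lambda ml: ml[0].tx_length)
        else:
            model, layout = cands[0]
        txs.add(model, layout)
    if len(txs) == 0:
        raise EmptyAnnotationError(f"{path}: no valid transcripts")
    return txs


def _assemble_transcript(tid: str, gid: str, feats: dict) -> tuple[TranscriptModel, TranscriptLayout]:
    exons = sorted(((f.start, f.end) for f in feats["exon"]))
    strands = {f.strand for f in feats["exon"]} | {f.strand for f in feats["CDS"]}
    if len(strands) != 1 or strands & {".", "?"}:
        raise AnnotationError(f"inconsistent or missing strand {strands}")
    strand = strands.pop()
    chroms = {f.seqid for f in feats["exon"]}
    if len(chroms) != 1:
        raise AnnotationError(f"exons on multiple sequences {chroms}")
    layout = TranscriptLayout(gene_id=gid, chrom=chroms.pop(), strand=strand, exons=exons)

    tx_length = layout.tx_length
    cds_len = sum(f.end - f.start + 1 for f in feats["CDS"])
    # Ensembl GTF excludes the stop codon from CDS and emits stop_codon
    # features; when present, fold them back in (our CDS is stop-inclusive).
    if feats["stop_codon"]:
        cds_len += sum(f.end - f.start + 1 for f in feats["stop_codon"])

    if strand == "+":
        cds_first = min(f.start for f in feats["CDS"]) - 1
    else:
        cds_first = max(f.end for f in feats["CDS"]) - 1
    utr5_len = layout.genomic_to_transcript(cds_first)
    if utr5_len is None:
        raise AnnotationError("CDS start not contained in exons")
    utr3_len = tx_length - utr5_len - cds_len
    if utr3_len < 0:
        raise AnnotationError(f"negative 3'UTR length ({utr3_len})")
    model = TranscriptModel(gene_id=gid, utr5_len=utr5_len, cds_len=cds_len, utr3_len=utr3_len)
    return model, layout
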