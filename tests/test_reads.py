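"""UMI extraction, deduplication and coverage-table behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fivepdecay import reads
from fivepdecay.reads import (
    CoverageTable,
    RawReadLibrary,
    dedup_reads,
    decode_umi,
    encode_umi,
    extract_umi,
    fivep_counts,
    rpm_normalize,
)
from fivepdecay.synthetic_data import DegradomeSimConfig, simulate_degradome


def test_extract_umi_takes_first_eight_bases():
    umi, rest = extract_umi("ACGTACGTTTTTGGG")
    assert umi == "ACGTACGT" and rest == "TTTTGGG"


def test_extract_umi_zero_length_is_identity():
    assert extract_umi("ACGT", umi_len=0) == ("", "ACGT")


def test_extract_umi_boundary_read_rejected():
    with pytest.raises(ValueError):
        extract_umi("ACGTACGT", umi_len=8)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=12))
def test_umi_codec_round_trip(umi):
    assert decode_umi(encode_umi(umi), len(umi)) == umi


def _lib(records):
    return RawReadLibrary.from_records(records)


def test_dedup_identity_on_distinct_records():
    lib = _lib([("G1", 5, "AAAA"), ("G1", 5, "AAAC"), ("G2", 5, "AAAA")])
    assert len(dedup_reads(lib)) == 3


def test_dedup_collapses_pcr_copies_and_is_idempotent():
    lib = _lib([("G1", 5, "AAAA")] * 3 + [("G1", 7, "AAAA")])
    once = dedup_reads(lib)
    assert len(once) == 2
    twice = dedup_reads(once)
    assert twice.to_frame().equals(once.to_frame())


def test_dedup_recovers_simulator_truth_in_distinct_umi_mode():
    cfg = DegradomeSimConfig(n_genes=30, n_reads=5000, distinct_umis=True, pcr_dup_mean=2.0, seed=3)
    _, lib, truth = simulate_degradome(cfg)
    assert len(lib) > truth.n_unique  # PCR inflated
    deduped = dedup_reads(lib)
    assert len(deduped) == truth.n_unique
    lhs = deduped.to_frame().sort_values(["gene_id", "five_prime_pos", "umi"]).reset_index(drop=True)
    rhs = truth.unique_molecules.sort_values(["gene_id", "five_prime_pos", "umi"]).reset_index(drop=True)
    assert lhs.equals(rhs)


def test_fivep_counts_empty_library(tiny_txs):
    cov = fivep_counts(_lib([]), tiny_txs)
    assert cov.library_size == 0 and cov.total() == 0


def test_fivep_counts_places_read_at_start_offset(tiny_txs):
    cov = fivep_counts(_lib([("G1", 86, "AAAA")]), tiny_txs)
    tx = tiny_txs["G1"]
    from fivepdecay.annotation import start_offset

    pos = int(np.flatnonzero(cov.counts["G1"])[0])
    assert start_offset(tx, pos) == -14


def test_fivep_counts_conservation_and_dropping(tiny_txs):
    lib = _lib([("G1", 0, "AAAA"), ("G1", 1, "AAAA"), ("UNKNOWN", 0, "AAAA"), ("G2", 10_000, "AAAA")])
    cov = fivep_counts(lib, tiny_txs)
    assert cov.total() == 2 and cov.library_size == 2 and cov.n_dropped == 2


def test_fivep_counts_order_invariance(tiny_txs):
    recs = [("G1", 5, "AAAA"), ("G2", 9, "CCCC"), ("G1", 5, "AACC"), ("G3", 0, "GGGG")]
    cov1 = fivep_counts(_lib(recs), tiny_txs)
    cov2 = fivep_counts(_lib(recs[::-1]), tiny_txs)
    for g in tiny_txs.gene_ids:
        assert np.array_equal(cov1.counts[g], cov2.counts[g])


def test_rpm_normalization_scales_by_library_size(tiny_txs):
    counts = {g: np.zeros(tiny_txs[g].tx_length) for g in tiny_txs.gene_ids}
    counts["G1"][10] = 5
    cov = CoverageTable(counts, library_size=2_000_000, scale="raw")
    rpm = rpm_normalize(cov)
    assert rpm.scale == "rpm"
    assert rpm.counts["G1"][10] == pytest.approx(2.5)
    with pytest.raises(ValueError):
        rpm_normalize(rpm)  # already scaled
    with pytest.raises(ValueError):
        rpm_normalize(CoverageTable({g: np.zeros(3) for g in "ab"}, library_size=0))


def test_rpm_total_is_million_times_retained_fraction(default_sim, default_cov):
    rpm = rpm_normalize(default_cov)
    assert rpm.total() == pytest.approx(1e6)


def test_coverage_tsv_round_trip(tmp_path, tiny_txs):
    lib = _lib([("G1", 5, "AAAA"), ("G1", 5, "TTTT"), ("G2", 9, "CCCC")])
    cov = fivep_counts(lib, tiny_txs)
    path = tmp_path / "cov.tsv"
    cov.to_tsv(path, tiny_txs)
    back = CoverageTable.from_tsv(path, tiny_txs)
    assert back.library_size == cov.library_size and back.scale == "raw"
    for g in tiny_txs.gene_ids:
        assert np.array_equal(back.counts[g], cov.counts[g])


def test_fastq_umi_extraction_round_trip(tmp_path):
    cfg = DegradomeSimConfig(n_genes=20, n_reads=200, seed=7)
    from fivepdecay.synthetic_data import write_fastq

    _, lib, _ = simulate_degradome(cfg)
    fq = tmp_path / "reads.fastq"
    out = tmp_path / "trimmed.fastq"
    write_fastq(lib, fq, read_len=30, seed=1)
    written, skipped = reads.extract_umis_fastq(fq, out, umi_len=cfg.umi_len)
    assert written == len(lib) and skipped == 0
    # UMIs survive in the read names, umi_tools style
    names = [line[1:].strip() for line in out.read_text().splitlines()[::4]]
    assert sorted(n.rsplit("_", 1)[1] for n in names) == sorted(lib.umi_strings())


def test_bed_round_trip(tmp_path):
    from fivepdecay.synthetic_data import write_bed

    cfg = DegradomeSimConfig(n_genes=10, n_reads=300, seed=9)
    _, lib, _ = simulate_degradome(cfg)
    path = tmp_path / "reads.bed"
    write_bed(lib, path)
    back = reads.load_bed_fivep(path)
    lhs = back.to_frame().sort_values(["gene_id", "five_prime_pos", "umi"]).reset_index(drop=True)
    rhs = lib.to_frame().sort_values(["gene_id", "five_prime_pos", "umi"]).reset_index(drop=True)
    assert lhs.equals(rhs)


def test_sam_ingestion_projects_both_strands(tmp_path):
    """5' ends from SAM: leftmost base for +, rightmost for -, through layouts."""
    import pysam

    from fivepdecay.annotation import load_transcript_models
    from fivepdecay.synthetic_data import write_gtf

    cfg = DegradomeSimConfig(n_genes=4, n_reads=10, seed=13)
    txs, _, _ = simulate_degradome(cfg)
    gtf = tmp_path / "ann.gtf"
    write_gtf(txs, gtf)
    txs2 = load_transcript_models(gtf)

    sam = tmp_path / "aln.sam"
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chrI", "LN": 1_000_000}, {"SN": "chrII", "LN": 1_000_000}],
    }
    # G0001 is plus-strand, G0002 minus-strand (simulator alternates)
    plus = txs2.layouts["G0001"]
    minus = txs2.layouts["G0002"]
    with pysam.AlignmentFile(sam, "w", header=header) as out:
        a = pysam.AlignedSegment(out.header)
        a.query_name = "r1_ACGTACGT"
        a.query_sequence = "A" * 20
        a.reference_name = plus.chrom
        a.reference_start = plus.exons[0][0] - 1 + 7  # transcript pos 7
        a.cigarstring = "20M"
        a.mapping_quality = 30
        a.flag = 0
        out.write(a)
        b = pysam.AlignedSegment(out.header)
        b.query_name = "r2_TTTTCCCC"
        b.query_sequence = "A" * 20
        b.reference_name = minus.chrom
        b.flag = 16  # reverse: biological 5' end is reference_end - 1
        b.reference_start = minus.exons[0][1] - 5 - 20  # 5' end maps to tx pos 5
        b.cigarstring = "20M"
        b.mapping_quality = 30
        out.write(b)
        c = pysam.AlignedSegment(out.header)  # low MAPQ, dropped
        c.query_name = "r3_AAAAAAAA"
        c.query_sequence = "A" * 20
        c.reference_name = plus.chrom
        c.reference_start = plus.exons[0][0] - 1
        c.cigarstring = "20M"
        c.mapping_quality = 0
        c.flag = 0
        out.write(c)

    lib = reads.load_sam_fivep(sam, txs2)
    df = lib.to_frame().sort_values("gene_id").reset_index(drop=True)
    assert list(df["gene_id"]) == ["G0001", "G0002"]
    assert list(df["five_prime_pos"]) == [7, 5]
    assert list(df["umi"]) == ["ACGTACGT", "TTTTCCCC"]
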