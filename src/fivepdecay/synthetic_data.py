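"""Synthetic datasets with known ground truth for the 5P-Seq and MS analyses.

Three generators emulate the statistical structure the pipeline assumes:

* ``simulate_degradome`` draws 5'P end positions from a per-gene intensity
  model — an initiation-pause atom 14 nt upstream of the start codon
  (the 5'P boundary of a ribosome whose P-site sits on the start), a 3-nt
  elongation lattice through the ORF, a termination atom 17 nt upstream
  of the stop codon, and a uniform background — then applies a
  genotype-dependent multiplier to 5'UTR occupancy, tags each molecule
  with a random UMI and emits PCR copies.
* ``simulate_ms_dataset`` builds peptide-level MS tables over several
  bait strains with a spiked set of truly enriched proteins.
* ``simulate_timecourse`` builds exponential mRNA decay and saturating
  protein induction curves for the assay calculators.

Everything is deterministic given the seed; truth records carry the
sampling intensities and spiked memberships so tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, TranscriptLayout, TranscriptSet
from .assays import DecayCourse, TimecoursePair
from .msquant import PeptideTable
from .reads import RawReadLibrary

__all__ = [
    "DegradomeSimConfig",
    "TruthRecord",
    "simulate_degradome",
    "simulate_ms_dataset",
    "simulate_timecourse",
    "SimulatedAssays",
    "write_fastq",
    "write_bed",
    "write_gtf",
]

# The 5'UTR occupancy multiplier applies to start offsets in this half-open
# interval (the uS window): background 5'P density upstream of the
# initiation-protected footprint.
UTR5_EFFECT_WINDOW = (-60, -15)


@dataclass(frozen=True)
class DegradomeSimConfig:
    """Study conditions for a simulated 5P-Seq library.

    Weights are relative intensities: ``w_init`` and ``w_term`` are point
    masses at the paused positions, ``w_elong`` is per elongating codon,
    and ``w_bg`` is per nucleotide of uniform background.  ``f_utr5``
    inflates 5'UTR occupancy genome-wide (the mutant genotype effect);
    ``f_utr5_osr`` multiplies it further on the osmostress-responsive
    (OSR) subset.
    """

    n_genes: int = 200
    utr5_len_range: tuple[int, int] = (62, 150)
    cds_codon_range: tuple[int, int] = (100, 500)
    utr3_len_range: tuple[int, int] = (50, 200)
    n_reads: int = 100_000
    w_init: float = 5.0
    w_elong: float = 1.0
    w_term: float = 5.0
    w_bg: float = 0.5
    p_offset: int = 14
    term_offset: int = 17
    f_utr5: float = 1.0
    osr_fraction: float = 0.15
    f_utr5_osr: float = 1.0
    umi_len: int = 8
    pcr_dup_mean: float = 1.0
    distinct_umis: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        weights = (self.w_init, self.w_elong, self.w_term, self.w_bg)
        if any(w < 0 for w in weights):
            raise ValueError("weights must be nonnegative")
        if not any(w > 0 for w in weights):
            raise ValueError("at least one weight must be positive")
        if self.utr5_len_range[0] < 62:
            raise ValueError(
                "utr5 min must be >= 62 so the upstream windows fit inside the 5'UTR"
            )
        if self.p_offset < 0 or self.term_offset < 0:
            raise ValueError("footprint offsets must be nonnegative")
        for name in ("utr5_len_range", "cds_codon_range", "utr3_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"bad range {name}={lo, hi}")
        if self.n_genes < 1 or self.n_reads < 1:
            raise ValueError("n_genes and n_reads must be positive")
        if not 0 <= self.osr_fraction <= 1:
            raise ValueError("osr_fraction must be in [0, 1]")
        if self.pcr_dup_mean < 0:
            raise ValueError("pcr_dup_mean must be nonnegative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DegradomeSimConfig":
        data = json.loads(Path(path).read_text())
        for key in ("utr5_len_range", "cds_codon_range", "utr3_len_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class TruthRecord:
    """Ground truth for one simulated library."""

    intensities: dict[str, np.ndarray]  # per-gene per-position sampling weights
    probabilities: dict[str, np.ndarray]  # globally normalized (sum over all = 1)
    osr_genes: list[str]
    f_utr5: float
    f_utr5_osr: float
    unique_molecules: pd.DataFrame  # gene_id, five_prime_pos, umi (pre-PCR)
    copies_per_molecule: np.ndarray

    @property
    def n_unique(self) -> int:
        return len(self.unique_molecules)


def _make_transcripts(cfg: DegradomeSimConfig, rng: np.random.Generator) -> TranscriptSet:
    txs = TranscriptSet()
    cursor = 1000
    for i in range(cfg.n_genes):
        gid = f"G{i + 1:04d}"
        utr5 = int(rng.integers(cfg.utr5_len_range[0], cfg.utr5_len_range[1] + 1))
        codons = int(rng.integers(cfg.cds_codon_range[0], cfg.cds_codon_range[1] + 1))
        utr3 = int(rng.integers(cfg.utr3_len_range[0], cfg.utr3_len_range[1] + 1))
        model = TranscriptModel(gene_id=gid, utr5_len=utr5, cds_len=3 * codons, utr3_len=utr3)
        strand = "+" if i % 2 == 0 else "-"
        layout = TranscriptLayout(
            gene_id=gid,
            chrom="chrI" if i % 2 == 0 else "chrII",
            strand=strand,
            exons=[(cursor, cursor + model.tx_length - 1)],
        )
        cursor += model.tx_length + 500
        txs.add(model, layout)
    return txs


def _gene_intensity(tx: TranscriptModel, cfg: DegradomeSimConfig, osr: bool) -> np.ndarray:
    """Per-position 5'P sampling weights for one gene."""
    vec = np.full(tx.tx_length, cfg.w_bg, dtype=np.float64)
    start, stop = tx.start_pos, tx.stop_pos
    init_pos = start - cfg.p_offset
    if init_pos < 0:
        raise ValueError(f"{tx.gene_id}: initiation footprint does not fit in the 5'UTR")
    vec[init_pos] += cfg.w_init
    n_codons = tx.cds_len // 3
    ks = np.arange(1, n_codons)  # elongating codons
    elong_pos = start - cfg.p_offset + 3 * ks
    elong_pos = elong_pos[(elong_pos >= 0) & (elong_pos < tx.tx_length)]
    vec[elong_pos] += cfg.w_elong
    term_pos = stop - cfg.term_offset
    if term_pos < 0:
        raise ValueError(f"{tx.gene_id}: termination footprint does not fit")
    vec[term_pos] += cfg.w_term
    # genotype effect on 5'UTR occupancy (uS window offsets)
    lo, hi = UTR5_EFFECT_WINDOW
    factor = cfg.f_utr5 * (cfg.f_utr5_osr if osr else 1.0)
    vec[start + lo : start + hi] *= factor
    return vec


def simulate_degradome(
    cfg: DegradomeSimConfig,
    txs: TranscriptSet | None = None,
    osr_genes: list[str] | None = None,
) -> tuple[TranscriptSet, RawReadLibrary, TruthRecord]:
    """Draw a 5P-Seq read library from the intensity model.

    ``n_reads`` unique molecules are sampled multinomially from the
    globally normalized per-position intensities; each gets a UMI
    (uniform random, or within-site sequential in ``distinct_umis`` mode)
    and ``1 + Geometric`` PCR copies.  The returned RawReadLibrary lists
    every emitted copy, in shuffled order.  Paired designs (mutant vs wt)
    should pass the first run's ``txs`` and truth ``osr_genes`` so both
    libraries share gene geometry and subset membership.
    """
    rng = np.random.default_rng(cfg.seed)
    geom_rng = np.random.default_rng(cfg.seed + 10_007)
    if txs is None:
        txs = _make_transcripts(cfg, geom_rng)
    gene_ids = txs.gene_ids
    if osr_genes is None:
        n_osr = int(round(cfg.osr_fraction * len(gene_ids)))
        osr_genes = list(geom_rng.choice(gene_ids, size=n_osr, replace=False)) if n_osr else []
    osr_set = set(osr_genes)

    intensities = {
        g: _gene_intensity(txs[g], cfg, g in osr_set) for g in gene_ids
    }
    flat = np.concatenate([intensities[g] for g in gene_ids])
    total = flat.sum()
    probs_flat = flat / total
    probabilities = {}
    offset = 0
    for g in gene_ids:
        L = txs[g].tx_length
        probabilities[g] = probs_flat[offset : offset + L]
        offset += L

    counts = rng.multinomial(cfg.n_reads, probs_flat)
    hit_bins = np.flatnonzero(counts)
    mol_flat = np.repeat(hit_bins, counts[hit_bins])

    lengths = np.array([txs[g].tx_length for g in gene_ids], dtype=np.int64)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    gene_idx = np.searchsorted(bounds, mol_flat, side="right") - 1
    pos = mol_flat - bounds[gene_idx]

    n = len(mol_flat)
    if cfg.distinct_umis:
        # sequential UMI codes within each (gene, position) bin: collisions
        # impossible, so dedup recovers the unique-molecule multiset exactly
        bin_start = np.concatenate([[0], np.cumsum(counts[hit_bins])[:-1]])
        within = np.arange(n) - np.repeat(bin_start, counts[hit_bins])
        if within.max(initial=0) >= 4**cfg.umi_len:
            raise ValueError("umi_len too short for distinct-UMI mode at this depth")
        umi = within.astype(np.int64)
    else:
        umi = rng.integers(0, 4**cfg.umi_len, size=n, dtype=np.int64)

    unique = RawReadLibrary(gene_ids, gene_idx, pos, umi, cfg.umi_len)
    truth = TruthRecord(
        intensities=intensities,
        probabilities=probabilities,
        osr_genes=sorted(osr_genes),
        f_utr5=cfg.f_utr5,
        f_utr5_osr=cfg.f_utr5_osr,
        unique_molecules=unique.to_frame(),
        copies_per_molecule=np.ones(n, dtype=np.int64),
    )

    if cfg.pcr_dup_mean > 0:
        p = 1.0 / (1.0 + cfg.pcr_dup_mean)
        copies = rng.geometric(p, size=n)  # support 1.., mean 1 + pcr_dup_mean
    else:
        copies = np.ones(n, dtype=np.int64)
    truth.copies_per_molecule = copies
    out_gene = np.repeat(gene_idx, copies)
    out_pos = np.repeat(pos, copies)
    out_umi = np.repeat(umi, copies)
    order = rng.permutation(len(out_gene))
    lib = RawReadLibrary(gene_ids, out_gene[order], out_pos[order], out_umi[order], cfg.umi_len)
    return txs, lib, truth


# ---------------------------------------------------------------------------
# MS peptide tables


def simulate_ms_dataset(
    n_proteins: int = 500,
    n_enriched: int = 10,
    n_replicates: int = 3,
    strains: tuple[str, ...] = ("GPD1", "STL1", "ASH1", "HYP2", "untagged"),
    enriched_in: tuple[str, ...] = ("GPD1", "STL1"),
    effect_log2: float = 3.0,
    rep_sd: float = 0.3,
    peptide_sd: float = 1.0,
    bait_fraction: float = 0.1,
    confident_rate: float = 0.95,
    seed: int = 0,
) -> tuple[PeptideTable, list[str]]:
    """Peptide tables over bait strains with a spiked enriched-protein set.

    Per (protein, strain, replicate): peptide count ~ Poisson with rate
    proportional to molecular weight; log2 intensities are normal around a
    protein-specific mean with replicate- and peptide-level noise.  The
    ``n_enriched`` spiked proteins gain ``effect_log2`` in both intensity
    mean and count rate, in the ``enriched_in`` strains only.  Peptides
    fall into the "bait" gel fraction with probability ``bait_fraction``,
    otherwise "remainder".  Returns the table and the spiked protein ids.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched exceeds n_proteins")
    if effect_log2 < 0:
        raise ValueError("effect_log2 must be nonnegative")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i + 1:04d}" for i in range(n_proteins)]
    mw = np.maximum(10.0, rng.lognormal(mean=np.log(50.0), sigma=0.4, size=n_proteins))
    base_mu = rng.normal(20.0, 2.0, size=n_proteins)  # log2 intensity level
    enriched = sorted(rng.choice(proteins, size=n_enriched, replace=False))
    enriched_set = set(enriched)

    rows: list[tuple] = []
    for strain in strains:
        for rep in range(1, n_replicates + 1):
            rep_shift = rng.normal(0.0, rep_sd, size=n_proteins)
            for i, prot in enumerate(proteins):
                boost = effect_log2 if (prot in enriched_set and strain in enriched_in) else 0.0
                lam = mw[i] * 0.15 * 2.0**boost
                count = int(rng.poisson(lam))
                if count == 0:
                    continue
                mu = base_mu[i] + boost + rep_shift[i]
                log2_int = rng.normal(mu, peptide_sd, size=count)
                in_bait = rng.random(count) < bait_fraction
                conf = rng.random(count) < confident_rate
                for j in range(count):
                    rows.append(
                        (
                            prot,
                            strain,
                            rep,
                            "bait" if in_bait[j] else "remainder",
                            f"{prot}_pep{j + 1}",
                            float(2.0 ** log2_int[j]),
                            bool(conf[j]),
                        )
                    )
    peptides = pd.DataFrame(
        rows,
        columns=["protein_id", "strain", "replicate", "gel_set", "peptide_id", "intensity", "confident"],
    )
    tbl = PeptideTable(peptides=peptides, protein_mw=pd.Series(mw, index=proteins, name="mw_kda"))
    return tbl, enriched


# ---------------------------------------------------------------------------
# Assay time courses


@dataclass
class SimulatedAssays:
    """Decay course plus mutant/wt induction curve pairs, with truth."""

    decay: DecayCourse
    pair_mut: TimecoursePair
    pair_wt: TimecoursePair
    truth: dict = field(default_factory=dict)


def simulate_timecourse(
    half_life_min: float = 20.0,
    te_ratio: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SimulatedAssays:
    """Exponential mRNA decay and saturating protein induction with noise.

    The decay course follows 2^(-t/half_life) with multiplicative
    log-normal noise of scale ``noise_sd``.  The mutant's protein curve is
    the wild type's scaled by ``te_ratio``, with identical mRNA induction
    on both, so the noiseless translation-efficiency ratio is exactly
    ``te_ratio``.
    """
    if half_life_min <= 0:
        raise ValueError("half_life_min must be positive")
    rng = np.random.default_rng(seed)
    t_decay = np.arange(0.0, 45.0, 5.0)
    decay_vals = 2.0 ** (-t_decay / half_life_min)
    if noise_sd > 0:
        decay_vals = decay_vals * np.exp(rng.normal(0.0, noise_sd, size=len(t_decay)))
    decay = DecayCourse(times_min=t_decay, abundances=decay_vals)

    t_prot = np.arange(0.0, 125.0, 5.0)
    t_mrna = np.arange(0.0, 65.0, 5.0)
    prot_wt = 100.0 * (1.0 - np.exp(-t_prot / 20.0))
    mrna = 50.0 * (1.0 - np.exp(-t_mrna / 15.0))

    def _noisy(v: np.ndarray) -> np.ndarray:
        if noise_sd <= 0:
            return v.copy()
        return v * np.exp(rng.normal(0.0, noise_sd, size=len(v)))

    pair_wt = TimecoursePair(t_prot, _noisy(prot_wt), t_mrna, _noisy(mrna))
    pair_mut = TimecoursePair(t_prot, _noisy(te_ratio * prot_wt), t_mrna, _noisy(mrna))
    return SimulatedAssays(
        decay=decay,
        pair_mut=pair_mut,
        pair_wt=pair_wt,
        truth={"half_life_min": half_life_min, "te_ratio": te_ratio, "noise_sd": noise_sd},
    )


# ---------------------------------------------------------------------------
# Writers (plain-text exchange formats)


def write_fastq(
    lib: RawReadLibrary,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
    read_len: int = 35,
    seed: int = 0,
) -> None:
    """Emit UMI-prefixed reads with random downstream sequence.

    The true 5'P position of each read is recorded in a sidecar TSV
    (read_id, gene_id, five_prime_pos) since the random sequence carries
    no mappable information.
    """
    rng = np.random.default_rng(seed)
    body_len = read_len - lib.umi_len
    if body_len < 1:
        raise ValueError("read_len must exceed umi_len")
    bases = np.array(list("ACGT"))
    umis = lib.umi_strings()
    genes = lib.gene_ids()
    qual = "I" * read_len
    with open(fastq_path, "w") as fq:
        for i in range(len(lib)):
            body = "".join(bases[rng.integers(0, 4, size=body_len)])
            fq.write(f"@read{i + 1}\n{umis[i]}{body}\n+\n{qual}\n")
    if truth_path is not None:
        pd.DataFrame(
            {"read_id": [f"read{i + 1}" for i in range(len(lib))],
             "gene_id": genes,
             "five_prime_pos": lib.pos}
        ).to_csv(truth_path, sep="\t", index=False)


def write_bed(lib: RawReadLibrary, path: str | Path) -> None:
    """Transcript-space BED6: chrom=gene, single-base 5' end, name=UMI."""
    df = lib.to_frame()
    bed = pd.DataFrame(
        {
            "chrom": df["gene_id"],
            "start": df["five_prime_pos"],
            "end": df["five_prime_pos"] + 1,
            "name": df["umi"],
            "score": 0,
            "strand": "+",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_gtf(txs: TranscriptSet, path: str | Path, source: str = "fivepdecay_sim") -> None:
    """Ensembl-dialect GTF: exon + CDS (+ stop_codon) per transcript.

    CDS features exclude the stop codon, which is emitted separately, as
    in Ensembl annotation; the loader folds it back into the
    stop-inclusive CDS length.
    """
    lines = []
    for gid in txs.gene_ids:
        tx = txs[gid]
        layout = txs.layouts.get(gid)
        if layout is None:
            raise ValueError(f"{gid}: no genomic layout; cannot write GTF")
        if len(layout.exons) != 1:
            raise ValueError("writer supports single-exon layouts")
        (g_start, g_end) = layout.exons[0]
        attrs = f'gene_id "{gid}"; transcript_id "{gid}.1";'
        strand = layout.strand
        chrom = layout.chrom

        def feat(ftype: str, s: int, e: int) -> str:
            return f"{chrom}\t{source}\t{ftype}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}"

        lines.append(feat("exon", g_start, g_end))
        if strand == "+":
            cds_s = g_start + tx.utr5_len
            cds_e = cds_s + tx.cds_len - 3 - 1
            stop_s, stop_e = cds_e + 1, cds_e + 3
        else:
            cds_e = g_end - tx.utr5_len
            cds_s = cds_e - (tx.cds_len - 3) + 1
            stop_e, stop_s = cds_s - 1, cds_s - 3
        lines.append(feat("CDS", cds_s, cds_e))
        lines.append(feat("stop_codon", stop_s, stop_e))
    Path(path).write_text("\n".join(lines) + "\n")
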