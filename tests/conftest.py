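"""Shared fixtures: small hand-built transcript sets and one cached simulation."""

from dataclasses import replace

import numpy as np
import pytest

from fivepdecay import reads, synthetic_data, windows
from fivepdecay.annotation import TranscriptModel, TranscriptSet


@pytest.fixture
def tiny_tx() -> TranscriptModel:
    return TranscriptModel(gene_id="G1", utr5_len=100, cds_len=300, utr3_len=80)


@pytest.fixture
def tiny_txs(tiny_tx) -> TranscriptSet:
    txs = TranscriptSet()
    txs.add(tiny_tx)
    txs.add(TranscriptModel(gene_id="G2", utr5_len=70, cds_len=303, utr3_len=50))
    txs.add(TranscriptModel(gene_id="G3", utr5_len=62, cds_len=240, utr3_len=45))
    return txs


@pytest.fixture(scope="session")
def default_sim():
    """One default-depth simulated library shared across read-only tests."""
    cfg = synthetic_data.DegradomeSimConfig(seed=11)
    txs, lib, truth = synthetic_data.simulate_degradome(cfg)
    return cfg, txs, lib, truth


@pytest.fixture(scope="session")
def default_cov(default_sim):
    _, txs, lib, _ = default_sim
    return reads.fivep_counts(reads.dedup_reads(lib), txs)


@pytest.fixture(scope="session")
def paired_loading_tables():
    """Mutant (f_utr5=2) vs wt loading-ratio tables on shared geometry."""
    cfg_wt = synthetic_data.DegradomeSimConfig(seed=21)
    txs, lib_wt, truth = synthetic_data.simulate_degradome(cfg_wt)
    cfg_mut = replace(cfg_wt, f_utr5=2.0, seed=22)
    _, lib_mut, _ = synthetic_data.simulate_degradome(cfg_mut, txs=txs, osr_genes=truth.osr_genes)
    tables = {}
    for label, lib in (("wt", lib_wt), ("mut", lib_mut)):
        cov = reads.fivep_counts(reads.dedup_reads(lib), txs)
        tables[label] = windows.loading_ratios(windows.window_counts(cov, txs))
    return tables, truth


def random_coverage(txs: TranscriptSet, rng: np.random.Generator, mean_reads: int = 300):
    """Raw coverage with Poisson counts at random positions, for oracles."""
    counts = {}
    total = 0
    for gid in txs.gene_ids:
        L = txs[gid].tx_length
        vec = rng.poisson(mean_reads / L, size=L).astype(float)
        counts[gid] = vec
        total += int(vec.sum())
    return reads.CoverageTable(counts, library_size=total, scale="raw")
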