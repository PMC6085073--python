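"""Window count tables and loading ratios around the start and stop codons.

Three 45-nt windows tile the start region — uS upstream of the start
codon, dS spanning the initiation-paused ribosome, ddS further inside the
ORF — and two windows flank the stop codon (uE, dE).  Per-gene log2
loading ratios (uSvsdS, uSvsddS, uEvsdE) compare 5'P read counts between
windows; a positive ratio means more ribosome protection on the 5' side.
Genes with fewer than ``min_reads`` reads in a ratio's two windows are
filtered from that ratio.

All intervals are half-open ``[lo, hi)`` on anchor offsets.  The default
scheme uses the documented 45-nt geometry (uS=[-60,-15), dS=[-14,31),
ddS=[32,77) on the start anchor; uE=[-62,-17), dE=[-17,46) on the stop
anchor).  The published inclusive bounds are mutually inconsistent with
uniform 45-nt windows under any single convention; the half-open reading
of the printed left bounds restores exact 45-nt windows at the cost of a
single unassigned nucleotide at start offset -15, and makes uE/dE a clean
partition.  A "paper-literal" preset exposing the printed inclusive
bounds verbatim is provided for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptSet
from .reads import CoverageTable

__all__ = ["WindowScheme", "window_counts", "loading_ratios", "RATIO_DEFS"]

Interval = tuple[int, int]

# ratio name -> (numerator window, denominator window, anchor geometry flag)
RATIO_DEFS = {
    "uSvsdS": ("uS", "dS"),
    "uSvsddS": ("uS", "ddS"),
    "uEvsdE": ("uE", "dE"),
}

_START_WINDOWS = ("uS", "dS", "ddS")
_STOP_WINDOWS = ("uE", "dE")


@dataclass(frozen=True)
class WindowScheme:
    """Half-open anchor-offset intervals for the five windows."""

    uS: Interval = (-60, -15)
    dS: Interval = (-14, 31)
    ddS: Interval = (32, 77)
    uE: Interval = (-62, -17)
    dE: Interval = (-17, 46)
    min_reads: int = 20
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        for name in _START_WINDOWS + _STOP_WINDOWS:
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"window {name}={lo, hi} is empty")
        if not self.allow_overlap:
            for group in (_START_WINDOWS, _STOP_WINDOWS):
                ivals = sorted(getattr(self, n) for n in group)
                for (a_lo, a_hi), (b_lo, b_hi) in zip(ivals, ivals[1:]):
                    if b_lo < a_hi:
                        raise ValueError(f"overlapping windows in group {group}")
        if self.min_reads < 0:
            raise ValueError("min_reads must be nonnegative")

    @classmethod
    def paper_literal(cls) -> "WindowScheme":
        """The printed inclusive bounds, verbatim.

        These windows are 46/46/46/46/64 nt and the uE/dE pair overlaps by
        two nucleotides — the published bound sets are internally
        inconsistent, which is why the default scheme re-derives clean
        half-open 45-nt windows instead.  ``allow_overlap`` is set so the
        verbatim bounds can still be explored.
        """
        return cls(uS=(-60, -14), dS=(-14, 32), ddS=(32, 78), uE=(-62, -16), dE=(-18, 46),
                   allow_overlap=True)

    def window(self, name: str) -> Interval:
        return getattr(self, name)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "WindowScheme":
        data = json.loads(Path(path).read_text())
        data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
        return cls(**data)


def window_counts(
    cov: CoverageTable, txs: TranscriptSet, scheme: WindowScheme | None = None
) -> pd.DataFrame:
    """Per-gene 5'P read counts in the five windows (raw coverage).

    Returns a DataFrame indexed by gene with columns uS, dS, ddS, uE, dE
    plus geometry flags: ``start_ok`` (5'UTR long enough to contain the
    full uS window, CDS long enough for dS/ddS) and ``stop_ok`` (CDS and
    3'UTR long enough for uE/dE).  Windows that overhang a short gene are
    clipped — out-of-gene offsets contribute nothing — and the flags mark
    such genes for exclusion from the corresponding ratios.
    """
    if cov.scale != "raw":
        raise ValueError(f"window_counts expects raw coverage, got scale={cov.scale!r}")
    scheme = scheme or WindowScheme()
    rows = {}
    for gene, vec in cov.counts.items():
        tx = txs[gene]
        rec = {}
        start_ok = stop_ok = True
        for name in _START_WINDOWS + _STOP_WINDOWS:
            lo, hi = scheme.window(name)
            anchor = tx.start_pos if name in _START_WINDOWS else tx.stop_pos
            p_lo, p_hi = anchor + lo, anchor + hi  # half-open on positions
            clipped_lo, clipped_hi = max(0, p_lo), min(tx.tx_length, p_hi)
            rec[name] = float(vec[clipped_lo:clipped_hi].sum()) if clipped_lo < clipped_hi else 0.0
            truncated = (clipped_lo, clipped_hi) != (p_lo, p_hi)
            if truncated and name in _START_WINDOWS:
                start_ok = False
            if truncated and name in _STOP_WINDOWS:
                stop_ok = False
        rec["start_ok"] = start_ok
        rec["stop_ok"] = stop_ok
        rows[gene] = rec
    wct = pd.DataFrame.from_dict(rows, orient="index")
    wct.index.name = "gene_id"
    return wct


def _log2_ratio(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log2(x/y) with a 0.5 pseudocount applied only when x or y is zero."""
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    needs = (x == 0) | (y == 0)
    x[needs] += 0.5
    y[needs] += 0.5
    return np.log2(x / y)


def loading_ratios(wct: pd.DataFrame, scheme: WindowScheme | None = None) -> pd.DataFrame:
    """Per-gene log2 loading ratios with per-ratio filter flags.

    For each ratio XvsY the filter passes iff the gene's geometry supports
    both windows and X + Y >= ``scheme.min_reads``; filtered genes carry
    NaN for that ratio.
    """
    scheme = scheme or WindowScheme()
    out = pd.DataFrame(index=wct.index)
    for ratio, (num, den) in RATIO_DEFS.items():
        geom = wct["start_ok"] if num in _START_WINDOWS else wct["stop_ok"]
        passes = geom & ((wct[num] + wct[den]) >= scheme.min_reads)
        values = _log2_ratio(wct[num].to_numpy(), wct[den].to_numpy())
        out[ratio] = np.where(passes, values, np.nan)
        out[f"{ratio}_pass"] = passes
    return out


def pooled_window_counts(
    covs: list[CoverageTable], txs: TranscriptSet, scheme: WindowScheme | None = None
) -> pd.DataFrame:
    """Window counts with replicate libraries pooled (summed) before ratios."""
    if not covs:
        raise ValueError("no coverage tables given")
    tables = [window_counts(c, txs, scheme) for c in covs]
    pooled = tables[0].copy()
    for t in tables[1:]:
        for name in _START_WINDOWS + _STOP_WINDOWS:
            pooled[name] = pooled[name].add(t[name], fill_value=0.0)
        pooled["start_ok"] &= t["start_ok"]
        pooled["stop_ok"] &= t["stop_ok"]
    return pooled
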