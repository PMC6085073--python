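"""Ratio-based calculators for the wet-lab validation assays.

Small, closed-form quantities: RNP pull-down qPCR enrichment ratios,
ddCt relative expression, first-order mRNA half-life after transcription
shut-off, translation-efficiency ratios from protein/mRNA area under the
curve, and the polysome-to-subpolysome (P/FM) ratio from sucrose-gradient
fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "QpcrQuad",
    "PolysomeProfile",
    "DecayCourse",
    "TimecoursePair",
    "HalfLifeResult",
    "pulldown_enrichment",
    "mrna_pair_ratio",
    "relative_expression",
    "half_life",
    "translation_efficiency_ratio",
    "te_from_pair",
    "detect_plateau_time",
    "pfm_ratio",
]


@dataclass(frozen=True)
class QpcrQuad:
    """Pull-down (PD) and input (I) relative quantities, tagged vs untagged."""

    pd_tagged: float
    input_tagged: float
    pd_untagged: float
    input_untagged: float

    def __post_init__(self) -> None:
        for name in ("pd_tagged", "input_tagged", "pd_untagged", "input_untagged"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def pulldown_enrichment(q: QpcrQuad) -> float:
    """(PD/I) of the MS2L-tagged strain over (PD/I) of the untagged strain."""
    return (q.pd_tagged / q.input_tagged) / (q.pd_untagged / q.input_untagged)


def mrna_pair_ratio(pd1: float, in1: float, pd2: float, in2: float) -> float:
    """(PD/I) of mRNA 1 over (PD/I) of mRNA 2, same pull-down."""
    if min(pd1, in1, pd2, in2) <= 0:
        raise ValueError("all quantities must be positive")
    return (pd1 / in1) / (pd2 / in2)


def relative_expression(
    ct_target: float, ct_ref: float, ct_target0: float, ct_ref0: float, efficiency: float = 2.0
) -> float:
    """ddCt fold change: E^-((Ct_t - Ct_ref) - (Ct_t0 - Ct_ref0)).

    ``efficiency`` is the per-cycle amplification factor from a standard
    curve (2.0 = perfect doubling); admissible range (1, 2.2].
    """
    if not 1.0 < efficiency <= 2.2:
        raise ValueError(f"efficiency {efficiency} outside (1, 2.2]")
    ddct = (ct_target - ct_ref) - (ct_target0 - ct_ref0)
    return efficiency ** (-ddct)


@dataclass
class DecayCourse:
    """Reference-normalized mRNA abundance after transcription shut-off."""

    times_min: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.times_min) != len(self.abundances):
            raise ValueError("times and abundances differ in length")
        if len(self.times_min) < 3:
            raise ValueError("need at least 3 time points")
        if self.times_min[0] != 0 or np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must strictly increase from 0")


@dataclass(frozen=True)
class HalfLifeResult:
    t_half_min: float  # inf when no decay
    se_min: float
    slope: float
    slope_se: float

    @property
    def no_decay(self) -> bool:
        return math.isinf(self.t_half_min)


def half_life(course: DecayCourse) -> HalfLifeResult:
    """First-order half-life from the log-linear decay fit.

    ln(abundance) is regressed on time; t1/2 = ln2 / (-slope), with the
    standard error propagated from the slope SE (delta method).  A
    non-negative slope yields an infinite half-life flag.
    """
    if np.any(course.abundances <= 0):
        raise ValueError("abundances must be positive for log-linear fitting")
    fit = stats.linregress(course.times_min, np.log(course.abundances))
    slope, slope_se = float(fit.slope), float(fit.stderr)
    if slope >= 0:
        return HalfLifeResult(math.inf, math.inf, slope, slope_se)
    t_half = math.log(2) / (-slope)
    se = math.log(2) * slope_se / slope**2
    return HalfLifeResult(t_half, se, slope, slope_se)


@dataclass
class TimecoursePair:
    """Matched induction curves: protein signal and mRNA level vs time.

    Protein AUC runs to its plateau; mRNA AUC runs to a fixed horizon
    (60 min of osmotic stress by default).
    """

    protein_times: np.ndarray
    protein_values: np.ndarray
    mrna_times: np.ndarray
    mrna_values: np.ndarray
    mrna_horizon_min: float = 60.0
    plateau_band: float = 0.05

    def __post_init__(self) -> None:
        for name in ("protein_times", "protein_values", "mrna_times", "mrna_values"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for t in (self.protein_times, self.mrna_times):
            if np.any(np.diff(t) <= 0):
                raise ValueError("times must be strictly increasing")
        if self.mrna_horizon_min > self.mrna_times[-1]:
            raise ValueError("mRNA horizon beyond the measured course")


def detect_plateau_time(times: np.ndarray, values: np.ndarray, band: float = 0.05) -> float:
    """First time from which the curve stays within ``band`` of its running maximum."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    peak = values.max()
    if peak <= 0:
        return float(times[-1])
    for i in range(len(times)):
        if np.all(values[i:] >= (1 - band) * peak):
            return float(times[i])
    return float(times[-1])


def _auc_to(times: np.ndarray, values: np.ndarray, horizon: float) -> float:
    """Trapezoidal area from t=times[0] to ``horizon`` (interpolating the end)."""
    if horizon >= times[-1]:
        return float(np.trapezoid(values, times))
    v_end = float(np.interp(horizon, times, values))
    mask = times < horizon
    t = np.concatenate([times[mask], [horizon]])
    v = np.concatenate([values[mask], [v_end]])
    return float(np.trapezoid(v, t))


def te_from_pair(pair: TimecoursePair) -> tuple[float, float]:
    """Translation efficiency of one strain: protein AUC (to plateau) / mRNA AUC (to horizon).

    Returns (TE, plateau_time_min).
    """
    plateau_t = detect_plateau_time(pair.protein_times, pair.protein_values, pair.plateau_band)
    protein_auc = _auc_to(pair.protein_times, pair.protein_values, plateau_t)
    mrna_auc = _auc_to(pair.mrna_times, pair.mrna_values, pair.mrna_horizon_min)
    if mrna_auc <= 0:
        raise ValueError("mRNA AUC is zero; cannot form a TE ratio")
    return protein_auc / mrna_auc, plateau_t


def translation_efficiency_ratio(mut: TimecoursePair, wt: TimecoursePair) -> float:
    """TE(mutant) / TE(wild type): protein produced per mRNA, mutant over wt."""
    te_mut, _ = te_from_pair(mut)
    te_wt, _ = te_from_pair(wt)
    if te_wt == 0:
        raise ValueError("wild-type TE is zero")
    return te_mut / te_wt


@dataclass
class PolysomeProfile:
    """Sucrose-gradient fraction quantities (free/monosome then polysomes)."""

    quantities: np.ndarray  # fractions 1..n in gradient order
    subpolysomal: frozenset = field(default_factory=lambda: frozenset({1, 2}))
    polysomal: frozenset = field(default_factory=lambda: frozenset(range(3, 9)))

    def __post_init__(self) -> None:
        self.quantities = np.asarray(self.quantities, dtype=float)
        if np.any(self.quantities < 0):
            raise ValueError("fraction quantities must be nonnegative")
        if self.subpolysomal & self.polysomal:
            raise ValueError("fraction index sets overlap")
        n = len(self.quantities)
        if max(self.subpolysomal | self.polysomal) > n:
            raise ValueError(f"index set references fraction beyond the {n} measured")

    def _sum(self, idx: frozenset) -> float:
        return float(sum(self.quantities[i - 1] for i in sorted(idx)))


def pfm_ratio(profile: PolysomeProfile) -> float:
    """Polysomal over free+monosomal RNA: sum(fractions 3-8) / sum(fractions 1-2)."""
    denom = profile._sum(profile.subpolysomal)
    if denom <= 0:
        raise ValueError("sub-polysomal signal is zero")
    return profile._sum(profile.polysomal) / denom
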