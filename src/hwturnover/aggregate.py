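"""Protein-level aggregation and tissue-phase comparison statistics.

Protein turnover is summarised as the median and (unscaled) median absolute
deviation of the rate constants of the protein's accepted peptides, with the
half-life ln(2)/k_median under first-order kinetics.  Rate constants between
the fascicular (FM) and interfascicular (IFM) matrix phases are compared
with the test chosen by normality (Kolmogorov-Smirnov against a normal with
the sample mean and SD) and pairing: paired t-test, Wilcoxon matched pairs,
or Mann-Whitney.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, EmptyProteinError, InsufficientDataError, PairingError
from .kinetics import KineticFit


@dataclass(frozen=True)
class ProteinTurnover:
    """Protein-level turnover summary from accepted constituent peptides."""

    protein_id: str
    phase: str
    k_median: float  # 1/day
    k_mad: float  # 1/day, unscaled median absolute deviation
    half_life: float  # days
    n_peptides: int


@dataclass(frozen=True)
class PhaseComparison:
    """Outcome of an FM-vs-IFM (or any two-group) rate-constant comparison."""

    unit: str  # "peptide" | "protein"
    test: str  # "paired t" | "Wilcoxon matched pairs" | "Mann-Whitney" | "unpaired t"
    statistic: float
    p_value: float
    n: int  # pairs if paired, else min group size
    median_a: float
    median_b: float


def half_life_from_k(k: float) -> float:
    """Half-life in days for a first-order rate constant k (1/day): ln(2)/k."""
    if k <= 0:
        raise DomainError(f"k must be positive, got {k}")
    return math.log(2.0) / k


def fsr_to_k(fsr_percent: float) -> float:
    """Convert a fractional synthesis rate in %/time to a first-order rate constant (1/time)."""
    if fsr_percent <= 0:
        raise DomainError(f"FSR must be positive, got {fsr_percent}")
    return fsr_percent / 100.0


def aggregate_protein(
    fits: list[KineticFit],
    min_unique_peptides: int = 1,
    accepted_only: bool = True,
) -> ProteinTurnover:
    """Median/MAD of peptide rate constants for one protein in one phase.

    All fits must belong to a single (protein, phase).  By default only
    accepted fits contribute; ``min_unique_peptides`` optionally enforces a
    stricter identification requirement (e.g. 2 unique peptides per protein).
    """
    usable = [f for f in fits if f.accepted or not accepted_only]
    if not usable:
        raise EmptyProteinError("no accepted peptide fits to aggregate")
    proteins = {f.protein_id for f in usable}
    phases = {f.phase for f in usable}
    if len(proteins) > 1 or len(phases) > 1:
        raise PairingError(
            f"fits span multiple proteins/phases: {sorted(proteins)} / {sorted(phases)}"
        )
    unique_peptides = {f.peptide for f in usable}
    if len(unique_peptides) < min_unique_peptides:
        raise EmptyProteinError(
            f"protein {next(iter(proteins))!r}: {len(unique_peptides)} unique peptide(s), "
            f"fewer than required {min_unique_peptides}"
        )
    ks = np.array([f.k for f in usable], dtype=float)
    k_median = float(np.median(ks))
    k_mad = float(np.median(np.abs(ks - k_median)))
    return ProteinTurnover(
        protein_id=next(iter(proteins)),
        phase=next(iter(phases)),
        k_median=k_median,
        k_mad=k_mad,
        half_life=half_life_from_k(k_median),
        n_peptides=len(unique_peptides),
    )


def _is_normal(values: np.ndarray, alpha: float) -> bool:
    """Kolmogorov-Smirnov normality check against N(sample mean, sample SD).

    Parameters are estimated from the sample (Lilliefors-style caveat: the
    nominal KS p-value is conservative in that case).  A zero-variance sample
    is treated as normal.
    """
    sd = values.std(ddof=1)
    if sd == 0:
        return True
    _, p = stats.kstest(values, "norm", args=(values.mean(), sd))
    return p >= alpha


def compare_phases(
    k_a,
    k_b,
    paired: bool,
    unit: str = "peptide",
    alpha_normality: float = 0.05,
    unpaired_t_if_normal: bool = False,
) -> PhaseComparison:
    """Two-group comparison of rate constants with normality-driven test choice.

    Paired data: paired t-test when both groups pass the KS normality check,
    otherwise the Wilcoxon matched-pairs test (zero differences split between
    signs so identical groups give p = 1).  Unpaired data: Mann-Whitney by
    default, or an unpaired t-test when both groups are normal and
    ``unpaired_t_if_normal`` is set.  Requires >= 3 values per group.
    """
    a = np.asarray(k_a, dtype=float)
    b = np.asarray(k_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"each group needs >= 3 values, got {a.size} and {b.size}"
        )
    if paired and a.size != b.size:
        raise PairingError(f"paired groups differ in length: {a.size} vs {b.size}")

    both_normal = _is_normal(a, alpha_normality) and _is_normal(b, alpha_normality)
    if paired:
        if both_normal:
            test = "paired t"
            statistic, p_value = (0.0, 1.0) if np.all(a == b) else stats.ttest_rel(a, b)
        else:
            test = "Wilcoxon matched pairs"
            if np.all(a == b):
                statistic, p_value = 0.0, 1.0
            else:
                statistic, p_value = stats.wilcoxon(a, b, zero_method="zsplit")
        n = a.size
    else:
        if both_normal and unpaired_t_if_normal:
            test = "unpaired t"
            statistic, p_value = stats.ttest_ind(a, b)
        else:
            test = "Mann-Whitney"
            statistic, p_value = stats.mannwhitneyu(a, b, alternative="two-sided")
        n = int(min(a.size, b.size))

    return PhaseComparison(
        unit=unit,
        test=test,
        statistic=float(statistic),
        p_value=float(p_value),
        n=n,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )
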