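"""Synthetic heavy-water labelling studies with known ground truth.

Emulates the study design of a rodent deuterium-labelling experiment:
animals sampled on days 0, 1, 3, 6, 15, 31, 63 and 127 (three animals per
time point), serum enrichment rising with first-order kinetics
(kp = 0.7913/day to a 5.58% plateau), and per-peptide M0 relative
abundances decaying under the non-steady-state turnover model.  Protein
rate constants are drawn lognormal with a 0.010/day median in the
fascicular matrix (FM) and spread covering ~1000-fold; the interfascicular
matrix (IFM) carries the same proteins at 1.8x faster turnover.  Peptide
chemistry (a, N) is derived from generated tryptic-like sequences so the
analysis pipeline recomputes exactly the constants used to simulate.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import PeptideChemistry
from .errors import DomainError
from .kinetics import PeptideTimeSeries, model_m0_exact
from .precursor import EnrichmentCurve, precursor_at

#: Precursor kinetics used as the simulation default (rate 1/day, plateau fraction).
DEFAULT_CURVE = EnrichmentCurve(kp=0.7913, pss=0.0558)

#: Lognormal sigma such that the central 95% of protein k spans ~1000-fold.
K_LOG_SD = float(np.log(1000.0) / (2 * 1.959964))

DEFAULT_SEED = 20200512

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design and noise model of a simulated labelling study."""

    days: tuple[float, ...] = (0.0, 1.0, 3.0, 6.0, 15.0, 31.0, 63.0, 127.0)
    animals_per_timepoint: int = 3
    phases: tuple[str, ...] = ("FM", "IFM")
    peptides_per_protein: int = 6
    noise_sd: float = 0.01  # additive Gaussian SD on M0 relative abundance
    missingness: float = 0.1  # P(drop) per (peptide, time point)
    serum_noise_sd: float = 0.002  # additive Gaussian SD on serum enrichment
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        if not days or days[0] != 0.0 or any(b <= a for a, b in zip(days, days[1:])):
            raise DomainError("days must be strictly increasing and start at 0")
        if not (0.0 <= self.missingness <= 1.0):
            raise DomainError(f"missingness must be in [0, 1], got {self.missingness}")
        if self.noise_sd < 0 or self.serum_noise_sd < 0:
            raise DomainError("noise SDs must be non-negative")
        if self.animals_per_timepoint < 1:
            raise DomainError("need at least one animal per time point")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated study: per-peptide k and chemistry, and the precursor curve."""

    table: pd.DataFrame  # columns: peptide, protein_id, phase, true_k, a, n_sites
    curve: EnrichmentCurve


@dataclass(frozen=True)
class StudyResult:
    """A complete simulated study: pipeline-ready tables plus ground truth."""

    peptide_table: pd.DataFrame
    serum: pd.DataFrame
    truth: SimulationTruth
    design: StudyDesign


def simulate_serum(
    design: StudyDesign,
    curve: EnrichmentCurve = DEFAULT_CURVE,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Serum enrichment observations: one record per animal per sampling day.

    Values follow precursor_at(t) plus Gaussian noise, truncated to [0, 1).
    Columns: time_day, animal_id, enrichment_fraction.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    sd = design.serum_noise_sd if noise_sd is None else noise_sd
    records = []
    for day in design.days:
        clean = precursor_at(curve, day)
        for animal in range(design.animals_per_timepoint):
            value = clean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            records.append(
                {
                    "time_day": day,
                    "animal_id": f"a{animal + 1}",
                    "enrichment_fraction": float(np.clip(value, 0.0, 1.0 - 1e-12)),
                }
            )
    return pd.DataFrame.from_records(records)


def simulate_peptide_series(
    chem: PeptideChemistry,
    true_k: float,
    design: StudyDesign,
    curve: EnrichmentCurve = DEFAULT_CURVE,
    rng: np.random.Generator | None = None,
    peptide: str | None = None,
    protein_id: str = "P1",
    phase: str = "whole",
) -> PeptideTimeSeries | None:
    """One peptide's M0 time series under the non-steady-state forward model.

    Each retained (day, replicate) record is model_m0_exact(true_k, t) plus
    Gaussian noise, clipped to (0, 1]; whole time points are dropped with the
    design's missingness probability.  Returns None when every time point was
    dropped (the empty-series flag).
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    times, reps, m0 = [], [], []
    clean = model_m0_exact(true_k, np.asarray(design.days), chem, curve)
    for day, value in zip(design.days, clean):
        if design.missingness > 0 and rng.random() < design.missingness:
            continue
        for rep in range(design.animals_per_timepoint):
            noisy = value + (rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0)
            times.append(day)
            reps.append(f"r{rep + 1}")
            m0.append(float(np.clip(noisy, 1e-6, 1.0)))
    if not times:
        return None
    return PeptideTimeSeries(
        peptide=peptide or chem.sequence,
        protein_id=protein_id,
        phase=phase,
        times=np.array(times),
        replicates=np.array(reps),
        m0=np.array(m0),
    )


def peptide_envelope(
    chem: PeptideChemistry,
    true_k: float,
    t: float,
    curve: EnrichmentCurve = DEFAULT_CURVE,
    max_isotopomer: int = 5,
) -> np.ndarray:
    """Theoretical isotopomer envelope M0..Mmax at time t, normalised to sum 1.

    Mixture of the surviving unlabelled pool (weight exp(-k t), natural
    envelope) and the newly synthesised pool, whose deuterium content is a
    binomial over round(N) sites at the synthesis-weighted mean enrichment,
    convolved with the natural envelope.  The natural envelope uses the same
    heavy-element convention as ``a`` (hydrogen excluded), and the truncated
    M0..Mmax window is renormalised, mirroring relative quantification over
    the observed peaks.
    """
    from .chem import isotope_envelope

    natural = isotope_envelope(
        chem.composition, max_shift=max_isotopomer, include_hydrogen=False
    )
    w_old = float(np.exp(-true_k * t))
    if w_old >= 1.0 - 1e-12:
        env = natural
    else:
        rel = float(model_m0_exact(true_k, t, chem, curve)) / chem.a
        rel_new_m0 = (rel - w_old) / (1.0 - w_old)
        n_int = max(int(round(chem.n_sites)), 1)
        p_eff = 1.0 - rel_new_m0 ** (1.0 / chem.n_sites) if chem.n_sites > 0 else 0.0
        j = np.arange(max_isotopomer + 1)
        from scipy.stats import binom

        label_dist = binom.pmf(j, n_int, p_eff)
        new_env = np.convolve(natural, label_dist)[: max_isotopomer + 1]
        env = w_old * natural + (1.0 - w_old) * new_env
    return env / env.sum()


def simulate_paired_k(
    n_pairs: int,
    phase_multiplier: float,
    rng: np.random.Generator,
    k_median: float = 0.010,
    k_log_sd: float = K_LOG_SD,
    noise_log_sd: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched FM/IFM rate-constant estimates for shared peptides.

    Each pair shares a lognormal peptide-level FM rate; the IFM member is
    ``phase_multiplier`` times faster.  Both members carry independent
    multiplicative lognormal estimation noise (``noise_log_sd``, emulating
    the scatter of per-peptide k fits).  Returns (k_fm, k_ifm) arrays.
    """
    base = k_median * np.exp(rng.normal(0.0, k_log_sd, size=n_pairs))
    k_fm = base * np.exp(rng.normal(0.0, noise_log_sd, size=n_pairs))
    k_ifm = base * phase_multiplier * np.exp(rng.normal(0.0, noise_log_sd, size=n_pairs))
    return k_fm, k_ifm


def _random_peptide(rng: np.random.Generator) -> str:
    """Random tryptic-like sequence (ends in K or R), length 8-22."""
    length = int(rng.integers(8, 23))
    body = rng.choice(_RESIDUES, size=length - 1)
    tail = rng.choice(np.array(["K", "R"]))
    return "".join(body) + tail


def _draw_chemistries(rng: np.random.Generator, n: int) -> list[PeptideChemistry]:
    """Unique synthetic peptides whose derived a lies in [0.3, 0.95] and N in [5, 40]."""
    out: list[PeptideChemistry] = []
    seen: set[str] = set()
    while len(out) < n:
        seq = _random_peptide(rng)
        if seq in seen:
            continue
        chem = PeptideChemistry.from_sequence(seq)
        if 0.3 <= chem.a <= 0.95 and 5.0 <= chem.n_sites <= 40.0:
            seen.add(seq)
            out.append(chem)
    return out


def simulate_study(
    design: StudyDesign | None = None,
    curve: EnrichmentCurve = DEFAULT_CURVE,
    n_proteins: int = 20,
    n_shared_peptides: int = 55,
    k_median: float = 0.010,
    k_log_sd: float = K_LOG_SD,
    phase_multiplier: float = 1.8,
    envelope: bool = False,
    seed: int | None = None,
) -> StudyResult:
    """Generate a complete two-phase labelling study with ground truth.

    Protein-level FM rate constants are lognormal(median ``k_median``,
    log-SD ``k_log_sd``); every IFM rate is the FM rate times
    ``phase_multiplier``.  ``n_shared_peptides`` peptides are observed in
    both phases (the basis for paired comparisons); the rest are assigned to
    a single phase with 2:1 FM weighting.  With ``envelope=True`` the
    peptide table carries isotopomers M0..M5 instead of M0 only.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(design.seed if seed is None else seed)

    n_peptides = n_proteins * design.peptides_per_protein
    if n_shared_peptides > n_peptides:
        raise DomainError(
            f"n_shared_peptides={n_shared_peptides} exceeds total peptides {n_peptides}"
        )
    chems = _draw_chemistries(rng, n_peptides)
    k_fm_protein = k_median * np.exp(rng.normal(0.0, k_log_sd, size=n_proteins))

    shared = set(range(n_shared_peptides))  # chem draw order is already random
    truth_rows, data_rows = [], []
    serum = simulate_serum(design, curve, rng=rng)

    for idx, chem in enumerate(chems):
        protein = idx // design.peptides_per_protein
        protein_id = f"PROT{protein + 1:03d}"
        k_fm = float(k_fm_protein[protein])
        if idx in shared:
            phases = list(design.phases)
        else:
            phases = [design.phases[0] if rng.random() < 2.0 / 3.0 else design.phases[1]]
        for phase in phases:
            true_k = k_fm * (phase_multiplier if phase == "IFM" else 1.0)
            series = simulate_peptide_series(
                chem, true_k, design, curve, rng=rng, protein_id=protein_id, phase=phase
            )
            truth_rows.append(
                {
                    "peptide": chem.sequence,
                    "protein_id": protein_id,
                    "phase": phase,
                    "true_k": true_k,
                    "a": chem.a,
                    "n_sites": chem.n_sites,
                }
            )
            if series is None:
                continue
            if envelope:
                for day, rep, m0 in zip(series.times, series.replicates, series.m0):
                    env = peptide_envelope(chem, true_k, float(day), curve)
                    # keep the noisy M0 and spread the residual over M1..M5
                    scale = (1.0 - m0) / (1.0 - env[0]) if env[0] < 1.0 else 0.0
                    values = np.concatenate([[m0], env[1:] * scale])
                    for iso, value in enumerate(values):
                        data_rows.append(
                            {
                                "peptide": chem.sequence,
                                "protein_id": protein_id,
                                "phase": phase,
                                "time_day": float(day),
                                "replicate": rep,
                                "isotopomer_index": iso,
                                "rel_abundance": float(value),
                            }
                        )
            else:
                for day, rep, m0 in zip(series.times, series.replicates, series.m0):
                    data_rows.append(
                        {
                            "peptide": chem.sequence,
                            "protein_id": protein_id,
                            "phase": phase,
                            "time_day": float(day),
                            "replicate": rep,
                            "isotopomer_index": 0,
                            "rel_abundance": float(m0),
                        }
                    )

    peptide_table = pd.DataFrame.from_records(data_rows)
    truth = SimulationTruth(table=pd.DataFrame.from_records(truth_rows), curve=curve)
    return StudyResult(peptide_table=peptide_table, serum=serum, truth=truth, design=design)
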