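"""CSV schemas, pipeline configuration and the end-to-end pipeline runner.

Interchange format is plain CSV (UTF-8, '.' decimal separator).  Schemas:

* peptide table (input): peptide, protein_id, phase, time_day, replicate,
  isotopomer_index, rel_abundance — M0 series are the rows with
  isotopomer_index = 0;
* serum table (input): time_day, animal_id, enrichment_fraction;
* peptide fits (output): peptide, protein_id, phase, k, r_squared, se,
  n_timepoints, method, accepted;
* protein turnover (output): protein_id, phase, n_peptides, k_median,
  k_mad, half_life_days;
* phase comparison (output): unit, test, statistic, p_value, n,
  median_fm, median_ifm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd

from . import __version__
from .aggregate import PhaseComparison, ProteinTurnover, aggregate_protein, compare_phases
from .chem import IsotopeTable, PeptideChemistry, default_isotope_table, load_site_table
from .errors import ConfigurationError, EmptyProteinError, InsufficientDataError, ParseError, SchemaError
from .kinetics import (
    KineticFit,
    PeptideTimeSeries,
    fit_k_manual,
    fit_k_nss,
    fit_k_two_exponential,
)
from .precursor import EnrichmentCurve, PrecursorFit, fit_precursor

logger = logging.getLogger("hwturnover")

PEPTIDE_COLUMNS = [
    "peptide",
    "protein_id",
    "phase",
    "time_day",
    "replicate",
    "isotopomer_index",
    "rel_abundance",
]
SERUM_COLUMNS = ["time_day", "animal_id", "enrichment_fraction"]

FIT_METHODS = ("nss_exact", "two_exponential", "manual_constrained")


@dataclass
class PipelineConfig:
    """All pipeline settings; every field can come from a key=value config file."""

    peptide_table: str = ""
    serum_table: str = ""
    out_dir: str = "results"
    method: str = "nss_exact"
    kp: float | None = None  # set both kp and pss to skip serum fitting
    pss: float | None = None
    min_timepoints: int = 4
    min_r_squared: float = 0.8
    max_se: float = 0.05
    min_unique_peptides: int = 1
    alpha: float = 0.05
    include_hydrogen: bool = False
    isotope_table: str = ""  # optional override CSV path
    site_table: str = ""  # optional override CSV path
    seed: int = 20200512

    def __post_init__(self) -> None:
        if self.method not in FIT_METHODS:
            raise ConfigurationError(f"method must be one of {FIT_METHODS}, got {self.method!r}")
        if self.min_timepoints < 1 or self.min_r_squared < 0 or self.max_se <= 0:
            raise ConfigurationError("filter thresholds must be positive")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Parse a plain key = value config file; later CLI overrides win."""
        known = {f.name: f for f in dc_fields(cls)}
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected key = value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ConfigurationError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _coerce(value, known[key].type)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(text: str, annotation) -> object:
    ann = str(annotation)
    if "bool" in ann:
        return text.lower() in ("1", "true", "yes", "on")
    if "int" in ann:
        return int(text)
    if "float" in ann:
        return None if text.lower() in ("", "none") else float(text)
    return text


def read_peptide_table(path) -> list[PeptideTimeSeries]:
    """Read the peptide isotopomer CSV and group M0 records into time series.

    Rows with isotopomer_index != 0 are ignored here (the M0 trace drives the
    kinetic fit).  Malformed rows raise :class:`ParseError` naming the line.
    """
    try:
        frame = pd.read_csv(path, dtype={"peptide": str, "protein_id": str, "phase": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty (no header)") from exc
    missing = [c for c in PEPTIDE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if frame.empty:
        logger.warning("%s: no data rows", path)
        return []
    for column in ("time_day", "rel_abundance", "isotopomer_index"):
        coerced = pd.to_numeric(frame[column], errors="coerce")
        bad = frame.index[coerced.isna() & frame[column].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"{path}: non-numeric {column} at line {int(bad[0]) + 2}: "
                f"{frame.loc[bad[0], column]!r}"
            )
        frame[column] = coerced
    m0 = frame[frame["isotopomer_index"] == 0]
    series: list[PeptideTimeSeries] = []
    for (peptide, protein_id, phase), group in m0.groupby(
        ["peptide", "protein_id", "phase"], sort=True
    ):
        series.append(
            PeptideTimeSeries(
                peptide=peptide,
                protein_id=protein_id,
                phase=phase,
                times=group["time_day"].to_numpy(dtype=float),
                replicates=group["replicate"].to_numpy(),
                m0=group["rel_abundance"].to_numpy(dtype=float),
            )
        )
    return series


def read_serum_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in SERUM_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return frame


def fits_to_frame(fits: list[KineticFit]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "peptide": f.peptide,
                "protein_id": f.protein_id,
                "phase": f.phase,
                "k": f.k,
                "r_squared": f.r_squared,
                "se": f.se,
                "n_timepoints": f.n_timepoints,
                "method": f.method,
                "accepted": f.accepted,
            }
            for f in fits
        ]
    )


def proteins_to_frame(proteins: list[ProteinTurnover]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "protein_id": p.protein_id,
                "phase": p.phase,
                "n_peptides": p.n_peptides,
                "k_median": p.k_median,
                "k_mad": p.k_mad,
                "half_life_days": p.half_life,
            }
            for p in proteins
        ]
    )


@dataclass
class PipelineReport:
    """Everything a pipeline run produced, plus where it was written."""

    precursor: PrecursorFit | None
    curve: EnrichmentCurve
    fits: list[KineticFit]
    proteins: list[ProteinTurnover]
    comparison: PhaseComparison | None
    outputs: dict = field(default_factory=dict)


def _fit_one(series, chem, curve, config) -> KineticFit:
    kwargs = dict(
        min_timepoints=config.min_timepoints,
        min_r_squared=config.min_r_squared,
        max_se=config.max_se,
    )
    if config.method == "manual_constrained":
        return fit_k_manual(series, chem, curve.pss, **kwargs)
    if config.method == "two_exponential":
        return fit_k_two_exponential(series, chem, curve, **kwargs)
    return fit_k_nss(series, chem, curve, **kwargs)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute serum fit → per-peptide kinetics → aggregation → phase comparison.

    Writes peptide_fits.csv, protein_turnover.csv, phase_comparison.csv (when
    both FM and IFM are present) and run_log.txt into ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    isotope_table = (
        IsotopeTable.from_csv(config.isotope_table, config.site_table or None)
        if config.isotope_table
        else default_isotope_table()
    )
    site_table = load_site_table(config.site_table) if config.site_table else isotope_table.site_values

    # stage 1: precursor kinetics
    precursor_fit = None
    if config.kp is not None and config.pss is not None:
        curve = EnrichmentCurve(kp=config.kp, pss=config.pss)
        logger.info("precursor: using configured kp=%.4f pss=%.4f", curve.kp, curve.pss)
    else:
        if not config.serum_table:
            raise ConfigurationError("either serum_table or both kp and pss must be configured")
        serum = read_serum_table(config.serum_table)
        precursor_fit = fit_precursor(
            serum["time_day"].to_numpy(float), serum["enrichment_fraction"].to_numpy(float)
        )
        curve = precursor_fit.curve
        logger.info(
            "precursor: fitted kp=%.4f pss=%.4f (R^2=%.4f)",
            curve.kp,
            curve.pss,
            precursor_fit.r_squared,
        )

    # stage 2: per-peptide kinetic fits
    all_series = read_peptide_table(config.peptide_table)
    fits: list[KineticFit] = []
    chem_cache: dict[str, PeptideChemistry] = {}
    for series in all_series:
        chem = chem_cache.get(series.peptide)
        if chem is None:
            chem = PeptideChemistry.from_sequence(
                series.peptide,
                isotope_table=isotope_table,
                site_table=site_table,
                include_hydrogen=config.include_hydrogen,
            )
            chem_cache[series.peptide] = chem
        try:
            fits.append(_fit_one(series, chem, curve, config))
        except InsufficientDataError as exc:
            logger.warning("fit skipped: %s", exc)
    n_accepted = sum(f.accepted for f in fits)
    logger.info("kinetics: %d peptide series fitted, %d accepted", len(fits), n_accepted)
    if fits and n_accepted == 0:
        logger.warning(
            "kinetics: zero peptides passed the acceptance filter "
            "(min_timepoints=%d, R^2>=%.2f or SE<=%.2f)",
            config.min_timepoints,
            config.min_r_squared,
            config.max_se,
        )

    # stage 3: protein-level aggregation
    proteins: list[ProteinTurnover] = []
    by_protein: dict[tuple[str, str], list[KineticFit]] = {}
    for fit in fits:
        if fit.accepted:
            by_protein.setdefault((fit.protein_id, fit.phase), []).append(fit)
    for (protein_id, phase), group in sorted(by_protein.items()):
        try:
            proteins.append(
                aggregate_protein(group, min_unique_peptides=config.min_unique_peptides)
            )
        except EmptyProteinError as exc:
            logger.warning("aggregation skipped for %s/%s: %s", protein_id, phase, exc)

    # stage 4: paired peptide-level FM vs IFM comparison on shared peptides
    comparison = None
    accepted = [f for f in fits if f.accepted]
    fm = {f.peptide: f.k for f in accepted if f.phase == "FM"}
    ifm = {f.peptide: f.k for f in accepted if f.phase == "IFM"}
    shared = sorted(set(fm) & set(ifm))
    if len(shared) >= 3:
        comparison = compare_phases(
            [fm[p] for p in shared],
            [ifm[p] for p in shared],
            paired=True,
            unit="peptide",
            alpha_normality=config.alpha,
        )
        logger.info(
            "comparison: %s on %d shared peptides, p=%.3g",
            comparison.test,
            comparison.n,
            comparison.p_value,
        )

    # stage 5: outputs
    outputs = {}
    fits_path = out_dir / "peptide_fits.csv"
    fits_to_frame(fits).to_csv(fits_path, index=False)
    outputs["fits"] = fits_path
    proteins_path = out_dir / "protein_turnover.csv"
    proteins_to_frame(proteins).to_csv(proteins_path, index=False)
    outputs["proteins"] = proteins_path
    if comparison is not None:
        comparison_path = out_dir / "phase_comparison.csv"
        pd.DataFrame.from_records(
            [
                {
                    "unit": comparison.unit,
                    "test": comparison.test,
                    "statistic": comparison.statistic,
                    "p_value": comparison.p_value,
                    "n": comparison.n,
                    "median_fm": comparison.median_a,
                    "median_ifm": comparison.median_b,
                }
            ]
        ).to_csv(comparison_path, index=False)
        outputs["comparison"] = comparison_path

    log_path = out_dir / "run_log.txt"
    log_path.write_text(
        "\n".join(
            [
                f"hwturnover version: {__version__}",
                f"seed: {config.seed}",
                f"method: {config.method}",
                f"kp: {curve.kp:.6f}",
                f"pss: {curve.pss:.6f}",
                f"filters: min_timepoints={config.min_timepoints} "
                f"min_r_squared={config.min_r_squared} max_se={config.max_se}",
                f"series fitted: {len(fits)}",
                f"accepted: {n_accepted}",
                f"proteins summarised: {len(proteins)}",
                "",
            ]
        )
    )
    outputs["log"] = log_path
    return PipelineReport(
        precursor=precursor_fit,
        curve=curve,
        fits=fits,
        proteins=proteins,
        comparison=comparison,
        outputs=outputs,
    )
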