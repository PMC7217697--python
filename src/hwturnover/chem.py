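"""Peptide isotope chemistry.

A peptide observed by LC-MS presents an isotopomer envelope M0, M1, ...
whose 0th peak (the monoisotopic species, all-light isotopes) has a natural
relative abundance ``a`` fixed by the elemental composition.  During
heavy-water labelling, newly synthesised peptide incorporates deuterium at
``N`` exchange-accessible hydrogen positions (a residue-dependent, possibly
fractional count), depressing M0.  At full labelling against a body-water
plateau enrichment ``pss`` the M0 relative abundance settles at

    A0_plateau = a * (1 - pss) ** N

This module computes compositions, ``a``, ``N``, the plateau, and full
natural isotopomer envelopes (by brute-force convolution) from sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from pyteomics import mass as _ptmass

from .errors import ConfigurationError, DomainError, InvalidSequenceError

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Composition deltas for supported peptide modifications (applied per site).
MODIFICATION_DELTAS: dict[str, dict[str, int]] = {
    # iodoacetamide alkylation of cysteine
    "carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
    # oxidation of methionine or proline
    "oxidation": {"O": 1},
}


@dataclass(frozen=True)
class ElementComposition:
    """Atom counts per element symbol for one molecular species."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for element, count in self.counts.items():
            if count < 0:
                raise DomainError(f"negative atom count for element {element!r}: {count}")

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def items(self):
        return self.counts.items()

    def total_atoms(self) -> int:
        return int(sum(self.counts.values()))

    def add(self, delta: Mapping[str, int], times: int = 1) -> "ElementComposition":
        merged = dict(self.counts)
        for element, count in delta.items():
            merged[element] = merged.get(element, 0) + times * count
        return ElementComposition({e: c for e, c in merged.items() if c != 0})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementComposition):
            return NotImplemented
        keys = set(self.counts) | set(other.counts)
        return all(self[k] == other[k] for k in keys)

    def __hash__(self) -> int:
        return hash(frozenset((k, v) for k, v in self.counts.items() if v))


@dataclass(frozen=True)
class IsotopeTable:
    """Natural isotope abundances per element and the residue labelling-site table.

    ``abundances`` maps an element symbol to a list of ``(mass_shift,
    fraction)`` pairs; the fractions for each element must sum to 1 within
    1e-9.  ``site_values`` maps a one-letter residue code to its number of
    deuterium-accessible labelling sites.
    """

    abundances: Mapping[str, tuple[tuple[int, float], ...]]
    site_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for element, pairs in self.abundances.items():
            total = sum(p for _, p in pairs)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"isotope abundances for {element!r} sum to {total!r}, not 1"
                )
            for shift, frac in pairs:
                if shift < 0 or not (0.0 <= frac <= 1.0):
                    raise ConfigurationError(
                        f"invalid isotope entry for {element!r}: shift={shift}, abundance={frac}"
                    )

    def light_abundance(self, element: str) -> float:
        """Abundance of the lightest (mass shift 0) isotope of ``element``."""
        pairs = self.abundances.get(element)
        if pairs is None:
            raise ConfigurationError(f"element {element!r} missing from isotope table")
        for shift, frac in pairs:
            if shift == 0:
                return frac
        raise ConfigurationError(f"element {element!r} has no mass-shift-0 isotope")

    def shift_distribution(self, element: str) -> np.ndarray:
        """Abundances as a dense array indexed by mass shift."""
        pairs = self.abundances.get(element)
        if pairs is None:
            raise ConfigurationError(f"element {element!r} missing from isotope table")
        out = np.zeros(max(s for s, _ in pairs) + 1)
        for shift, frac in pairs:
            out[shift] = frac
        return out

    @classmethod
    def from_csv(cls, isotope_path, site_path=None) -> "IsotopeTable":
        """Load from the documented CSV schemas.

        ``isotope_path``: columns element, mass_shift, abundance.
        ``site_path`` (optional): columns residue, n_sites.
        """
        table: dict[str, list[tuple[int, float]]] = {}
        with open(isotope_path, newline="") as handle:
            for row in csv.DictReader(handle):
                table.setdefault(row["element"], []).append(
                    (int(row["mass_shift"]), float(row["abundance"]))
                )
        sites: dict[str, float] = {}
        if site_path is not None:
            sites = load_site_table(site_path)
        return cls({e: tuple(v) for e, v in table.items()}, sites)

    @classmethod
    def default(cls) -> "IsotopeTable":
        """IUPAC natural abundances and literature rat labelling-site values."""
        pkg = resources.files("hwturnover.data")
        with resources.as_file(pkg / "isotope_abundances.csv") as iso_path, resources.as_file(
            pkg / "residue_labeling_sites.csv"
        ) as site_path:
            return cls.from_csv(iso_path, site_path)


def load_site_table(path) -> dict[str, float]:
    """Read a residue→labelling-site CSV (columns residue, n_sites)."""
    sites: dict[str, float] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or not {"residue", "n_sites"} <= set(reader.fieldnames):
            raise ConfigurationError(f"site table {path} must have columns residue,n_sites")
        for row in reader:
            value = float(row["n_sites"])
            if value < 0:
                raise ConfigurationError(f"negative site count for residue {row['residue']!r}")
            sites[row["residue"]] = value
    return sites


_DEFAULT_TABLE: IsotopeTable | None = None


def default_isotope_table() -> IsotopeTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = IsotopeTable.default()
    return _DEFAULT_TABLE


def composition_from_sequence(
    sequence: str, modifications: list[str] | None = None
) -> ElementComposition:
    """Elemental composition of a peptide: residue sum plus one terminal water.

    ``modifications`` lists modification names from :data:`MODIFICATION_DELTAS`
    (one entry per modified site, e.g. ``["carbamidomethyl", "oxidation"]``).
    """
    if not sequence:
        raise InvalidSequenceError("empty peptide sequence")
    for ch in sequence:
        if ch not in STANDARD_RESIDUES:
            raise InvalidSequenceError(f"unknown residue code {ch!r} in sequence {sequence!r}")
    comp = ElementComposition(dict(_ptmass.Composition(sequence=sequence)))
    for mod in modifications or []:
        delta = MODIFICATION_DELTAS.get(mod)
        if delta is None:
            raise ConfigurationError(
                f"unknown modification {mod!r}; known: {sorted(MODIFICATION_DELTAS)}"
            )
        comp = comp.add(delta)
    return comp


def natural_m0_abundance(
    composition: ElementComposition,
    isotope_table: IsotopeTable | None = None,
    include_hydrogen: bool = False,
) -> float:
    """Natural relative abundance ``a`` of the monoisotopic (M0) species.

    The probability that every atom is its lightest isotope: the product over
    elements of (light abundance)^(atom count).  By default hydrogen is
    excluded (contributes factor 1), matching the convention of computing
    ``a`` from the heavy isotopes of C, N, O and S only; set
    ``include_hydrogen=True`` to count natural deuterium as well.
    """
    table = isotope_table or default_isotope_table()
    result = 1.0
    for element, count in composition.items():
        if element == "H" and not include_hydrogen:
            continue
        if count:
            result *= table.light_abundance(element) ** count
    return result


def isotope_envelope(
    composition: ElementComposition,
    isotope_table: IsotopeTable | None = None,
    max_shift: int = 10,
    include_hydrogen: bool = True,
) -> np.ndarray:
    """Natural isotopomer envelope by brute-force convolution.

    Convolves the per-atom isotope shift distributions of every atom in the
    composition and returns abundances for mass shifts 0..max_shift (the
    truncated tail mass is simply dropped, so the array sums to ≤ 1).
    """
    table = isotope_table or default_isotope_table()
    envelope = np.array([1.0])
    for element, count in composition.items():
        if element == "H" and not include_hydrogen:
            continue
        dist = table.shift_distribution(element)
        for _ in range(count):
            envelope = np.convolve(envelope, dist)[: max_shift + 1]
    out = np.zeros(max_shift + 1)
    out[: envelope.size] = envelope
    return out


def labeling_sites(sequence: str, site_table: Mapping[str, float] | None = None) -> float:
    """Total number of deuterium-accessible labelling sites ``N`` of a peptide.

    Sums the per-residue site values (additive over concatenation).  Values
    may be fractional because site accessibility is a population average.
    """
    if not sequence:
        raise InvalidSequenceError("empty peptide sequence")
    table = site_table if site_table is not None else default_isotope_table().site_values
    total = 0.0
    for ch in sequence:
        if ch not in table:
            raise ConfigurationError(f"residue {ch!r} missing from labelling-site table")
        total += table[ch]
    return total


def plateau_m0(a: float, pss: float, n_sites: float) -> float:
    """M0 relative abundance at full labelling: ``a * (1 - pss) ** N``.

    ``a`` is the natural M0 abundance, ``pss`` the plateau precursor
    enrichment and ``n_sites`` the labelling-site count N.
    """
    if not (0.0 < a <= 1.0):
        raise DomainError(f"a must be in (0, 1], got {a}")
    if not (0.0 <= pss < 1.0):
        raise DomainError(f"pss must be in [0, 1), got {pss}")
    if n_sites < 0:
        raise DomainError(f"N must be non-negative, got {n_sites}")
    return a * (1.0 - pss) ** n_sites


@dataclass(frozen=True)
class PeptideChemistry:
    """Per-peptide constants needed by the kinetic model: sequence, composition, a, N."""

    sequence: str
    composition: ElementComposition
    a: float
    n_sites: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a <= 1.0):
            raise DomainError(f"a must be in (0, 1], got {self.a}")
        if self.n_sites < 0:
            raise DomainError(f"N must be non-negative, got {self.n_sites}")

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        modifications: list[str] | None = None,
        isotope_table: IsotopeTable | None = None,
        site_table: Mapping[str, float] | None = None,
        include_hydrogen: bool = False,
    ) -> "PeptideChemistry":
        comp = composition_from_sequence(sequence, modifications)
        table = isotope_table or default_isotope_table()
        return cls(
            sequence=sequence,
            composition=comp,
            a=natural_m0_abundance(comp, table, include_hydrogen=include_hydrogen),
            n_sites=labeling_sites(sequence, site_table if site_table is not None else table.site_values),
        )

    def plateau(self, pss: float) -> float:
        return plateau_m0(self.a, pss, self.n_sites)
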