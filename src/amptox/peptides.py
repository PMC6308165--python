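"""Sequence-derived physicochemical descriptors for linear peptides.

Everything here is closed-form arithmetic over per-residue constants:
monoisotopic and average mass (with optional C-terminal amidation),
protonated-ion m/z, the GRAVY hydropathy index (Kyte-Doolittle), and a
residue/basicity census.  Residue mass tables are taken from pyteomics;
the hydropathy scale from Biopython.  Only the 20 canonical residues are
accepted; the single supported modification is C-terminal amidation
(-OH -> -NH2, a shift of about -0.984 Da).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE
from pyteomics import mass as _pmass

__all__ = [
    "CANONICAL_RESIDUES",
    "BASIC_RESIDUES",
    "CTerm",
    "PeptideSequence",
    "MassTable",
    "HydropathyScale",
    "PeptideValidationError",
    "parse_peptide",
    "monoisotopic_mass",
    "average_mass",
    "protonated_mz",
    "gravy",
    "count_basic",
    "residue_counts",
    "describe",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Arg and Lys are strongly basic; His is included as weakly basic at pH 7.
BASIC_RESIDUES = frozenset("RKH")

PROTON_MASS = _pmass.calculate_mass(formula="H") - _pmass.nist_mass["e*"][0][0]


class PeptideValidationError(ValueError):
    """Raised when a peptide string fails validation."""


class CTerm(enum.Enum):
    """C-terminal chemistry of a peptide chain."""

    FREE_ACID = "free_acid"
    AMIDE = "amide"


def _residue_mass_tables() -> tuple[dict[str, float], dict[str, float]]:
    mono, avg = {}, {}
    for aa in CANONICAL_RESIDUES:
        comp = _pmass.std_aa_comp[aa]
        mono[aa] = _pmass.calculate_mass(composition=comp)
        avg[aa] = _pmass.calculate_mass(composition=comp, average=True)
    return mono, avg


@dataclass(frozen=True)
class MassTable:
    """Per-residue mass constants used by all mass computations (Da)."""

    monoisotopic: dict[str, float]
    average: dict[str, float]
    water_monoisotopic: float
    water_average: float
    proton: float
    amide_delta_monoisotopic: float
    amide_delta_average: float

    @classmethod
    def standard(cls) -> "MassTable":
        mono, avg = _residue_mass_tables()
        return cls(
            monoisotopic=mono,
            average=avg,
            water_monoisotopic=_pmass.calculate_mass(formula="H2O"),
            water_average=_pmass.calculate_mass(formula="H2O", average=True),
            proton=PROTON_MASS,
            amide_delta_monoisotopic=(
                _pmass.calculate_mass(formula="NH2") - _pmass.calculate_mass(formula="OH")
            ),
            amide_delta_average=(
                _pmass.calculate_mass(formula="NH2", average=True)
                - _pmass.calculate_mass(formula="OH", average=True)
            ),
        )


_STANDARD_MASSES = MassTable.standard()


@dataclass(frozen=True)
class HydropathyScale:
    """Per-residue hydropathy values; default is Kyte-Doolittle."""

    values: dict[str, float] = field(default_factory=lambda: dict(_KYTE_DOOLITTLE))

    def __post_init__(self) -> None:
        missing = CANONICAL_RESIDUES - set(self.values)
        if missing:
            raise ValueError(f"hydropathy scale missing residues: {sorted(missing)}")


_KD_SCALE = HydropathyScale()


@dataclass(frozen=True)
class PeptideSequence:
    """A validated linear peptide: uppercase one-letter codes plus C-terminal state."""

    residues: str
    cterm: CTerm = CTerm.FREE_ACID
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise PeptideValidationError("peptide must contain at least one residue")
        for i, aa in enumerate(self.residues, start=1):
            if aa not in CANONICAL_RESIDUES:
                raise PeptideValidationError(
                    f"non-canonical residue {aa!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def parse_peptide(text: str, cterm: CTerm | str = CTerm.FREE_ACID, name: str = "") -> PeptideSequence:
    """Validate a one-letter peptide string (case-insensitive) into a PeptideSequence."""
    if isinstance(cterm, str):
        cterm = CTerm(cterm)
    cleaned = "".join(text.split()).upper()
    if not cleaned:
        raise PeptideValidationError("empty peptide sequence")
    return PeptideSequence(residues=cleaned, cterm=cterm, name=name)


def monoisotopic_mass(seq: PeptideSequence, table: MassTable = _STANDARD_MASSES) -> float:
    """Neutral monoisotopic mass in Da (full precision; display rounds to 1 decimal)."""
    m = sum(table.monoisotopic[aa] for aa in seq.residues) + table.water_monoisotopic
    if seq.cterm is CTerm.AMIDE:
        m += table.amide_delta_monoisotopic
    return m


def average_mass(seq: PeptideSequence, table: MassTable = _STANDARD_MASSES) -> float:
    """Neutral average (isotope-abundance-weighted) mass in Da."""
    m = sum(table.average[aa] for aa in seq.residues) + table.water_average
    if seq.cterm is CTerm.AMIDE:
        m += table.amide_delta_average
    return m


def protonated_mz(seq: PeptideSequence, charge: int = 1, table: MassTable = _STANDARD_MASSES) -> float:
    """m/z of the [M+zH]z+ ion from the monoisotopic neutral mass."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (monoisotopic_mass(seq, table) + charge * table.proton) / charge


def gravy(seq: PeptideSequence, scale: HydropathyScale = _KD_SCALE) -> float:
    """Grand average of hydropathicity: mean per-residue hydropathy over the chain.

    Negative values indicate a hydrophilic peptide.  Displayed to three
    decimals by convention.
    """
    return sum(scale.values[aa] for aa in seq.residues) / len(seq)


def count_basic(seq: PeptideSequence) -> int:
    """Number of basic residues (Arg, Lys, His)."""
    return sum(aa in BASIC_RESIDUES for aa in seq.residues)


def residue_counts(seq: PeptideSequence) -> dict[str, int]:
    """Census of residue occurrences, keyed by one-letter code."""
    return dict(Counter(seq.residues))


def describe(seq: PeptideSequence) -> dict[str, object]:
    """Descriptor bundle at the conventional display precisions."""
    return {
        "name": seq.name,
        "length": len(seq),
        "monoisotopic_mass": round(monoisotopic_mass(seq), 1),
        "mh_plus": round(protonated_mz(seq, 1), 1),
        "average_mass": round(average_mass(seq)),
        "gravy": round(gravy(seq), 3),
        "basic_count": count_basic(seq),
    }
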