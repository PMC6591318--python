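"""Monoisotopic mass tables and all mass / m/z arithmetic.

Every other stage of the pipeline routes its arithmetic through this
module so that a single residue-mass table (shipped as a versioned
plain-text file, overridable by the user) governs all reported masses.

Masses are monoisotopic throughout.  Glycan building blocks are treated
generically at the mass level: a hexose residue increment (Hex,
162.05282 Da), a hexuronic-acid residue increment (HexA, 176.03209 Da)
and a sulfate (SO3, 79.95682 Da).  Mass spectrometry cannot distinguish
glucose from mannose, so compositions are never given a sugar identity.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "HEX_MASS",
    "HEXA_MASS",
    "SULFATE_MASS",
    "MASS_TABLE_VERSION",
    "ResidueMassTable",
    "GlycanComposition",
    "GlycopeptideIon",
    "load_default_table",
    "peptide_mass",
    "glycan_mass",
    "mz",
    "ppm_error",
    "glycoform_mz",
    "round_mz",
]

PROTON_MASS = 1.0072765
WATER_MASS = 18.0105646

HEX_MASS = 162.05282
HEXA_MASS = 176.03209
SULFATE_MASS = 79.95682

#: Carbamidomethylation of cysteine from iodoacetamide alkylation,
#: applied as a fixed modification.
CARBAMIDOMETHYL = 57.02146

MASS_TABLE_VERSION = "1"


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus fixed modifications.

    Parameters
    ----------
    residue_masses
        One-letter amino-acid code to monoisotopic residue mass (Da).
    water_mass, proton_mass
        Terminal water and proton masses (Da).
    fixed_mods
        Residue code to mass shift (Da), added on every occurrence.
        Defaults to carbamidomethyl on C.
    version
        Identifier of the shipped table the instance derives from.
    """

    residue_masses: dict[str, float]
    water_mass: float = WATER_MASS
    proton_mass: float = PROTON_MASS
    fixed_mods: dict[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )
    version: str = MASS_TABLE_VERSION

    def __post_init__(self) -> None:
        if not self.residue_masses:
            raise ValueError("residue mass table is empty")
        bad = [r for r, m in self.residue_masses.items() if m <= 0]
        if bad:
            raise ValueError(f"non-positive residue masses for {bad!r}")
        if self.water_mass <= 0 or self.proton_mass <= 0:
            raise ValueError("water and proton masses must be positive")

    def without_fixed_mods(self) -> "ResidueMassTable":
        return replace(self, fixed_mods={})


def load_default_table(path: str | None = None) -> ResidueMassTable:
    """Load the shipped residue-mass table, or a user override.

    The file format is two tab-separated columns (residue, mass in Da);
    lines starting with ``#`` are comments.
    """
    if path is None:
        ref = importlib.resources.files("glycoladder.data").joinpath(
            f"residue_masses_v{MASS_TABLE_VERSION}.tsv"
        )
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    masses: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, value = line.split("\t")
        masses[code] = float(value)
    return ResidueMassTable(residue_masses=masses)


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Integer counts of glycan units defining a candidate N-glycan."""

    hex_count: int = 0
    hexa_count: int = 0
    sulfate_count: int = 0

    def __post_init__(self) -> None:
        if min(self.hex_count, self.hexa_count, self.sulfate_count) < 0:
            raise ValueError("glycan unit counts must be non-negative")

    @property
    def total_units(self) -> int:
        return self.hex_count + self.hexa_count + self.sulfate_count

    def label(self) -> str:
        """Human-readable composition label, e.g. ``Hex, HexA_3``."""
        parts = []
        for count, name in (
            (self.hex_count, "Hex"),
            (self.hexa_count, "HexA"),
            (self.sulfate_count, "SO3"),
        ):
            if count == 1:
                parts.append(name)
            elif count > 1:
                parts.append(f"{name}_{count}")
        return ", ".join(parts) if parts else "unmodified"


EMPTY_GLYCAN = GlycanComposition(0, 0, 0)


@dataclass(frozen=True)
class GlycopeptideIon:
    """A peptide + glycan + charge with its theoretical m/z."""

    peptide_sequence: str
    glycan: GlycanComposition
    charge: int
    theoretical_mz: float
    sequon_position: int | None = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


def peptide_mass(sequence: str, table: ResidueMassTable) -> float:
    """Neutral monoisotopic peptide mass (Da), fixed mods included.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a residue code absent from
        the table; the message names the offending character and its
        1-based position.
    """
    if not sequence:
        raise ValueError("peptide sequence is empty")
    total = table.water_mass
    for i, residue in enumerate(sequence, start=1):
        try:
            total += table.residue_masses[residue]
        except KeyError:
            raise ValueError(
                f"unknown residue code {residue!r} at position {i} "
                f"of {sequence!r}"
            ) from None
        total += table.fixed_mods.get(residue, 0.0)
    return total


def glycan_mass(glycan: GlycanComposition) -> float:
    """Mass shift (Da) contributed by a glycan composition."""
    return (
        glycan.hex_count * HEX_MASS
        + glycan.hexa_count * HEXA_MASS
        + glycan.sulfate_count * SULFATE_MASS
    )


def mz(neutral_mass: float, charge: int, table: ResidueMassTable) -> float:
    """m/z (Th) of the [M+zH]^z+ ion of a neutral mass."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * table.proton_mass) / charge


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError(
            f"theoretical m/z must be positive, got {theoretical_mz}"
        )
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def glycoform_mz(
    sequence: str,
    glycan: GlycanComposition,
    charge: int,
    table: ResidueMassTable,
    sequon_position: int | None = None,
) -> GlycopeptideIon:
    """Theoretical ion for a peptide carrying a glycan at a given charge."""
    neutral = peptide_mass(sequence, table) + glycan_mass(glycan)
    return GlycopeptideIon(
        peptide_sequence=sequence,
        glycan=glycan,
        charge=charge,
        theoretical_mz=mz(neutral, charge, table),
        sequon_position=sequon_position,
    )


def round_mz(value: float, ndigits: int = 2) -> float:
    """Round-half-up to `ndigits` decimals, matching reported precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
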