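"""Glycan-loss (Y-type) fragment annotation for glycopeptide MS/MS spectra.

Collision-induced dissociation of a glycopeptide preferentially breaks
glycosidic bonds, leaving the intact peptide plus successively truncated
glycans (Y ions).  The Y series of a precursor is therefore the same
mass ladder searched in MS1, reinterpreted as fragments of a single
precursor — including the bare peptide and the intact glycopeptide.

Fragments from a linear ion trap carry far larger mass errors than
Orbitrap MS1 peaks, so matching here uses an absolute Da tolerance
(default 0.25 Da) rather than ppm.  Peptide-backbone b/y ions are out of
scope; the inference rests on glycan losses alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .laddersearch import PeakList, ladder_compositions
from .masscalc import (
    EMPTY_GLYCAN,
    GlycanComposition,
    ResidueMassTable,
    glycoform_mz,
)

__all__ = [
    "FragmentAnnotation",
    "y_series",
    "annotate_msms",
    "is_consistent",
]

DEFAULT_FRAGMENT_TOLERANCE_DA = 0.25
DEFAULT_MIN_MATCHES = 3


@dataclass(frozen=True)
class FragmentAnnotation:
    label: str
    theoretical_mz: float
    observed_mz: float | None
    error_da: float | None
    charge: int

    @property
    def matched(self) -> bool:
        return self.observed_mz is not None


def _step_label(glycan: GlycanComposition) -> str:
    return "peptide" if glycan == EMPTY_GLYCAN else f"peptide+{glycan.label()}"


def y_series(
    peptide_sequence: str,
    composition: GlycanComposition,
    charge: int,
    table: ResidueMassTable,
) -> list[tuple[str, float]]:
    """Theoretical Y-ion series from bare peptide to intact precursor.

    Fragment charge is taken equal to the precursor charge; entries are
    (label, theoretical m/z) in order of increasing glycan mass.
    """
    return [
        (
            _step_label(glycan),
            glycoform_mz(peptide_sequence, glycan, charge, table).theoretical_mz,
        )
        for glycan in ladder_compositions(composition)
    ]


def annotate_msms(
    spectrum: PeakList,
    peptide_sequence: str,
    composition: GlycanComposition,
    charge: int,
    table: ResidueMassTable,
    tolerance_da: float = DEFAULT_FRAGMENT_TOLERANCE_DA,
) -> list[FragmentAnnotation]:
    """Match each Y-series entry to the nearest peak within `tolerance_da`.

    Unmatched entries are returned with observed m/z set to None.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be positive")
    if spectrum.ms_level != 2 or spectrum.precursor_mz is None:
        raise ValueError("annotate_msms requires an MS2 spectrum with a precursor m/z")
    annotations = []
    for label, theo in y_series(peptide_sequence, composition, charge, table):
        best_obs: float | None = None
        best_err: float | None = None
        for obs, _intensity in spectrum.peaks:
            err = obs - theo
            if abs(err) > tolerance_da:
                continue
            if best_err is None or abs(err) < abs(best_err):
                best_obs, best_err = obs, err
        annotations.append(
            FragmentAnnotation(
                label=label,
                theoretical_mz=theo,
                observed_mz=best_obs,
                error_da=best_err,
                charge=charge,
            )
        )
    return annotations


def is_consistent(
    annotations: list[FragmentAnnotation],
    min_matches: int = DEFAULT_MIN_MATCHES,
) -> bool:
    """Whether a spectrum supports the composition: >= K series members match."""
    return sum(a.matched for a in annotations) >= min_matches
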