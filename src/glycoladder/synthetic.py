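"""Synthetic instrument-output generators with known ground truth.

Every pipeline stage can be exercised without any external download:

* :func:`gen_fixture_proteome` — five archaellin-like proteins, each
  embedding its experimentally characterized glycopeptides between
  flanking sequences built so that sequential trypsin + Glu-C digestion
  releases the payload peptides exactly;
* :func:`gen_ms1` — an MS1 peak list carrying a glycoform ladder with
  ppm-scale Normal mass jitter, log-normal intensities and uniform
  decoy peaks;
* :func:`gen_msms` — a Y-ion fragment spectrum with Da-scale Normal
  fragment error (ion-trap accuracy) plus decoys;
* :func:`gen_ct_table` — replicated qPCR Ct tables with per-gene true
  fold-changes decomposed into biological and technical Normal noise.

All generators are pure functions of (truth, seed): the same seed
always reproduces the same output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digestion import ProteinRecord
from .laddersearch import PeakList, ladder_compositions
from .masscalc import (
    GlycanComposition,
    ResidueMassTable,
    glycoform_mz,
    load_default_table,
)
from .msms import y_series

__all__ = [
    "ARCHAELLIN_PEPTIDES",
    "SpectrumTruth",
    "CtTruth",
    "gen_fixture_proteome",
    "gen_ms1",
    "gen_msms",
    "gen_ct_table",
]

#: The experimentally characterized archaellin glycopeptides: for each
#: archaellin-like fixture protein, (peptide sequence, 1-based position
#: of the glycosylated Asn within the peptide).
ARCHAELLIN_PEPTIDES: dict[str, list[tuple[str, int]]] = {
    "FlaA1": [("TASGTDTVDYANLTVR", 12), ("QAAGADNINLSK", 9)],
    "FlaA2": [("QAAGADNINLSK", 9), ("FNTTSIK", 2), ("VDYVNLTVR", 5)],
    "FlaB1": [("VDYVNLTVR", 5), ("QAAGADNINLTK", 9)],
    "FlaB2": [("QAAGADNINLSK", 9), ("VVNYANLTVR", 6)],
    "FlaB3": [("VDYVNLTVR", 5), ("QAAGADNINLTK", 9)],
}

# Flank residues avoid N (no accidental sequons), K/R/E (no extra
# cleavage complexity inside a flank) and P (no cleavage suppression at
# payload boundaries).
_FLANK_ALPHABET = "AGSTVLDFY"

TETRASACCHARIDE = GlycanComposition(1, 3, 0)

DEFAULT_MZ_RANGE = (400.0, 2000.0)


@dataclass(frozen=True)
class SpectrumTruth:
    """Ground truth for one synthetic glycopeptide spectrum."""

    peptide: str = "VVNYANLTVR"
    sequon_position: int = 6
    composition: GlycanComposition = TETRASACCHARIDE
    charge: int = 2
    occupied_steps: frozenset[int] | None = None  # None = all steps
    ppm_jitter_sd: float = 5.0
    n_decoys: int = 20
    seed: int = 0
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE

    def __post_init__(self) -> None:
        if self.ppm_jitter_sd < 0:
            raise ValueError("ppm_jitter_sd must be >= 0")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")


@dataclass(frozen=True)
class CtTruth:
    """Ground truth for a synthetic qPCR Ct table.

    `fold_changes` maps (strain, phase, gene) to the true expression
    fold-change relative to (control_strain, same phase); the reference
    gene is pinned to fold-change 1 everywhere.
    """

    genes: tuple[str, ...] = ("flaA1", "flaA2", "flaB1", "flaB2", "flaB3")
    reference_gene: str = "rrn16S"
    strains: tuple[str, str] = ("parent", "delta_aglB")
    control_strain: str = "parent"
    phases: tuple[str, ...] = ("log", "stationary")
    baseline_ct: dict[str, float] = field(
        default_factory=lambda: {
            "flaA1": 22.0, "flaA2": 23.0, "flaB1": 21.5,
            "flaB2": 22.5, "flaB3": 23.5, "rrn16S": 12.0,
        }
    )
    fold_changes: dict[tuple[str, str, str], float] = field(default_factory=dict)
    n_bio_reps: int = 3
    n_tech_reps: dict[str, int] = field(
        default_factory=lambda: {"log": 8, "stationary": 4}
    )
    biological_sd: float = 0.3
    technical_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.biological_sd < 0 or self.technical_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def true_fold_change(self, strain: str, phase: str, gene: str) -> float:
        if gene == self.reference_gene or strain == self.control_strain:
            return 1.0
        return self.fold_changes.get((strain, phase, gene), 1.0)


def gen_fixture_proteome(
    seed: int = 0,
    flank_length: int = 8,
) -> list[ProteinRecord]:
    """Five archaellin-like proteins embedding the characterized peptides.

    Each payload peptide is preceded by a random flank ending in K, so
    trypsin opens its N-terminus; every payload ends in K or R, so
    trypsin closes its C-terminus; flanks contain no K/R/E/P/N, so the
    payloads survive Glu-C digestion intact, acquire no missed
    cleavages, and the flanks contribute no sequons.  The embedded
    peptides are seed-invariant; only the flanks vary.
    """
    rng = np.random.default_rng(seed)
    records = []
    for name, peptides in ARCHAELLIN_PEPTIDES.items():
        parts = []
        for pep, _asn in peptides:
            flank = "".join(rng.choice(list(_FLANK_ALPHABET), size=flank_length))
            parts.append(flank + "K" + pep)
        tail = "".join(rng.choice(list(_FLANK_ALPHABET), size=flank_length))
        records.append(
            ProteinRecord(
                id=name,
                sequence="".join(parts) + tail,
                description=f"synthetic archaellin-like fixture ({name})",
            )
        )
    return records


def _intensities(rng: np.random.Generator, n: int) -> np.ndarray:
    # log-normal around 1e5 counts, ~3x geometric spread
    return np.exp(rng.normal(np.log(1e5), 1.0, size=n))


def _assemble(
    signal_mz: np.ndarray,
    rng: np.random.Generator,
    n_decoys: int,
    mz_range: tuple[float, float],
    **meta,
) -> PeakList:
    decoy_mz = rng.uniform(*mz_range, size=n_decoys)
    mzs = np.concatenate([signal_mz, decoy_mz])
    intensities = np.concatenate(
        [_intensities(rng, len(signal_mz)), _intensities(rng, n_decoys)]
    )
    order = np.argsort(mzs)
    peaks = tuple(
        (float(mzs[i]), float(intensities[i])) for i in order
    )
    return PeakList(peaks=peaks, **meta)


def gen_ms1(
    truth: SpectrumTruth,
    table: ResidueMassTable | None = None,
) -> PeakList:
    """MS1 peak list with the truth's glycoform ladder plus decoys."""
    if table is None:
        table = load_default_table()
    rng = np.random.default_rng(truth.seed)
    steps = ladder_compositions(truth.composition)
    occupied = (
        range(len(steps)) if truth.occupied_steps is None else truth.occupied_steps
    )
    theo = np.array(
        [
            glycoform_mz(truth.peptide, steps[i], truth.charge, table).theoretical_mz
            for i in sorted(occupied)
        ]
    )
    jitter = rng.normal(0.0, truth.ppm_jitter_sd * 1e-6, size=len(theo))
    return _assemble(
        theo * (1.0 + jitter),
        rng,
        truth.n_decoys,
        truth.mz_range,
        ms_level=1,
        source_id=f"synthetic-ms1-seed{truth.seed}",
    )


def gen_msms(
    truth: SpectrumTruth,
    fragment_sd_da: float = 0.1,
    table: ResidueMassTable | None = None,
) -> PeakList:
    """MS2 Y-ion spectrum of the truth's glycopeptide precursor."""
    if fragment_sd_da < 0:
        raise ValueError("fragment_sd_da must be >= 0")
    if table is None:
        table = load_default_table()
    rng = np.random.default_rng(truth.seed)
    series = y_series(truth.peptide, truth.composition, truth.charge, table)
    theo = np.array([mz for _label, mz in series])
    observed = theo + rng.normal(0.0, fragment_sd_da, size=len(theo))
    precursor = float(theo[-1])
    return _assemble(
        observed,
        rng,
        truth.n_decoys,
        truth.mz_range,
        ms_level=2,
        precursor_mz=precursor,
        precursor_charge=truth.charge,
        source_id=f"synthetic-msms-seed{truth.seed}",
    )


def gen_ct_table(truth: CtTruth) -> pd.DataFrame:
    """Replicated Ct table under the truth's fold-changes and noise model.

    Ct = baseline - log2(fold-change) + bio noise (shared within a
    biological replicate) + tech noise (per well).  The reference gene's
    fold-change is 1 in every condition.
    """
    rng = np.random.default_rng(truth.seed)
    rows = []
    genes = (*truth.genes, truth.reference_gene)
    for strain in truth.strains:
        for phase in truth.phases:
            n_tech = truth.n_tech_reps[phase]
            for gene in genes:
                base = truth.baseline_ct[gene]
                fc = truth.true_fold_change(strain, phase, gene)
                for bio in range(1, truth.n_bio_reps + 1):
                    bio_noise = rng.normal(0.0, truth.biological_sd)
                    for tech in range(1, n_tech + 1):
                        ct = (
                            base
                            - np.log2(fc)
                            + bio_noise
                            + rng.normal(0.0, truth.technical_sd)
                        )
                        rows.append(
                            {
                                "strain": strain,
                                "phase": phase,
                                "gene": gene,
                                "bio_rep": bio,
                                "tech_rep": tech,
                                "ct": float(ct),
                            }
                        )
    return pd.DataFrame(rows)
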