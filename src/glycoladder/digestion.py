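"""In-silico sequential protease digestion and N-glycosylation sequon scan.

The wet-lab workflow digests archaellins with trypsin overnight and then
with Glu-C (V8) protease, so the in-silico counterpart applies enzymes
sequentially: products of the first digest are substrates of the second.
Cleavage rules:

* trypsin — C-terminal to K or R, suppressed when the next residue is P
  (the conventional Keil rule);
* glu-c — C-terminal to E by default (ammonium-bicarbonate-buffer
  specificity); set ``gluc_cleaves_d=True`` for the phosphate-buffer
  D+E specificity.

Candidate N-glycosylation sites are N-X-S/T sequons with X != P.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ProteinRecord",
    "DigestPeptide",
    "Sequon",
    "SUPPORTED_ENZYMES",
    "digest",
    "digest_sequence",
    "find_sequons",
    "candidate_glycopeptides",
]

_SEQUON_RE = re.compile(r"N(?=[^P][ST])")

SUPPORTED_ENZYMES = ("trypsin", "glu-c")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product located within its parent protein."""

    sequence: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates [{self.start}..{self.end}] disagree with "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class Sequon:
    """An N-X-S/T (X != P) motif at a specific Asn."""

    protein_id: str
    asn_position: int  # 1-based
    motif: str

    def __post_init__(self) -> None:
        if not _SEQUON_RE.match(self.motif):
            raise ValueError(f"{self.motif!r} is not an N-X-[S/T] sequon")


def _cleavage_sites(sequence: str, enzyme: str, gluc_cleaves_d: bool) -> list[int]:
    """0-based indices after which the enzyme cuts."""
    if enzyme == "trypsin":
        targets, suppress_proline = "KR", True
    elif enzyme == "glu-c":
        targets = "ED" if gluc_cleaves_d else "E"
        suppress_proline = False
    else:
        raise ValueError(
            f"unknown enzyme {enzyme!r}; supported: {', '.join(SUPPORTED_ENZYMES)}"
        )
    sites = []
    for i, res in enumerate(sequence[:-1]):
        if res in targets and not (suppress_proline and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def _digest_one(
    peptide: DigestPeptide,
    enzyme: str,
    max_missed: int,
    gluc_cleaves_d: bool,
) -> list[DigestPeptide]:
    sites = _cleavage_sites(peptide.sequence, enzyme, gluc_cleaves_d)
    # fragment boundaries in local 0-based coords: [b0, b1), [b1, b2), ...
    bounds = [0, *[s + 1 for s in sites], len(peptide.sequence)]
    out = []
    for i in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            lo, hi = bounds[i], bounds[j]
            out.append(
                DigestPeptide(
                    sequence=peptide.sequence[lo:hi],
                    protein_id=peptide.protein_id,
                    start=peptide.start + lo,
                    end=peptide.start + hi - 1,
                    missed_cleavages=peptide.missed_cleavages + missed,
                )
            )
    return out


def digest(
    protein: ProteinRecord,
    enzymes: Sequence[str] = ("trypsin", "glu-c"),
    max_missed: int = 0,
    gluc_cleaves_d: bool = False,
) -> list[DigestPeptide]:
    """Sequentially digest a protein, returning all peptide products.

    Enzymes are applied in order; every product of one round (at every
    missed-cleavage level) is a substrate of the next. Output is sorted
    by (start, end) with duplicates removed.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    for e in enzymes:
        if e not in SUPPORTED_ENZYMES:
            raise ValueError(
                f"unknown enzyme {e!r}; supported: {', '.join(SUPPORTED_ENZYMES)}"
            )
    current = [
        DigestPeptide(
            sequence=protein.sequence,
            protein_id=protein.id,
            start=1,
            end=len(protein.sequence),
        )
    ]
    for enzyme in enzymes:
        current = [
            frag
            for pep in current
            for frag in _digest_one(pep, enzyme, max_missed, gluc_cleaves_d)
        ]
    unique = {(p.start, p.end): p for p in sorted(
        current, key=lambda p: p.missed_cleavages
    )}
    return sorted(unique.values(), key=lambda p: (p.start, p.end))


def digest_sequence(
    sequence: str,
    enzymes: Sequence[str] = ("trypsin", "glu-c"),
    max_missed: int = 0,
    gluc_cleaves_d: bool = False,
) -> list[str]:
    """Convenience wrapper returning peptide strings for a bare sequence."""
    peps = digest(
        ProteinRecord(id="seq", sequence=sequence),
        enzymes,
        max_missed,
        gluc_cleaves_d,
    )
    return [p.sequence for p in peps]


def find_sequons(protein: ProteinRecord) -> list[Sequon]:
    """All N-X-S/T (X != P) sequons; overlapping occurrences each reported."""
    return [
        Sequon(
            protein_id=protein.id,
            asn_position=m.start() + 1,
            motif=protein.sequence[m.start() : m.start() + 3],
        )
        for m in _SEQUON_RE.finditer(protein.sequence)
    ]


def candidate_glycopeptides(
    peptides: Iterable[DigestPeptide],
    sequons: Iterable[Sequon],
) -> list[tuple[DigestPeptide, Sequon]]:
    """Pair every peptide with each sequon whose Asn it contains."""
    by_protein: dict[str, list[Sequon]] = {}
    for s in sequons:
        by_protein.setdefault(s.protein_id, []).append(s)
    pairs = []
    for pep in peptides:
        for seq in by_protein.get(pep.protein_id, []):
            if pep.start <= seq.asn_position <= pep.end:
                pairs.append((pep, seq))
    return pairs
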