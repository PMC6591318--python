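"""Glycoform-ladder search over MS1 peak lists and composition scoring.

A glycopeptide carrying an n-unit glycan shows up in MS1 as a *ladder*:
the bare peptide plus one peak per biosynthetic intermediate, spaced by
the glycan-unit masses divided by the charge.  This module finds such
ladders for candidate (peptide, sequon) pairs and decides which terminal
glycan composition the peaks support best.

Scoring uses presence/absence of peaks only — intensities are carried
through for reporting but never scored, because the underlying inference
is about which masses exist, not how abundant they are.

The composition verdict applies *unique-evidence* counting: ladders of
competing hypotheses share their lower steps (an unsulfated tetrasaccharide
ladder is a prefix of every sulfated variant's), so a hypothesis is only
credited with peaks that the best-scoring hypothesis does not already
explain.  A hypothesis with zero unique peaks is reported as
"not detected" — never "absent", since non-detection by mass cannot
exclude trace modification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .digestion import DigestPeptide, Sequon
from .masscalc import (
    EMPTY_GLYCAN,
    GlycanComposition,
    ResidueMassTable,
    glycoform_mz,
    ppm_error,
    round_mz,
)

__all__ = [
    "PeakList",
    "LadderStep",
    "LadderMatch",
    "CompositionVerdict",
    "DEFAULT_HYPOTHESES",
    "ladder_compositions",
    "match_peak",
    "build_ladder",
    "score_compositions",
    "ladder_report",
]

#: Glycan hypotheses screened by default: the tetrasaccharide of one
#: hexose and three hexuronic acids, the previously reported alternative
#: of two hexoses and two hexuronic acids, and 1-3x sulfated variants of
#: the tetrasaccharide.
DEFAULT_HYPOTHESES = (
    GlycanComposition(1, 3, 0),
    GlycanComposition(2, 2, 0),
    GlycanComposition(1, 3, 1),
    GlycanComposition(1, 3, 2),
    GlycanComposition(1, 3, 3),
)


@dataclass(frozen=True)
class PeakList:
    """An observed spectrum: (m/z, intensity) pairs plus metadata."""

    peaks: tuple[tuple[float, float], ...]
    ms_level: int = 1
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if any(m <= 0 for m in mzs):
            raise ValueError("all m/z values must be positive")
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError("intensities must be non-negative")
        if mzs != sorted(mzs):
            raise ValueError("peaks must be sorted ascending by m/z")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 peak lists require a precursor m/z")
        if self.ms_level not in (1, 2):
            raise ValueError("ms_level must be 1 or 2")

    @property
    def mz_values(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.peaks)


@dataclass(frozen=True)
class LadderStep:
    glycan: GlycanComposition
    theoretical_mz: float
    observed_mz: float | None = None
    observed_intensity: float | None = None
    ppm: float | None = None

    @property
    def matched(self) -> bool:
        return self.observed_mz is not None


@dataclass(frozen=True)
class LadderMatch:
    """The ladder steps of one candidate glycopeptide found in a spectrum."""

    peptide: DigestPeptide
    charge: int
    composition: GlycanComposition
    steps: tuple[LadderStep, ...]
    sequon: Sequon | None = None

    @property
    def n_matched(self) -> int:
        return sum(s.matched for s in self.steps)

    @property
    def matched_mzs(self) -> tuple[float, ...]:
        return tuple(s.observed_mz for s in self.steps if s.matched)

    @property
    def mean_abs_ppm(self) -> float:
        errs = [abs(s.ppm) for s in self.steps if s.ppm is not None]
        return sum(errs) / len(errs) if errs else math.nan


@dataclass
class HypothesisScore:
    composition: GlycanComposition
    total_matched: int
    mean_abs_ppm: float
    unique_peaks: int
    detected: bool


@dataclass
class CompositionVerdict:
    """Ranked support for each glycan hypothesis across all candidates."""

    scores: list[HypothesisScore]
    best: GlycanComposition | None
    sufficient_evidence: bool
    matches: list[LadderMatch] = field(default_factory=list)

    def score_for(self, composition: GlycanComposition) -> HypothesisScore:
        for s in self.scores:
            if s.composition == composition:
                return s
        raise KeyError(composition)


def ladder_compositions(terminal: GlycanComposition) -> list[GlycanComposition]:
    """Biosynthetic step series from the bare peptide to the full glycan.

    Hexoses are added first, then hexuronic acids one at a time, then
    sulfates.  Compositionally equivalent orderings would produce the
    same step masses and are not enumerated separately.
    """
    steps = [EMPTY_GLYCAN]
    for h in range(1, terminal.hex_count + 1):
        steps.append(GlycanComposition(h, 0, 0))
    for a in range(1, terminal.hexa_count + 1):
        steps.append(GlycanComposition(terminal.hex_count, a, 0))
    for s in range(1, terminal.sulfate_count + 1):
        steps.append(
            GlycanComposition(terminal.hex_count, terminal.hexa_count, s)
        )
    return steps


def match_peak(
    peaklist: PeakList,
    target_mz: float,
    tolerance_ppm: float,
) -> tuple[float, float, float] | None:
    """Nearest peak to `target_mz` within the ppm window, or None.

    Returns (observed m/z, intensity, signed ppm error); among in-window
    peaks the one with smallest \\|ppm\\| wins, ties going to the lower m/z.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    best: tuple[float, float, float] | None = None
    for obs_mz, intensity in peaklist.peaks:
        err = ppm_error(obs_mz, target_mz)
        if abs(err) > tolerance_ppm:
            continue
        if best is None or abs(err) < abs(best[2]):
            best = (obs_mz, intensity, err)
        # ties keep the earlier (lower-m/z) peak: strict < above
    return best


def build_ladder(
    peaklist: PeakList,
    peptide: DigestPeptide,
    charge: int,
    composition: GlycanComposition,
    tolerance_ppm: float,
    table: ResidueMassTable,
    sequon: Sequon | None = None,
) -> LadderMatch:
    """Match the full glycoform ladder of one candidate against a spectrum."""
    steps = []
    for glycan in ladder_compositions(composition):
        ion = glycoform_mz(peptide.sequence, glycan, charge, table)
        hit = match_peak(peaklist, ion.theoretical_mz, tolerance_ppm)
        if hit is None:
            steps.append(LadderStep(glycan, ion.theoretical_mz))
        else:
            obs, intensity, err = hit
            steps.append(
                LadderStep(glycan, ion.theoretical_mz, obs, intensity, err)
            )
    return LadderMatch(
        peptide=peptide,
        charge=charge,
        composition=composition,
        steps=tuple(steps),
        sequon=sequon,
    )


def score_compositions(
    peaklist: PeakList,
    candidates: Sequence[tuple[DigestPeptide, Sequon]],
    hypothesis_set: Sequence[GlycanComposition] = DEFAULT_HYPOTHESES,
    charges: Sequence[int] = (1, 2, 3),
    tolerance_ppm: float = 10.0,
    table: ResidueMassTable | None = None,
    min_steps: int = 3,
) -> CompositionVerdict:
    """Decide which glycan composition a peak list supports best.

    Builds ladders for every candidate x charge x hypothesis and
    aggregates matched steps per hypothesis.  The best hypothesis
    maximizes matched steps (ties broken by lower mean |ppm|); each
    competing hypothesis is then checked for peaks the best one does not
    explain.  Evidence is "sufficient" only if some single ladder
    matches at least `min_steps` steps.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if not hypothesis_set:
        raise ValueError("hypothesis set is empty")
    if table is None:
        from .masscalc import load_default_table

        table = load_default_table()

    all_matches: list[LadderMatch] = []
    per_hyp: dict[GlycanComposition, list[LadderMatch]] = {
        h: [] for h in hypothesis_set
    }
    for hyp in hypothesis_set:
        for pep, seq in candidates:
            for z in charges:
                m = build_ladder(
                    peaklist, pep, z, hyp, tolerance_ppm, table, sequon=seq
                )
                per_hyp[hyp].append(m)
                all_matches.append(m)

    def aggregate(ms: list[LadderMatch]) -> tuple[int, float]:
        total = sum(m.n_matched for m in ms)
        errs = [
            abs(s.ppm) for m in ms for s in m.steps if s.ppm is not None
        ]
        return total, (sum(errs) / len(errs) if errs else math.inf)

    agg = {h: aggregate(ms) for h, ms in per_hyp.items()}
    step_masses = {
        h: frozenset(ladder_compositions(h)) for h in hypothesis_set
    }

    def extension_supported(big: GlycanComposition) -> bool:
        # A hypothesis whose ladder extends another's (e.g. a sulfated
        # variant of an unsulfated glycan) shares all the smaller
        # ladder's step masses, so its matched-step total is inflated by
        # inherited peaks.  Accept the larger hypothesis only if a
        # majority of its extension-step slots (across candidates and
        # charges) are matched; a stray decoy peak in one slot is not
        # enough to add a unit to the composition.
        for small in hypothesis_set:
            if small == big or not step_masses[small] < step_masses[big]:
                continue
            ext = step_masses[big] - step_masses[small]
            slots = matched = 0
            for m in per_hyp[big]:
                for s in m.steps:
                    if s.glycan in ext:
                        slots += 1
                        matched += s.matched
            if slots and matched * 2 <= slots:
                return False
        return True

    viable = [h for h in hypothesis_set if extension_supported(h)]
    best = min(viable, key=lambda h: (-agg[h][0], agg[h][1]))
    best_peaks = {
        mz for m in per_hyp[best] for mz in m.matched_mzs
    }

    scores = []
    for h in hypothesis_set:
        total, mean_ppm = agg[h]
        peaks_h = {mz for m in per_hyp[h] for mz in m.matched_mzs}
        unique = len(peaks_h - best_peaks) if h != best else len(peaks_h)
        scores.append(
            HypothesisScore(
                composition=h,
                total_matched=total,
                mean_abs_ppm=mean_ppm,
                unique_peaks=unique,
                detected=(h == best) or unique > 0,
            )
        )
    scores.sort(key=lambda s: (-s.total_matched, s.mean_abs_ppm))

    best_single = max(m.n_matched for m in per_hyp[best])
    sufficient = best_single >= min_steps
    return CompositionVerdict(
        scores=scores,
        best=best if sufficient else None,
        sufficient_evidence=sufficient,
        matches=all_matches,
    )


def ladder_report(matches: Iterable[LadderMatch]) -> pd.DataFrame:
    """Tabulate ladder matches in the style of a glycosylation-site table.

    One row per ladder step: protein, peptide, charge, observed m/z
    (``n.d.`` when the step has no matching peak), calculated m/z at
    2 decimals, and the bound-glycan label.
    """
    rows = []
    for m in matches:
        for step in m.steps:
            rows.append(
                {
                    "protein": m.peptide.protein_id,
                    "peptide": m.peptide.sequence,
                    "charge": m.charge,
                    "observed_mz": (
                        f"{round_mz(step.observed_mz):.2f}"
                        if step.matched
                        else "n.d."
                    ),
                    "calculated_mz": f"{round_mz(step.theoretical_mz):.2f}",
                    "bound_glycan": (
                        "" if step.glycan == EMPTY_GLYCAN else step.glycan.label()
                    ),
                    "ppm": step.ppm,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein",
            "peptide",
            "charge",
            "observed_mz",
            "calculated_mz",
            "bound_glycan",
            "ppm",
        ],
    )
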