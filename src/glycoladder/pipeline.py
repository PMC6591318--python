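"""Pipeline configuration and orchestration.

Ties the stages together in the order of the underlying analysis:
digest proteins, locate sequons, search glycoform ladders in MS1 peak
lists, annotate MS/MS spectra, decide the glycan composition, and
(optionally) run the qPCR relative-expression analysis.  A run writes
its effective configuration next to its outputs so every reported mass
is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import digestion, io, laddersearch, msms, qpcr
from .masscalc import (
    GlycanComposition,
    ResidueMassTable,
    glycoform_mz,
    load_default_table,
    round_mz,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "theoretical_table"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable run configuration with the defaults of the analysis."""

    fasta: str | None = None
    peaklists: list[str] = field(default_factory=list)
    ct_table: str | None = None
    enzymes: list[str] = field(default_factory=lambda: ["trypsin", "glu-c"])
    max_missed_cleavages: int = 0
    gluc_cleaves_d: bool = False
    ms1_tolerance_ppm: float = 10.0
    ms2_tolerance_da: float = 0.25
    charges: list[int] = field(default_factory=lambda: [1, 2, 3])
    hypotheses: list[list[int]] = field(
        default_factory=lambda: [
            [h.hex_count, h.hexa_count, h.sulfate_count]
            for h in laddersearch.DEFAULT_HYPOTHESES
        ]
    )
    qpcr_method: str = "ddct"
    qpcr_reference_gene: str = "rrn16S"
    qpcr_case_strain: str = "delta_aglB"
    qpcr_control_strain: str = "parent"
    seed: int = 0
    output_dir: str = "glycoladder_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def hypothesis_set(self) -> list[GlycanComposition]:
        return [GlycanComposition(*h) for h in self.hypotheses]


@dataclass
class PipelineResult:
    peptide_table: pd.DataFrame
    verdict: laddersearch.CompositionVerdict | None
    msms_annotations: pd.DataFrame | None
    qpcr_report: pd.DataFrame | None
    output_dir: Path


def theoretical_table(
    candidates: list[tuple[digestion.DigestPeptide, digestion.Sequon]],
    hypothesis: GlycanComposition,
    charge: int,
    table: ResidueMassTable,
) -> pd.DataFrame:
    """Theoretical glycoform ladder m/z for every candidate glycopeptide."""
    rows = []
    for pep, seq in candidates:
        for glycan in laddersearch.ladder_compositions(hypothesis):
            ion = glycoform_mz(pep.sequence, glycan, charge, table)
            rows.append(
                {
                    "protein": pep.protein_id,
                    "peptide": pep.sequence,
                    "asn_position": seq.asn_position,
                    "charge": charge,
                    "bound_glycan": glycan.label(),
                    "calculated_mz": round_mz(ion.theoretical_mz),
                }
            )
    return pd.DataFrame(rows)


def _verdict_to_dict(verdict: laddersearch.CompositionVerdict) -> dict:
    return {
        "sufficient_evidence": verdict.sufficient_evidence,
        "best_composition": (
            verdict.best.label() if verdict.best is not None else None
        ),
        "hypotheses": [
            {
                "composition": s.composition.label(),
                "hex": s.composition.hex_count,
                "hexa": s.composition.hexa_count,
                "sulfate": s.composition.sulfate_count,
                "total_matched_steps": s.total_matched,
                "mean_abs_ppm": (
                    None if s.mean_abs_ppm != s.mean_abs_ppm else s.mean_abs_ppm
                ),
                "unique_peaks": s.unique_peaks,
                "status": "detected" if s.detected else "not detected",
            }
            for s in verdict.scores
        ],
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = load_default_table()
    logger.info(
        "mass table v%s; MS1 tolerance %.1f ppm; MS2 tolerance %.2f Da",
        table.version,
        config.ms1_tolerance_ppm,
        config.ms2_tolerance_da,
    )

    if config.fasta is None:
        raise ValueError("pipeline requires a FASTA input (config key 'fasta')")
    try:
        proteins = io.read_fasta(config.fasta)
    except (OSError, ValueError) as exc:
        raise RuntimeError(f"[digest] cannot read FASTA: {exc}") from exc

    peptides = [
        p
        for prot in proteins
        for p in digestion.digest(
            prot,
            config.enzymes,
            config.max_missed_cleavages,
            config.gluc_cleaves_d,
        )
    ]
    sequons = [s for prot in proteins for s in digestion.find_sequons(prot)]
    candidates = digestion.candidate_glycopeptides(peptides, sequons)

    primary = config.hypothesis_set()[0]
    peptide_table = theoretical_table(candidates, primary, 2, table)
    peptide_table.to_csv(out / "glycopeptide_table.tsv", sep="\t", index=False)

    verdict = None
    msms_frames = []
    for path in config.peaklists:
        for pl in io.read_peaklists(path):
            if pl.ms_level == 1:
                if not candidates:
                    continue
                verdict = laddersearch.score_compositions(
                    pl,
                    candidates,
                    config.hypothesis_set(),
                    charges=config.charges,
                    tolerance_ppm=config.ms1_tolerance_ppm,
                    table=table,
                )
                ladder_df = laddersearch.ladder_report(
                    [
                        m
                        for m in verdict.matches
                        if verdict.best is not None
                        and m.composition == verdict.best
                        and m.n_matched > 0
                    ]
                )
                ladder_df.to_csv(out / "ladder_report.tsv", sep="\t", index=False)
                with open(out / "composition_verdict.json", "w") as fh:
                    json.dump(_verdict_to_dict(verdict), fh, indent=2)
            else:
                for pep, _seq in candidates:
                    charge = pl.precursor_charge or 2
                    ann = msms.annotate_msms(
                        pl,
                        pep.sequence,
                        primary,
                        charge,
                        table,
                        tolerance_da=config.ms2_tolerance_da,
                    )
                    msms_frames.append(
                        pd.DataFrame(
                            {
                                "source": pl.source_id,
                                "peptide": pep.sequence,
                                "label": [a.label for a in ann],
                                "theoretical_mz": [a.theoretical_mz for a in ann],
                                "observed_mz": pd.array(
                                    [a.observed_mz for a in ann], dtype=float
                                ),
                                "error_da": pd.array(
                                    [a.error_da for a in ann], dtype=float
                                ),
                            }
                        )
                    )

    msms_df = pd.concat(msms_frames, ignore_index=True) if msms_frames else None
    if msms_df is not None:
        msms_df.to_csv(out / "msms_annotations.tsv", sep="\t", index=False)

    qpcr_df = None
    if config.ct_table is not None:
        ct = qpcr.read_ct_table(config.ct_table)
        target_genes = sorted(
            set(ct["gene"]) - {config.qpcr_reference_gene}
        )
        phases = sorted(set(ct["phase"]))
        qpcr_df = qpcr.expression_report(
            ct,
            target_genes,
            config.qpcr_reference_gene,
            config.qpcr_case_strain,
            config.qpcr_control_strain,
            phases,
            method=config.qpcr_method,
        )
        qpcr_df.to_csv(out / "relative_expression.csv", index=False)

    config.to_yaml(out / "effective_config.yaml")
    return PipelineResult(
        peptide_table=peptide_table,
        verdict=verdict,
        msms_annotations=msms_df,
        qpcr_report=qpcr_df,
        output_dir=out,
    )
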