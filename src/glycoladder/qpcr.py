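"""Efficiency-aware qRT-PCR relative-expression analysis.

Implements the standard workflow for comparative quantification of
transcripts between strains/conditions:

* primer efficiency from a serial-dilution standard curve
  (``E = 10**(-1/slope)`` of the Ct-vs-log10(dilution) regression; a
  perfect assay doubles per cycle, slope -3.3219, E = 2);
* relative expression by the 2^-ddCt method (default) or the
  efficiency-corrected ratio ``E_target**dCt_target / E_ref**dCt_ref``,
  which reduce to each other when every efficiency is exactly 2;
* two-sided unpaired Student's t-test between strains on per-biological-
  replicate ratios.

Technical replicates are averaged within their biological replicate
before any statistics, so n is always the number of biological
replicates.  Ratios are reported relative to a control condition
(e.g. the parent strain at the same growth phase), whose own mean ratio
is 1 by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "EfficiencyFit",
    "RelativeExpression",
    "read_ct_table",
    "validate_ct_table",
    "fit_efficiency",
    "relative_expression",
    "compare_strains",
    "expression_report",
    "significance_tier",
]

logger = logging.getLogger(__name__)

CT_COLUMNS = ["strain", "phase", "gene", "bio_rep", "tech_rep", "ct"]

#: Significance tiers used in report annotation: a, b, c.
SIGNIFICANCE_TIERS = (("a", 1e-4), ("b", 5e-4), ("c", 1e-2))


@dataclass(frozen=True)
class EfficiencyFit:
    """Primer-efficiency estimate from a serial-dilution standard curve."""

    gene: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float


@dataclass(frozen=True)
class RelativeExpression:
    """Fold-change of one gene in a case condition vs a control condition."""

    gene: str
    strain: str
    growth_phase: str
    ratio: float
    sem: float
    n: int
    replicate_ratios: tuple[float, ...]
    method: str


def read_ct_table(path: str) -> pd.DataFrame:
    """Read a Ct table CSV with columns strain, phase, gene, bio_rep, tech_rep, ct."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    validate_ct_table(df)
    return df


def validate_ct_table(df: pd.DataFrame) -> None:
    ct = df["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise ValueError("all Ct values must be finite and positive")


def fit_efficiency(
    dilution_series: list[tuple[float, float]],
    gene: str = "",
) -> EfficiencyFit:
    """Fit Ct = slope * log10(dilution) + intercept and derive efficiency.

    Parameters
    ----------
    dilution_series
        (log10 dilution, Ct) pairs; at least 3 distinct dilution points.
    """
    if len(dilution_series) < 3:
        raise ValueError("need >= 3 dilution points to fit an efficiency")
    x = np.array([d for d, _ in dilution_series], dtype=float)
    y = np.array([c for _, c in dilution_series], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    if np.ptp(x) == 0:
        raise ValueError("dilution series has zero variance")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise ValueError("flat dilution curve: efficiency undefined")
    return EfficiencyFit(
        gene=gene,
        slope=res.slope,
        intercept=res.intercept,
        efficiency=10.0 ** (-1.0 / res.slope),
        r_squared=res.rvalue**2,
    )


def _mean_ct(
    df: pd.DataFrame, strain: str, phase: str, gene: str
) -> pd.Series:
    """Per-biological-replicate mean Ct (technical replicates averaged)."""
    sub = df[
        (df["strain"] == strain) & (df["phase"] == phase) & (df["gene"] == gene)
    ]
    if sub.empty:
        raise ValueError(
            f"no Ct values for gene {gene!r} in ({strain!r}, {phase!r})"
        )
    return sub.groupby("bio_rep")["ct"].mean()


def relative_expression(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    case_condition: tuple[str, str],
    control_condition: tuple[str, str],
    method: str = "ddct",
    efficiencies: dict[str, float] | None = None,
) -> RelativeExpression:
    """Fold-change of `target_gene` in case vs control, per biological replicate.

    ``ddct``: ratio = 2^-[(Ct_t - Ct_r)_case - (Ct_t - Ct_r)_control].
    ``efficiency_corrected``: ratio = E_t^dCt_t / E_r^dCt_r with dCt =
    control - case (Pfaffl ratio); requires fitted per-gene efficiencies.

    The control-condition dCt is the mean over control biological
    replicates; the case dCt varies per replicate, yielding one ratio
    per biological replicate, summarized as mean +/- SEM.
    """
    validate_ct_table(table)
    if method not in ("ddct", "efficiency_corrected"):
        raise ValueError(f"unknown method {method!r}")
    if method == "efficiency_corrected":
        if efficiencies is None:
            raise ValueError("efficiency_corrected requires per-gene efficiencies")
        for g in (target_gene, reference_gene):
            if g not in efficiencies:
                raise ValueError(f"no efficiency provided for gene {g!r}")
        e_t, e_r = efficiencies[target_gene], efficiencies[reference_gene]
    else:
        e_t = e_r = 2.0

    case_strain, case_phase = case_condition
    ctrl_strain, ctrl_phase = control_condition
    ct_t_case = _mean_ct(table, case_strain, case_phase, target_gene)
    ct_r_case = _mean_ct(table, case_strain, case_phase, reference_gene)
    ct_t_ctrl = _mean_ct(table, ctrl_strain, ctrl_phase, target_gene)
    ct_r_ctrl = _mean_ct(table, ctrl_strain, ctrl_phase, reference_gene)
    if not ct_t_case.index.equals(ct_r_case.index):
        raise ValueError(
            "reference gene missing for some biological replicates of the case"
        )

    # dCt = Ct_control_mean - Ct_case, per gene (positive dCt = more
    # template in the case sample)
    dct_t = float(ct_t_ctrl.mean()) - ct_t_case
    dct_r = float(ct_r_ctrl.mean()) - ct_r_case
    ratios = (e_t**dct_t) / (e_r**dct_r)

    values = ratios.to_numpy(dtype=float)
    n = len(values)
    sem = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return RelativeExpression(
        gene=target_gene,
        strain=case_strain,
        growth_phase=case_phase,
        ratio=float(values.mean()),
        sem=sem,
        n=n,
        replicate_ratios=tuple(values),
        method=method,
    )


def compare_strains(
    expr_case: tuple[float, ...] | list[float],
    expr_control: tuple[float, ...] | list[float],
) -> float:
    """Two-sided unpaired Student's t-test on per-replicate ratios.

    Degenerate zero-variance input (both groups constant) returns
    p = 1.0 for identical means with a warning, since the t statistic is
    undefined there; a zero-variance difference in means returns p = 0.0.
    """
    a = np.asarray(expr_case, dtype=float)
    b = np.asarray(expr_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group for a t-test")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        logger.warning(
            "zero variance in both groups; t statistic undefined, "
            "returning p=1.0 for equal means"
        )
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def significance_tier(p_value: float) -> str:
    """Report annotation letter for a p-value (empty when not significant)."""
    for letter, threshold in SIGNIFICANCE_TIERS:
        if p_value < threshold:
            return letter
    return ""


def expression_report(
    table: pd.DataFrame,
    target_genes: list[str],
    reference_gene: str,
    case_strain: str,
    control_strain: str,
    phases: list[str],
    method: str = "ddct",
    efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-phase relative expression of case vs control strain.

    Mirrors the usual knockout-vs-parent design: each gene is normalized
    to the reference gene and to the control strain at the same growth
    phase; p-values compare case vs control per-replicate ratios.
    """
    rows = []
    for phase in phases:
        for gene in target_genes:
            case = relative_expression(
                table, gene, reference_gene,
                (case_strain, phase), (control_strain, phase),
                method=method, efficiencies=efficiencies,
            )
            ctrl = relative_expression(
                table, gene, reference_gene,
                (control_strain, phase), (control_strain, phase),
                method=method, efficiencies=efficiencies,
            )
            p = compare_strains(case.replicate_ratios, ctrl.replicate_ratios)
            rows.append(
                {
                    "gene": gene,
                    "phase": phase,
                    "strain": case_strain,
                    "ratio": case.ratio,
                    "sem": case.sem,
                    "n": case.n,
                    "control_ratio": ctrl.ratio,
                    "control_sem": ctrl.sem,
                    "p_value": p,
                    "tier": significance_tier(p),
                }
            )
    return pd.DataFrame(rows)
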