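"""Primer-efficiency fitting and relative-expression computation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glycoladder.qpcr import (
    compare_strains,
    expression_report,
    fit_efficiency,
    relative_expression,
    significance_tier,
)
from glycoladder.synthetic import CtTruth, gen_ct_table

KNOCKDOWN = {
    ("delta_aglB", phase, gene): 0.125
    for phase in ("log", "stationary")
    for gene in ("flaA1", "flaA2", "flaB1", "flaB2", "flaB3")
}


def _noiseless_table(fold_change: float) -> pd.DataFrame:
    truth = CtTruth(
        fold_changes={
            ("delta_aglB", p, g): fold_change
            for p in ("log", "stationary")
            for g in ("flaA1", "flaA2", "flaB1", "flaB2", "flaB3")
        },
        biological_sd=0.0,
        technical_sd=0.0,
    )
    return gen_ct_table(truth)


class TestFitEfficiency:
    def test_perfect_doubling_series(self):
        fit = fit_efficiency([(0.0, 20.0), (-1.0, 23.3219), (-2.0, 26.6439)])
        assert fit.efficiency == pytest.approx(2.0, abs=1e-3)
        assert fit.slope == pytest.approx(-3.3219, abs=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_slope_to_efficiency_closed_form(self):
        series = [(d, 20.0 - 3.6 * d) for d in (0.0, -1.0, -2.0, -3.0)]
        fit = fit_efficiency(series)
        assert fit.efficiency == pytest.approx(10 ** (1 / 3.6), abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_efficiency([(0.0, 20.0), (-1.0, 23.3)])
        with pytest.raises(ValueError):
            fit_efficiency([(0.0, 20.0), (0.0, 20.1), (0.0, 19.9)])


class TestRelativeExpression:
    def test_null_contrast_is_unity(self):
        table = _noiseless_table(1.0)
        res = relative_expression(
            table, "flaB2", "rrn16S",
            ("delta_aglB", "log"), ("parent", "log"),
        )
        assert res.ratio == pytest.approx(1.0, abs=1e-12)

    def test_two_cycle_shift_gives_quarter(self):
        table = _noiseless_table(0.25)
        res = relative_expression(
            table, "flaB2", "rrn16S",
            ("delta_aglB", "log"), ("parent", "log"),
        )
        assert res.ratio == pytest.approx(0.25, abs=1e-12)

    def test_recovers_eightfold_knockdown_within_ci(self):
        truth = CtTruth(fold_changes=KNOCKDOWN, seed=42)
        table = gen_ct_table(truth)
        res = relative_expression(
            table, "flaA1", "rrn16S",
            ("delta_aglB", "log"), ("parent", "log"),
        )
        assert res.n == 3
        half_width = stats.t.ppf(0.975, res.n - 1) * res.sem
        assert abs(res.ratio - 0.125) <= half_width + 0.05

    def test_efficiency_two_equals_ddct(self):
        table = gen_ct_table(CtTruth(fold_changes=KNOCKDOWN, seed=7))
        args = (
            table, "flaB1", "rrn16S",
            ("delta_aglB", "stationary"), ("parent", "stationary"),
        )
        ddct = relative_expression(*args, method="ddct")
        corrected = relative_expression(
            *args,
            method="efficiency_corrected",
            efficiencies={"flaB1": 2.0, "rrn16S": 2.0},
        )
        assert ddct.replicate_ratios == pytest.approx(
            corrected.replicate_ratios
        )

    def test_missing_reference_gene_errors(self):
        table = _noiseless_table(1.0)
        with pytest.raises(ValueError):
            relative_expression(
                table, "flaA1", "nonexistent",
                ("delta_aglB", "log"), ("parent", "log"),
            )

    def test_efficiency_corrected_requires_efficiencies(self):
        table = _noiseless_table(1.0)
        with pytest.raises(ValueError):
            relative_expression(
                table, "flaA1", "rrn16S",
                ("delta_aglB", "log"), ("parent", "log"),
                method="efficiency_corrected",
            )

    @given(shift=st.floats(-5.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, shift):
        """Adding a constant to every Ct leaves all ratios unchanged."""
        table = gen_ct_table(CtTruth(fold_changes=KNOCKDOWN, seed=3))
        shifted = table.assign(ct=table["ct"] + shift)
        base = relative_expression(
            table, "flaA2", "rrn16S",
            ("delta_aglB", "log"), ("parent", "log"),
        )
        res = relative_expression(
            shifted, "flaA2", "rrn16S",
            ("delta_aglB", "log"), ("parent", "log"),
        )
        assert res.replicate_ratios == pytest.approx(base.replicate_ratios)

    def test_control_condition_mean_ratio_near_unity(self):
        table = gen_ct_table(CtTruth(fold_changes=KNOCKDOWN, seed=5))
        res = relative_expression(
            table, "flaA1", "rrn16S", ("parent", "log"), ("parent", "log"),
        )
        assert res.ratio == pytest.approx(1.0, abs=3 * res.sem + 0.05)


class TestCompareStrains:
    def test_identical_groups(self):
        assert compare_strains((1.0, 1.1, 0.9), (1.0, 1.1, 0.9)) == pytest.approx(
            1.0
        )

    def test_zero_variance_defined_behaviour(self):
        assert compare_strains((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)) == 1.0
        assert compare_strains((1.0, 1.0), (2.0, 2.0)) == 0.0

    def test_insufficient_replicates(self):
        with pytest.raises(ValueError):
            compare_strains((1.0,), (1.0, 2.0))

    def test_matches_hand_computed_t(self):
        a, b = (0.10, 0.15, 0.12), (1.0, 0.9, 1.1)
        # pooled-variance two-sample t, closed form
        na, nb = len(a), len(b)
        va = np.var(a, ddof=1)
        vb = np.var(b, ddof=1)
        sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        t = (np.mean(a) - np.mean(b)) / (sp * math.sqrt(1 / na + 1 / nb))
        expected = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert compare_strains(a, b) == pytest.approx(expected)

    def test_large_effect_usually_significant(self):
        hits = 0
        for seed in range(30):
            table = gen_ct_table(CtTruth(fold_changes=KNOCKDOWN, seed=seed))
            case = relative_expression(
                table, "flaB2", "rrn16S",
                ("delta_aglB", "log"), ("parent", "log"),
            )
            ctrl = relative_expression(
                table, "flaB2", "rrn16S",
                ("parent", "log"), ("parent", "log"),
            )
            if compare_strains(case.replicate_ratios, ctrl.replicate_ratios) < 0.05:
                hits += 1
        assert hits >= 27  # >= 90% of seeds


def test_significance_tiers():
    assert significance_tier(5e-5) == "a"
    assert significance_tier(2e-4) == "b"
    assert significance_tier(5e-3) == "c"
    assert significance_tier(0.05) == ""


def test_expression_report_shape_and_no_effect_gene():
    truth = CtTruth(
        fold_changes={
            ("delta_aglB", p, g): 0.125
            for p in ("log", "stationary")
            for g in ("flaA1", "flaA2", "flaB1", "flaB2")
        },
        seed=13,
    )
    # flaB3 carries no effect, mirroring an unchanged control transcript
    table = gen_ct_table(truth)
    report = expression_report(
        table,
        ["flaA1", "flaB3"],
        "rrn16S",
        "delta_aglB",
        "parent",
        ["log", "stationary"],
    )
    assert len(report) == 4
    flab3 = report[report["gene"] == "flaB3"]
    assert (flab3["ratio"] - 1.0).abs().max() < 0.6
    flaa1 = report[(report["gene"] == "flaA1") & (report["phase"] == "log")]
    assert float(flaa1["ratio"].iloc[0]) < 0.3
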