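"""MS1 glycoform-ladder matching and composition scoring."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoladder.laddersearch import (
    DEFAULT_HYPOTHESES,
    PeakList,
    build_ladder,
    ladder_compositions,
    ladder_report,
    match_peak,
    score_compositions,
)
from glycoladder.masscalc import (
    EMPTY_GLYCAN,
    GlycanComposition,
    glycoform_mz,
    load_default_table,
    ppm_error,
)
from glycoladder.synthetic import SpectrumTruth, gen_ms1

TABLE = load_default_table()
TETRA = GlycanComposition(1, 3, 0)


def peaklist(*mzs, **kwargs):
    return PeakList(
        peaks=tuple((m, 100.0) for m in sorted(mzs)), **kwargs
    )


class TestPeakListInvariants:
    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            PeakList(peaks=((600.0, 1.0), (500.0, 1.0)))

    def test_rejects_nonpositive_mz_and_ms2_without_precursor(self):
        with pytest.raises(ValueError):
            PeakList(peaks=((-5.0, 1.0),))
        with pytest.raises(ValueError):
            PeakList(peaks=((500.0, 1.0),), ms_level=2)


class TestMatchPeak:
    def test_within_tolerance(self):
        hit = match_peak(peaklist(919.90), 919.899, tolerance_ppm=20)
        assert hit is not None
        assert hit[2] == pytest.approx(1.09, abs=0.01)

    def test_outside_tolerance(self):
        assert match_peak(peaklist(920.9), 919.899, tolerance_ppm=20) is None

    def test_tie_breaks_to_lower_mz(self):
        # 599.5 and 600.5 sit at exactly -/+ 0.5/600 relative error
        hit = match_peak(peaklist(599.5, 600.5), 600.0, tolerance_ppm=1000)
        assert hit[0] == 599.5

    def test_empty_peaklist_gives_absent(self):
        assert match_peak(PeakList(peaks=()), 600.0, 10) is None

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_peak(peaklist(600.0), 600.0, 0)

    @given(
        mzs=st.lists(
            st.floats(400.0, 2000.0), min_size=1, max_size=50, unique=True
        ),
        target=st.floats(400.0, 2000.0),
        tol=st.floats(0.5, 50.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_exhaustive_scan(self, mzs, target, tol):
        """Oracle: brute-force scan over every peak's ppm error."""
        pl = peaklist(*mzs)
        hit = match_peak(pl, target, tol)
        in_window = [
            (m, abs(ppm_error(m, target))) for m in sorted(mzs)
            if abs(ppm_error(m, target)) <= tol
        ]
        if not in_window:
            assert hit is None
        else:
            best = min(in_window, key=lambda t: (t[1], t[0]))
            assert hit[0] == best[0]


class TestLadderCompositions:
    def test_tetrasaccharide_series(self):
        assert ladder_compositions(TETRA) == [
            EMPTY_GLYCAN,
            GlycanComposition(1, 0, 0),
            GlycanComposition(1, 1, 0),
            GlycanComposition(1, 2, 0),
            GlycanComposition(1, 3, 0),
        ]

    def test_sulfates_appended_after_saccharides(self):
        steps = ladder_compositions(GlycanComposition(1, 1, 2))
        assert steps[-2:] == [
            GlycanComposition(1, 1, 1),
            GlycanComposition(1, 1, 2),
        ]

    def test_empty_composition_degenerate(self):
        assert ladder_compositions(EMPTY_GLYCAN) == [EMPTY_GLYCAN]


def _ladder_mzs(peptide_seq, composition, charge):
    return [
        glycoform_mz(peptide_seq, g, charge, TABLE).theoretical_mz
        for g in ladder_compositions(composition)
    ]


class TestBuildLadder:
    def test_full_ladder_matches_all_steps(self, vvny_candidate):
        pep, seq = vvny_candidate[0]
        pl = peaklist(*_ladder_mzs("VVNYANLTVR", TETRA, 2))
        match = build_ladder(pl, pep, 2, TETRA, 10.0, TABLE, sequon=seq)
        assert match.n_matched == 5
        assert [s.glycan for s in match.steps] == ladder_compositions(TETRA)

    def test_bare_peptide_only(self, vvny_candidate):
        pep, _ = vvny_candidate[0]
        pl = peaklist(_ladder_mzs("VVNYANLTVR", TETRA, 2)[0])
        assert build_ladder(pl, pep, 2, TETRA, 10.0, TABLE).n_matched == 1

    def test_monotone_in_tolerance(self, vvny_candidate):
        pep, _ = vvny_candidate[0]
        pl = gen_ms1(SpectrumTruth(seed=7, ppm_jitter_sd=8.0))
        counts = [
            build_ladder(pl, pep, 2, TETRA, tol, TABLE).n_matched
            for tol in (1.0, 2.0, 5.0, 10.0, 20.0)
        ]
        assert counts == sorted(counts)


class TestScoreCompositions:
    def test_recovers_tetrasaccharide_truth(self, vvny_candidate):
        pl = gen_ms1(SpectrumTruth(seed=3))
        verdict = score_compositions(pl, vvny_candidate, table=TABLE)
        assert verdict.best == TETRA
        assert verdict.sufficient_evidence

    def test_sulfated_variants_not_detected_under_unsulfated_truth(
        self, vvny_candidate
    ):
        pl = gen_ms1(SpectrumTruth(seed=3, n_decoys=0))
        verdict = score_compositions(pl, vvny_candidate, table=TABLE)
        for score in verdict.scores:
            if score.composition.sulfate_count > 0:
                assert not score.detected
                assert score.unique_peaks == 0

    def test_recovers_alternative_truth(self, vvny_candidate):
        alt = GlycanComposition(2, 2, 0)
        pl = gen_ms1(SpectrumTruth(composition=alt, seed=5))
        verdict = score_compositions(pl, vvny_candidate, table=TABLE)
        assert verdict.best == alt

    def test_pure_noise_flags_insufficient_evidence(self, vvny_candidate):
        truth = SpectrumTruth(seed=11, occupied_steps=frozenset(), n_decoys=30)
        verdict = score_compositions(
            gen_ms1(truth), vvny_candidate, table=TABLE
        )
        assert not verdict.sufficient_evidence
        assert verdict.best is None

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            score_compositions(peaklist(600.0), [], table=TABLE)


class TestLadderReport:
    def test_unobserved_steps_reported_nd(self, vvny_candidate):
        pep, seq = vvny_candidate[0]
        mzs = _ladder_mzs("VVNYANLTVR", TETRA, 2)
        pl = peaklist(*mzs[1:])  # bare peptide absent
        match = build_ladder(pl, pep, 2, TETRA, 10.0, TABLE, sequon=seq)
        df = ladder_report([match])
        assert list(df["observed_mz"])[0] == "n.d."
        assert list(df["calculated_mz"]) == [
            "574.82", "655.85", "743.87", "831.88", "919.90",
        ]
        assert list(df["bound_glycan"]) == [
            "", "Hex", "Hex, HexA", "Hex, HexA_2", "Hex, HexA_3",
        ]

    def test_empty_input_header_only(self):
        df = ladder_report([])
        assert df.empty
        assert "calculated_mz" in df.columns


def test_default_hypotheses_cover_reported_alternatives():
    sulfated = [h for h in DEFAULT_HYPOTHESES if h.sulfate_count > 0]
    assert GlycanComposition(2, 2, 0) in DEFAULT_HYPOTHESES
    assert len(sulfated) == 3
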