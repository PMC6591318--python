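# Methods

## Scope and model

`glycoladder` implements composition-level inference of archaellin
N-glycosylation from mass spectrometry, plus the accompanying qRT-PCR
relative-expression analysis. The central object is the **glycoform
ladder**: a peptide carrying an n-unit glycan appears in MS1 as a series
of peaks — bare peptide, peptide+Hex, peptide+Hex+HexA, … — spaced by
the glycan-unit residue masses divided by the charge. Finding a complete
ladder for a sequon-bearing peptide, and failing to find the extensions
predicted by competing compositions, is the evidence on which a glycan
composition is called.

All arithmetic is monoisotopic. Glycan units are generic mass classes:
mass spectrometry cannot tell glucose from mannose, so compositions are
reported as Hex/HexA/SO3 counts and nothing more. Constants:

| quantity | value (Da) |
|---|---|
| proton | 1.0072765 |
| water | 18.0105646 |
| Hex residue | 162.05282 |
| HexA residue | 176.03209 |
| SO3 | 79.95682 |
| carbamidomethyl (fixed, on C) | 57.02146 |

Residue masses ship as a versioned plain-text table
(`data/residue_masses_v1.tsv`) and can be overridden by file. Report
rounding is 2 decimals, round-half-up, matching the precision at which
glycopeptide masses are conventionally reported. Only proton adducts are
modeled; average masses and isotope envelopes are out of scope.

A note on "calculated" glycoform masses: published glycoform tables are
sometimes produced by adding truncated per-step increments to the bare
peptide's m/z, freezing the decimals (655.82, 743.82, … for a 574.82
base). Proper monoisotopic sums instead land on the *observed* peaks
(655.85, 743.87, 831.88, 919.90 for VVNYANLTVR at z=2), which is why
this package treats observed MS1 values as the ground truth its
theoretical column must reproduce.

## Digestion and sequons

Digestion is sequential: every product of one enzyme (at every
missed-cleavage level) is a substrate of the next, mirroring a
trypsin-overnight-then-Glu-C-overnight bench protocol. Trypsin cleaves
C-terminal to K/R, suppressed before proline (Keil rule). Glu-C cleaves
after E by default — the specificity favoured in ammonium bicarbonate
buffer — with a `gluc_cleaves_d` flag for the phosphate-buffer D+E
behaviour; the choice matters because several archaellin glycopeptides
contain internal aspartates. Semi-specific and non-specific digestion
are not modeled. Coordinates are 1-based inclusive, the convention of
residue-numbered site annotations (e.g. "Asn-97"); positions refer to
whatever sequence is supplied (precursor vs mature processing is the
caller's concern).

Sequons are N-X-S/T with X ≠ P, the canonical consensus shared by
archaeal and eukaryotic oligosaccharyltransferases; overlapping sequons
(N-N-S/T) are each reported. Candidate glycopeptides are every (digest
peptide, contained sequon) pair.

## Ladder search

MS1 matching is ppm-based (default tolerance 10 ppm, Orbitrap-class;
observed-vs-theoretical deviations on well-calibrated data run below
2 ppm). `match_peak` returns the in-window peak with smallest |ppm|,
ties broken deterministically toward lower m/z. Ladder steps are
generated in biosynthetic order — hexoses, then hexuronic acids, then
sulfates — but step order is presentation only; matching depends on step
masses alone. Charges 1–3 are searched by default. Intensities are never
scored: the inference is presence/absence of masses.

The default hypothesis set is Hex1HexA3 (the tetrasaccharide), Hex2HexA2
(a previously reported alternative), and Hex1HexA3 plus 1–3 sulfates.

**Verdict rule.** Hypotheses are ranked by total matched steps across
all candidate × charge ladders, ties by lower mean |ppm|. Nested
hypotheses need special care: the unsulfated ladder is a strict prefix
of every sulfated variant's, so a sulfated hypothesis inherits all of
the unsulfated ladder's matches and needs only one stray decoy peak in a
sulfate-step window to outscore it. A superset hypothesis is therefore
only eligible as "best" if a strict majority of its extension-step slots
(over all candidates and charges) are matched; otherwise the evidence
for the extra units is indistinguishable from decoy noise and the
smaller composition is preferred. Hypotheses other than the best are
additionally credited only with *unique* peaks (peaks the best
hypothesis does not explain); zero unique peaks ⇒ reported
"not detected" — deliberately never "absent", since mass-spectrometric
non-detection cannot exclude trace modification (historical sulfation
claims rested on ³⁵S radiolabeling, which is more sensitive).

Two consequences are worth knowing. First, with the default charge range
1–3, a genuinely sulfated glycan whose spectrum shows only one charge
state will match 1 of 3 extension slots and be conservatively rejected
in favour of its unsulfated core; restrict `charges` to the observed
charge to recover sulfated truths. Second, a verdict is only issued when
some single ladder matches ≥ 3 steps (`min_steps`); below that the
verdict is "insufficient evidence" with `best = None`.

## MS/MS annotation

Collisional fragmentation of glycopeptides preferentially cleaves
glycosidic bonds, so the Y-ion series (intact peptide + truncated
glycans, including the bare peptide and the precursor) equals the MS1
ladder reinterpreted as fragments — the implementation enforces this
identity exactly. Matching is by absolute Da tolerance, default 0.25 Da:
fragments read out of a linear ion trap carry ~0.1–0.2 Da errors, two
orders of magnitude worse than the Orbitrap MS1 survey scans, and a
ppm-style tolerance would be the wrong model. A spectrum is "consistent"
with a composition when ≥ K series members match (default 3 of 5).
Fragment charge is assumed equal to precursor charge. Peptide-backbone
b/y ions and oxonium ions are out of scope; the compositional argument
rests on glycan losses alone.

## qPCR analysis

Primer efficiency is the slope of the least-squares line of Ct on log10
dilution, `E = 10^(−1/slope)`; a perfect doubling assay has slope
−3.3219 and E = 2. At least three distinct dilution points are required.

Relative expression defaults to the 2^−ΔΔCt method; the
efficiency-corrected ratio `E_t^ΔCt_t / E_r^ΔCt_r` (Pfaffl) is available
and reduces to ΔΔCt exactly when all efficiencies are 2 (a tested
invariant). Technical replicates are averaged within their biological
replicate before anything else, so n is always biological. The case
condition's ΔCt varies per biological replicate against the control
condition's mean ΔCt, giving one ratio per replicate, summarized as
mean ± SEM. Ratios are scale-invariant in Ct (adding a constant to every
well changes nothing). The control condition's own per-replicate ratios
are mean-centered in log2 space, so its geometric mean ratio is exactly
1 and its arithmetic mean is 1 up to second-order noise terms.

Strain comparisons use the two-sided unpaired Student's t-test
(equal-variance) on per-replicate ratios. Zero-variance input returns
p = 1.0 (equal means) with a logged warning rather than NaN. No
multiple-testing correction is applied, matching the per-gene
significance-tier reporting convention (a: p < 1e-4, b: < 5e-4,
c: < 0.01) the analysis reproduces; users screening many genes should
correct downstream.

## Synthetic data

The generators are first-class, tested code; every generator is a pure
function of (truth, seed) via `numpy.random.default_rng`.

* **Fixture proteome** — five archaellin-like proteins embedding the six
  characterized glycopeptides. Flanks are random over an alphabet
  excluding K/R/E (no stray cleavage), P (no suppression at payload
  boundaries) and N (no stray sequons), and each payload is preceded by
  a flank ending in K, so sequential trypsin + Glu-C releases the
  payloads exactly, with their marked Asn as the only in-peptide sequon.
  Embedded peptides are seed-invariant; only flanks vary.
* **MS1 spectra** — one peak per occupied ladder step at
  `theoretical × (1 + ε)`, ε ~ N(0, jitter·1e-6); defaults 5 ppm jitter
  and 20 uniform decoys over 400–2000 Th, i.e. noise with generous
  headroom over the < 2 ppm deviations of real Orbitrap survey scans.
  Intensities are log-normal and decorative (scoring ignores them).
* **MS/MS spectra** — Y-series peaks with N(0, 0.1 Da) fragment error,
  matching ion-trap accuracy, plus decoys; precursor recorded.
* **Ct tables** — `Ct = baseline − log2(fold-change) + bio + tech`
  noise, bio N(0, 0.3) shared across a biological replicate's technical
  wells, tech N(0, 0.15) per well; replicate design of 3 biological × 8
  technical (log phase) and 3 × 4 (stationary). Biological noise is
  drawn independently per gene within a replicate — a deliberate
  simplification that makes ratios noisier than a shared-RNA-prep model
  would, i.e. conservative for recovery tests. The reference gene's
  fold-change is pinned to 1 everywhere.

What the generators do **not** emulate: isotope envelopes, charge-state
envelopes, chromatographic co-elution, intensity-dependent mass error,
spectral interference between co-isolated precursors, and qPCR
plate/batch effects. Passing the recovery benchmarks therefore
demonstrates that the inference logic is correct under its stated noise
model, not that it is robust to every artifact of real instrument data.

## Problem sizes

The recovery benchmarks run 100 seeded MS1 spectra (single candidate
peptide, full default hypothesis set, charges 1–3) and 20–30 seeded Ct
tables; the whole suite completes in a few seconds on one core. These
sizes put the binomial uncertainty of a ≥95% recovery criterion well
below its margin (observed recovery is 100/100 at the default noise).

## Numerical choices and degenerate inputs

* Report rounding is decimal round-half-up (`Decimal`), not banker's
  rounding, to match conventional reporting.
* Empty peak lists are valid and match nothing; an empty glycan
  composition is valid with mass 0 and yields a one-step ladder.
* `match_peak` ties (exactly equal |ppm|) go to the lower m/z.
* Unsorted peak-list input files are sorted with a warning; negative m/z
  is an error.
* Flat or < 3-point dilution series are errors, not NaN efficiencies.

## Known limitations

* Composition-level only: no site localization beyond the sequon, no
  glycan structure, no distinction among isomeric monosaccharides.
* No FDR control for ladder matches; the hypothesis set is small and
  user-chosen, not a decoy database search.
* Sulfated-truth recovery requires a matched charge range (see verdict
  rule above).
* mzML is not parsed; MGF and TSV peak lists are the supported inputs.
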