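# glycoladder

Composition-level inference of archaellin *N*-glycosylation from mass
spectrometry, plus qRT-PCR relative-expression analysis.

Archaella — the rotary swimming filaments of archaea — are built from
archaellin subunits that are heavily *N*-glycosylated, and in
*Halobacterium salinarum* the glycan attached at N-X-S/T sequons is a
tetrasaccharide of one hexose and three hexuronic acids. The evidence
for such a composition is a **glycoform ladder**: in an MS1 survey scan,
a glycopeptide with an *n*-unit glycan appears as a series of peaks —
the bare peptide, then the peptide plus each biosynthetic intermediate —
spaced by the monoisotopic glycan-unit masses divided by the charge:

```
m/z(k) = (M_peptide + Σ glycan units + z·m_H+) / z
Hex = 162.05282 Da    HexA = 176.03209 Da    SO3 = 79.95682 Da
```

`glycoladder` is for proteomics practitioners who want this inference
as a tested, reusable pipeline rather than a manual calculation:

* **masscalc** — monoisotopic peptide/glycoform mass arithmetic over a
  versioned, overridable residue-mass table;
* **digestion** — sequential in-silico trypsin + Glu-C digestion and
  N-X-S/T (X ≠ P) sequon detection;
* **laddersearch** — ppm-tolerance glycoform-ladder matching in MS1 peak
  lists and a composition verdict that weighs competing glycan
  hypotheses (including sulfated variants) by unique evidence;
* **msms** — glycan-loss (Y-ion) annotation of MS/MS spectra at
  ion-trap (Da-scale) tolerance;
* **qpcr** — primer-efficiency fitting, 2^−ΔΔCt / efficiency-corrected
  relative expression, and unpaired t-tests;
* **synthetic** — seeded generators for fixture proteomes, MS1/MS2
  spectra and Ct tables with known ground truth, so the whole pipeline
  is testable offline.

## Worked example

Score glycan-composition hypotheses against a synthetic MS1 spectrum of
the FlaB2 peptide VVNYANLTVR carrying the tetrasaccharide (5 ppm mass
jitter, 20 decoy peaks):

```python
import glycoladder as g
from glycoladder.laddersearch import ladder_report, score_compositions
from glycoladder.synthetic import SpectrumTruth, gen_ms1

table = g.load_default_table()
flab2 = next(p for p in g.gen_fixture_proteome(seed=1) if p.id == "FlaB2")
cands = [(p, s) for p, s in g.candidate_glycopeptides(
             g.digest(flab2), g.find_sequons(flab2))
         if p.sequence == "VVNYANLTVR"]

verdict = score_compositions(gen_ms1(SpectrumTruth(seed=7)), cands, table=table)
print("best:", verdict.best.label())
for s in verdict.scores:
    print(f"{s.composition.label():18s} matched={s.total_matched:2d} "
          f"unique={s.unique_peaks} "
          f"{'detected' if s.detected else 'not detected'}")
```

prints

```
best: Hex, HexA_3
Hex, HexA_3        matched= 5 unique=5 detected
Hex, HexA_3, SO3   matched= 5 unique=0 not detected
Hex, HexA_3, SO3_2 matched= 5 unique=0 not detected
Hex, HexA_3, SO3_3 matched= 5 unique=0 not detected
Hex_2, HexA_2      matched= 2 unique=0 not detected
```

All five ladder steps of the tetrasaccharide are found; the sulfated
variants explain no peak the unsulfated ladder does not already explain
(their matches are inherited prefix steps), so they are reported "not
detected" — not "absent", since non-detection by mass cannot exclude
trace modification. The alternative Hex₂HexA₂ composition matches only
the two steps it shares with the truth. The per-step table from
`ladder_report` shows the recovered ladder:

```
protein    peptide  charge observed_mz calculated_mz bound_glycan
  FlaB2 VVNYANLTVR       2      574.82        574.82
  FlaB2 VVNYANLTVR       2      655.85        655.85          Hex
  FlaB2 VVNYANLTVR       2      743.87        743.87    Hex, HexA
  FlaB2 VVNYANLTVR       2      831.88        831.88  Hex, HexA_2
  FlaB2 VVNYANLTVR       2      919.90        919.90  Hex, HexA_3
```

i.e. the doubly protonated bare peptide at m/z 574.82 and glycoforms at
655.85, 743.87, 831.88 and 919.90 Th.

The same stages are available from the shell:

```sh
glycoladder generate --preset table2 --outdir demo   # fixture proteome
glycoladder generate --preset fig3   --outdir demo   # synthetic spectra
glycoladder ladders demo/archaellins.fasta demo/ms1_ladder.tsv
glycoladder qpcr demo/ct_table.csv --case-strain delta_aglB
glycoladder run --config my_run.yaml                 # full pipeline
```

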