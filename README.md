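# lipidisc

Discriminant lipid-species analysis for keratinocyte differentiation
studies.

Cultured human epidermal keratinocytes remodel their lipidome as they exit
the stem-cell compartment.  Two complementary experiments expose this:
near-synchronous suspension-induced differentiation (blocked by PKC
inhibition) profiled by shotgun lipidomics over a time course, and siRNA
knockdowns of lipid-modifying enzymes (read out as the fraction of
involucrin-positive cells in a 258-gene screen, then profiled by
lipidomics for the validated hits ELOVL1 and SLC27A1).  `lipidisc`
implements the full downstream chain that turns those tables into a short
list of candidate differentiation-inducing lipid species:

- **nomenclature** — a parser for shorthand annotations
  (`Ceramide – 32:1:2 (C14:0 Cer)`, `Phosphatidylcholine – 17:0:0;17:1:0`)
  with class taxonomy and composition tallies;
- **core** — mol% normalization (`100·pmol/Σpmol` per sample), class
  composition, species Z-scores, deterministic Euclidean complete-linkage
  clustering, near-zero-variance filtering, PCA;
- **splsda** — sparse partial least squares discriminant analysis, written
  from scratch: per component the X-weight vector u ∝ Xᵀ(Yv) is
  hard-thresholded to its `keepX` largest |entries|, renormalized, and both
  X and the one-hot class matrix Y are deflated on the score t = Xu
  (regression mode).  Defaults: `ncomp = 3`, `keepX = 250`, unit-scaled X;
- **discriminants** — the extraction rules: |loading| > 0.01 on the
  component separating a class **and** enrichment in that class (strict
  class-median comparison for the suspension model; replicate-mean fold
  change vs siScramble, with an `Accumulated` sentinel for species
  undetectable in the control, for the knockdowns), plus structural
  cross-experiment intersection;
- **screen** — modified Z-scores (0.6745·(x−median)/MAD per culture
  condition, so both conditions pool), per-plate fold changes against
  nontargeting controls, replicate QC, and volcano hit calling
  (inducer: FC > 2.5, inhibitor: FC < 0.6, each with Welch p < 0.05);
- **simulate** — seeded generators for all three data types with planted
  ground truth, so every stage is testable without the original data.

## Worked example

Run the numbered analysis scripts in order (synthetic data, seed 1):

```sh
python analysis/01_simulate_datasets.py
python analysis/02_suspension_timecourse.py
python analysis/03_knockdown_timecourse.py
python analysis/04_sirna_screen.py
python analysis/05_intersection.py
```

Script 02 prints, among other things:

```
discriminant species: 36 (differentiated recovered 20/20, commitment
recovered 15/15, false positives 1)
```

i.e. the 3-component sPLS-DA plus the loading/enrichment rules recover all
20 planted differentiated markers and all 15 commitment markers from the
300-species suspension time course, admitting one unplanted species.
Script 03 reports the knockdown sets, e.g.

```
siELOVL1: 22 discriminant species (planted recovered 22/22, false
positives 0); 2 reported as Accumulated
  PA – 20:1:0;23:0:0: Accumulated (48 and 72 h)
```

where `Accumulated` marks species undetectable in the siScramble controls.
Script 04 calls exactly the ten planted screen hits (four inhibitors with
FC ≈ 0.4, six inducers with FC ≈ 3.5) with no false calls, and script 05
intersects the suspension and knockdown sets and tabulates the bundled
42-species published candidate panel:

```
  sphingolipids: 12 (Cer 6, HexCer 6)
  glycerophospholipids: 30 (PC 8, PS 7)
```

The same stages are available as a CLI (`lipidisc simulate | normalize |
classcomp | cluster | pca | splsda | discriminants | intersect | screen |
composition | run-all`); `lipidisc run-all --simulate --seed 1 --out
results/demo` executes everything and writes a `summary.json`.  Real
lipidomics exports can be ingested as long or wide delimited tables
(`sample`, `lipid`, `pmol` columns, or a species × sample matrix with a
design sidecar).

## Layout

```
src/lipidisc/       library (all computation lives here)
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit, property, acceptance)
scripts/            acceptance.py
docs/methods.md     models, parameters, design decisions, limitations
```
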