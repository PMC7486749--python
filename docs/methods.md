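# Methods

`lipidisc` implements the downstream computational chain used to nominate
differentiation-inducing lipid species in cultured human keratinocytes:
shotgun-lipidomics tables are normalized to mol%, projected with sparse
partial least squares discriminant analysis (sPLS-DA), filtered by
loading-threshold + enrichment rules, intersected across two independent
differentiation models, and cross-referenced with a plate-based siRNA
screen scored by modified Z-scores and volcano thresholds.  This note
records the models, the parameters that matter, and the design decisions
taken where the procedure was genuinely open.

## Lipid nomenclature

Species are written `Class – C:U:H` (carbons : double bonds : hydroxyls).
Sphingolipids (Cer, HexCer, SM) report one whole-molecule triplet; the
fatty-acid alias in parentheses (e.g. `(C14:0 Cer)`) is derived by
subtracting a d18:1 sphingoid backbone — 18 carbons, one double bond, two
hydroxyls — fixed because every published alias we checked is consistent
with exactly that base.  Glycerophospholipids carry two per-chain triplets
(`;`-separated), DAG two, TAG three, cardiolipin four; lyso classes one;
ether classes carry the `O-` suffix.  Both long spellings and short tokens
parse; equality is structural (class + chains), so cross-experiment
intersection is immune to spelling differences.  Cardiolipin is tallied
under "other" rather than with the two-chain glycerophospholipids.
Hexosylceramide head-group isomers (glucosyl vs galactosyl) are not
modeled: MS cannot distinguish them.

## mol% normalization and matrix preprocessing

Each sample row of the pmol matrix is divided by its total and scaled to
100, removing the arbitrary per-sample input amount of direct-infusion MS.
All enrichment statistics and fold changes are computed on mol%.  Note the
closure this induces: raising a subset of species necessarily depresses the
mol% of every other species, which is what gives the enrichment filters
their specificity in the simulations (see below).

Species-wise Z-scores use the sample SD (n−1); zero-SD species are dropped
with a logged warning (configurable to an error) so heatmap/clustering
input stays finite.  Hierarchical clustering is Euclidean complete-linkage,
implemented here with an explicit determinism contract: height ties merge
the pair whose smallest member labels sort first, and each node places the
subtree containing the smallest label on the left, so tree and leaf order
are invariant to input row permutation (cross-checked against SciPy on
tie-free data).  Near-zero-variance filtering follows the screening rule of
the multivariate ecosystem this pipeline mirrors: a feature is removed when
most-common/second-most-common frequency ratio > 95/5 **and** the distinct
value fraction < 10% (strict inequalities, verified against the reference R
implementation; constants are always removed).  A plain variance-threshold
mode is available.  PCA centers and, by default, unit-scales columns.

## Sparse PLS-DA

The discriminant engine is a NIPALS-style power iteration on the
cross-covariance between the centered/scaled predictor matrix X (samples ×
species) and the centered one-hot class matrix Y, with per-component hard
selection:

1. initialize the Y-weight v from the leading left singular vector of YᵀX
   (deterministic, seed-free);
2. iterate u ∝ Xᵀ(Yv) → hard-threshold u to its keepX largest |entries|
   (exact ties keep the smaller column index) → normalize → v ∝ Yᵀ(Xu) →
   normalize, until the change in u falls below 1e-9 (max 500 iterations;
   non-convergence keeps the last iterate with a warning);
3. score t = Xu; deflate both X and Y by regression on t (regression mode);
4. record the sparse weight vector ("loadings" for the threshold rules),
   the regression loadings Xᵀt/(tᵀt), and the scores.

Hard selection is pure: surviving weights are not shrunk (a soft-threshold
mode exists behind a switch; near the ±0.01 rule threshold the two can
differ, which is documented as the main cross-implementation divergence
risk).  keepX larger than the species count is clamped with a warning —
the published parameterization (ncomp = 3, keepX = 250 per component) is
used even on panels with fewer species.  With keepX = p and two classes,
component 1 provably equals the leading singular vector of the
cross-covariance; the tests assert this to 1e-8 cosine.

Component signs are arbitrary; `orient_component` flips a component so a
reference class scores non-negatively.  The discriminant rules below are
formulated on |loading| combined with an explicit enrichment direction,
making them orientation-free; a "signed" emulation mode applies the
one-sided rule after orientation.

## Discriminant extraction

*Suspension model* (four classes — adherent 0 h; commitment 4–8 h
untreated; differentiated 12–24 h untreated; inhibited = all PKCi-treated):
fit sPLS-DA (3 components, keepX 250) on mol%; the discriminant set is the
union of component-2 species with |loading| > 0.01 that are
median-enriched in the differentiated class and component-3 species with
|loading| > 0.01 median-enriched in the commitment class.  "Median
enriched" means the class median strictly exceeds the median of **every**
other class (the strictest reading; a pooled-others comparator is
available).  Ties are not enrichment.

*Knockdown model*: one sPLS-DA per timepoint (48 h, 72 h) on treatment
labels {siScramble, siELOVL1, siSLC27A1}.  siELOVL1 species qualify on
components 1 or 2, siSLC27A1 on component 2 only (the narrower reading of
the published sentence; component 1 can be added by argument), at either
timepoint, with replicate-mean enrichment over siScramble (fold change
> 1).  A positive knockdown mean over a zero control mean is flagged with
the `Accumulated` sentinel, which outranks any numeric fold change in the
maximum-fold-change report (`"Accumulated (48 and 72 h)"` style).  Both
means zero → not enriched, fold change undefined.

Intersection of discriminant sets uses canonical structural species
identity and keeps the records of both sources.

## Screen scoring

Readouts are per-well fractions of involucrin-positive cells.  The modified
Z-score z = 0.6745·(x − median)/MAD is computed within one normalization
unit — by default a culture condition across all its plates, which is what
lets the growth and serum arms pool into one dataset (per-plate
normalization is available; the 0.6745 Iglewicz–Hoaglin constant is
configurable and cancels everywhere except the Z axis itself).  Fold
changes are per-plate ratios to the mean of the nontargeting wells of the
same plate, averaged across replicates and conditions; they are computed on
raw readouts, not Z-scores, because Z-scores can be negative.  Hits are
called from a two-sided Welch t of the target wells' pooled Z-values
against the nontargeting wells of the same plates, with strict volcano
thresholds: inducer iff p < 0.05 and FC > 2.5; inhibitor iff p < 0.05 and
FC < 0.6.  No multiple-testing correction is applied by default (the
volcano operates on raw p-values); involucrin-targeting wells are
transfection QC only and are excluded from control means and calling.
Targets with fewer than two usable wells are reported uncalled.

## Synthetic data

The generator reproduces the statistical *shape* of the study's data, not
any real lipidome's values.  A 300-species panel (17 classes, PC-dominant,
minor Cer/HexCer; class shares normalized to 1) splits each class share
lognormally across species (log-SD 0.8, spanning ~2 orders of magnitude).
Abundances are pmol = total × share × effect × noise with per-sample totals
jittered ±30% and per-(sample, species) lognormal noise of log-SD 0.04
(~4% CV — the scale of direct-infusion technical variation, calibrated so
the four differentiation classes separate in latent space as cleanly as the
study's score plots indicate).  All randomness derives from one seed via
stable hashing of entity names, so datasets are byte-identical across runs
and insensitive to adding entities.

The suspension design (duplicates, 0/4/8/12/24 h × control/PKCi) plants
three signatures: 50 adherent-only species at 3× (the detachment shift that
dominates the first latent component, as in the real data), 15 transient
commitment markers at 3× (4–8 h, control only), and 20 differentiated
markers ramping to 3× at 12–24 h in the control arm only (PKCi blocks
them).  The relative signature sizes (50 > 20 > 15) are what pins the
adherent/differentiated/commitment contrasts to components 1/2/3.  mol%
closure then depresses every unplanted species in the signal classes, which
is the mechanism that holds false positives down; with the default noise
the differentiated markers are recovered at ~100% sensitivity with ≈1
false species per run.

The knockdown design (triplicates, three treatments × 24/48/72 h) plants
20 siELOVL1 markers at 3× from 48 h (plus two control-undetectable species
exercising the `Accumulated` path) and 12 milder siSLC27A1 markers at 2.5×.
The weak siSLC27A1 signature deliberately leaves the mean-enrichment filter
permissive — its discriminant set is several times larger than the planted
truth, paralleling the study's own large set for this nearly
control-indistinguishable knockdown.

The screen (258 targets, 90 test + 6 control wells per 96-well plate,
quadruplicate, growth ≈ 5% / serum ≈ 15% baseline differentiating
fraction) plants 4 inhibitors at 0.4× and 6 inducers at 3.5×, with 15%
lognormal well noise, ~5% plate offsets, positive-control wells at 0.2×,
and clipping to [0, 1].  At these settings all ten hits are recovered with
essentially no false calls and the Welch test's type-I error on null
targets stays at the nominal 5%.  Replicate-vs-mean Pearson correlation at
the default noise is ~0.97 because the ten large planted effects dominate;
raising well noise to log-SD 0.45 reproduces the ~0.8 regime reported for
the real screen (this is the setting used for the reproducibility figure
in the acceptance report).

### What the simulations do and do not show

Passing recovery tests show the chain is correctly wired and sensitive at
the planted effect sizes under closure; they do not certify specificity on
real data.  In particular, the extraction rule is intrinsically permissive
under a global null: strict median-top enrichment is satisfied by ~1/4 of
null species regardless of noise scale (the comparison is
scale-invariant), and a 0.01 threshold on unit-norm weight vectors with
250 nonzero entries (typical magnitude 1/√250 ≈ 0.063) filters little.
Null simulations therefore yield large discriminant sets, and the
specificity observed with planted effects comes from closure-induced
depletion, not from the thresholds.  Real lipidomes also have correlated
species noise, batch structure and detection-limit censoring that the
generator does not model.

## Numerical and degenerate-input conventions

SDs use n−1 throughout.  All-zero samples, all-zero enrichment groups,
zero-MAD normalization units, missing treatment groups, and chain
arithmetic that would go negative raise errors naming the offending entity.
Missing (sample, species) pairs in long input are zeros (shotgun lipidomics
reports only detected species); duplicate rows are summed with a warning.
Plotting is deliberately out of scope — all outputs are tables.

## Problem sizes

Defaults everywhere match the emulated study designs: 18 suspension
samples × 300 species, 9 knockdown samples per timepoint, 2,208 screen
wells; recovery statistics aggregate 20 seeded runs and the type-I check
uses 1,000 null targets.  A full test-suite run and the acceptance script
each complete in well under a minute of compute.
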