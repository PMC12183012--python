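# Methods

This note records the models, parameter choices and known limitations
behind `exomy`. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is asserted that the
code does not itself reproduce.

## Scope and design stance

The package models the *interpretation layer* of an exome-based
first-tier genetic workup for male infertility: turning per-target read
depths into copy-number dosages, dosages into AZF/karyotype/CFTR calls,
and calls into validation statistics and diagnostic categories. Read
alignment, SNV calling and the published third-party exome CNV callers
(CoNIFER, ExomeDepth) are deliberately out of scope; in their place
stands a transparent median-of-ratios caller with explicit thresholds, so
that every decision is inspectable and unit-testable. The goal is a
reference implementation of the decision logic, not a re-implementation
of any specific production pipeline.

## Reference model (`refmodel`)

Coordinates are GRCh37 throughout, 0-based half-open internally and
1-based inclusive in all emitted nomenclature. The bundled target map
(291 targets) is a curated miniature of a clinical exome:

* chrY: single-copy genes (SRY, ZFY, PCDH11Y, AMELY, TBL1Y, PRKY on Yp;
  USP9Y, DDX3Y in AZFa; KDM5D, EIF1AY, RPS4Y2 in AZFb) and the multicopy
  families (HSFY×2, RBMY×6, PRY×2, BPY2×3, DAZ×4), plus one distal Yq
  anchor target. Family targets carry the family-total baseline
  (collapsed short-read mapping on palindromic sequence).
* chrX: 40 scaffold targets (baseline 1 in a 46,XY genome).
* autosomes: 120 scaffold/gene targets (baseline 2), including CFTR exon
  targets for two enrichment-kit versions. The "v1" kit is the bundled
  set minus two deep-intronic spike-in targets; "v2" includes them.

Target counts per gene follow exon counts of the real genes in spirit
(USP9Y is a 46-exon gene and gets 25 targets; single-exon SRY gets one).
Boundary coordinates of the AZF-relevant targets are aligned to the
breakpoint coordinates that recurrent deletion classes produce in
practice, so that a simulated b2/b4 deletion emits the canonical result
string; interior target placement within a gene is schematic. Genes
between DDX3Y and HSFY (UTY, TMSB4Y, NLGN4Y, VCY, CDY2) are intentionally
absent from the map: they are uninformative for the deletion rules, and
their absence makes the flanking-target uncertainty bounds of classical
deletions reproduce the printed convention. There is no enrichment in
chrY:9,368,285–14,517,915 (spanning the centromere); the loader warns if
a user map places targets there.

The cytoband table is the standard hg19 banding for chrX and chrY. The
CFTR panel definition is a user-editable JSON bundling the variants
needed for kit-membership and coverage logic; the commercial kit's full
53-variant content is not reproduced. The two deep-intronic variant
positions are curated approximations placed in intronic gaps of the
bundled target set — only their covered-in-v2/not-in-v1 status is
meaningful, not the exact base. The 130-gene infertility panel list is
likewise a curation from published gene–disease validity assessments with
the documented composition (52 oligo/azoospermia, 2 CBAVD, 34 MMAF/PCD,
3 acephalic, 2 globozoospermia, 2 fertilization failure, 7 other
astheno-/teratozoospermia, 28 AZF-region genes).

## Coverage simulator (`simcov`)

The generator emulates the depth signal of a ~100× clinical exome:

* **Capture efficiency.** Per-target efficiencies are log-normal
  (`efficiency_sd` = 0.25 on the log scale, mean 1) and shared by all
  samples of a batch. Reference-ratio normalization assumes exactly this
  cancellation, which is why reference panels are simulated in the same
  batch as the test samples.
* **Counts.** Depth is negative binomial with mean
  `e_t · mean_depth · copies_t / 2` and variance `μ + αμ²`, α =
  `dispersion` = 0.005. At 100× this gives a per-target coefficient of
  variation of ≈ 12%, in the range observed for normalized coverage
  ratios of well-behaved exome batches. No published dispersion estimate
  was available for the emulated setting; the value is a simulator
  convention chosen once for realism, and the variance is monotone in α
  (property-tested).
* **Copy arithmetic.** A genotype is a karyotype class plus CNV events,
  or a fraction-weighted mosaic of such components. Multicopy families
  are collapsed: a family target's copy number is the surviving family
  total, so a gr/gr deletion (DAZ 4→2) halves every DAZ target's depth
  rather than zeroing half the targets. Y events act on whole gene loci
  (a copy survives unless its locus lies inside the event interval).
* **Mosaics** are continuous mixtures; the bundled validation mosaics use
  fractions in the reported 14–87% range. Expected depths are exactly
  linear in the mixture (verified against Monte-Carlo means at ≥10⁴
  draws).

What the simulator does *not* model: GC bias, mappability variation
beyond the family collapse, reference-sample heterogeneity, FFPE-style
degradation, or SNV-level noise. Passing tests therefore demonstrate the
correctness and calibration of the decision logic under a well-behaved
depth model, not performance on adversarial real-world batches.

The validation cohort compositions are fixed: the AZF arm has 24
positives (2 AZFa, 2 AZFb P5/proximal-P1, 2 AZFbc P5/distal-P1, 11 AZFc
b2/b4, 7 idic(Y)) and 37 negatives; the sex-chromosome arm has 22
positives (10× 47,XXY, 5× 47,XYY, 3× 46,XX SRY+, 2× idic(Yq11), 2×
iso(Yp)) and 51 negatives; the reference panel has 90 samples.

## Dosage and calling (`depthcnv`)

Normalization is median-of-ratios in copy units (README formula), with a
final rescaling so the autosomal median dosage is exactly 2. Targets with
zero reference median are masked and logged; fewer than 10 reference
samples, or more than 10% zero-median targets, is an error.

Copy-state thresholds (copy units): a single-copy gene is absent below
0.25 and present at or above 0.6, with the interval between explicitly
indeterminate (possible mosaic). A multicopy family counts as completely
lost only below 0.5 total copies and as partially reduced below
baseline − 0.8 — chosen so gr/gr (≈ 2 of 4 copies) can never satisfy a
complete-loss rule.

chrY segmentation assigns each target its gene/family robust dosage,
smooths with a 7-target running median (symmetrically truncated at the
chromosome ends), snaps to integer states within 0.15·state, and merges
maximal runs. Intermediate (fractional) states must be sustained over at
least 10 consecutive targets to form a mosaic segment; shorter wobbles
are reassigned to the nearest of {neighboring state, normal}, proximal on
ties — deterministic by construction. Call objects carry the inner
(first-to-last aberrant target) interval and outer (flanking retained
target) bounds; a run reaching the most distal enriched target is flagged
terminal.

The mosaic-fraction estimator is the closed form f = 1 − dosage/baseline
for losses and f = (dosage − b)/k for gains from b to b+k copies, clamped
to [0, 1], with an interval propagated from the dosage spread. Simulation
at 100× shows the estimator mean within ±0.03 of truth at f ∈
{0.2, 0.3, 0.5} (200 seeded replicates; acceptance suite).

## AZF classification (`azf`)

A region is deleted iff **both** its rule genes are completely lost;
AZFb+AZFc together give the AZFbc class, with a terminal subtype when the
loss runs through the last enriched Yq target (the isodicentric-Y
signature). Loss of additional genes (e.g. both PRY copies with an
otherwise classical AZFc deletion — an atypical proximal breakpoint) is
annotated, never silently absorbed, and its clinical meaning is left
open. Single-gene losses, indeterminate dosages and reduced families
yield `partial_suspected` with a low-confidence flag; family-dosage
subtyping (gr/gr vs b2/b3) is marked suspected because collapsed dosage
alone cannot discriminate breakpoints. The classifier is total over all
2⁶ presence/absence combinations of the rule genes (exhaustively tested
against an independent truth-table oracle) and monotone: adding a lost
gene never converts a classical call to none.

Interval-based classification counts a gene as lost only when *all* its
targets (all family copies' loci) fall inside the deleted intervals, then
applies the same rules — so printed deletion coordinates and dosage
profiles go through one decision path.

## Karyotype inference (`sexkaryo`)

Compartments: X (all chrX targets), Yp (targets before the enrichment
gap), proximal Yq (AZFa block), distal Yq (AZFb/AZFc and the distal
anchor), SRY. Summaries are medians of per-copy relative dosages;
compartments under 5 targets are flagged low-confidence (SRY always is).

The decision table snaps compartment dosages to integers within a
tolerance of 0.15·state — the tolerance widens with the state because
depth noise is multiplicative. 0.15 was chosen, together with the default
noise model, to put the 50% detection point for whole-Y mosaicism at
f ≈ 0.12–0.15: the detection-power curve (fraction of simulations
classified non-normal) is monotone in f, ≈ 0 at f = 0, below 0.5 at
f = 0.10, above it at f = 0.20 and ≈ 1 at f = 0.5, i.e. the detection
limit sits inside the 10–20% band reported from practice. A wider snap
window of 0.2 would park the 50% point exactly at the band edge, which is
why 0.15 is the default.

Structural-Y logic: Yp gain with distal Yq ≈ 0 is `idic_or_iso_Y`; a
fractional Yp gain is read as the isodicentric line in mosaic with 45,X,
f = Yp − 1. If proximal Yq (AZFa) is also lost, the gain/loss transition
lies in the unenriched pericentromeric region and iso(Yp) vs idic(Yq)
cannot be distinguished — both candidates are listed and no breakpoint
band is asserted. Two failure modes are deliberately reproduced, not
patched: (1) a ~50/50 mosaic of 45,X with idic(Yq11.221) averages to a
seemingly normal male Yp/AZFa dosage with zero distal Yq and is reported
as 46,XY plus a terminal-deletion reading with an explicit ambiguity
note; (2) high-fraction mosaics (f ≳ 0.85) snap to the non-mosaic
aneuploid class, mirroring the observation that some true mosaics appear
non-mosaic at the depth level. Mosaics are limited to two cell lines.

## CFTR logic (`cftr`)

Kit membership is normalized-string lookup (unicode dashes, whitespace,
case). Enrichment coverage is an interval-overlap test against the kit
version's targets; v1 lacks the two deep-intronic loci, v2 covers both,
and v2 is a strict superset (property-tested). Genotype classification
counts pathogenic alleles (CF-causing or mild/CBAVD-associated; hom = 2;
a 5T allele only with TG ≥ 11; phase in trans assumed from input): ≥ 2 →
biallelic CFTR-related, 1 → carrier. `standard_detectable` requires every
contributing variant to be both a kit member and v1-covered. The CBAVD
semen pattern is azoospermia with volume < 1.5 mL or pH < 7.2; missing
fields propagate as unknown, never as false.

Risk arithmetic is exact-rational: carrier frequency from incidence via
Hardy–Weinberg (q = √incidence, 2q(1−q)), couple risk = father
transmission (1 or ½) × partner carrier probability × ½. The "one of N"
rendering rounds the reciprocal to the nearest integer and snaps to the
conventional round figure (multiple of 10) when within 5% — this
reproduces the customary 1/3600 → "one of 30" figure (exact reciprocal
30.5). The default partner residual carrier probability after a negative
screening panel is 1/600, an input parameter whose derivation (panel
sensitivity against population allele spectrum) is outside this package.

## Reporting (`evalreport`)

Rule-of-three bounds are (1 − 3/n)·100 to one decimal; sensitivity and
specificity print as whole percents in summary style with one-decimal
values available. Diagnostic categories form a total, deterministic
function of the finding flags: standard-detectable (sex-chromosome or
structural anomaly, classical AZF deletion, or fully kit-detectable
biallelic CFTR), extra yield (panel-gene pathogenic finding, biallelic
CFTR involving a non-kit variant, or a reportable VUS — reportability is
a config switch, default on), CF-carrier-only, none.

ISCN-like strings print the inner interval with band range and copy
state, plus an HGVS-like g. string with outer/inner uncertainty pairs and
pter/qter for chromosome ends; mosaic states print as ranges (×1∼2,
parsed back as the midpoint). `parse_iscn_like` also accepts the
sub-segmented and whole-chromosome ploidy forms used in printed result
tables, and `profile_from_iscn` turns a parsed string into a synthetic
dosage profile so printed results can be re-interpreted through the same
classifiers as fresh data. Format→parse is the identity on calls the
package itself produces (property-tested); parsing arbitrary external
nomenclature beyond these forms is not attempted.

## Problem sizes and determinism

Default analyses use the bundled 291-target map, 90-sample reference
panels, 61- and 73-sample validation arms, 50–200 replicates for
power/bias curves — sizes chosen so the full suite and the acceptance
script each run in well under a minute while keeping Monte-Carlo error
far from every decision threshold. All randomness flows through a single
seed (`numpy.random.default_rng`); identical seeds give bit-identical
tables, and the validation arms classify with 100% concordance across
arbitrary seeds at the default depth and dispersion (spot-checked over 30
consecutive seeds in development).

## Known limitations

* The caller is a deliberately simple stand-in; it does not reproduce
  CoNIFER/ExomeDepth behavior, window sizes or priors.
* Coordinates of bundled targets are schematic within genes; only
  relative structure and the boundary coordinates of recurrent deletion
  classes are meaningful.
* No autosome-wide CNV discovery: autosomal targets exist for
  normalization and for user-flagged panel regions only. Balanced and
  Robertsonian translocations are invisible to depth data by nature.
* The synthetic noise model omits GC and mappability structure; real-data
  thresholds would need recalibration against a laboratory's own
  reference batches.
* AZFc sub-amplicon genotyping (b1/b3 vs b2/b3 vs gr/gr) from collapsed
  family dosage is reported as suspected only.
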