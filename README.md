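# exomy

Exome read-depth interpretation for genetic diagnostics of male infertility:
Y-chromosome AZF microdeletions, sex-chromosome aneuploidies and structural
Y anomalies (including mosaics), CFTR screening-panel logic for
CBAVD/carrier findings, and the validation statistics used to qualify such
a workflow — exercised end to end on a bundled synthetic coverage
simulator.

## Who this is for

Clinical-genomics developers and methodologists who want a transparent,
testable model of how an all-in-one exome strategy replaces the three
classical first-tier tests (karyotyping, STS-PCR AZF deletion screening,
and targeted CFTR panels) for infertile men. The package is not a
diagnostic device; it is a faithful, fully synthetic re-implementation of
the interpretation layer, with every decision rule explicit and unit
tested.

## The core ideas

**Dosage from depth.** For target *t* with mean depth *d<sub>t</sub>*, the
copy-number dosage against a reference cohort *R* is

    dosage_t = b_t · (d_t / m) / median_{r∈R}(d_t^r / m_r)

where *m* is the sample's autosomal median depth and *b<sub>t</sub>* the
target's copy number in a reference 46,XY genome (2 autosomal, 1 for
single-copy X/Y genes, the family total for collapsed multicopy families —
e.g. DAZ = 4). After normalization the autosomal median is exactly 2, a
single-copy Y gene in a normal male reads ≈ 1, and a 30% mosaic Y loss
reads ≈ 0.7.

**Two genes per AZF region.** A classical complete deletion is called only
when *both* marker genes of a region are completely lost: USP9Y and DDX3Y
(AZFa), EIF1AY and RPS4Y2 (AZFb), the BPY2 and DAZ families (AZFc).
Partial deletions such as gr/gr (DAZ 4→2) spare family copies and are
flagged `partial_suspected`, never as a classical deletion.

**Karyotype from compartment dosages.** Medians over X, Yp, proximal Yq
(AZFa) and distal Yq compartments are snapped to integer states within a
tolerance; intermediate chromosome-wide dosages become two-line mosaic
calls with fraction *f* = 1 − dosage (loss). A Yp gain with distal Yq loss
is isodicentric/isochromosome Y; when the transition falls in the
unenriched pericentromeric gap (chrY:9,368,285–14,517,915) the two cannot
be distinguished and both candidates are reported.

**Validation statistics.** With zero discordances among *n* controls the
rule of three gives a 95% sensitivity/specificity bound of
(1 − 3/*n*) × 100. Carrier and couple risks use Hardy–Weinberg and exact
rational arithmetic.

## Worked example

```python
import numpy as np
from exomy import simcov, depthcnv, azf, sexkaryo

targets = __import__("exomy").refmodel.default_target_map()
params = simcov.DepthParams(mean_depth=100.0, seed=1)   # ~100x exome
rng = np.random.default_rng(1)
batch = simcov.CaptureBatch.draw(targets, params, rng)
reference = simcov.simulate_reference_cohort(90, params, targets, batch, rng)

# a b2/b4 AZFc deletion
table = simcov.simulate_sample(
    simcov.GenotypeSpec.deletion(simcov.AZFC_DEL), params, targets, batch, rng)
profile = depthcnv.normalize(table, reference, targets)
print(depthcnv.gene_dosage(profile, "DAZ").estimate)   # 0.0 (of baseline 4)
print(azf.classify_profile(profile).azf_class)         # AZFc_b2b4
call = depthcnv.segment_y(profile)[0]
from exomy.evalreport import format_iscn_like
print(format_iscn_like(call))
# seq[GRCh37] Yq11.223q11.23(25130410_27198251)×0
#   NC_000024.9:g.(24564028_25130410)_(27198251_58911807)del
```

The DAZ family dosage collapses to ≈ 0 of 4 copies, both AZFc rule genes
are completely lost, so the sample classifies as a classical b2/b4
deletion; the result string carries the inner (last-lost) interval and the
outer flanking-target uncertainty bounds.

The same pipeline from a shell:

```bash
exomy simulate --seed 1 --arm azf --out simdir/
exomy evaluate --seed 1
# azf arm: 61/61 concordant (100.0%), rule-of-three bound 95.1%
# sex arm: 73/73 concordant (100.0%), rule-of-three bound 95.9%
```

## Layout

| module | role |
| --- | --- |
| `exomy.refmodel` | GRCh37 target/gene/cytoband/panel reference model (bundled data) |
| `exomy.simcov` | synthetic coverage generator with genotype truth labels |
| `exomy.depthcnv` | normalization, gene/family dosages, chrY segmentation, mosaic fraction |
| `exomy.azf` | AZF deletion classification |
| `exomy.sexkaryo` | sex-karyotype and mosaicism inference, detection-power curves |
| `exomy.cftr` | CFTR kit membership, enrichment coverage, CBAVD/carrier, risk arithmetic |
| `exomy.evalreport` | rule of three, confusion matrices, diagnostic categories, ISCN-like strings |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
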