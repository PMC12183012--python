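"""Synthetic exome-coverage generator with genotype truth labels.

Emulates the per-target mean-depth signal of a 100x clinical exome for
arbitrary sex-chromosome karyotypes, AZF-region CNVs and mosaic mixtures.

Model
-----
Every target ``t`` has a capture efficiency ``e_t`` drawn once per batch from
a log-normal distribution (mean 1) and shared by all samples of the batch --
reference-ratio normalization relies on this cancellation.  The observed
depth is an overdispersed count around

    mu_t = e_t * mean_depth * copies_t / 2

where ``copies_t`` is the effective copy number of the target under the
genotype: for a multicopy family target it is the *surviving family total*
(collapsed short-read mapping on palindromic sequence), and for a mosaic it
is the fraction-weighted mixture of the component copy numbers.  Counts are
negative binomial with ``var = mu + dispersion * mu**2``.

The generator produces truth labels alongside each sample so that calling
and classification can be scored against the planted genotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .refmodel import CHRY_ENRICHMENT_GAP, TargetInterval, default_target_map

__all__ = [
    "CnvEvent",
    "GenotypeSpec",
    "DepthParams",
    "CaptureBatch",
    "CoverageTable",
    "LabeledCohort",
    "simulate_sample",
    "simulate_reference_cohort",
    "simulate_validation_cohort",
    "simulate_cftr_genotype",
    "write_coverage_tsv",
    "read_coverage_tsv",
]

# canonical deletion/duplication intervals (GRCh37) used by the named
# genotype constructors; boundaries follow the bundled target map
AZFA_DEL = (14600000, 15100000)
AZFB_DEL = (20708556, 24564028)          # P5/proximal P1
AZFBC_DEL = (20708556, 27198251)         # P5/distal P1
AZFC_DEL = (25130409, 27198251)          # b2/b4
GRGR_DEL = (25200000, 25500000)          # removes DAZ1+DAZ2, spares BPY2
B2B3_DEL = (26900000, 27060000)          # removes DAZ3+DAZ4
AZFBC_DUP = (20708556, 27198251)
IDIC_Q11221_BP = 17000000                # within Yq11.221, enriched flank
ISO_YP_BP = 12000000                     # inside the unenriched gap
XX_MALE_YP_BP = 6000000                  # der(X)t(X;Y) retained Yp segment


@dataclass(frozen=True)
class CnvEvent:
    """A copy-number event: ``delta`` is the per-haplotype copy change.

    A hemizygous/complete loss is ``delta=-1`` on chrY (copy states floor at
    zero); a heterozygous autosomal deletion is ``delta=-1`` of 2, a
    homozygous one ``delta=-2``; a duplication is ``delta=+1``.
    """

    chrom: str
    start: int
    end: int
    delta: int

    def contains_locus(self, start: int, end: int) -> bool:
        mid = (start + end) // 2
        return self.start <= mid < self.end


@dataclass(frozen=True)
class GenotypeSpec:
    """A (possibly mosaic) genotype: karyotype class plus CNV events."""

    karyotype: str = "46,XY"
    events: tuple[CnvEvent, ...] = ()
    breakpoint: int | None = None
    components: tuple[tuple["GenotypeSpec", float], ...] = ()
    label: dict = field(default_factory=dict, compare=False)

    _KARYOTYPES = ("46,XY", "47,XXY", "47,XYY", "45,X", "46,XX_SRY+",
                   "idic_Y", "iso_Yp")

    def __post_init__(self) -> None:
        if self.components:
            fracs = [f for _, f in self.components]
            if any(not (0 < f <= 1) for f in fracs):
                raise ValueError("mosaic fractions must lie in (0, 1]")
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ValueError("mosaic fractions must sum to 1")
        elif self.karyotype not in self._KARYOTYPES:
            raise ValueError(f"unknown karyotype class {self.karyotype!r}")

    # -- constructors -------------------------------------------------------
    @classmethod
    def normal_male(cls, **label) -> "GenotypeSpec":
        return cls(label=dict(label))

    @classmethod
    def aneuploid(cls, kclass: str, **label) -> "GenotypeSpec":
        return cls(karyotype=kclass, label=dict(label))

    @classmethod
    def xx_male(cls, breakpoint: int = XX_MALE_YP_BP, **label) -> "GenotypeSpec":
        return cls(karyotype="46,XX_SRY+", breakpoint=breakpoint,
                   label=dict(label))

    @classmethod
    def idic_y(cls, breakpoint: int = IDIC_Q11221_BP, **label) -> "GenotypeSpec":
        """Isodicentric Y: Yp (and Yq proximal to the breakpoint) doubled,
        the rest of Yq lost."""
        return cls(karyotype="idic_Y", breakpoint=breakpoint, label=dict(label))

    @classmethod
    def iso_yp(cls, **label) -> "GenotypeSpec":
        return cls(karyotype="iso_Yp", breakpoint=ISO_YP_BP, label=dict(label))

    @classmethod
    def deletion(cls, interval: tuple[int, int], chrom: str = "chrY",
                 delta: int = -1, **label) -> "GenotypeSpec":
        return cls(events=(CnvEvent(chrom, interval[0], interval[1], delta),),
                   label=dict(label))

    @classmethod
    def duplication(cls, interval: tuple[int, int], chrom: str = "chrY",
                    **label) -> "GenotypeSpec":
        return cls(events=(CnvEvent(chrom, interval[0], interval[1], +1),),
                   label=dict(label))

    @classmethod
    def mosaic(cls, *components: tuple["GenotypeSpec", float],
               **label) -> "GenotypeSpec":
        return cls(components=tuple(components), label=dict(label))

    def with_label(self, **label) -> "GenotypeSpec":
        merged = dict(self.label)
        merged.update(label)
        return replace(self, label=merged)

    # -- copy arithmetic ----------------------------------------------------
    def _y_locus_state(self, start: int, end: int) -> float:
        """Copy state of one chrY locus under this (non-mosaic) karyotype."""
        k = self.karyotype
        if k in ("46,XY",):
            base = 1.0
        elif k == "47,XYY":
            base = 2.0
        elif k in ("45,X",):
            base = 0.0
        elif k == "47,XXY":
            base = 1.0
        elif k == "46,XX_SRY+":
            base = 1.0 if end <= (self.breakpoint or XX_MALE_YP_BP) else 0.0
        elif k in ("idic_Y", "iso_Yp"):
            bp = self.breakpoint if self.breakpoint is not None else (
                ISO_YP_BP if k == "iso_Yp" else IDIC_Q11221_BP)
            base = 2.0 if end <= bp else 0.0
        else:  # pragma: no cover - guarded in __post_init__
            raise AssertionError(k)
        return base

    def _x_count(self) -> float:
        return {"46,XY": 1.0, "47,XXY": 2.0, "47,XYY": 1.0, "45,X": 1.0,
                "46,XX_SRY+": 2.0, "idic_Y": 1.0, "iso_Yp": 1.0}[self.karyotype]

    def target_copies(self, target: TargetInterval,
                      gene_loci: dict[str, tuple[str, int, int]]) -> float:
        """Effective copy number of ``target`` under this spec."""
        if self.components:
            return sum(f * comp.target_copies(target, gene_loci)
                       for comp, f in self.components)
        if target.chrom == "chrY":
            if target.family_id is not None:
                family_genes = [g for g, loc in gene_loci.items()
                                if loc[0] == "chrY"
                                and _family_of(g, gene_loci) == target.family_id]
                # surviving family total: one copy state per copy locus
                return sum(
                    self._apply_y_interval(gene_loci[g][1], gene_loci[g][2])
                    for g in family_genes)
            start, end = ((gene_loci[target.gene][1], gene_loci[target.gene][2])
                          if target.gene in gene_loci
                          else (target.start, target.end))
            return self._apply_y_interval(start, end)
        if target.chrom == "chrX":
            copies = self._x_count()
        else:
            copies = 2.0
        for ev in self.events:
            if ev.chrom == target.chrom and ev.contains_locus(target.start,
                                                              target.end):
                copies = max(0.0, copies + ev.delta)
        return copies

    def _apply_y_interval(self, start: int, end: int) -> float:
        state = self._y_locus_state(start, end)
        for ev in self.events:
            if ev.chrom == "chrY" and ev.contains_locus(start, end):
                state = max(0.0, state + ev.delta)
        return state


def _family_of(gene: str, gene_loci: dict) -> str | None:
    return gene_loci[gene][3] if len(gene_loci[gene]) > 3 else None


def build_gene_loci(targets: list[TargetInterval]) -> dict[str, tuple]:
    """Per gene-symbol locus extent: (chrom, min start, max end, family_id)."""
    loci: dict[str, list] = {}
    for t in targets:
        if t.gene is None:
            continue
        cur = loci.get(t.gene)
        if cur is None:
            loci[t.gene] = [t.chrom, t.start, t.end, t.family_id]
        else:
            cur[1] = min(cur[1], t.start)
            cur[2] = max(cur[2], t.end)
    return {g: tuple(v) for g, v in loci.items()}


@dataclass
class DepthParams:
    """Sequencing-depth model parameters.

    mean_depth
        Mean autosomal diploid depth; 100x emulates the clinical aim.
    efficiency_sd
        Log-scale sd of per-target capture efficiency (batch effect).
    dispersion
        Negative-binomial overdispersion: ``var = mu + dispersion * mu**2``.
    """

    mean_depth: float = 100.0
    efficiency_sd: float = 0.25
    dispersion: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.efficiency_sd < 0 or self.dispersion < 0:
            raise ValueError("dispersion parameters must be >= 0")


@dataclass
class CaptureBatch:
    """Per-target capture efficiencies shared by all samples of a batch."""

    efficiencies: dict[str, float]

    @classmethod
    def draw(cls, targets: list[TargetInterval], params: DepthParams,
             rng: np.random.Generator) -> "CaptureBatch":
        sd = params.efficiency_sd
        eff = np.exp(rng.normal(-0.5 * sd * sd, sd, size=len(targets)))
        return cls({t.target_id: float(e) for t, e in zip(targets, eff)})


@dataclass
class CoverageTable:
    """Observed mean depth per target for one sample."""

    sample_id: str
    depths: dict[str, float]
    truth: dict = field(default_factory=dict)

    def depth(self, target_id: str) -> float:
        return self.depths[target_id]


def _draw_counts(mu: np.ndarray, dispersion: float,
                 rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(mu)
    pos = mu > 0
    if dispersion > 0:
        r = 1.0 / dispersion
        p = r / (r + mu[pos])
        out[pos] = rng.negative_binomial(r, p)
    else:
        out[pos] = rng.poisson(mu[pos])
    return out.astype(float)


def simulate_sample(spec: GenotypeSpec, params: DepthParams,
                    targets: list[TargetInterval] | None = None,
                    batch: CaptureBatch | None = None,
                    rng: np.random.Generator | None = None,
                    sample_id: str = "S1") -> CoverageTable:
    """Draw one coverage table for ``spec``; identical seeds give identical
    output.  Expected depth of target t is ``e_t * mean * copies_t / 2``."""
    targets = targets if targets is not None else default_target_map()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    batch = batch if batch is not None else CaptureBatch.draw(targets, params, rng)
    loci = build_gene_loci(targets)
    _check_spec(spec, targets, loci)
    copies = np.array([spec.target_copies(t, loci) for t in targets])
    eff = np.array([batch.efficiencies[t.target_id] for t in targets])
    mu = eff * params.mean_depth * copies / 2.0
    counts = _draw_counts(mu, params.dispersion, rng)
    table = CoverageTable(sample_id,
                          {t.target_id: float(c)
                           for t, c in zip(targets, counts)})
    table.truth = dict(spec.label)
    return table


def expected_depths(spec: GenotypeSpec, params: DepthParams,
                    targets: list[TargetInterval],
                    batch: CaptureBatch | None = None) -> dict[str, float]:
    """Noise-free expected depth per target (the count-model mean)."""
    loci = build_gene_loci(targets)
    _check_spec(spec, targets, loci)
    out = {}
    for t in targets:
        eff = batch.efficiencies[t.target_id] if batch else 1.0
        out[t.target_id] = eff * params.mean_depth * spec.target_copies(t, loci) / 2.0
    return out


def _check_spec(spec: GenotypeSpec, targets: list[TargetInterval],
                loci: dict) -> None:
    known_chroms = {t.chrom for t in targets}
    stack = [spec]
    while stack:
        s = stack.pop()
        for comp, _ in s.components:
            stack.append(comp)
        for ev in s.events:
            if ev.chrom not in known_chroms:
                raise ValueError(
                    f"event references unknown chromosome {ev.chrom!r}")


def simulate_reference_cohort(n: int, params: DepthParams,
                              targets: list[TargetInterval] | None = None,
                              batch: CaptureBatch | None = None,
                              rng: np.random.Generator | None = None
                              ) -> list[CoverageTable]:
    """``n`` independent 46,XY samples sharing one capture batch.

    Fewer than 10 samples is refused: the median-of-ratios normalization
    needs a minimally stable reference.
    """
    if n < 10:
        raise ValueError("reference cohort must have >= 10 samples")
    targets = targets if targets is not None else default_target_map()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    batch = batch if batch is not None else CaptureBatch.draw(targets, params, rng)
    spec = GenotypeSpec.normal_male(karyotype="46,XY")
    return [simulate_sample(spec, params, targets, batch, rng, f"REF{i:03d}")
            for i in range(n)]


# ---------------------------------------------------------------------------
# validation cohort

def _azf_specs() -> list[GenotypeSpec]:
    specs = []
    for i in range(2):
        specs.append(GenotypeSpec.deletion(AZFA_DEL, azf="AZFa"))
    for i in range(2):
        specs.append(GenotypeSpec.deletion(AZFB_DEL, azf="AZFb_P5_proxP1"))
    for i in range(2):
        specs.append(GenotypeSpec.deletion(AZFBC_DEL, azf="AZFbc_P5_distP1"))
    for i in range(11):
        specs.append(GenotypeSpec.deletion(AZFC_DEL, azf="AZFc_b2b4"))
    for i in range(7):
        specs.append(GenotypeSpec.idic_y(azf="AZFbc_terminal"))
    for i in range(37):
        specs.append(GenotypeSpec.normal_male(azf="none"))
    return specs


def _sex_specs() -> list[GenotypeSpec]:
    specs = []
    for i in range(10):
        specs.append(GenotypeSpec.aneuploid("47,XXY", karyotype="47,XXY"))
    for i in range(5):
        specs.append(GenotypeSpec.aneuploid("47,XYY", karyotype="47,XYY"))
    for i in range(3):
        specs.append(GenotypeSpec.xx_male(karyotype="46,XX_SRY+"))
    for i in range(2):
        specs.append(GenotypeSpec.idic_y(karyotype="idic_or_iso_Y"))
    for i in range(2):
        specs.append(GenotypeSpec.iso_yp(karyotype="idic_or_iso_Y"))
    for i in range(51):
        specs.append(GenotypeSpec.normal_male(karyotype="46,XY"))
    return specs


def _optional_specs() -> list[GenotypeSpec]:
    """Mosaics and partial AZF rearrangements from the optional arm."""
    normal = GenotypeSpec.normal_male()
    specs = [
        GenotypeSpec.mosaic((GenotypeSpec.aneuploid("45,X"), 0.30),
                            (normal, 0.70),
                            karyotype="mos 45,X/46,XY", fraction=0.30),
        GenotypeSpec.mosaic((GenotypeSpec.aneuploid("45,X"), 0.14),
                            (normal, 0.86),
                            karyotype="mos 45,X/46,XY", fraction=0.14),
        GenotypeSpec.mosaic((GenotypeSpec.aneuploid("45,X"), 0.87),
                            (normal, 0.13),
                            karyotype="mos 45,X/46,XY", fraction=0.87),
        GenotypeSpec.mosaic((GenotypeSpec.aneuploid("47,XXY"), 0.50),
                            (normal, 0.50),
                            karyotype="mos 47,XXY/46,XY", fraction=0.50),
        # the documented trap: ~50/50 45,X with idic(Yq11.221) mimics a
        # non-mosaic terminal AZFbc deletion
        GenotypeSpec.mosaic((GenotypeSpec.aneuploid("45,X"), 17 / 30),
                            (GenotypeSpec.idic_y(), 13 / 30),
                            karyotype="mos 45,X/46,X,idic(Yq11.221)",
                            fraction=13 / 30),
        GenotypeSpec.deletion(GRGR_DEL, azf="partial_grgr"),
        GenotypeSpec.deletion(B2B3_DEL, azf="partial_b2b3"),
        GenotypeSpec.duplication(AZFBC_DUP, azf="AZFbc_duplication"),
    ]
    return specs


@dataclass
class LabeledCohort:
    """Simulated samples with truth labels plus their reference panel."""

    samples: list[CoverageTable]
    reference: list[CoverageTable]
    batch: CaptureBatch

    def truth_labels(self, key: str) -> list[str]:
        return [s.truth.get(key, "") for s in self.samples]

    def write_labels(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({s.sample_id: s.truth for s in self.samples}, fh,
                      indent=1, sort_keys=True)


def simulate_validation_cohort(params: DepthParams,
                               targets: list[TargetInterval] | None = None,
                               arm: str = "azf",
                               n_reference: int = 90,
                               seed: int | None = None) -> LabeledCohort:
    """The validation-cohort composition with truth labels.

    ``arm="azf"``: 24 positives (2 AZFa, 2 AZFb, 2 AZFbc, 11 AZFc b2/b4,
    7 idic(Y)) + 37 negatives.  ``arm="sex"``: 22 positives (10 47,XXY,
    5 47,XYY, 3 46,XX SRY+, 2 idic(Y), 2 iso(Yp)) + 51 negatives.
    ``arm="optional"``: mosaics (fractions in the reported 14-87% range)
    and partial AZF rearrangements.
    """
    targets = targets if targets is not None else default_target_map()
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    batch = CaptureBatch.draw(targets, params, rng)
    specs = {"azf": _azf_specs, "sex": _sex_specs,
             "optional": _optional_specs}.get(arm)
    if specs is None:
        raise ValueError(f"unknown validation arm {arm!r}")
    reference = simulate_reference_cohort(n_reference, params, targets,
                                          batch, rng)
    samples = [simulate_sample(spec, params, targets, batch, rng,
                               f"{arm.upper()}{i:03d}")
               for i, spec in enumerate(specs())]
    return LabeledCohort(samples=samples, reference=reference, batch=batch)


# ---------------------------------------------------------------------------
# CFTR genotype simulation

def simulate_cftr_genotype(variant_specs: list[tuple[str, str]],
                           phenotype: dict | None = None,
                           panel=None):
    """Build a CFTR variant table plus a semen-phenotype record.

    ``variant_specs`` is a list of ``(cdna, zygosity)`` pairs; each cdna must
    exist in the panel definition unless suffixed ``"|novel"``.  Returns
    ``(list[CftrVariant], SemenPhenotype)``.
    """
    from . import cftr as _cftr
    from .refmodel import default_panel

    panel = panel or default_panel()
    variants = []
    for cdna, zygosity in variant_specs:
        novel = cdna.endswith("|novel")
        cdna = cdna.removesuffix("|novel")
        entry = panel.lookup(cdna)
        if entry is None and not novel:
            raise ValueError(
                f"variant {cdna!r} not in panel definition; tag it |novel")
        variants.append(_cftr.CftrVariant.from_panel_entry(
            cdna, zygosity, entry))
    pheno = _cftr.SemenPhenotype(**(phenotype or {}))
    return variants, pheno


# ---------------------------------------------------------------------------
# coverage table I/O (BED-like TSV)

def write_coverage_tsv(table: CoverageTable,
                       targets: list[TargetInterval],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttarget_id\tmean_depth\n")
        for t in targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.target_id}\t"
                     f"{table.depths[t.target_id]:.6g}\n")


def read_coverage_tsv(path: str | Path, sample_id: str | None = None
                      ) -> CoverageTable:
    depths = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx_id = header.index("target_id")
        idx_d = header.index("mean_depth")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            depths[fields[idx_id]] = float(fields[idx_d])
    return CoverageTable(sample_id or Path(path).stem, depths)
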