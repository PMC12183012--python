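"""CFTR panel logic: kit membership, enrichment coverage, CBAVD vs carrier
classification, and carrier/couple risk arithmetic.

Congenital bilateral absence of the vas deferens (CBAVD) is the CFTR-related
obstructive-azoospermia phenotype; two CFTR alleles that are CF-causing or
CBAVD-associated (including a 5T allele with a long TG tract) establish it.
A single pathogenic allele indicates carriership of cystic fibrosis, which
matters for the couple's reproductive risk: if the partner's residual
carrier probability after a negative screening panel is p, the risk of an
affected child is p/2 when the man carries two pathogenic alleles (he
always transmits one) and p/4 when he carries one.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction

from .refmodel import PanelDefinition, cftr_enrichment, default_panel

__all__ = [
    "CftrVariant",
    "SemenPhenotype",
    "RiskResult",
    "CftrFindings",
    "is_panel_member",
    "is_covered",
    "classify_cftr_findings",
    "cbavd_phenotype_consistent",
    "carrier_freq_from_incidence",
    "affected_child_risk",
    "DEFAULT_PARTNER_RESIDUAL",
]

_ZYGOSITIES = ("het", "hom", "hem")
_SEVERITIES = ("CF-causing", "mild", "T/TG-modifier", "VUS")

# residual carrier probability of a partner with a negative screening panel;
# an input parameter, this is the documented default
DEFAULT_PARTNER_RESIDUAL = Fraction(1, 600)

_CDNA_RE = re.compile(
    r"^c\.[0-9*+-]+(_[0-9*+-]+)?([ACGT]>[ACGT]|DEL|DUP|INS[ACGT]*|[ACGT]*)$",
    re.IGNORECASE)


@dataclass
class CftrVariant:
    """One CFTR variant call with zygosity and panel/coverage annotation."""

    cdna: str
    zygosity: str
    genomic_hgvs: str | None = None
    chrom: str = "chr7"
    start: int | None = None
    end: int | None = None
    severity: str = "VUS"
    panel_member: bool = False
    tg_repeat: int | None = None    # TG-tract length for 5T alleles

    def __post_init__(self) -> None:
        if self.zygosity not in _ZYGOSITIES:
            raise ValueError(f"zygosity must be one of {_ZYGOSITIES}")
        if self.severity not in _SEVERITIES:
            raise ValueError(f"severity must be one of {_SEVERITIES}")
        if not _CDNA_RE.match(self.cdna.replace(" ", "")):
            raise ValueError(f"unparseable cDNA HGVS: {self.cdna!r}")

    @classmethod
    def from_panel_entry(cls, cdna: str, zygosity: str,
                         entry: dict | None) -> "CftrVariant":
        if entry is None:
            return cls(cdna=cdna, zygosity=zygosity)
        tg = 12 if entry.get("legacy") == "5T" else None
        return cls(cdna=cdna, zygosity=zygosity,
                   genomic_hgvs=entry.get("genomic_hgvs"),
                   chrom=entry.get("chrom", "chr7"),
                   start=entry.get("start"), end=entry.get("end"),
                   severity=entry.get("severity", "VUS"),
                   panel_member=bool(entry.get("in_kit")),
                   tg_repeat=tg)

    @property
    def allele_count(self) -> int:
        return 2 if self.zygosity == "hom" else 1

    @property
    def pathogenic(self) -> bool:
        """Counts toward a CFTR-related (CBAVD/CF) genotype.

        CF-causing and mild/CBAVD-associated variants count; a 5T allele
        counts only with a long TG tract (>= 11 repeats, splicing-relevant).
        """
        if self.severity in ("CF-causing", "mild"):
            return True
        if self.severity == "T/TG-modifier":
            return (self.tg_repeat or 0) >= 11
        return False


@dataclass
class SemenPhenotype:
    """Concentration class plus ejaculate volume (mL) and pH."""

    concentration: str | None = None   # azoospermia / oligozoospermia / normal
    volume_ml: float | None = None
    ph: float | None = None

    def __post_init__(self) -> None:
        if self.volume_ml is not None and self.volume_ml < 0:
            raise ValueError("volume must be >= 0")
        if self.ph is not None and not (5 <= self.ph <= 9):
            raise ValueError("pH out of plausible range [5, 9]")


@dataclass
class RiskResult:
    """Probability as an exact rational plus a 'one of N' rendering."""

    probability: Fraction
    one_of: int

    def __post_init__(self) -> None:
        if not (0 <= self.probability <= 1):
            raise ValueError("probability must lie in [0, 1]")

    def __str__(self) -> str:
        return f"one of {self.one_of}"


def is_panel_member(variant: CftrVariant | str,
                    panel: PanelDefinition | None = None) -> bool:
    """Normalized-string membership of a variant in the screening kit."""
    panel = panel or default_panel()
    cdna = variant if isinstance(variant, str) else variant.cdna
    if not cdna or not cdna.strip():
        raise ValueError("empty variant")
    return panel.is_member(cdna)


def is_covered(variant: CftrVariant, version: str = "v1",
               targets=None) -> bool:
    """Whether the variant's locus overlaps the kit version's enrichment.

    v1 lacks the two deep-intronic loci (intron 22 c.3718-2477 and
    c.1680-886); v2 covers both.
    """
    if variant.start is None or variant.end is None:
        raise ValueError(f"variant {variant.cdna} has no genomic position")
    intervals = cftr_enrichment(version, targets)
    return any(s < variant.end and variant.start < e for s, e in intervals)


@dataclass
class CftrFindings:
    classification: str                  # biallelic_CFTR_related / carrier / none
    standard_detectable: bool
    pathogenic_alleles: int
    contributing: list[CftrVariant] = field(default_factory=list)
    phenotype_consistent: bool | None = None
    notes: list[str] = field(default_factory=list)


def cbavd_phenotype_consistent(phenotype: SemenPhenotype | None) -> bool | None:
    """True iff azoospermia with low volume (<1.5 mL) OR low pH (<7.2).

    Missing fields yield ``None`` (unknown), never False: an obstructive
    pattern cannot be excluded on absent data.
    """
    if phenotype is None or phenotype.concentration is None:
        return None
    if phenotype.concentration != "azoospermia":
        return False
    vol_low = None if phenotype.volume_ml is None else phenotype.volume_ml < 1.5
    ph_low = None if phenotype.ph is None else phenotype.ph < 7.2
    if vol_low or ph_low:
        return True
    if vol_low is None and ph_low is None:
        return None
    if vol_low is False and ph_low is None or vol_low is None and ph_low is False:
        return None
    return False


def classify_cftr_findings(variants: list[CftrVariant],
                           phenotype: SemenPhenotype | None = None,
                           targets=None) -> CftrFindings:
    """Biallelic CFTR-related genotype vs carrier vs none.

    Two or more pathogenic/CBAVD-associated alleles (hom counts as two;
    phasing in trans is assumed from input) give the biallelic class, one
    gives carrier.  ``standard_detectable`` requires every contributing
    variant to be a kit member AND covered by the v1 enrichment.  For
    carriers, a normal-volume/pH azoospermia phenotype is noted as arguing
    against a missed CBAVD genotype.
    """
    contributing = [v for v in variants if v.pathogenic]
    alleles = sum(v.allele_count for v in contributing)
    consistent = cbavd_phenotype_consistent(phenotype)
    notes: list[str] = []
    if alleles >= 2:
        cls = "biallelic_CFTR_related"
    elif alleles == 1:
        cls = "carrier"
        if consistent is False:
            notes.append("normal semen volume and/or pH argues against a "
                         "missed CBAVD genotype")
        elif consistent is True:
            notes.append("CBAVD-consistent semen phenotype with a single "
                         "detected allele: consider full-gene reanalysis")
    else:
        cls = "none"
    std = bool(contributing) and all(
        v.panel_member and is_covered(v, "v1", targets) for v in contributing)
    return CftrFindings(classification=cls, standard_detectable=std,
                        pathogenic_alleles=alleles, contributing=contributing,
                        phenotype_consistent=consistent, notes=notes)


def _round_one_of(reciprocal: float) -> int:
    """Nearest integer, snapped to the convention's round figure (a multiple
    of 10) when that figure lies within 5%."""
    nearest = round(reciprocal)
    round_fig = round(reciprocal / 10) * 10
    if round_fig > 0 and abs(reciprocal - round_fig) <= 0.05 * reciprocal:
        return int(round_fig)
    return int(nearest)


def carrier_freq_from_incidence(incidence: float | Fraction) -> RiskResult:
    """Hardy-Weinberg carrier frequency from a disease incidence.

    q = sqrt(incidence); carrier frequency 2q(1-q), reported as "one of N"
    with N the rounded reciprocal (incidence 1/3600 gives one of 30).
    """
    inc = Fraction(incidence).limit_denominator(10**12) \
        if not isinstance(incidence, Fraction) else incidence
    if not (0 < inc < 1):
        raise ValueError("incidence must lie in (0, 1)")
    q = math.sqrt(float(inc))
    freq = 2 * q * (1 - q)
    one_of = _round_one_of(1.0 / freq)
    return RiskResult(probability=Fraction(freq).limit_denominator(10**9),
                      one_of=one_of)


_GT = {"het": "0/1", "hom": "1/1", "hem": "1"}
_GT_REV = {v: k for k, v in _GT.items()}

_SNV_RE = re.compile(r"g\.(\d+)([ACGT])>([ACGT])")


def write_vcf(variants: list[CftrVariant], path) -> None:
    """Write a minimal VCF v4.2 with a GT field and a cDNA-HGVS INFO key.

    SNV REF/ALT bases are recovered from the genomic HGVS when present;
    indels without stored sequence use symbolic alleles.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CDNA,Number=1,Type=String,Description="cDNA HGVS">',
        '##INFO=<ID=SEV,Number=1,Type=String,Description="Severity tag">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    for v in variants:
        if v.start is None:
            raise ValueError(f"variant {v.cdna} has no genomic position")
        pos = v.start + 1
        m = _SNV_RE.search(v.genomic_hgvs or "")
        if m:
            ref, alt = m.group(2), m.group(3)
        elif "del" in v.cdna:
            ref, alt = "N", "<DEL>"
        elif "dup" in v.cdna or "ins" in v.cdna:
            ref, alt = "N", "<DUP>"
        else:
            ref, alt = "N", "<ALT>"
        info = f"CDNA={v.cdna};SEV={v.severity}"
        lines.append(f"{v.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}"
                     f"\tGT\t{_GT[v.zygosity]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path, panel: PanelDefinition | None = None) -> list[CftrVariant]:
    """Read a minimal VCF written by :func:`write_vcf` back into variants."""
    panel = panel or default_panel()
    variants = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            info = dict(kv.split("=", 1) for kv in fields[7].split(";")
                        if "=" in kv)
            cdna = info.get("CDNA")
            if cdna is None:
                raise ValueError(f"{path}: record without CDNA INFO key")
            zygosity = _GT_REV.get(fields[9])
            if zygosity is None:
                raise ValueError(f"{path}: unsupported GT {fields[9]!r}")
            entry = panel.lookup(cdna)
            v = CftrVariant.from_panel_entry(cdna, zygosity, entry)
            if entry is None:
                v.severity = info.get("SEV", "VUS")
                v.chrom = fields[0]
                v.start = int(fields[1]) - 1
                v.end = v.start + len(fields[3])
            variants.append(v)
    return variants


def affected_child_risk(father_alleles: int,
                        partner_carrier_prob: Fraction | float
                        = DEFAULT_PARTNER_RESIDUAL) -> RiskResult:
    """Couple risk of an affected child per pregnancy, exact rational.

    risk = (father transmits: 1 if two alleles, 1/2 if one)
         x partner carrier probability x 1/2 (carrier partner transmits).
    """
    if father_alleles not in (1, 2):
        raise ValueError("father must carry 1 or 2 pathogenic alleles")
    p = partner_carrier_prob if isinstance(partner_carrier_prob, Fraction) \
        else Fraction(partner_carrier_prob).limit_denominator(10**9)
    if not (0 <= p <= 1):
        raise ValueError("partner carrier probability must lie in [0, 1]")
    transmit = Fraction(1) if father_alleles == 2 else Fraction(1, 2)
    risk = transmit * p * Fraction(1, 2)
    if risk == 0:
        raise ValueError("partner carrier probability of zero gives no risk "
                         "to report")
    return RiskResult(probability=risk,
                      one_of=_round_one_of(1.0 / float(risk)))
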