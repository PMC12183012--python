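"""Validation statistics, diagnostic categorization and result nomenclature.

Covers the reporting layer of the workflow: rule-of-three validation
bounds, sensitivity/specificity tallies, the diagnostic categories of the
evaluation summary (detectable by standard methods / extra yield of exome
analysis / CF carriership only), ISCN-like result strings for CNV and
karyotype calls, and gene-panel filtering of variant tables.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

from .azf import AzfClass, AzfClassification
from .cftr import CftrFindings
from .depthcnv import CnvCall, DosageProfile
from .refmodel import (CHROM_ACCESSIONS, CytobandTable, band_for_interval,
                       default_cytobands, default_target_map, load_panel_genes)
from .sexkaryo import KaryotypeCall, SexDosages, classify_karyotype, estimate_sex_dosages

logger = logging.getLogger(__name__)

__all__ = [
    "RuleOfThreeBound",
    "ConfusionMatrix",
    "DiagnosticReport",
    "CohortSummary",
    "rule_of_three_bound",
    "confusion_stats",
    "assign_category",
    "filter_to_panel",
    "format_iscn_like",
    "format_karyotype_iscn",
    "parse_iscn_like",
    "profile_from_iscn",
    "summarize_cohort",
]


# ---------------------------------------------------------------------------
# validation statistics

@dataclass(frozen=True)
class RuleOfThreeBound:
    """95% lower bound on sensitivity/specificity with zero discordances.

    With zero events among n validated samples, the 95% upper bound on the
    event rate is 3/n, hence the bound (1 - 3/n) x 100, floored at 0.
    """

    n: int
    bound_percent: float

    def __str__(self) -> str:
        return f"at least {self.bound_percent}%"


def rule_of_three_bound(n: int) -> RuleOfThreeBound:
    if n < 1:
        raise ValueError("n must be >= 1")
    pct = max(0.0, 1.0 - 3.0 / n) * 100.0
    return RuleOfThreeBound(n=n, bound_percent=round(pct, 1))


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    def sensitivity_percent(self, whole: bool = True) -> float:
        pct = self.sensitivity * 100
        return round(pct) if whole else round(pct, 1)

    def specificity_percent(self, whole: bool = True) -> float:
        pct = self.specificity * 100
        return round(pct) if whole else round(pct, 1)


def confusion_stats(calls, truth) -> ConfusionMatrix:
    """Tally a detection vector against truth (both boolean sequences)."""
    calls = list(calls)
    truth = list(truth)
    if len(calls) != len(truth):
        raise ValueError(f"label vectors differ in length "
                         f"({len(calls)} vs {len(truth)})")
    tp = sum(1 for c, t in zip(calls, truth) if c and t)
    fp = sum(1 for c, t in zip(calls, truth) if c and not t)
    tn = sum(1 for c, t in zip(calls, truth) if not c and not t)
    fn = sum(1 for c, t in zip(calls, truth) if not c and t)
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# diagnostic categorization

CATEGORIES = ("standard_detectable", "extra_yield", "cf_carrier_only", "none")

_CLASSICAL_AZF = {AzfClass.AZFA, AzfClass.AZFB, AzfClass.AZFBC,
                  AzfClass.AZFC, AzfClass.AZFBC_TERMINAL}


@dataclass
class DiagnosticReport:
    """Per-sample findings mapped to one diagnostic category."""

    sample_id: str
    karyotype: KaryotypeCall | None = None
    azf: AzfClassification | None = None
    cftr: CftrFindings | None = None
    panel_pathogenic: bool = False     # pathogenic SNV/CNV in a panel gene
    reportable_vus: bool = False
    iscn: list[str] = field(default_factory=list)
    category: str | None = None

    def assign(self, vus_reportable: bool = True) -> str:
        self.category = assign_category(self, vus_reportable=vus_reportable)
        return self.category


def assign_category(report: DiagnosticReport,
                    vus_reportable: bool = True) -> str:
    """Total, deterministic category rule over the finding flags.

    standard_detectable: sex-chromosomal/structural anomaly, classical
    complete AZF deletion, or biallelic CFTR with every variant in the
    screening kit and v1-covered.  extra_yield: panel-gene pathogenic
    finding, biallelic CFTR involving a non-kit variant, or a reportable
    VUS.  cf_carrier_only: a single pathogenic CFTR allele.  Otherwise none.
    """
    sex_abnormal = (report.karyotype is not None
                    and report.karyotype.karyotype not in
                    ("46,XY", "indeterminate"))
    classical_azf = (report.azf is not None
                     and report.azf.azf_class in _CLASSICAL_AZF)
    cftr = report.cftr
    biallelic = cftr is not None and cftr.classification == "biallelic_CFTR_related"
    carrier = cftr is not None and cftr.classification == "carrier"
    if sex_abnormal or classical_azf or (biallelic and cftr.standard_detectable):
        return "standard_detectable"
    if report.panel_pathogenic or (biallelic and not cftr.standard_detectable) \
            or (vus_reportable and report.reportable_vus):
        return "extra_yield"
    if carrier:
        return "cf_carrier_only"
    return "none"


def filter_to_panel(variant_table, gene_list: list[str] | None = None):
    """Keep only variants whose gene is on the infertility panel.

    ``variant_table`` is a pandas DataFrame with a ``gene`` column; the
    default gene list is the bundled 130-gene panel.
    """
    genes = gene_list if gene_list is not None else load_panel_genes()
    if not genes:
        raise ValueError("gene panel is empty")
    gene_set = set(genes)
    kept = variant_table[variant_table["gene"].isin(gene_set)]
    logger.info("panel filter: %d of %d variants retained",
                len(kept), len(variant_table))
    return kept


# ---------------------------------------------------------------------------
# ISCN-like nomenclature

def _fmt_state(state: float) -> str:
    if float(state).is_integer():
        return str(int(state))
    import math
    return f"{math.floor(state)}∼{math.ceil(state)}"


def _parse_state(text: str) -> float:
    text = text.replace("~", "∼")
    if "∼" in text:
        lo, hi = text.split("∼")
        return (float(lo) + float(hi)) / 2.0
    return float(text)


def format_iscn_like(call: CnvCall,
                     cytobands: CytobandTable | None = None) -> str:
    """ISCN-like result string for one CNV call.

    The inner interval (1-based inclusive) prints in the band/coordinate
    part; the HGVS-like g. part carries the outer/inner uncertainty pairs,
    with pter/qter when a bound reaches a chromosome end.
    """
    cytobands = cytobands or default_cytobands()
    if call.chrom not in cytobands.bands:
        raise ValueError(f"no cytobands available for {call.chrom}")
    acc = CHROM_ACCESSIONS[call.chrom]
    inner1 = (call.inner[0] + 1, call.inner[1])
    bands = band_for_interval(call.chrom, inner1[0], inner1[1], cytobands)
    chrom_len = cytobands.chromosome_length(call.chrom)
    seq = f"seq[GRCh37] {bands}({inner1[0]}_{inner1[1]})×{_fmt_state(call.copy_state)}"
    prox = "pter" if call.outer[0] <= 0 else f"({call.outer[0]}_{inner1[0]})"
    dist = "qter" if call.outer[1] >= chrom_len else f"({inner1[1]}_{call.outer[1] + 1})"
    op = "del" if call.direction == "loss" else "dup"
    return f"{seq} {acc}:g.{prox}_{dist}{op}"


_KARYO_SEQ = {
    "46,XY": "seq(X)×1,(Y)×1",
    "47,XXY": "seq(X)×2,(Y)×1 NC_000023.10:g.[pter_qter]sup",
    "47,XYY": "seq(X)×1,(Y)×2 NC_000024.9:g.[pter_qter]sup",
    "45,X": "seq(X)×1,(Y)×0 NC_000024.9:g.[pter_qter]del",
}


def format_karyotype_iscn(call: KaryotypeCall) -> str:
    """Whole-chromosome result string for a non-structural karyotype call."""
    s = _KARYO_SEQ.get(call.karyotype)
    if s is None:
        raise ValueError(
            f"no whole-chromosome nomenclature for {call.karyotype!r}; "
            "structural calls are formatted from their CnvCalls")
    return s


@dataclass
class ParsedSegment:
    chrom: str
    start: int | None      # 1-based inclusive; None = pter
    end: int | None        # 1-based inclusive; None = qter
    state: float


@dataclass
class ParsedResult:
    kind: str                        # "ploidy" | "segments"
    segments: list[ParsedSegment]
    calls: list[CnvCall] = field(default_factory=list)


_PLOIDY_RE = re.compile(r"seq\((X|Y)\)×(\d+)(?:,\((X|Y)\)×(\d+))?")
_UNIT_RE = re.compile(
    r"(?P<bands>(?:[0-9]{1,2}|X|Y)[pq][0-9pqter.]*)\((?P<inner>[^()]*)\)"
    r"(?:×(?P<state>[0-9]+(?:∼[0-9]+)?))?")
_GDOT_RE = re.compile(
    r"(?P<acc>NC_0+(?P<num>\d+)\.\d+):g\."
    r"(?P<prox>pter|\((?P<a>\d+)_(?P<b>\d+)\))_"
    r"(?P<dist>qter|\((?P<c>\d+)_(?P<d>\d+)\))"
    r"(?P<op>del|dup)")


def _normalize(text: str) -> str:
    for dash in ("‐", "‑", "‒", "–", "−"):
        text = text.replace(dash, "-")
    return (text.replace(" ", "").replace(" ", "")
            .replace("~", "∼").replace("x", "×")
            .replace("×", "×"))


def parse_iscn_like(text: str,
                    cytobands: CytobandTable | None = None) -> ParsedResult:
    """Parse a result string into copy-state segments (and CNV calls).

    Accepts the whole-chromosome ploidy style (``seq(X)x2,(Y)x1 ...``) and
    the segment style (``seq[GRCh37] Yq11...(start_end)x0 NC_...:g...del``),
    including sub-segmented parentheses and pter/qter bounds.  Unicode
    multiplication signs, tildes and hyphens are normalized.
    """
    cytobands = cytobands or default_cytobands()
    raw = text
    text = _normalize(text)
    if text.startswith("seq("):
        m = _PLOIDY_RE.match(text)
        if not m:
            raise ValueError(f"unparseable ploidy string: {raw!r}")
        segs = [ParsedSegment(f"chr{m.group(1)}", None, None, float(m.group(2)))]
        if m.group(3):
            segs.append(ParsedSegment(f"chr{m.group(3)}", None, None,
                                      float(m.group(4))))
        return ParsedResult(kind="ploidy", segments=segs)
    if not text.startswith("seq[GRCh37]"):
        raise ValueError(f"unrecognized result string: {raw!r}")
    body = text[len("seq[GRCh37]"):]
    segments: list[ParsedSegment] = []
    for m in _UNIT_RE.finditer(body.split("NC_")[0] if "NC_" in body else body):
        bands = m.group("bands")
        cm = re.match(r"([0-9]{1,2}|X|Y)", bands)
        chrom = f"chr{cm.group(1)}"
        outer_state = m.group("state")
        for sub in m.group("inner").split(","):
            if not sub:
                continue
            state = outer_state
            if "×" in sub:
                sub, state = sub.split("×")
            if state is None:
                continue
            if "_" in sub:
                s_txt, e_txt = sub.split("_")
            else:
                s_txt = e_txt = sub
            start = None if s_txt == "pter" else int(s_txt)
            end = None if e_txt == "qter" else int(e_txt)
            segments.append(ParsedSegment(chrom, start, end,
                                          _parse_state(state)))
    calls: list[CnvCall] = []
    seg_by_chrom: dict[str, list[ParsedSegment]] = {}
    for s in segments:
        seg_by_chrom.setdefault(s.chrom, []).append(s)
    for m in _GDOT_RE.finditer(text):
        num = int(m.group("num"))
        chrom = {23: "chrX", 24: "chrY"}.get(num, f"chr{num}")
        op = m.group("op")
        chrom_len = (cytobands.chromosome_length(chrom)
                     if chrom in cytobands.bands else None)
        # the matching seq segment (by direction) supplies the inner bounds
        # that a pter/qter g. bound does not carry, plus the copy state
        matching = [s for s in seg_by_chrom.get(chrom, [])
                    if (s.state < 1) == (op == "del")]
        seg = matching[0] if len(matching) == 1 else None
        if m.group("b") is not None:
            inner_start = int(m.group("b")) - 1
            outer_start = int(m.group("a"))
        else:
            inner_start = (seg.start - 1 if seg and seg.start is not None
                           else 0)
            outer_start = 0
        if m.group("c") is not None:
            inner_end = int(m.group("c"))
            outer_end = int(m.group("d")) - 1
        else:
            inner_end = (seg.end if seg and seg.end is not None
                         else chrom_len)
            outer_end = chrom_len
        state = seg.state if seg is not None else (0.0 if op == "del" else 2.0)
        if inner_end is None or outer_end is None:
            continue
        calls.append(CnvCall(
            chrom=chrom, inner=(inner_start, inner_end),
            outer=(outer_start, outer_end), copy_state=state,
            direction="loss" if op == "del" else "gain",
            terminal=m.group("dist") == "qter"))
    return ParsedResult(kind="segments", segments=segments, calls=calls)


def profile_from_iscn(parsed: ParsedResult, targets=None,
                      sample_id: str = "parsed") -> DosageProfile:
    """Synthesize a dosage profile from a parsed result string.

    Unmentioned targets take their 46,XY baseline; mentioned segments set
    the per-haplotype state of the targets they cover.  The profile feeds
    the regular karyotype/AZF classifiers, so printed results can be
    re-interpreted through the same decision logic as fresh data.
    """
    targets = targets if targets is not None else default_target_map()
    dosages = {}
    for t in targets:
        rel = 1.0
        for s in parsed.segments:
            if s.chrom != t.chrom:
                continue
            start0 = 0 if s.start is None else s.start - 1
            end0 = float("inf") if s.end is None else s.end
            if start0 < t.end and t.start < end0:
                rel = s.state
        dosages[t.target_id] = rel * t.baseline_copies
    return DosageProfile(sample_id=sample_id, targets=list(targets),
                         dosages=dosages)


def karyotype_from_iscn(text: str, targets=None) -> KaryotypeCall:
    """Parse a printed result string and classify its karyotype."""
    parsed = parse_iscn_like(text)
    profile = profile_from_iscn(parsed, targets)
    return classify_karyotype(estimate_sex_dosages(profile))


# ---------------------------------------------------------------------------
# cohort summary

@dataclass
class CohortSummary:
    n: int
    category_counts: Counter
    finding_counts: Counter
    abnormal: int
    abnormal_percent: float

    def percent(self, category: str) -> float:
        return round(100.0 * self.category_counts.get(category, 0) / self.n, 1)

    def to_tsv(self) -> str:
        lines = ["category\tcount\tpercent"]
        for cat in CATEGORIES:
            lines.append(f"{cat}\t{self.category_counts.get(cat, 0)}\t"
                         f"{self.percent(cat)}")
        lines.append(f"any_relevant_finding\t{self.abnormal}\t"
                     f"{self.abnormal_percent}")
        return "\n".join(lines) + "\n"


def summarize_cohort(reports: list[DiagnosticReport]) -> CohortSummary:
    """Counts and one-decimal percents per category and finding class."""
    if not reports:
        raise ValueError("no reports to summarize")
    cats = Counter()
    findings = Counter()
    for r in reports:
        cat = r.category if r.category is not None else assign_category(r)
        cats[cat] += 1
        if r.karyotype is not None and r.karyotype.karyotype not in \
                ("46,XY", "indeterminate"):
            findings[f"karyotype:{r.karyotype.karyotype}"] += 1
        if r.azf is not None and r.azf.azf_class in _CLASSICAL_AZF:
            findings[f"azf:{r.azf.azf_class}"] += 1
        if r.cftr is not None and r.cftr.classification != "none":
            findings[f"cftr:{r.cftr.classification}"] += 1
        if r.panel_pathogenic:
            findings["panel:pathogenic"] += 1
        if r.reportable_vus:
            findings["panel:vus"] += 1
    abnormal = sum(c for cat, c in cats.items() if cat != "none")
    return CohortSummary(
        n=len(reports), category_counts=cats, finding_counts=findings,
        abnormal=abnormal,
        abnormal_percent=round(100.0 * abnormal / len(reports), 1))
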