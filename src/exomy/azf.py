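"""AZF deletion classification from gene dosages or explicit intervals.

Classical complete deletions are recognized by the two-genes-per-region
rule: a region is deleted only when BOTH of its marker genes are completely
lost (AZFa: USP9Y+DDX3Y, AZFb: EIF1AY+RPS4Y2, AZFc: BPY2+DAZ families).
Partial deletions such as gr/gr or b2/b3 spare some family copies, leave an
intermediate family dosage and are flagged as suspected only -- never as a
classical deletion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import math

from .depthcnv import CallerConfig, DosageProfile, gene_dosage
from .refmodel import TargetInterval, region_rules

__all__ = [
    "AzfClass",
    "AzfClassification",
    "classify_azf",
    "classify_profile",
    "classify_from_interval",
    "azf_batch_classify",
]


class AzfClass:
    """Classification labels (string constants)."""

    NONE = "none"
    AZFA = "AZFa"
    AZFB = "AZFb_P5_proxP1"
    AZFBC = "AZFbc_P5_distP1"
    AZFC = "AZFc_b2b4"
    AZFBC_TERMINAL = "AZFbc_terminal"
    PARTIAL = "partial_suspected"
    DUPLICATION = "AZFbc_duplication"
    INDETERMINATE = "indeterminate"

    ALL = (NONE, AZFA, AZFB, AZFBC, AZFC, AZFBC_TERMINAL, PARTIAL,
           DUPLICATION, INDETERMINATE)


# genes whose loss is expected under each classical class; anything beyond
# is an atypical-breakpoint annotation (e.g. PRY loss with an AZFc deletion)
_RULE_GENES = ("USP9Y", "DDX3Y", "EIF1AY", "RPS4Y2", "BPY2", "DAZ")
_FAMILY_BASELINES = {"BPY2": 3, "DAZ": 4}


@dataclass
class AzfClassification:
    """Result of AZF rule evaluation."""

    azf_class: str
    evidence: dict[str, str] = field(default_factory=dict)
    terminal: bool = False
    subtype: str | None = None        # gr/gr-like, b2/b3-like, unspecified
    low_confidence: bool = False
    notes: list[str] = field(default_factory=list)
    missing_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.azf_class not in AzfClass.ALL:
            raise ValueError(f"unknown AZF class {self.azf_class!r}")
        if self.azf_class not in (AzfClass.NONE, AzfClass.INDETERMINATE) \
                and not self.evidence:
            raise ValueError("non-none classification requires evidence")


def _status(dosage: float, baseline: float, config: CallerConfig) -> str:
    """'lost' / 'present' / 'reduced' / 'indeterminate' for one rule gene."""
    if math.isnan(dosage):
        return "missing"
    if baseline <= 1:
        if dosage < config.absent_below:
            return "lost"
        if dosage >= config.present_at_least:
            return "present"
        return "indeterminate"
    # family: dosage in copies of the family baseline
    if dosage < config.family_absent_below:
        return "lost"
    if dosage <= baseline - config.family_reduced_margin:
        return "reduced"
    if dosage >= 2 * baseline - config.family_reduced_margin:
        return "gained"
    return "present"


def classify_azf(dosages: dict[str, float],
                 terminal: bool | None = None,
                 config: CallerConfig | None = None) -> AzfClassification:
    """Apply the two-genes-per-region rule to a gene-dosage map.

    ``dosages`` maps the six rule genes (and optionally extension genes
    such as PRY, KDM5D, HSFY, RBMY) to copy-unit dosages; families are in
    copies of their family baseline (DAZ of 4, BPY2 of 3).  ``terminal``
    marks a loss that extends through the last enriched Yq target.
    """
    config = config or CallerConfig()
    missing = [g for g in _RULE_GENES if g not in dosages
               or math.isnan(dosages[g])]
    if missing:
        return AzfClassification(AzfClass.INDETERMINATE,
                                 missing_genes=missing,
                                 notes=[f"missing dosage for {g}"
                                        for g in missing])

    status = {g: _status(dosages[g], _FAMILY_BASELINES.get(g, 1), config)
              for g in dosages}
    evidence = {g: status[g] for g in _RULE_GENES}

    deleted = {}
    for rule in region_rules():
        g1, g2 = rule.required_genes
        deleted[rule.region] = status[g1] == "lost" and status[g2] == "lost"

    gained = (status.get("EIF1AY") == "gained" or dosages["EIF1AY"] >= 2 - config.family_reduced_margin / 2) and \
             (status["BPY2"] == "gained" and status["DAZ"] == "gained")

    notes: list[str] = []
    extra_lost = sorted(g for g in status
                        if g not in _RULE_GENES and status[g] == "lost")
    if extra_lost:
        notes.append("additional gene loss: " + ", ".join(extra_lost))

    if gained and not any(deleted.values()):
        ev = {g: status[g] for g in ("EIF1AY", "RPS4Y2", "BPY2", "DAZ")}
        return AzfClassification(AzfClass.DUPLICATION, evidence=ev,
                                 notes=notes)

    if deleted["AZFb"] and deleted["AZFc"]:
        cls = AzfClass.AZFBC_TERMINAL if terminal else AzfClass.AZFBC
        if deleted["AZFa"]:
            notes.append("AZFa also completely lost (whole-Yq loss)")
        return AzfClassification(cls, evidence=evidence,
                                 terminal=bool(terminal), notes=notes)
    if deleted["AZFb"]:
        if deleted["AZFa"]:
            notes.append("AZFa also completely lost")
        return AzfClassification(AzfClass.AZFB, evidence=evidence,
                                 terminal=bool(terminal), notes=notes)
    if deleted["AZFc"]:
        if deleted["AZFa"]:
            notes.append("AZFa also completely lost")
        return AzfClassification(AzfClass.AZFC, evidence=evidence,
                                 terminal=bool(terminal), notes=notes)
    if deleted["AZFa"]:
        return AzfClassification(AzfClass.AZFA, evidence=evidence,
                                 terminal=bool(terminal), notes=notes)

    # no classical deletion: look for partial/suspect patterns
    reduced_families = [g for g in ("DAZ", "BPY2")
                        if status[g] in ("reduced", "lost")]
    odd_singles = [g for g in _RULE_GENES
                   if _FAMILY_BASELINES.get(g) is None
                   and status[g] in ("lost", "indeterminate")]
    if reduced_families or odd_singles:
        subtype = "unspecified"
        if status["DAZ"] in ("reduced", "lost") and status["BPY2"] == "present":
            subtype = "gr/gr-or-b2/b3-like"
        return AzfClassification(
            AzfClass.PARTIAL, evidence=evidence, subtype=subtype,
            low_confidence=True,
            notes=notes + ["partial/atypical pattern; suspected, not validated"])
    return AzfClassification(AzfClass.NONE, notes=notes)


def classify_profile(profile: DosageProfile,
                     config: CallerConfig | None = None) -> AzfClassification:
    """Classify a normalized dosage profile.

    Gene dosages are taken per rule gene/family; the terminal flag comes
    from the dosage of the most distal enriched Yq target.
    """
    config = config or CallerConfig()
    dosages = {}
    for gene in _RULE_GENES + ("PRY", "KDM5D", "HSFY", "RBMY"):
        gd = gene_dosage(profile, gene)
        if gd.n_targets:
            dosages[gene] = gd.estimate
        elif gene in _RULE_GENES:
            dosages[gene] = float("nan")
    ytargets = sorted(profile.targets_on("chrY"), key=lambda t: t.start)
    terminal = False
    if ytargets:
        last = ytargets[-1]
        terminal = profile.relative(last) < config.absent_below
    return classify_azf(dosages, terminal=terminal, config=config)


def classify_from_interval(intervals: list[tuple[int, int]],
                           targets: list[TargetInterval],
                           config: CallerConfig | None = None,
                           chrom: str = "chrY") -> AzfClassification:
    """Classify explicit ×0 deletion interval(s) (0-based half-open).

    A gene counts as lost only when ALL of its targets -- for a family, the
    targets of all copies -- fall inside the union of deleted intervals.
    """
    if chrom != "chrY":
        raise ValueError("AZF interval classification requires chrY intervals")
    ytargets = [t for t in targets if t.chrom == "chrY"]
    if not ytargets:
        raise ValueError("target map has no chrY targets")

    def covered(t: TargetInterval) -> bool:
        return any(s <= t.start and t.end <= e for s, e in intervals)

    groups: dict[str, list[TargetInterval]] = {}
    for t in ytargets:
        key = t.family_id or t.gene
        if key is not None:
            groups.setdefault(key, []).append(t)

    dosages: dict[str, float] = {}
    for key, members in groups.items():
        baseline = members[0].baseline_copies
        if members[0].family_id is not None:
            # surviving copies: a copy survives unless all its targets are covered
            genes: dict[str, list[TargetInterval]] = {}
            for m in members:
                genes.setdefault(m.gene, []).append(m)
            surviving = sum(0 if all(covered(m) for m in ms) else 1
                            for ms in genes.values())
            dosages[key] = surviving * baseline / len(genes)
        else:
            dosages[key] = 0.0 if all(covered(m) for m in members) else float(baseline)
    last = max(ytargets, key=lambda t: t.end)
    terminal = covered(last)
    return classify_azf(dosages, terminal=terminal, config=config)


def azf_batch_classify(classifications: list[AzfClassification]) -> Counter:
    """Tally class labels over a cohort (empty cohort gives empty counts)."""
    return Counter(c.azf_class for c in classifications)
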