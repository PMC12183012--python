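"""Static GRCh37 reference model: enrichment targets, AZF regions, cytobands.

The model describes the portion of a clinical exome that matters for
male-infertility copy-number interpretation: chrY single-copy genes and
multicopy gene families (DAZ, BPY2, PRY, RBMY, HSFY), the AZFa/b/c region
annotation, a scaffold of chrX and autosomal targets used for dosage
normalization, and the CFTR exon targets of two enrichment-kit versions.

Short-read depth on the palindromic AZFb/AZFc sequence collapses the
near-identical family copies onto shared targets, so each family target
carries the *family total* baseline copy number (e.g. every DAZ target has
``baseline_copies == 4``).  Single-copy Y genes carry 1, chrX targets 1 (male
reference) and autosomal targets 2.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "TargetInterval",
    "RegionRule",
    "CytobandTable",
    "PanelDefinition",
    "TargetMapError",
    "CHRY_ENRICHMENT_GAP",
    "CHROM_ACCESSIONS",
    "AZF_REGIONS",
    "load_target_map",
    "write_target_map",
    "default_target_map",
    "region_rules",
    "load_cytobands",
    "default_cytobands",
    "band_for_interval",
    "load_panel_definition",
    "default_panel",
    "load_panel_genes",
    "cftr_enrichment",
]

#: chrY interval (GRCh37, 0-based half-open) with no exome enrichment; the
#: region spans the centromere, so a gain/loss transition falling inside it
#: cannot be localised from depth data (iso(Yp) vs idic(Yq) ambiguity).
CHRY_ENRICHMENT_GAP = (9368285, 14517915)

#: RefSeq chromosome accessions for GRCh37, for HGVS-style nomenclature.
CHROM_ACCESSIONS = {
    "chr1": "NC_000001.10",
    "chr2": "NC_000002.11",
    "chr4": "NC_000004.11",
    "chr7": "NC_000007.13",
    "chr9": "NC_000009.11",
    "chr12": "NC_000012.11",
    "chr15": "NC_000015.9",
    "chr19": "NC_000019.9",
    "chrX": "NC_000023.10",
    "chrY": "NC_000024.9",
}

AZF_REGIONS = ("AZFa", "AZFb", "AZFc")

_CHROM_ORDER = {c: i for i, c in enumerate(
    [f"chr{n}" for n in range(1, 23)] + ["chrX", "chrY"])}


class TargetMapError(ValueError):
    """Raised for malformed or inconsistent target-map input."""


@dataclass(frozen=True)
class TargetInterval:
    """One enrichment target with gene/family/region annotation.

    Coordinates are GRCh37, 0-based half-open.  ``baseline_copies`` is the
    copy count in a reference 46,XY genome; for a multicopy-family target it
    is the family total (collapsed mapping).
    """

    chrom: str
    start: int
    end: int
    target_id: str
    gene: str | None = None
    family_id: str | None = None
    baseline_copies: int = 2
    azf_region: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise TargetMapError(
                f"target {self.target_id}: start must be < end "
                f"({self.start} >= {self.end})")
        if self.baseline_copies < 1:
            raise TargetMapError(
                f"target {self.target_id}: baseline_copies must be >= 1")
        if self.azf_region is not None and self.azf_region not in AZF_REGIONS:
            raise TargetMapError(
                f"target {self.target_id}: unknown AZF region "
                f"{self.azf_region!r}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class RegionRule:
    """The two genes whose complete loss defines a region's classical deletion."""

    region: str
    required_genes: tuple[str, str]


_REGION_RULES = (
    RegionRule("AZFa", ("USP9Y", "DDX3Y")),
    RegionRule("AZFb", ("EIF1AY", "RPS4Y2")),
    RegionRule("AZFc", ("BPY2", "DAZ")),
)


def region_rules() -> tuple[RegionRule, ...]:
    """Two-genes-per-region rules for classical AZF deletion detection.

    AZFa requires complete loss of USP9Y and DDX3Y, AZFb of EIF1AY and
    RPS4Y2, AZFc of the BPY2 and DAZ families.  Partial deletions (gr/gr,
    b2/b3) spare some family copies and therefore never satisfy a rule.
    """
    return _REGION_RULES


# ---------------------------------------------------------------------------
# target map I/O

_COLUMNS = ("chrom", "start", "end", "target_id", "gene", "family_id",
            "baseline_copies", "azf_region")


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("exomy").joinpath("data", name))


def load_target_map(path: str | Path | None = None) -> list[TargetInterval]:
    """Read a BED-like 8-column target map; defaults to the bundled GRCh37 map.

    Returns targets sorted by (chrom, start).  Raises :class:`TargetMapError`
    naming the offending line for malformed rows, duplicate target ids and
    overlapping targets that share an id; warns if a target lies inside the
    chrY enrichment gap.
    """
    path = _data_path("targets_grch37.tsv") if path is None else Path(path)
    targets: list[TargetInterval] = []
    seen_ids: dict[str, TargetInterval] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise TargetMapError(f"{path}: empty target map")
        if tuple(header.rstrip("\n").split("\t")) != _COLUMNS:
            raise TargetMapError(f"{path}: line 1: bad header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_COLUMNS):
                raise TargetMapError(
                    f"{path}: line {lineno}: expected {len(_COLUMNS)} "
                    f"columns, got {len(fields)}")
            chrom, start, end, tid, gene, family, copies, region = fields
            try:
                t = TargetInterval(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    target_id=tid,
                    gene=None if gene == "." else gene,
                    family_id=None if family == "." else family,
                    baseline_copies=int(copies),
                    azf_region=None if region == "." else region,
                )
            except (ValueError, TargetMapError) as exc:
                raise TargetMapError(f"{path}: line {lineno}: {exc}") from exc
            prev = seen_ids.get(tid)
            if prev is not None:
                if prev.overlaps(t.start, t.end) and prev.chrom == t.chrom:
                    raise TargetMapError(
                        f"{path}: line {lineno}: overlapping targets share "
                        f"id {tid!r}")
                raise TargetMapError(
                    f"{path}: line {lineno}: duplicate target id {tid!r}")
            seen_ids[tid] = t
            if t.chrom == "chrY" and t.overlaps(*CHRY_ENRICHMENT_GAP):
                warnings.warn(
                    f"target {tid} lies in the unenriched chrY region "
                    f"{CHRY_ENRICHMENT_GAP[0]}-{CHRY_ENRICHMENT_GAP[1]}; "
                    "depth there is not interpretable",
                    stacklevel=2)
            targets.append(t)
    if not targets:
        raise TargetMapError(f"{path}: empty target map")
    targets.sort(key=lambda t: (_CHROM_ORDER.get(t.chrom, 99), t.chrom,
                                t.start, t.end))
    return targets


def write_target_map(targets: list[TargetInterval], path: str | Path) -> None:
    """Write a target map in the same 8-column format ``load_target_map`` reads."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for t in targets:
            fh.write("\t".join([
                t.chrom, str(t.start), str(t.end), t.target_id,
                t.gene or ".", t.family_id or ".",
                str(t.baseline_copies), t.azf_region or ".",
            ]) + "\n")


_DEFAULT_MAP: list[TargetInterval] | None = None


def default_target_map() -> list[TargetInterval]:
    """The bundled GRCh37 target map (cached)."""
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = load_target_map()
    return list(_DEFAULT_MAP)


# ---------------------------------------------------------------------------
# cytobands

@dataclass
class CytobandTable:
    """Per-chromosome ordered cytogenetic bands (UCSC cytoBand format)."""

    bands: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def chromosome_length(self, chrom: str) -> int:
        if chrom not in self.bands:
            raise KeyError(f"no cytobands for {chrom}")
        return self.bands[chrom][-1][2]

    def band_at(self, chrom: str, pos: int) -> str:
        if chrom not in self.bands:
            raise KeyError(f"no cytobands for {chrom}")
        table = self.bands[chrom]
        for name, start, end in table:
            if start <= pos < end:
                return name
        # positions exactly at the chromosome end belong to the last band
        if pos == table[-1][2]:
            return table[-1][0]
        raise ValueError(f"{chrom}:{pos} outside chromosome bounds")


def load_cytobands(path: str | Path | None = None) -> CytobandTable:
    """Read a UCSC-format cytoBand file (defaults to the bundled chrX/chrY table)."""
    path = _data_path("cytoband_grch37.txt") if path is None else Path(path)
    table = CytobandTable()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name = line.split("\t")[:4]
            table.bands.setdefault(chrom, []).append(
                (name, int(start), int(end)))
    for chrom, bands in table.bands.items():
        bands.sort(key=lambda b: b[1])
        for (n1, _, e1), (n2, s2, _) in zip(bands, bands[1:]):
            if e1 != s2:
                raise TargetMapError(
                    f"cytobands do not tile {chrom}: {n1} ends at {e1}, "
                    f"{n2} starts at {s2}")
    return table


_DEFAULT_BANDS: CytobandTable | None = None


def default_cytobands() -> CytobandTable:
    global _DEFAULT_BANDS
    if _DEFAULT_BANDS is None:
        _DEFAULT_BANDS = load_cytobands()
    return _DEFAULT_BANDS


def band_for_interval(chrom: str, start: int, end: int,
                      cytobands: CytobandTable | None = None) -> str:
    """Band-range string for an interval, e.g. ``"Yq11.223q11.23"``.

    ``start``/``end`` are 1-based inclusive coordinates as used in emitted
    nomenclature.  An interval inside a single band prints that band once.
    """
    cytobands = cytobands or default_cytobands()
    if start > end:
        raise ValueError("interval start must be <= end")
    first = cytobands.band_at(chrom, start - 1)
    last = cytobands.band_at(chrom, end - 1)
    letter = chrom.removeprefix("chr")
    if first == last:
        return f"{letter}{first}"
    return f"{letter}{first}{last}"


# ---------------------------------------------------------------------------
# CFTR screening panel

def _normalize_hgvs(text: str) -> str:
    """Case/whitespace/unicode-dash normalization for HGVS c. strings."""
    text = text.strip().replace(" ", "")
    for dash in ("‐", "‑", "‒", "–", "—", "−"):
        text = text.replace(dash, "-")
    # keep case of nucleotides meaningful only at the substitution letters;
    # comparisons use an upper-cased key with the leading "c." kept lower.
    if text.lower().startswith("c."):
        return "c." + text[2:].upper()
    return text.upper()


@dataclass
class PanelDefinition:
    """A targeted CFTR screening assay: kit name plus member variants."""

    kit: str
    transcript: str
    variants: list[dict]

    def __post_init__(self) -> None:
        self._by_cdna = {_normalize_hgvs(v["cdna"]): v for v in self.variants}

    def lookup(self, cdna: str) -> dict | None:
        if not cdna or not cdna.strip():
            raise ValueError("empty cDNA HGVS string")
        return self._by_cdna.get(_normalize_hgvs(cdna))

    def is_member(self, cdna: str) -> bool:
        entry = self.lookup(cdna)
        return bool(entry and entry.get("in_kit"))


def load_panel_definition(path: str | Path | None = None) -> PanelDefinition:
    """Read a panel definition JSON (defaults to the bundled CF-EU2v1 file)."""
    import json

    path = _data_path("cftr_panel.json") if path is None else Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    return PanelDefinition(kit=raw["kit"], transcript=raw["transcript"],
                           variants=raw["variants"])


_DEFAULT_PANEL: PanelDefinition | None = None


def default_panel() -> PanelDefinition:
    global _DEFAULT_PANEL
    if _DEFAULT_PANEL is None:
        _DEFAULT_PANEL = load_panel_definition()
    return _DEFAULT_PANEL


def load_panel_genes(path: str | Path | None = None) -> list[str]:
    """The male-infertility gene panel as a list of unique gene symbols."""
    path = _data_path("infertility_panel_genes.txt") if path is None else Path(path)
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise TargetMapError(f"duplicate panel genes: {dupes}")
    return genes


def cftr_enrichment(version: str,
                    targets: list[TargetInterval] | None = None
                    ) -> list[tuple[int, int]]:
    """CFTR enrichment intervals for a kit version (``"v1"`` or ``"v2"``).

    v2 is the bundled target set; v1 is the same set minus the two
    deep-intronic spike-in targets, which only the updated kit covers.
    """
    targets = targets if targets is not None else default_target_map()
    cftr = [t for t in targets if t.gene == "CFTR"]
    if version == "v2":
        keep = cftr
    elif version == "v1":
        keep = [t for t in cftr if "spike" not in t.target_id]
    else:
        raise ValueError(f"unknown enrichment version {version!r}")
    return [(t.start, t.end) for t in keep]
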