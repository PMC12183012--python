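"""Reference-cohort depth normalization, dosage estimation and Y segmentation.

The caller is deliberately transparent: a median-of-ratios normalization
against a reference cohort followed by explicit copy-state thresholds.

Per-target dosage is expressed in *copy units of the 46,XY baseline*:

    dosage_t = baseline_copies_t * (d_t / m_sample) / median_ref(d_t / m_ref)

where ``m`` is the sample's autosomal median depth.  Ratios are finally
rescaled so the autosomal median dosage is exactly 2.  A single-copy Y gene
in a normal male therefore reads ~1, a DAZ-family target ~4, and mosaic
states appear as fractional dosages (e.g. 0.7 for a 30% Y loss).

Copy-state thresholds (single-copy genes, baseline 1): absent below 0.25,
present at or above 0.6, in between indeterminate / possible mosaic.  A
multicopy family is completely lost only below 0.5 total copies, so a gr/gr
deletion (2 of 4 DAZ copies surviving) is never read as a complete loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .refmodel import TargetInterval

logger = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "DosageProfile",
    "GeneDosage",
    "CnvCall",
    "MosaicEstimate",
    "normalize",
    "gene_dosage",
    "segment_y",
    "estimate_mosaic_fraction",
]


@dataclass(frozen=True)
class CallerConfig:
    """Copy-state thresholds, all in copy units."""

    absent_below: float = 0.25       # single-copy gene called absent
    present_at_least: float = 0.6    # single-copy gene called present
    family_absent_below: float = 0.5   # multicopy family complete loss
    family_reduced_margin: float = 0.8  # family partial loss: below baseline-margin
    snap_tol: float = 0.15           # |dosage - integer| within -> that integer
    min_mosaic_targets: int = 10     # fractional states need a sustained run
    smooth_window: int = 7           # running-median window for segmentation
    min_reference: int = 10
    min_nonzero_fraction: float = 0.9


@dataclass
class GeneDosage:
    """Robust per-gene/family dosage in copy units of its baseline."""

    name: str
    estimate: float
    spread: float
    n_targets: int
    baseline: int


@dataclass
class DosageProfile:
    """Normalized per-target copy dosages for one sample."""

    sample_id: str
    targets: list[TargetInterval]
    dosages: dict[str, float]
    masked: set[str] = field(default_factory=set)

    def dosage(self, target_id: str) -> float:
        return self.dosages[target_id]

    def targets_on(self, chrom: str) -> list[TargetInterval]:
        return [t for t in self.targets
                if t.chrom == chrom and t.target_id not in self.masked]

    def relative(self, t: TargetInterval) -> float:
        """Dosage divided by baseline: 1.0 means the normal 46,XY state."""
        return self.dosages[t.target_id] / t.baseline_copies


@dataclass
class CnvCall:
    """A copy-state segment with inner/outer breakpoint-uncertainty bounds.

    ``inner`` spans first-to-last aberrant target (0-based half-open);
    ``outer`` extends to the nearest retained flanking targets, or the
    chromosome ends when none remain (matching the printed
    ``(a_b)_(c_d)`` convention).
    """

    chrom: str
    inner: tuple[int, int]
    outer: tuple[int, int]
    copy_state: float
    direction: str               # "loss" | "gain"
    terminal: bool = False

    def __post_init__(self) -> None:
        if not (self.outer[0] <= self.inner[0]
                and self.inner[1] <= self.outer[1]):
            raise ValueError("outer interval must contain inner interval")
        if self.copy_state < 0:
            raise ValueError("copy state must be >= 0")


def normalize(sample, reference, targets: list[TargetInterval],
              config: CallerConfig | None = None) -> DosageProfile:
    """Median-of-ratios normalization of one sample against a reference cohort.

    Requires at least ``config.min_reference`` reference samples and a
    nonzero reference median for at least 90% of targets; individual
    zero-median targets are masked and logged.
    """
    config = config or CallerConfig()
    if len(reference) < config.min_reference:
        raise ValueError(
            f"reference cohort too small: {len(reference)} < "
            f"{config.min_reference}")
    ids = [t.target_id for t in targets]
    auto_idx = np.array([t.chrom not in ("chrX", "chrY") for t in targets])
    if auto_idx.sum() < 10:
        raise ValueError("target map has too few autosomal targets")

    def stat(depths: np.ndarray) -> np.ndarray:
        med = np.median(depths[auto_idx])
        if med <= 0:
            raise ValueError("autosomal median depth is zero")
        return depths / med

    sample_depths = np.array([sample.depths[i] for i in ids], dtype=float)
    ref_stats = np.vstack([stat(np.array([r.depths[i] for i in ids],
                                         dtype=float)) for r in reference])
    ref_median = np.median(ref_stats, axis=0)
    nonzero = ref_median > 0
    if nonzero.mean() < config.min_nonzero_fraction:
        raise ValueError(
            f"only {nonzero.mean():.0%} of targets have nonzero reference "
            "median; reference cohort unusable")
    masked = {i for i, ok in zip(ids, nonzero) if not ok}
    for tid in sorted(masked):
        logger.warning("target %s masked: zero reference median", tid)

    ratio = np.full(len(ids), np.nan)
    ratio[nonzero] = stat(sample_depths)[nonzero] / ref_median[nonzero]
    auto_ratio = np.median(ratio[auto_idx & nonzero])
    if auto_ratio <= 0:
        raise ValueError("sample autosomal dosage collapsed to zero")
    ratio = ratio / auto_ratio
    baselines = np.array([t.baseline_copies for t in targets], dtype=float)
    dosages = baselines * ratio
    return DosageProfile(
        sample_id=sample.sample_id,
        targets=list(targets),
        dosages={i: float(d) for i, d, ok in zip(ids, dosages, nonzero) if ok},
        masked=masked,
    )


def gene_dosage(profile: DosageProfile, name: str) -> GeneDosage:
    """Median dosage over the member targets of a gene or family.

    ``name`` matches ``gene`` or ``family_id``; the estimate is in copy
    units of the member targets' baseline.  All-masked genes return a
    missing-dosage sentinel (NaN estimate, ``n_targets == 0``).
    """
    members = [t for t in profile.targets
               if (t.gene == name or t.family_id == name)
               and t.target_id not in profile.masked]
    if not members:
        sentinel = GeneDosage(name, math.nan, math.nan, 0, 0)
        return sentinel
    vals = np.array([profile.dosages[t.target_id] for t in members])
    est = float(np.median(vals))
    # scaled MAD as a robust spread; 0 for a single target
    spread = float(1.4826 * np.median(np.abs(vals - est))) if len(vals) > 1 else 0.0
    return GeneDosage(name, est, spread, len(members),
                      members[0].baseline_copies)


def _called_state(relative: float, config: CallerConfig) -> float:
    """Per-target relative copy state (1.0 = normal 46,XY dosage).

    Snaps to the nearest integer state when within ``snap_tol``; otherwise
    returns the fractional value rounded to 0.1 (possible mosaic).  Boundary
    values go to the nearest expected dosage, deterministically.
    """
    nearest = round(relative)
    # depth noise scales with the copy state, so the snap window does too
    if abs(relative - nearest) <= config.snap_tol * max(nearest, 1):
        return float(max(nearest, 0))
    return round(max(relative, 0.0), 1)


def segment_y(profile: DosageProfile,
              config: CallerConfig | None = None,
              use_gene_dosage: bool = True) -> list[CnvCall]:
    """Merge chrY targets into maximal same-copy-state segments.

    Targets inherit their gene's (or family's) robust dosage when
    ``use_gene_dosage`` is set, which keeps single noisy targets from
    fragmenting a segment.  Normal profiles return an empty list.
    """
    config = config or CallerConfig()
    ytargets = sorted(profile.targets_on("chrY"), key=lambda t: t.start)
    if not ytargets:
        return []
    gene_cache: dict[str, GeneDosage] = {}
    states = []
    for t in ytargets:
        key = t.family_id or t.gene
        if use_gene_dosage and key is not None:
            gd = gene_cache.get(key)
            if gd is None:
                gd = gene_dosage(profile, key)
                gene_cache[key] = gd
            rel = gd.estimate / gd.baseline
        else:
            rel = profile.relative(t)
        states.append(rel)
    # running median across adjacent targets: a single noisy gene must not
    # fragment a segment; boundaries stay exact for runs of >= half a window
    half = max(config.smooth_window // 2, 0)
    n_st = len(states)
    smoothed = []
    for k in range(n_st):
        h = min(half, k, n_st - 1 - k)   # symmetric truncation at the ends
        smoothed.append(float(np.median(states[k - h:k + h + 1])))
    states = [_called_state(rel, config) for rel in smoothed]

    def same_run(a: float, b: float) -> bool:
        if float(a).is_integer() or float(b).is_integer():
            return a == b
        return abs(a - b) <= 0.2   # adjacent mosaic wobble merges

    # raw maximal runs over all chrY targets (state 1.0 runs included)
    runs: list[list] = []          # [first_idx, last_idx, state]
    for k, s in enumerate(states):
        if runs and same_run(runs[-1][2], s):
            runs[-1][1] = k
        else:
            runs.append([k, k, s])

    def coalesce() -> None:
        k = 1
        while k < len(runs):
            if runs[k][2] == runs[k - 1][2]:
                runs[k - 1][1] = runs[k][1]
                del runs[k]
            else:
                k += 1

    # a short intermediate-dosage run is noise, not mosaicism: reassign it
    # to the neighboring state nearest its value (proximal on ties)
    changed = True
    while changed:
        changed = False
        for k, run in enumerate(runs):
            length = run[1] - run[0] + 1
            if float(run[2]).is_integer() \
                    or length >= config.min_mosaic_targets:
                continue
            candidates = [1.0]     # the normal state is always an option
            if k > 0:
                candidates.append(runs[k - 1][2])
            if k + 1 < len(runs):
                candidates.append(runs[k + 1][2])
            run[2] = min(candidates, key=lambda s: abs(s - run[2]))
            changed = True
        if changed:
            coalesce()

    calls: list[CnvCall] = []
    n = len(ytargets)
    for first, last, state in runs:
        if state == 1.0:
            continue
        inner = (ytargets[first].start, ytargets[last].end)
        outer_start = ytargets[first - 1].end if first > 0 else 0
        terminal = last == n - 1
        outer_end = ytargets[last + 1].start if not terminal else None
        calls.append(CnvCall(
            chrom="chrY",
            inner=inner,
            outer=(outer_start, outer_end if outer_end is not None
                   else _chrom_end("chrY")),
            copy_state=state,
            direction="loss" if state < 1.0 else "gain",
            terminal=terminal,
        ))
    return calls


def _chrom_end(chrom: str) -> int:
    from .refmodel import default_cytobands
    return default_cytobands().chromosome_length(chrom)


def write_calls_bed(calls: list[CnvCall], path) -> None:
    """Export call inner intervals as BED (name = direction/state)."""
    with open(path, "w") as fh:
        for c in calls:
            name = f"{c.direction}_x{c.copy_state:g}"
            fh.write(f"{c.chrom}\t{c.inner[0]}\t{c.inner[1]}\t{name}\n")


def write_calls_json(calls: list[CnvCall], path) -> None:
    """Export calls with full breakpoint uncertainty as JSON."""
    import json

    records = [{
        "chrom": c.chrom, "inner": list(c.inner), "outer": list(c.outer),
        "copy_state": c.copy_state, "direction": c.direction,
        "terminal": c.terminal,
    } for c in calls]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


@dataclass
class MosaicEstimate:
    fraction: float
    interval: tuple[float, float]


def estimate_mosaic_fraction(dosage: float, baseline: float,
                             direction: str, gain_copies: int = 1,
                             spread: float = 0.0,
                             n_targets: int = 1) -> MosaicEstimate:
    """Mosaic fraction from an intermediate dosage.

    Loss of a ``baseline``-copy state: ``f = 1 - dosage/baseline``.  Gain
    from ``baseline`` to ``baseline + gain_copies``:
    ``f = (dosage - baseline)/gain_copies``.  Both clamped to [0, 1]; the
    interval propagates the dosage spread (~95% normal interval of the
    median).
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if dosage < 0:
        raise ValueError("dosage must be >= 0")
    if direction == "loss":
        f = 1.0 - dosage / baseline
        scale = baseline
    elif direction == "gain":
        if gain_copies < 1:
            raise ValueError("gain_copies must be >= 1")
        f = (dosage - baseline) / gain_copies
        scale = float(gain_copies)
    else:
        raise ValueError(f"direction must be 'loss' or 'gain', got {direction!r}")
    f = min(max(f, 0.0), 1.0)
    se = 1.2533 * spread / (scale * math.sqrt(max(n_targets, 1)))
    lo = min(max(f - 1.96 * se, 0.0), 1.0)
    hi = min(max(f + 1.96 * se, 0.0), 1.0)
    return MosaicEstimate(fraction=f, interval=(lo, hi))
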