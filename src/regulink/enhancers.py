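"""Enhancer-class assignment and SE-to-gene mapping.

Enhancer taxonomy (mutually exclusive, in precedence order):

* ``super`` — region overlaps a supplied super-enhancer catalogue; a published
  SE list always overrides local mark logic.
* ``active`` — H3K27ac present.
* ``poised`` — H3K27me3 together with H3K4me1, without H3K27ac.
* ``intermediate`` — H3K4me1 alone.
* ``unclassified`` — none of the above.

The exact mark convention for "intermediate" enhancers is a documented design
choice (see docs/methods.md), not a settled community standard.

``stitch_and_rank`` is a ROSE-style convenience for users without a published
SE list: candidate peaks are stitched within a distance, stitched regions are
ranked by total signal, and the cutoff is the ranked-curve point where a line
of slope ``(max - min) / n`` is tangent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    PeakSet,
    ValidationError,
    merge_intervals,
    overlap_flags,
)

__all__ = [
    "ENHANCER_CLASSES",
    "EnhancerClassCall",
    "SEGeneAssignment",
    "StitchResult",
    "classify_enhancers",
    "assign_se_genes",
    "stitch_and_rank",
    "write_class_bed",
]

ENHANCER_CLASSES = ("super", "active", "intermediate", "poised", "unclassified")


@dataclass(frozen=True)
class EnhancerClassCall:
    region: GenomicInterval
    enh_class: str


@dataclass(frozen=True)
class SEGeneAssignment:
    """Nearest-TSS assignment of a super-enhancer to a gene."""

    se: GenomicInterval
    gene_id: str
    distance: int  # bp from the SE boundary to the TSS; 0 if the TSS is inside
    tie: bool


@dataclass
class StitchResult:
    se_list: PeakSet
    te_list: PeakSet
    cutoff_signal: float
    degenerate: bool  # all stitched regions had equal signal; no SEs callable


def classify_enhancers(
    regions: PeakSet,
    se_list: PeakSet,
    k27ac: PeakSet,
    k4me1: PeakSet,
    k27me3: PeakSet,
) -> tuple[list[EnhancerClassCall], dict[str, int]]:
    """Assign each region exactly one enhancer class (precedence as documented)."""
    in_se = overlap_flags(regions, se_list) if len(se_list) else np.zeros(len(regions), bool)
    in_ac = overlap_flags(regions, k27ac)
    in_me1 = overlap_flags(regions, k4me1)
    in_me3 = overlap_flags(regions, k27me3)
    calls = []
    counts = {c: 0 for c in ENHANCER_CLASSES}
    for i, iv in enumerate(regions):
        if in_se[i]:
            cls = "super"
        elif in_ac[i]:
            cls = "active"
        elif in_me3[i] and in_me1[i]:
            cls = "poised"
        elif in_me1[i]:
            cls = "intermediate"
        else:
            cls = "unclassified"
        counts[cls] += 1
        calls.append(EnhancerClassCall(iv, cls))
    return calls, counts


def _tss_distance(tss: int, start: int, end: int) -> int:
    """Base distance from a TSS to an interval: 0 when covered, else gap to the
    nearest covered base (symmetric on both sides)."""
    if start <= tss < end:
        return 0
    if tss < start:
        return start - tss
    return tss - (end - 1)


def assign_se_genes(
    se_list: PeakSet,
    genes: Sequence[GeneModel],
    max_distance: int = 100_000,
) -> dict[str, SEGeneAssignment]:
    """Map each SE to the gene with the nearest TSS, keyed by SE name.

    SEs whose nearest TSS exceeds ``max_distance`` are omitted.  Equidistant
    genes are broken toward the lexicographically smaller gene_id and flagged.
    """
    if not genes:
        raise ValidationError("assign_se_genes requires a nonempty gene collection")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, SEGeneAssignment] = {}
    for idx, se in enumerate(se_list):
        candidates = by_chrom.get(se.chrom, [])
        if not candidates:
            continue
        best: list[GeneModel] = []
        best_d: int | None = None
        for g in candidates:
            d = _tss_distance(g.tss, se.start, se.end)
            if best_d is None or d < best_d:
                best, best_d = [g], d
            elif d == best_d:
                best.append(g)
        assert best_d is not None
        if best_d > max_distance:
            continue
        winner = min(best, key=lambda g: g.gene_id)
        key = se.name if se.name != "." else f"se_{idx}"
        out[key] = SEGeneAssignment(se=se, gene_id=winner.gene_id,
                                    distance=best_d, tie=len(best) > 1)
    return out


def stitch_and_rank(
    candidate_peaks: PeakSet,
    track: CoverageTrack,
    stitch_distance: int = 12_500,
    tss_exclude: PeakSet | None = None,
) -> StitchResult:
    """Stitch candidate peaks, rank stitched regions by signal, split SE vs TE.

    Candidates overlapping ``tss_exclude`` are dropped before stitching.  The
    signal cutoff is ``y[i*]`` at the rank ``i*`` maximizing ``m*i - y[i]`` on
    the ascending signal curve, with ``m = (max - min) / n`` — the tangent
    point of a line of that slope.  Regions with signal strictly above the
    cutoff are called SEs.  With all-equal signals the split degenerates to
    zero SEs and is flagged.
    """
    peaks = candidate_peaks
    if tss_exclude is not None and len(tss_exclude):
        keep = ~overlap_flags(peaks, tss_exclude)
        peaks = peaks.subset(np.nonzero(keep)[0])
    stitched = merge_intervals(peaks, gap=stitch_distance, label="stitched")
    n = len(stitched)
    if n < 3:
        raise ValidationError(
            f"only {n} stitched regions; the ranked-curve cutoff needs >= 3"
        )
    signals = np.array(
        [track.sum_range(iv.chrom, iv.start, iv.end) for iv in stitched]
    )
    order = np.argsort(signals, kind="stable")
    y = signals[order]
    m = (y[-1] - y[0]) / n
    i_star = int(np.argmax(m * np.arange(n) - y))
    cutoff = float(y[i_star])
    degenerate = bool(y[-1] == y[0])
    is_se = signals > cutoff
    se_ivs, te_ivs = [], []
    for iv, sig, flag in zip(stitched, signals, is_se):
        scored = GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name,
                                 score=float(sig))
        (se_ivs if flag else te_ivs).append(scored)
    return StitchResult(
        se_list=PeakSet("SE", se_ivs),
        te_list=PeakSet("TE", te_ivs),
        cutoff_signal=cutoff,
        degenerate=degenerate,
    )


def write_class_bed(calls: Iterable[EnhancerClassCall], path: str | Path) -> None:
    """BED + class column for downstream tools."""
    with open(path, "w") as fh:
        for call in calls:
            iv = call.region
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{call.enh_class}\n")
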