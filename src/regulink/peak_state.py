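"""Chromatin-state classification of TF peaks and genomic-compartment annotation.

A peak's state is a pure function of its overlap with the active mark
(H3K4me3) and the repressive mark (H3K27me3): the active mark alone gives
``active_k4me3``, both marks give ``bivalent``, the repressive mark alone
gives ``repressive_k27me3``, and neither gives ``unmarked``.  Peaks are
separately annotated to genomic compartments (promoter / gene body /
intergenic) relative to a gene table, with promoters defined as a +-3 kb
window around the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .core import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    PeakSet,
    ValidationError,
    overlap_flags,
    overlap_pairs,
)

__all__ = [
    "STATES",
    "ChromatinStateCall",
    "StateSummary",
    "FeatureAnnotation",
    "FeatureSummary",
    "TargetMap",
    "promoter_regions",
    "classify_states",
    "annotate_features",
    "assign_target_genes",
    "write_state_table",
]

STATES = ("active_k4me3", "bivalent", "repressive_k27me3", "unmarked")
THREE_WAY_CATEGORIES = ("promoter", "gene_body", "intergenic")
COBIND_CATEGORIES = ("promoter", "other", "intergenic")
DEFAULT_PROMOTER_HALFWIDTH = 3000


@dataclass(frozen=True)
class ChromatinStateCall:
    peak: GenomicInterval
    state: str


@dataclass
class StateSummary:
    n: int
    counts: dict[str, int]
    fractions: dict[str, float]


@dataclass(frozen=True)
class FeatureAnnotation:
    peak: GenomicInterval
    category: str
    assigned_genes: tuple[str, ...]


@dataclass
class FeatureSummary:
    n: int
    scheme: str
    counts: dict[str, int]
    percentages: dict[str, float]


@dataclass
class TargetMap:
    """Bidirectional peak <-> target-gene mapping under the promoter-window rule."""

    peak_to_genes: dict[int, tuple[str, ...]]
    gene_to_peaks: dict[str, tuple[int, ...]]

    def target_genes(self) -> set[str]:
        return set(self.gene_to_peaks)


def promoter_regions(
    genes: Iterable[GeneModel],
    halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    sizes: ChromSizes | None = None,
) -> PeakSet:
    """One promoter window ``[tss - halfwidth, tss + halfwidth)`` per gene.

    Windows are clipped to chromosome bounds and carry the gene_id as name.
    """
    if halfwidth <= 0:
        raise ValidationError("halfwidth must be > 0")
    out = []
    for g in genes:
        start = max(0, g.tss - halfwidth)
        end = g.tss + halfwidth
        if sizes is not None and g.chrom in sizes:
            end = min(end, sizes[g.chrom])
        out.append(GenomicInterval(g.chrom, start, end, name=g.gene_id, strand=g.strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return PeakSet("promoters", out)


def classify_states(
    peaks: PeakSet,
    k4me3: PeakSet,
    k27me3: PeakSet,
    min_overlap_bp: int = 1,
) -> tuple[list[ChromatinStateCall], StateSummary]:
    """Classify every peak by overlap with the active and repressive marks."""
    f_act = overlap_flags(peaks, k4me3, min_overlap_bp=min_overlap_bp)
    f_rep = overlap_flags(peaks, k27me3, min_overlap_bp=min_overlap_bp)
    calls = []
    counts = {s: 0 for s in STATES}
    for iv, a, r in zip(peaks, f_act, f_rep):
        if a and r:
            state = "bivalent"
        elif a:
            state = "active_k4me3"
        elif r:
            state = "repressive_k27me3"
        else:
            state = "unmarked"
        counts[state] += 1
        calls.append(ChromatinStateCall(iv, state))
    n = len(peaks)
    fractions = {s: (counts[s] / n if n else 0.0) for s in STATES}
    return calls, StateSummary(n=n, counts=counts, fractions=fractions)


def annotate_features(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    scheme: str = "three_way",
    halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    sizes: ChromSizes | None = None,
    min_overlap_bp: int = 1,
) -> tuple[list[FeatureAnnotation], FeatureSummary]:
    """Annotate each peak to a genomic compartment, promoter taking precedence.

    ``three_way`` labels are promoter / gene_body / intergenic; the ``cobind``
    scheme reports the same partition as promoter / other / intergenic (any
    genic, non-promoter overlap counts as "other").
    """
    if scheme == "three_way":
        categories = THREE_WAY_CATEGORIES
        genic_label = "gene_body"
    elif scheme == "cobind":
        categories = COBIND_CATEGORIES
        genic_label = "other"
    else:
        raise ValidationError(f"unknown annotation scheme {scheme!r}")

    promoters = promoter_regions(genes, halfwidth=halfwidth, sizes=sizes)
    bodies = PeakSet("gene_bodies", (g.span() for g in genes))
    in_prom = overlap_flags(peaks, promoters, min_overlap_bp=min_overlap_bp)
    in_body = overlap_flags(peaks, bodies, min_overlap_bp=min_overlap_bp)

    gene_hits: dict[int, list[str]] = {}
    for i, j, _ov in overlap_pairs(peaks, promoters, min_overlap_bp=min_overlap_bp):
        gene_hits.setdefault(i, []).append(promoters[j].name)

    annotations = []
    counts = {c: 0 for c in categories}
    for i, iv in enumerate(peaks):
        if in_prom[i]:
            category = "promoter"
            assigned = tuple(sorted(gene_hits.get(i, ())))
        elif in_body[i]:
            category = genic_label
            assigned = ()
        else:
            category = "intergenic"
            assigned = ()
        counts[category] += 1
        annotations.append(FeatureAnnotation(iv, category, assigned))
    n = len(peaks)
    percentages = {c: (100.0 * counts[c] / n if n else 0.0) for c in categories}
    return annotations, FeatureSummary(n=n, scheme=scheme, counts=counts,
                                       percentages=percentages)


def assign_target_genes(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    sizes: ChromSizes | None = None,
) -> TargetMap:
    """Gene g is a target of peak p iff g's promoter window overlaps p."""
    promoters = promoter_regions(genes, halfwidth=halfwidth, sizes=sizes)
    peak_to_genes: dict[int, list[str]] = {}
    gene_to_peaks: dict[str, list[int]] = {}
    for i, j, _ov in overlap_pairs(peaks, promoters):
        gid = promoters[j].name
        peak_to_genes.setdefault(i, []).append(gid)
        gene_to_peaks.setdefault(gid, []).append(i)
    return TargetMap(
        peak_to_genes={i: tuple(sorted(v)) for i, v in peak_to_genes.items()},
        gene_to_peaks={g: tuple(sorted(v)) for g, v in gene_to_peaks.items()},
    )


def write_state_table(
    calls: Sequence[ChromatinStateCall],
    annotations: Sequence[FeatureAnnotation],
    path: str | Path,
) -> None:
    """Per-peak TSV: coordinates, state, compartment, assigned genes."""
    if len(calls) != len(annotations):
        raise ValidationError("state calls and annotations must align")
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tstate\tcategory\tgenes\n")
        for call, ann in zip(calls, annotations):
            iv = call.peak
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{call.state}\t"
                f"{ann.category}\t{','.join(ann.assigned_genes)}\n"
            )
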