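"""Promoter-capture interaction calls: I/O, classification, and gene queries.

Each call pairs a promoter-containing *bait* anchor (carrying the bait gene
ids) with a distal *other end*.  Other ends are classified with promoter
precedence — the capture design is promoter-centric, so an other end that is
itself a promoter is a promoter-promoter interaction even when it also
overlaps an enhancer — otherwise by the enhancer class of the overlapped
region, else ``promoter_other``.  Upstream caller scores are passed through
untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

from .core import FormatError, GenomicInterval, PeakSet, ValidationError, overlap_pairs
from .enhancers import ENHANCER_CLASSES, EnhancerClassCall

__all__ = [
    "INTERACTION_CLASSES",
    "InteractionCall",
    "InteractionClassCall",
    "GeneInteraction",
    "FactorEnrichment",
    "read_interactions",
    "write_interactions",
    "classify_interactions",
    "peaks_at_interactions",
    "factor_enrichment_in_mediated",
    "gene_interactions",
]

INTERACTION_CLASSES = ("promoter_promoter", "promoter_enhancer", "promoter_other")

_HEADER = ["bait_chrom", "bait_start", "bait_end", "bait_genes",
           "oe_chrom", "oe_start", "oe_end", "score"]


@dataclass(frozen=True)
class InteractionCall:
    bait: GenomicInterval
    bait_genes: tuple[str, ...]
    other_end: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if not self.bait_genes:
            raise ValidationError("interaction with empty bait_genes")

    @property
    def inter_chromosomal(self) -> bool:
        return self.bait.chrom != self.other_end.chrom

    def distance(self) -> float:
        """Absolute midpoint distance; inter-chromosomal pairs are unbounded."""
        if self.inter_chromosomal:
            return math.inf
        return float(abs(self.other_end.midpoint - self.bait.midpoint))


@dataclass(frozen=True)
class InteractionClassCall:
    interaction: InteractionCall
    iclass: str
    enh_subclass: str | None  # set iff iclass == promoter_enhancer
    tf_at_bait: dict = field(default_factory=dict, compare=False)
    tf_at_other_end: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class GeneInteraction:
    call: InteractionClassCall
    distance: float


@dataclass
class FactorEnrichment:
    fraction_mediated: float
    fraction_all: float
    ratio: float | None
    p_value: float | None
    n_mediated: int
    n_all: int
    degenerate: bool


def read_interactions(path: str | Path) -> list[InteractionCall]:
    """Read ibed-style interaction calls (tab-separated, header required).

    ``bait_genes`` is ";"-separated; an empty field is an error naming the row.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty interaction file")
    header = lines[0].split("\t")
    if header != _HEADER:
        raise FormatError(f"{path}: expected header {_HEADER}, got {header}")
    calls = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_HEADER):
            raise FormatError(f"{path}:{lineno}: expected {len(_HEADER)} fields")
        genes = tuple(g for g in fields[3].split(";") if g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: empty bait_genes field")
        try:
            bait = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            oe = GenomicInterval(fields[4], int(fields[5]), int(fields[6]))
            score = float(fields[7])
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        calls.append(InteractionCall(bait=bait, bait_genes=genes,
                                     other_end=oe, score=score))
    return calls


def write_interactions(calls: Iterable[InteractionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for c in calls:
            fh.write(
                f"{c.bait.chrom}\t{c.bait.start}\t{c.bait.end}\t"
                f"{';'.join(c.bait_genes)}\t{c.other_end.chrom}\t"
                f"{c.other_end.start}\t{c.other_end.end}\t{format(c.score, 'g')}\n"
            )


def _anchor_flags(anchors: Sequence[GenomicInterval], tf: PeakSet) -> np.ndarray:
    from .core import overlap_flags

    return overlap_flags(anchors, tf)


def classify_interactions(
    calls: Sequence[InteractionCall],
    promoters: PeakSet,
    enh_calls: Sequence[EnhancerClassCall],
    tf_sets: Mapping[str, PeakSet] | None = None,
) -> tuple[list[InteractionClassCall], dict[str, int]]:
    """Classify every interaction by its other end; classes partition the input.

    Unclassified enhancer regions do not count as enhancers.  When one other
    end overlaps several classified enhancers, the largest overlap wins, ties
    broken by class precedence (super > active > intermediate > poised).
    """
    from .core import overlap_flags

    others = [c.other_end for c in calls]
    in_prom = overlap_flags(others, promoters) if len(promoters) else \
        np.zeros(len(others), dtype=bool)

    classified = [e for e in enh_calls if e.enh_class != "unclassified"]
    enh_regions = [e.region for e in classified]
    precedence = {c: i for i, c in enumerate(ENHANCER_CLASSES)}
    best_sub: dict[int, tuple[int, int, str]] = {}  # call idx -> (-ov, rank, class)
    for i, j, ov in overlap_pairs(others, enh_regions):
        cls = classified[j].enh_class
        key = (-ov, precedence[cls], cls)
        if i not in best_sub or key < best_sub[i]:
            best_sub[i] = key

    tf_sets = dict(tf_sets or {})
    bait_flags = {lab: _anchor_flags([c.bait for c in calls], tf)
                  for lab, tf in tf_sets.items()}
    oe_flags = {lab: _anchor_flags(others, tf) for lab, tf in tf_sets.items()}

    out = []
    counts = {c: 0 for c in INTERACTION_CLASSES}
    for i, call in enumerate(calls):
        if in_prom[i]:
            iclass, sub = "promoter_promoter", None
        elif i in best_sub:
            iclass, sub = "promoter_enhancer", best_sub[i][2]
        else:
            iclass, sub = "promoter_other", None
        counts[iclass] += 1
        out.append(InteractionClassCall(
            interaction=call,
            iclass=iclass,
            enh_subclass=sub,
            tf_at_bait={lab: bool(flags[i]) for lab, flags in bait_flags.items()},
            tf_at_other_end={lab: bool(flags[i]) for lab, flags in oe_flags.items()},
        ))
    return out, counts


def peaks_at_interactions(
    calls: Sequence[InteractionClassCall],
    tf: PeakSet,
    where: str = "either",
) -> tuple[list[InteractionClassCall], float]:
    """Interactions whose selected anchor(s) carry at least one TF peak."""
    if where not in ("bait", "other_end", "either"):
        raise ValidationError(f"unknown anchor selector {where!r}")
    if len(calls) == 0:
        raise ValidationError("fraction undefined for an empty interaction set")
    bait_hit = _anchor_flags([c.interaction.bait for c in calls], tf)
    oe_hit = _anchor_flags([c.interaction.other_end for c in calls], tf)
    if where == "bait":
        hit = bait_hit
    elif where == "other_end":
        hit = oe_hit
    else:
        hit = bait_hit | oe_hit
    subset = [c for c, h in zip(calls, hit) if h]
    return subset, len(subset) / len(calls)


def factor_enrichment_in_mediated(
    calls_all: Sequence[InteractionClassCall],
    calls_mediated: Sequence[InteractionClassCall],
    tf2: PeakSet,
    where: str = "either",
) -> FactorEnrichment:
    """Fraction of interactions with a second factor at an anchor, in the
    mediated subset vs the full universe, with a two-proportion z-test."""
    if len(calls_all) == 0:
        raise ValidationError("empty interaction universe")
    sub_a, frac_a = peaks_at_interactions(calls_all, tf2, where=where)
    k_a, n_a = len(sub_a), len(calls_all)
    n_m = len(calls_mediated)
    if n_m == 0:
        return FactorEnrichment(fraction_mediated=0.0, fraction_all=frac_a,
                                ratio=None, p_value=None, n_mediated=0,
                                n_all=n_a, degenerate=True)
    sub_m, frac_m = peaks_at_interactions(calls_mediated, tf2, where=where)
    k_m = len(sub_m)
    if k_m == 0 and k_a == 0:
        return FactorEnrichment(fraction_mediated=0.0, fraction_all=0.0,
                                ratio=None, p_value=None, n_mediated=n_m,
                                n_all=n_a, degenerate=True)
    if k_m == n_m and k_a == n_a:
        p = 1.0
    else:
        _stat, p = proportions_ztest([k_m, k_a], [n_m, n_a])
    ratio = None if frac_a == 0 else frac_m / frac_a
    return FactorEnrichment(fraction_mediated=frac_m, fraction_all=frac_a,
                            ratio=ratio, p_value=float(p), n_mediated=n_m,
                            n_all=n_a, degenerate=False)


def gene_interactions(
    gene_id: str, calls: Sequence[InteractionClassCall]
) -> list[GeneInteraction]:
    """All interactions whose bait genes contain ``gene_id`` (no dedup).

    An unknown gene yields an empty report.  Distances are absolute midpoint
    separations; inter-chromosomal interactions report ``inf``.
    """
    report = []
    for c in calls:
        if gene_id in c.interaction.bait_genes:
            report.append(GeneInteraction(call=c, distance=c.interaction.distance()))
    return report
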