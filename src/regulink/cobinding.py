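"""Co-binding statistics between two factors and the resampling-null overlap CI.

The uncertainty attached to an overlap count follows the empirical recipe of
shuffling the query intervals uniformly over the genome and reading the 2.5th
and 97.5th percentiles of the null draws as a 95% interval; the default of
100 draws matches the published procedure, while stability-sensitive analyses
should raise ``n_draws``.  The empirical p-value uses the add-one rule and is
therefore never 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import (
    ChromSizes,
    PeakSet,
    ValidationError,
    _chrom_arrays,
    _flags_vs_union,
    _union_arrays,
    overlap_flags,
)

__all__ = [
    "CoOccupancy",
    "ConditionalFractions",
    "OverlapCI",
    "intersect_peaksets",
    "conditional_fraction",
    "overlap_ci",
]


@dataclass
class CoOccupancy:
    """a-intervals overlapped by b, with the symmetric overlap fractions."""

    co_set: PeakSet
    fraction_a: float
    fraction_b: float
    n_a: int
    n_b: int


@dataclass
class ConditionalFractions:
    """Per-stratum fraction of set-A intervals overlapped by set B.

    Strata with no intervals report ``None`` (undefined), never 0.
    """

    fractions: dict[str, float | None]
    counts: dict[str, tuple[int, int]]  # stratum -> (overlapped, total)
    pooled_fraction: float | None


@dataclass
class OverlapCI:
    observed: int
    n_query: int
    draws: np.ndarray
    ci_low: float
    ci_high: float
    empirical_p: float
    seed: int
    n_draws: int
    mode: str

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "observed": self.observed,
            "n_query": self.n_query,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
            "n_draws": self.n_draws,
            "mode": self.mode,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def intersect_peaksets(a: PeakSet, b: PeakSet) -> CoOccupancy:
    """Subset of ``a`` overlapped by ``b`` and the two overlap fractions.

    An interval counts once no matter how many partner features it touches,
    matching percentage-of-peaks reporting.
    """
    if len(a) == 0:
        raise ValidationError("fraction_a undefined for an empty query set")
    flags_a = overlap_flags(a, b)
    co = a.subset(np.nonzero(flags_a)[0], label=f"{a.label}+{b.label}")
    fraction_a = float(np.mean(flags_a))
    fraction_b = float(np.mean(overlap_flags(b, a))) if len(b) else 0.0
    return CoOccupancy(co_set=co, fraction_a=fraction_a, fraction_b=fraction_b,
                       n_a=len(a), n_b=len(b))


def conditional_fraction(
    a_strata: Mapping[str, PeakSet], b: PeakSet
) -> ConditionalFractions:
    """Overlapped fraction of each stratum of A; the size-weighted mean over
    strata equals the pooled fraction by construction."""
    fractions: dict[str, float | None] = {}
    counts: dict[str, tuple[int, int]] = {}
    tot_hit = tot_n = 0
    for name, stratum in a_strata.items():
        n = len(stratum)
        if n == 0:
            fractions[name] = None
            counts[name] = (0, 0)
            continue
        hit = int(np.count_nonzero(overlap_flags(stratum, b)))
        fractions[name] = hit / n
        counts[name] = (hit, n)
        tot_hit += hit
        tot_n += n
    pooled = tot_hit / tot_n if tot_n else None
    return ConditionalFractions(fractions=fractions, counts=counts,
                                pooled_fraction=pooled)


def _count_overlap(starts, ends, union, mode: str) -> int:
    if mode == "intervals":
        return int(np.count_nonzero(_flags_vs_union(starts, ends, union)))
    # base-pair mode: total intersection length with the merged union
    ustarts, uends = union
    total = 0
    lo = np.searchsorted(uends, starts, side="right")
    hi = np.searchsorted(ustarts, ends, side="left")
    for s, e, i0, i1 in zip(starts, ends, lo, hi):
        if i0 >= i1:
            continue
        total += int(
            np.sum(np.minimum(uends[i0:i1], e) - np.maximum(ustarts[i0:i1], s))
        )
    return total


def overlap_ci(
    query: PeakSet,
    reference: PeakSet,
    sizes: ChromSizes,
    n_draws: int = 100,
    seed: int = 0,
    match_chrom: bool = True,
    mode: str = "intervals",
) -> OverlapCI:
    """Observed query/reference overlap with a shuffled-null percentile CI.

    Each draw re-places every query interval uniformly at random (keeping its
    length, and by default its chromosome) and re-counts the overlap.  The
    95% interval spans the 2.5th-97.5th percentiles of the draws;
    ``empirical_p = (1 + #{draws >= observed}) / (n_draws + 1)``.

    ``mode="intervals"`` counts query intervals touching the reference (the
    default); ``mode="bases"`` counts intersected base pairs.
    """
    if n_draws < 2:
        raise ValidationError("n_draws must be >= 2")
    if mode not in ("intervals", "bases"):
        raise ValidationError(f"unknown overlap mode {mode!r}")
    query.validate(sizes)
    union = _union_arrays(reference)
    empty = (np.array([], dtype=np.int64), np.array([], dtype=np.int64))

    by_chrom = _chrom_arrays(query)
    observed = 0
    for chrom, (_idx, starts, ends) in by_chrom.items():
        observed += _count_overlap(starts, ends, union.get(chrom, empty), mode)

    rng = np.random.default_rng(seed)
    chrom_names = list(sizes)
    lens = np.array([sizes[c] for c in chrom_names], dtype=np.int64)
    # per-chromosome interval lengths, in the fixed order of the query
    lengths_by_chrom = {
        chrom: (ends - starts) for chrom, (_i, starts, ends) in by_chrom.items()
    }
    draws = np.empty(n_draws, dtype=np.int64)
    for d in range(n_draws):
        count = 0
        if match_chrom:
            for chrom in by_chrom:
                L = lengths_by_chrom[chrom]
                s = rng.integers(0, sizes[chrom] - L + 1)
                count += _count_overlap(s, s + L, union.get(chrom, empty), mode)
        else:
            all_lens = np.concatenate(list(lengths_by_chrom.values())) \
                if by_chrom else np.array([], dtype=np.int64)
            for L in all_lens:
                slots = np.maximum(lens - L + 1, 0)
                total = int(slots.sum())
                if total == 0:
                    raise ValidationError("query interval does not fit anywhere")
                ci = int(rng.choice(len(chrom_names), p=slots / total))
                s = int(rng.integers(0, slots[ci]))
                arr_s = np.array([s], dtype=np.int64)
                count += _count_overlap(
                    arr_s, arr_s + int(L), union.get(chrom_names[ci], empty), mode
                )
        draws[d] = count

    ci_low, ci_high = np.percentile(draws, [2.5, 97.5])
    empirical_p = (1 + int(np.count_nonzero(draws >= observed))) / (n_draws + 1)
    return OverlapCI(observed=int(observed), n_query=len(query), draws=draws,
                     ci_low=float(ci_low), ci_high=float(ci_high),
                     empirical_p=float(empirical_p), seed=int(seed),
                     n_draws=int(n_draws), mode=mode)
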