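"""Genomic interval primitives, standard-format I/O, and the overlap/shuffle engine.

All coordinates are 0-based, half-open ``[start, end)``, matching BED.
Interval length is always ``end - start``.  Everything downstream — chromatin
state calls, enhancer classes, interaction anchors — is built on the types
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ChromSizes",
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "CoverageTrack",
    "read_bed",
    "read_gene_table",
    "write_gene_table",
    "read_bedgraph",
    "overlap_pairs",
    "overlap_flags",
    "merge_intervals",
    "shuffle_intervals",
]

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """An input file violates its format contract (bad column, coordinate...)."""


class ValidationError(ValueError):
    """In-memory data violates a model invariant."""


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length (bp).  Bounds every placement and clip."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        self._sizes: dict[str, int] = {}
        items = sizes.items() if isinstance(sizes, Mapping) else sizes
        for name, length in items:
            name = str(name)
            length = int(length)
            if name in self._sizes:
                raise ValidationError(f"duplicate chromosome name: {name!r}")
            if length < 1:
                raise ValidationError(f"chromosome {name!r} has length {length} < 1")
            self._sizes[name] = length

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def total(self) -> int:
        return sum(self._sizes.values())

    @classmethod
    def read(cls, path: str | Path) -> "ChromSizes":
        pairs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                pairs.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length") from exc
        return cls(pairs)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, the universal currency of the toolkit."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp (0 when disjoint or on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


class PeakSet(Sequence[GenomicInterval]):
    """A labelled, ordered collection of intervals (one ChIP-seq factor/mark)."""

    def __init__(self, label: str, intervals: Iterable[GenomicInterval] = ()):
        self.label = label
        self.intervals: tuple[GenomicInterval, ...] = tuple(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return PeakSet(self.label, self.intervals[i])
        return self.intervals[i]

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PeakSet)
            and self.label == other.label
            and self.intervals == other.intervals
        )

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"

    def sorted(self) -> "PeakSet":
        return PeakSet(
            self.label,
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
        )

    def subset(self, indices: Iterable[int], label: str | None = None) -> "PeakSet":
        return PeakSet(
            self.label if label is None else label,
            (self.intervals[i] for i in indices),
        )

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def validate(self, sizes: ChromSizes | None = None) -> None:
        if sizes is not None:
            for iv in self.intervals:
                if iv.chrom not in sizes:
                    raise ValidationError(f"unknown chromosome {iv.chrom!r}")
                if iv.end > sizes[iv.chrom]:
                    raise ValidationError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {sizes[iv.chrom]}"
                    )

    def write_bed(self, path: str | Path, dialect: str = "bed6") -> None:
        if dialect not in ("bed3", "bed6"):
            raise ValidationError(f"unknown BED dialect {dialect!r}")
        with open(path, "w") as fh:
            for iv in self.intervals:
                if dialect == "bed3":
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
                else:
                    score = "." if iv.score is None else format(iv.score, "g")
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
                    )


def read_bed(path: str | Path, dialect: str = "bed6", label: str | None = None) -> PeakSet:
    """Read a BED3/BED6 file into a :class:`PeakSet`.

    Coordinates are kept 0-based half-open exactly as BED defines them;
    ``track``/``browser``/comment lines are skipped.  Malformed coordinates
    raise :class:`FormatError` naming the offending line.
    """
    if dialect not in ("bed3", "bed6"):
        raise ValidationError(f"unknown BED dialect {dialect!r}")
    path = Path(path)
    intervals = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith(("track", "browser", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        name, score, strand = ".", None, "."
        if dialect == "bed6":
            if len(fields) > 3:
                name = fields[3]
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            if len(fields) > 5:
                strand = fields[5]
        try:
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
            )
        except ValidationError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(label if label is not None else path.stem, intervals)


@dataclass(frozen=True)
class GeneModel:
    """A gene as TSS/TES on a strand; defines promoters and gene bodies.

    On the minus strand the TSS is the larger coordinate, so ``tss > tes``.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss == self.tes:
            raise ValidationError(f"gene {self.gene_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValidationError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValidationError(f"gene {self.gene_id}: - strand requires tss > tes")
        if min(self.tss, self.tes) < 0:
            raise ValidationError(f"gene {self.gene_id}: negative coordinate")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, self.end, name=self.gene_id, strand=self.strand
        )


GENE_TABLE_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "tss", "tes"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the tab-separated gene table (header: gene_id/symbol/chrom/strand/tss/tes)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "chrom": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene_id {dups[:5]}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            genes.append(
                GeneModel(row.gene_id, row.symbol, row.chrom, row.strand,
                          int(row.tss), int(row.tes))
            )
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\n")


class CoverageTrack:
    """Per-chromosome stepwise signal with a library-size normalizer.

    Steps within a chromosome are sorted and non-overlapping; regions not
    covered by any step have value 0.  ``total_signal`` (sum of
    value x step-length, or a supplied library-size proxy) is the denominator
    for per-million normalization.
    """

    def __init__(
        self,
        steps: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_signal: float | None = None,
    ):
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        computed = 0.0
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValidationError(f"{chrom}: ragged step arrays")
            if len(starts):
                if np.any(ends <= starts):
                    raise ValidationError(f"{chrom}: step with end <= start")
                if np.any(starts[1:] < ends[:-1]):
                    raise ValidationError(f"{chrom}: overlapping or unsorted steps")
                if np.any(values < 0):
                    raise ValidationError(f"{chrom}: negative step value")
                computed += float(np.sum(values * (ends - starts)))
            self._steps[chrom] = (starts, ends, values)
        self._total = computed if total_signal is None else float(total_signal)
        if self._total <= 0:
            raise ValidationError("total_signal must be > 0")

    @property
    def total_signal(self) -> float:
        return self._total

    def chroms(self) -> list[str]:
        return list(self._steps)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._steps[chrom]

    @classmethod
    def from_steps(
        cls,
        rows: Iterable[tuple[str, int, int, float]],
        total_signal: float | None = None,
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in rows:
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        arrays = {}
        for chrom, triples in by_chrom.items():
            triples.sort()
            s = np.array([t[0] for t in triples], dtype=np.int64)
            e = np.array([t[1] for t in triples], dtype=np.int64)
            v = np.array([t[2] for t in triples], dtype=np.float64)
            arrays[chrom] = (s, e, v)
        return cls(arrays, total_signal=total_signal)

    def sum_range(self, chrom: str, start: int, end: int) -> float:
        """Exact sum of signal (value x covered bp) over ``[start, end)``."""
        if chrom not in self._steps or end <= start:
            return 0.0
        s, e, v = self._steps[chrom]
        i0 = int(np.searchsorted(e, start, side="right"))
        i1 = int(np.searchsorted(s, end, side="left"))
        if i0 >= i1:
            return 0.0
        lens = np.minimum(e[i0:i1], end) - np.maximum(s[i0:i1], start)
        return float(np.sum(v[i0:i1] * lens))

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self._steps:
                s, e, v = self._steps[chrom]
                for i in range(len(s)):
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{format(v[i], '.10g')}\n")


def read_bedgraph(path: str | Path, total_signal: float | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph; steps may be unsorted but must not overlap."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad coordinate or value") from exc
    try:
        return CoverageTrack.from_steps(rows, total_signal=total_signal)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------


def _chrom_arrays(ps: Sequence[GenomicInterval]):
    by: dict[str, list[int]] = {}
    for i, iv in enumerate(ps):
        by.setdefault(iv.chrom, []).append(i)
    out = {}
    for chrom, idx in by.items():
        idx_arr = np.array(idx, dtype=np.int64)
        starts = np.array([ps[i].start for i in idx], dtype=np.int64)
        ends = np.array([ps[i].end for i in idx], dtype=np.int64)
        out[chrom] = (idx_arr, starts, ends)
    return out


def overlap_pairs(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> list[tuple[int, int, int]]:
    """All pairs ``(i, j, overlap_bp)`` with intersection >= ``min_overlap_bp``.

    Indices refer to input order.  Symmetric: ``overlap_pairs(a, b)`` is the
    transpose of ``overlap_pairs(b, a)``.  Implemented as a per-chromosome
    sorted sweep with binary-search pruning.
    """
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    res: list[tuple[int, int, int]] = []
    a_by = _chrom_arrays(a)
    b_by = _chrom_arrays(b)
    for chrom in set(a_by) & set(b_by):
        ia, sa, ea = a_by[chrom]
        ib, sb, eb = b_by[chrom]
        order = np.argsort(sa, kind="stable")
        sa, ea, ia = sa[order], ea[order], ia[order]
        for j in range(len(sb)):
            # candidates: a.start <= b.end - min_overlap
            k = int(np.searchsorted(sa, eb[j] - min_overlap_bp, side="right"))
            if k == 0:
                continue
            ov = np.minimum(ea[:k], eb[j]) - np.maximum(sa[:k], sb[j])
            hits = np.nonzero(ov >= min_overlap_bp)[0]
            jj = int(ib[j])
            for t in hits:
                res.append((int(ia[t]), jj, int(ov[t])))
    res.sort()
    return res


def merge_intervals(
    peaks: Sequence[GenomicInterval], gap: int = 0, label: str | None = None
) -> PeakSet:
    """Merge intervals closer than ``gap`` bp (0 = merge only overlapping/adjacent)."""
    src_label = getattr(peaks, "label", "merged")
    ivs = sorted(peaks, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = replace(prev, end=iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                          name=f"m{len(merged) + 1}"))
    return PeakSet(label if label is not None else src_label, merged)


def _union_arrays(b: Sequence[GenomicInterval]):
    """Merged union of b per chromosome, as (starts, ends) sorted arrays."""
    out = {}
    merged = merge_intervals(b, gap=0)
    by: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by.items():
        out[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    return out


def _flags_vs_union(starts, ends, union):
    """Boolean overlap flags of intervals (arrays) against a merged union."""
    ustarts, uends = union
    idx = np.searchsorted(ustarts, ends, side="left")
    flags = np.zeros(len(starts), dtype=bool)
    has_prev = idx > 0
    flags[has_prev] = uends[idx[has_prev] - 1] > starts[has_prev]
    return flags


def overlap_flags(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> np.ndarray:
    """Per-interval boolean: does a[i] intersect any interval of b?"""
    if min_overlap_bp != 1:
        flags = np.zeros(len(a), dtype=bool)
        for i, _j, _ov in overlap_pairs(a, b, min_overlap_bp=min_overlap_bp):
            flags[i] = True
        return flags
    flags = np.zeros(len(a), dtype=bool)
    union = _union_arrays(b)
    a_by = _chrom_arrays(a)
    for chrom, (idx, starts, ends) in a_by.items():
        if chrom not in union:
            continue
        flags[idx] = _flags_vs_union(starts, ends, union[chrom])
    return flags


# ---------------------------------------------------------------------------
# Shuffle engine (the random-draw primitive of the resampling null)
# ---------------------------------------------------------------------------


def shuffle_intervals(
    a: Sequence[GenomicInterval],
    sizes: ChromSizes,
    seed: int | None = None,
    match_chrom: bool = True,
    rng: np.random.Generator | None = None,
) -> PeakSet:
    """Place each interval uniformly at random over valid start positions.

    Lengths are preserved exactly.  With ``match_chrom`` (default) each
    interval stays on its source chromosome; otherwise the placement is
    uniform over all valid positions genome-wide.  Deterministic given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    names = list(sizes)
    lens = np.array([sizes[c] for c in names], dtype=np.int64)
    out = []
    for iv in a:
        L = iv.length
        if match_chrom:
            if iv.chrom not in sizes:
                raise ValidationError(f"unknown chromosome {iv.chrom!r}")
            clen = sizes[iv.chrom]
            if L > clen:
                raise ValidationError(
                    f"interval of length {L} does not fit on {iv.chrom} ({clen} bp)"
                )
            start = int(rng.integers(0, clen - L + 1))
            chrom = iv.chrom
        else:
            slots = np.maximum(lens - L + 1, 0)
            total = int(slots.sum())
            if total == 0:
                raise ValidationError(
                    f"interval of length {L} does not fit on any chromosome"
                )
            ci = int(rng.choice(len(names), p=slots / total))
            chrom = names[ci]
            start = int(rng.integers(0, slots[ci]))
        out.append(replace(iv, chrom=chrom, start=start, end=start + L))
    return PeakSet(getattr(a, "label", "shuffled"), out)
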