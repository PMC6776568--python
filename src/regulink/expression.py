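"""Knockdown differential-expression calls and gene-set joins.

The significance rule is a plain double threshold on the linear
knockdown/control fold change and the raw p-value: a gene is *up* when
``fold_change > fc_threshold`` and ``p < p_threshold`` (defaults 1.3 and
0.05), *down* when ``fold_change < 1 / fc_threshold`` with the same p cut,
otherwise *ns*.  Both inequalities are strict, and the reciprocal threshold
makes the rule symmetric under inverting every fold change.  No
multiple-testing correction is applied by default; pass ``bh_fdr=True`` to
filter on Benjamini-Hochberg-adjusted values instead of raw p.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import FormatError, ValidationError

__all__ = [
    "DE_STATUSES",
    "DERecord",
    "DECounts",
    "GeneSetSummary",
    "read_de_table",
    "call_de",
    "class_de_summary",
    "geneset_overlap",
]

DE_STATUSES = ("up", "down", "ns")


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    fold_change: float  # knockdown / control, linear scale
    p_value: float
    status: str


@dataclass
class DECounts:
    n_up: int
    n_down: int
    n_ns: int

    @property
    def n(self) -> int:
        return self.n_up + self.n_down + self.n_ns


@dataclass
class GeneSetSummary:
    label: str
    n: int
    n_measured: int
    n_unmeasured: int
    frac_up: float | None
    frac_down: float | None
    frac_ns: float | None


def read_de_table(path: str | Path, log2fc: bool = False) -> pd.DataFrame:
    """Read a per-gene DE table (gene_id, fold_change, p_value, tab-separated).

    With ``log2fc=True`` the fold_change column is interpreted as log2 and
    converted to the linear scale.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "fold_change", "p_value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if log2fc:
        df = df.assign(fold_change=np.exp2(df["fold_change"]))
    return df


def call_de(
    table: pd.DataFrame | Iterable[tuple[str, float, float]],
    fc_threshold: float = 1.3,
    p_threshold: float = 0.05,
    bh_fdr: bool = False,
) -> tuple[list[DERecord], DECounts]:
    """Apply the double-threshold significance rule to a DE table."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValidationError("thresholds must be > 0")
    if isinstance(table, pd.DataFrame):
        rows = list(table[["gene_id", "fold_change", "p_value"]].itertuples(index=False))
    else:
        rows = list(table)
    pvals = np.array([float(r[2]) for r in rows])
    if bh_fdr and len(pvals):
        pvals = multipletests(pvals, method="fdr_bh")[1]
    records = []
    counts = {s: 0 for s in DE_STATUSES}
    for (gene_id, fc, _p), p in zip(rows, pvals):
        fc = float(fc)
        if fc <= 0:
            raise ValidationError(f"gene {gene_id}: non-positive fold change {fc}")
        if p < p_threshold and fc > fc_threshold:
            status = "up"
        elif p < p_threshold and fc < 1.0 / fc_threshold:
            status = "down"
        else:
            status = "ns"
        counts[status] += 1
        records.append(DERecord(str(gene_id), fc, float(p), status))
    return records, DECounts(n_up=counts["up"], n_down=counts["down"],
                             n_ns=counts["ns"])


def class_de_summary(
    gene_sets: Mapping[str, Iterable[str]],
    de: Sequence[DERecord],
) -> dict[str, GeneSetSummary]:
    """Per-label DE status fractions over measured genes.

    Genes absent from the DE table count as unmeasured and are reported
    separately; fractions over measured genes sum to 1.  A label with no
    measured genes reports ``None`` fractions.
    """
    status_by_gene = {r.gene_id: r.status for r in de}
    out = {}
    for label, genes in gene_sets.items():
        genes = set(genes)
        measured = [g for g in genes if g in status_by_gene]
        n_meas = len(measured)
        if n_meas == 0:
            out[label] = GeneSetSummary(label, len(genes), 0, len(genes),
                                        None, None, None)
            continue
        n_up = sum(status_by_gene[g] == "up" for g in measured)
        n_down = sum(status_by_gene[g] == "down" for g in measured)
        out[label] = GeneSetSummary(
            label=label, n=len(genes), n_measured=n_meas,
            n_unmeasured=len(genes) - n_meas,
            frac_up=n_up / n_meas, frac_down=n_down / n_meas,
            frac_ns=(n_meas - n_up - n_down) / n_meas,
        )
    return out


def geneset_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> tuple[int, float]:
    """Overlap count and one-sided hypergeometric enrichment tail p-value."""
    a, b = set(set_a), set(set_b)
    if universe_size < len(a) or universe_size < len(b):
        raise ValidationError("universe smaller than one of the gene sets")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(b), len(a)))
    return k, min(p, 1.0)
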