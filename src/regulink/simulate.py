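"""Synthetic miniature study with planted ground truth.

``simulate_study`` lays out a deterministic genome (default 3 x 10 Mb), a gene
table, TF and histone-mark peak sets, SE/TE region lists, bedGraph coverage
tracks, promoter-capture interaction calls and a knockdown DE table — and
records every planted label in a :class:`GroundTruthManifest` JSON.  Entities
are *placed by construction* to satisfy their labels (a peak planted
"active_k4me3" physically overlaps an H3K4me3 peak and no H3K27me3 peak), so
full-pipeline recovery of every planted composition is exact rather than
statistical.

Layout sketch, per chromosome: a gene zone (fixed-stride genes with
alternating strands; promoter/gene-body peaks and SE/TE regions live in and
between genes), then an intergenic TF-peak zone, a zone of extra TF-B peaks,
and a reserved "other" zone hosting anchors for interactions that touch
neither promoter nor enhancer.  Planted peaks within each set keep >= 1 kb
spacing so overlap logic is unambiguous.

Coverage is built as rectangular bumps over region extents plus optional
Poisson noise (``coverage_noise`` scales the Poisson rate; 0 disables noise,
making e.g. the SE/TE density fold exactly ``se_te_signal_fold``).
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import (
    ChromSizes,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    PeakSet,
    ValidationError,
    write_gene_table,
)
from .interactions import InteractionCall, write_interactions

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate_study",
    "degrade",
    "load_bundle",
    "random_peaks",
    "simulate_region_coverage",
]

GENE0 = 50_000
GENE_LEN = 30_000
GENE_STRIDE = 60_000
PEAK_W = 400
MARK_PAD = 100
BODY_OFFSETS = (6_000, 14_000)
SE_OFFSET, SE_LEN = 38_000, 10_000
TE_OFFSET, TE_LEN = 40_000, 2_000

STATE_NAMES = ("active_k4me3", "bivalent", "repressive_k27me3", "unmarked")
FEATURE_NAMES = ("promoter", "gene_body", "intergenic")
ICLASS_NAMES = ("promoter_promoter", "promoter_enhancer", "promoter_other")
TE_CLASS_CYCLE = ("active", "intermediate", "poised")


class SimError(ValidationError):
    """Infeasible simulation configuration (detected before writing anything)."""


@dataclass
class SimConfig:
    """Every tunable of the miniature study; defaults are the study conditions."""

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 10_000_000), ("chr2", 10_000_000), ("chr3", 10_000_000),
    )
    n_genes: int = 300
    n_tf_peaks: int = 2000
    state_composition: dict = field(default_factory=lambda: {
        "active_k4me3": 0.50, "bivalent": 0.20,
        "repressive_k27me3": 0.20, "unmarked": 0.10,
    })
    feature_composition: dict = field(default_factory=lambda: {
        "promoter": 0.01, "gene_body": 0.29, "intergenic": 0.70,
    })
    # per-state co-binding of TF-B on TF-A; the state-weighted mean is the
    # overall co-binding fraction (0.60 under the defaults)
    cobind_by_state: dict = field(default_factory=lambda: {
        "active_k4me3": 0.70, "bivalent": 0.50,
        "repressive_k27me3": 0.50, "unmarked": 0.50,
    })
    n_extra_tfb: int = 200
    n_se: int = 30
    n_te: int = 30
    se_te_signal_fold: float = 3.0
    te_amplitude: float = 2.0
    tf_amplitude: float = 5.0
    coverage_noise: float = 1.0  # Poisson rate scale; 0 = noiseless
    coverage_bin: int = 50
    n_interactions: int = 500
    interaction_class_fractions: dict = field(default_factory=lambda: {
        "promoter_promoter": 0.60, "promoter_enhancer": 0.30,
        "promoter_other": 0.10,
    })
    mediated_fraction: float = 0.40
    n_de_genes: int = 1000
    n_de_up: int = 120
    n_de_down: int = 80

    @property
    def cobind_fraction(self) -> float:
        return sum(self.state_composition[s] * self.cobind_by_state[s]
                   for s in STATE_NAMES)


@dataclass
class SimBundle:
    """Paths of a written study bundle plus its ground-truth manifest."""

    directory: Path
    paths: dict[str, Path]
    manifest: dict


def _exact_count(fraction: float, n: int, what: str) -> int:
    x = fraction * n
    r = round(x)
    if abs(x - r) > 1e-6:
        raise SimError(f"{what}: fraction {fraction} of {n} is not an integer")
    return int(r)


def random_peaks(
    n: int,
    length: int,
    sizes: ChromSizes,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    label: str = "random",
) -> PeakSet:
    """``n`` intervals of fixed length placed uniformly over the genome."""
    if rng is None:
        rng = np.random.default_rng(seed)
    names = list(sizes)
    slots = np.array([max(sizes[c] - length + 1, 0) for c in names], dtype=np.int64)
    total = int(slots.sum())
    if total == 0:
        raise ValidationError(f"length {length} does not fit on any chromosome")
    out = []
    for i in range(n):
        ci = int(rng.choice(len(names), p=slots / total))
        s = int(rng.integers(0, slots[ci]))
        out.append(GenomicInterval(names[ci], s, s + length, name=f"{label}_{i + 1}"))
    return PeakSet(label, out)


def _flatten_bumps(
    bumps: Iterable[tuple[str, int, int, float]],
) -> list[tuple[str, int, int, float]]:
    """Sum possibly-overlapping rectangular bumps into disjoint steps."""
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, s, e, amp in bumps:
        by_chrom.setdefault(chrom, []).append((int(s), int(e), float(amp)))
    steps = []
    for chrom in sorted(by_chrom):
        events: dict[int, float] = {}
        for s, e, amp in by_chrom[chrom]:
            events[s] = events.get(s, 0.0) + amp
            events[e] = events.get(e, 0.0) - amp
        level = 0.0
        prev = None
        for pos in sorted(events):
            if prev is not None and level > 0:
                steps.append((chrom, prev, pos, level))
            level += events[pos]
            prev = pos
    return steps


def simulate_region_coverage(
    bumps: Iterable[tuple[str, int, int, float]],
    noise: float = 0.0,
    bin_size: int = 50,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CoverageTrack:
    """Coverage from rectangular bumps, optionally Poisson-perturbed per bin.

    With ``noise > 0`` each ``bin_size`` window within a bump is replaced by
    ``Poisson(value * width * noise) / (width * noise)`` — unbiased, with
    variance shrinking as ``noise`` grows.  ``noise = 0`` keeps the exact
    rectangles.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    flat = _flatten_bumps(bumps)
    rows: list[tuple[str, int, int, float]] = []
    if noise <= 0:
        rows = flat
    else:
        for chrom, s, e, v in flat:
            pos = s
            while pos < e:
                w = min(bin_size, e - pos)
                lam = v * w * noise
                val = float(rng.poisson(lam)) / (w * noise)
                rows.append((chrom, pos, pos + w, val))
                pos += w
    return CoverageTrack.from_steps(rows)


# ---------------------------------------------------------------------------
# Study generator
# ---------------------------------------------------------------------------


def _layout_genes(config: SimConfig) -> list[GeneModel]:
    chroms = [c for c, _l in config.chromosomes]
    if config.n_genes % len(chroms) != 0:
        raise SimError("n_genes must be divisible by the number of chromosomes")
    gpc = config.n_genes // len(chroms)
    genes = []
    gid = 0
    for chrom in chroms:
        for i in range(gpc):
            gid += 1
            start = GENE0 + i * GENE_STRIDE
            strand = "+" if i % 2 == 0 else "-"
            tss, tes = (start, start + GENE_LEN) if strand == "+" \
                else (start + GENE_LEN, start)
            genes.append(GeneModel(f"g{gid:04d}", f"GENE{gid:04d}", chrom,
                                   strand, tss, tes))
    return genes


def simulate_study(config: SimConfig, outdir: str | Path) -> SimBundle:
    """Write the full synthetic study bundle and its ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)

    sizes = ChromSizes(config.chromosomes)
    chroms = list(sizes)
    n_chrom = len(chroms)
    gpc = config.n_genes // n_chrom if config.n_genes % n_chrom == 0 else None
    if gpc is None:
        raise SimError("n_genes must be divisible by the number of chromosomes")

    # --- feature counts -----------------------------------------------------
    if abs(sum(config.feature_composition.values()) - 1) > 1e-9:
        raise SimError("feature_composition must sum to 1")
    if abs(sum(config.state_composition.values()) - 1) > 1e-9:
        raise SimError("state_composition must sum to 1")
    n_prom = _exact_count(config.feature_composition["promoter"],
                          config.n_tf_peaks, "promoter peaks")
    n_body = _exact_count(config.feature_composition["gene_body"],
                          config.n_tf_peaks, "gene-body peaks")
    n_int = _exact_count(config.feature_composition["intergenic"],
                         config.n_tf_peaks, "intergenic peaks")
    body_capacity = 2 * config.n_genes - n_prom
    if n_prom > config.n_genes:
        raise SimError("more promoter peaks than genes (promoter space)")
    if n_body > body_capacity:
        raise SimError("more gene-body peaks than gene-body slots")

    genes = _layout_genes(config)
    gene_zone_end = GENE0 + gpc * GENE_STRIDE

    # --- SE / TE regions in inter-gene gaps ---------------------------------
    if config.n_se % n_chrom or config.n_te % n_chrom:
        raise SimError("n_se and n_te must be divisible by the number of chromosomes")
    se_pc, te_pc = config.n_se // n_chrom, config.n_te // n_chrom
    if 9 + 8 * (max(se_pc, te_pc) - 1) > gpc - 2:
        raise SimError("too many SE/TE regions for the gene zone")
    se_list, te_list = [], []
    se_gene_truth: dict[str, dict] = {}
    for ci, chrom in enumerate(chroms):
        for k in range(se_pc):
            i = 5 + 8 * k  # odd => gap follows a minus-strand gene
            g = genes[ci * gpc + i]
            start = GENE0 + i * GENE_STRIDE + SE_OFFSET
            name = f"se_{len(se_list) + 1:03d}"
            se_list.append(GenomicInterval(chrom, start, start + SE_LEN, name=name))
            # the minus-strand TSS sits GENE_LEN into the gene, 8 kb left of
            # the SE start: the unambiguous nearest gene by construction
            se_gene_truth[name] = {"gene_id": g.gene_id,
                                   "distance": SE_OFFSET - GENE_LEN}
        for k in range(te_pc):
            i = 9 + 8 * k
            start = GENE0 + i * GENE_STRIDE + TE_OFFSET
            name = f"te_{len(te_list) + 1:03d}"
            te_list.append(GenomicInterval(chrom, start, start + TE_LEN, name=name))
    te_classes = {iv.name: TE_CLASS_CYCLE[i % len(TE_CLASS_CYCLE)]
                  for i, iv in enumerate(te_list)}

    # --- interaction bookkeeping needed before peak placement ----------------
    for key, frac in config.interaction_class_fractions.items():
        if key not in ICLASS_NAMES:
            raise SimError(f"unknown interaction class {key!r}")
    n_pp = _exact_count(config.interaction_class_fractions["promoter_promoter"],
                        config.n_interactions, "P-P interactions")
    n_pe = _exact_count(config.interaction_class_fractions["promoter_enhancer"],
                        config.n_interactions, "P-E interactions")
    n_po = _exact_count(config.interaction_class_fractions["promoter_other"],
                        config.n_interactions, "other interactions")
    if n_pp + n_pe + n_po != config.n_interactions:
        raise SimError("interaction class fractions must sum to 1")
    m_pp = _exact_count(config.mediated_fraction, n_pp, "mediated P-P")
    m_pe = _exact_count(config.mediated_fraction, n_pe, "mediated P-E")
    m_po = _exact_count(config.mediated_fraction, n_po, "mediated other")

    n_se_tf = min(config.n_se // 2, max(1, m_pe)) if m_pe else 0
    n_other_tf = min(10, max(1, m_po)) if m_po else 0

    # --- TF-A peak placement -------------------------------------------------
    prom_gene_idx = sorted({round(k * config.n_genes / n_prom)
                            for k in range(n_prom)}) if n_prom else []
    if len(prom_gene_idx) != n_prom:
        raise SimError("could not spread promoter peaks over distinct genes")
    prom_gene_ids = {genes[i].gene_id for i in prom_gene_idx}

    peaks: list[dict] = []
    for i in prom_gene_idx:
        g = genes[i]
        peaks.append({"chrom": g.chrom, "start": g.tss - PEAK_W // 2,
                      "feature": "promoter"})
    # gene-body slots in deterministic order; promoter-peak genes give one slot
    slots = []
    for gi, g in enumerate(genes):
        offsets = BODY_OFFSETS if g.gene_id not in prom_gene_ids else BODY_OFFSETS[:1]
        for off in offsets:
            slots.append((g.chrom, g.start + off))
    for chrom, start in slots[:n_body]:
        peaks.append({"chrom": chrom, "start": start, "feature": "gene_body"})

    tf_bound_se = [iv.name for iv in se_list[:n_se_tf]]
    se_by_name = {iv.name: iv for iv in se_list}
    for name in tf_bound_se:
        iv = se_by_name[name]
        c = iv.midpoint
        peaks.append({"chrom": iv.chrom, "start": c - PEAK_W // 2,
                      "feature": "intergenic"})

    # zone boundaries per chromosome
    n_strided = n_int - n_se_tf - n_other_tf
    if n_strided < 0:
        raise SimError("intergenic composition too small for interaction anchors")
    strided_pc = [n_strided // n_chrom + (1 if r < n_strided % n_chrom else 0)
                  for r in range(n_chrom)]
    extra_pc = [config.n_extra_tfb // n_chrom +
                (1 if r < config.n_extra_tfb % n_chrom else 0)
                for r in range(n_chrom)]
    other_tf_pc = [n_other_tf // n_chrom + (1 if r < n_other_tf % n_chrom else 0)
                   for r in range(n_chrom)]
    n_po_nonmed = n_po - m_po
    po_anchor_pc = [n_po_nonmed // n_chrom + (1 if r < n_po_nonmed % n_chrom else 0)
                    for r in range(n_chrom)]

    int_zone = gene_zone_end + 150_000
    zone_info = {}
    other_tf_peaks: list[GenomicInterval] = []
    po_anchors: list[GenomicInterval] = []
    tfb_extra: list[GenomicInterval] = []
    for ci, chrom in enumerate(chroms):
        z = int_zone
        for k in range(strided_pc[ci]):
            peaks.append({"chrom": chrom, "start": z + k * 4000,
                          "feature": "intergenic"})
        z_tfb = z + strided_pc[ci] * 4000 + 100_000
        for k in range(extra_pc[ci]):
            s = z_tfb + k * 3000
            tfb_extra.append(GenomicInterval(chrom, s, s + PEAK_W))
        z_otf = z_tfb + extra_pc[ci] * 3000 + 100_000
        for k in range(other_tf_pc[ci]):
            s = z_otf + k * 4000
            peaks.append({"chrom": chrom, "start": s, "feature": "intergenic"})
            other_tf_peaks.append(GenomicInterval(chrom, s, s + PEAK_W))
        z_anchor = z_otf + other_tf_pc[ci] * 4000 + 100_000
        for k in range(po_anchor_pc[ci]):
            s = z_anchor + k * 2000
            po_anchors.append(GenomicInterval(chrom, s, s + 600))
        zone_end = z_anchor + po_anchor_pc[ci] * 2000
        if zone_end > sizes[chrom] - 10_000:
            raise SimError(f"layout exceeds {chrom}: needs {zone_end} bp")
        zone_info[chrom] = {"intergenic_zone_start": int_zone, "zone_end": zone_end}

    if len(peaks) != config.n_tf_peaks:
        raise SimError(
            f"internal layout error: placed {len(peaks)} != {config.n_tf_peaks}"
        )

    # final TF-A peak set: sorted, named, then labelled
    peaks.sort(key=lambda p: (p["chrom"], p["start"]))
    tf_a_ivs = []
    for i, p in enumerate(peaks):
        p["name"] = f"A{i + 1:05d}"
        tf_a_ivs.append(GenomicInterval(p["chrom"], p["start"],
                                        p["start"] + PEAK_W, name=p["name"]))
    tf_a = PeakSet("TFA", tf_a_ivs)

    # --- states and co-binding ----------------------------------------------
    state_counts = {s: _exact_count(config.state_composition[s],
                                    config.n_tf_peaks, f"state {s}")
                    for s in STATE_NAMES}
    if sum(state_counts.values()) != config.n_tf_peaks:
        raise SimError("state composition must sum to 1")
    perm = rng.permutation(config.n_tf_peaks)
    state_of: dict[str, str] = {}
    pos = 0
    idx_by_state: dict[str, np.ndarray] = {}
    for s in STATE_NAMES:
        idx = perm[pos:pos + state_counts[s]]
        idx_by_state[s] = idx
        for i in idx:
            state_of[peaks[i]["name"]] = s
        pos += state_counts[s]

    cobound: set[str] = set()
    for s in STATE_NAMES:
        idx = idx_by_state[s]
        k = _exact_count(config.cobind_by_state[s], len(idx), f"cobind {s}")
        chosen = rng.choice(idx, size=k, replace=False) if k else []
        for i in chosen:
            cobound.add(peaks[i]["name"])

    tf_b_ivs = []
    for iv in tf_a_ivs:
        if iv.name in cobound:
            tf_b_ivs.append(GenomicInterval(iv.chrom, iv.start + 100,
                                            iv.start + 100 + PEAK_W))
    tf_b_ivs.extend(tfb_extra)
    tf_b_ivs.sort(key=lambda iv: (iv.chrom, iv.start))
    tf_b = PeakSet("TFB", [replace(iv, name=f"B{i + 1:05d}")
                           for i, iv in enumerate(tf_b_ivs)])

    # --- histone marks -------------------------------------------------------
    k4me3, k27me3, k4me1, k27ac = [], [], [], []
    for iv in tf_a_ivs:
        s = state_of[iv.name]
        if s in ("active_k4me3", "bivalent"):
            k4me3.append(GenomicInterval(iv.chrom, iv.start - MARK_PAD,
                                         iv.end + MARK_PAD))
        if s in ("bivalent", "repressive_k27me3"):
            k27me3.append(GenomicInterval(iv.chrom, iv.start - MARK_PAD,
                                          iv.end + MARK_PAD))
    for iv in se_list:  # SEs carry the active-enhancer marks
        k4me1.append(replace(iv, name="."))
        k27ac.append(replace(iv, name="."))
    for iv in te_list:
        cls = te_classes[iv.name]
        k4me1.append(replace(iv, name="."))
        if cls == "active":
            k27ac.append(replace(iv, name="."))
        elif cls == "poised":
            k27me3.append(replace(iv, name="."))

    def _mark_set(label, ivs):
        ivs = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return PeakSet(label, [replace(iv, name=f"{label}_{i + 1}")
                               for i, iv in enumerate(ivs)])

    marks = {
        "h3k4me3": _mark_set("h3k4me3", k4me3),
        "h3k27me3": _mark_set("h3k27me3", k27me3),
        "h3k4me1": _mark_set("h3k4me1", k4me1),
        "h3k27ac": _mark_set("h3k27ac", k27ac),
    }

    # --- coverage tracks -----------------------------------------------------
    se_amp = config.te_amplitude * config.se_te_signal_fold
    med1_bumps = [(iv.chrom, iv.start, iv.end, se_amp) for iv in se_list] + \
                 [(iv.chrom, iv.start, iv.end, config.te_amplitude) for iv in te_list]
    tfa_bumps = med1_bumps + [(iv.chrom, iv.start, iv.end, config.tf_amplitude)
                              for iv in tf_a_ivs]
    med1_track = simulate_region_coverage(med1_bumps, noise=config.coverage_noise,
                                          bin_size=config.coverage_bin, rng=rng)
    tfa_track = simulate_region_coverage(tfa_bumps, noise=config.coverage_noise,
                                         bin_size=config.coverage_bin, rng=rng)

    # --- interactions --------------------------------------------------------
    tf_free_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.gene_id not in prom_gene_ids:
            tf_free_by_chrom.setdefault(g.chrom, []).append(g)
    prom_genes = [genes[i] for i in prom_gene_idx]
    free_se = [iv for iv in se_list if iv.name not in tf_bound_se]
    tf_bound_se_ivs = [se_by_name[n] for n in tf_bound_se]
    other_tf_cycle = other_tf_peaks

    specs: list[tuple[str, bool]] = (
        [("promoter_promoter", True)] * m_pp +
        [("promoter_promoter", False)] * (n_pp - m_pp) +
        [("promoter_enhancer", True)] * m_pe +
        [("promoter_enhancer", False)] * (n_pe - m_pe) +
        [("promoter_other", True)] * m_po +
        [("promoter_other", False)] * (n_po - m_po)
    )
    counters = {"pp_m": 0, "pp_n": 0, "pe_m": 0, "pe_n": 0, "po_m": 0,
                "po_n": 0, "bait": {c: 0 for c in chroms}}
    calls: list[InteractionCall] = []
    truth_int: dict[str, dict] = {}
    nonmed_pp_seen = 0
    for spec_i, (iclass, mediated) in enumerate(specs):
        subclass = None
        if iclass == "promoter_promoter":
            if mediated:
                g = prom_genes[counters["pp_m"] % len(prom_genes)]
                counters["pp_m"] += 1
            else:
                pool = tf_free_by_chrom[chroms[counters["pp_n"] % n_chrom]]
                g = pool[(counters["pp_n"] * 7) % len(pool)]
                counters["pp_n"] += 1
            oe = GenomicInterval(g.chrom, g.tss - 500, g.tss + 500)
            oe_gene = g.gene_id
        elif iclass == "promoter_enhancer":
            if mediated:
                iv = tf_bound_se_ivs[counters["pe_m"] % len(tf_bound_se_ivs)]
                c = iv.midpoint
                oe = GenomicInterval(iv.chrom, c - 500, c + 500)
                subclass = "super"
                counters["pe_m"] += 1
            else:
                j = counters["pe_n"]
                pool = te_list + free_se
                iv = pool[j % len(pool)]
                oe = GenomicInterval(iv.chrom, iv.start + 100, iv.start + 700)
                subclass = "super" if iv.name.startswith("se") \
                    else te_classes[iv.name]
                counters["pe_n"] += 1
            oe_gene = None
        else:
            if mediated:
                p = other_tf_cycle[counters["po_m"] % len(other_tf_cycle)]
                oe = GenomicInterval(p.chrom, p.start - 300, p.end + 300)
                counters["po_m"] += 1
            else:
                oe = po_anchors[counters["po_n"]]
                counters["po_n"] += 1
            oe_gene = None

        bait_chrom = oe.chrom
        if iclass == "promoter_promoter" and not mediated:
            nonmed_pp_seen += 1
            if nonmed_pp_seen % 25 == 0:  # sprinkle inter-chromosomal pairs
                bait_chrom = chroms[(chroms.index(oe.chrom) + 1) % n_chrom]
        pool = tf_free_by_chrom[bait_chrom]
        bi = counters["bait"][bait_chrom]
        bait_gene = pool[bi % len(pool)]
        if oe_gene is not None and bait_gene.gene_id == oe_gene:
            bi += 1
            bait_gene = pool[bi % len(pool)]
        counters["bait"][bait_chrom] = bi + 1
        bait = GenomicInterval(bait_gene.chrom, bait_gene.tss - 1000,
                               bait_gene.tss + 1000)
        score = float(rng.uniform(5, 15))
        calls.append(InteractionCall(bait=bait, bait_genes=(bait_gene.gene_id,),
                                     other_end=oe, score=round(score, 3)))
        truth_int[f"int_{spec_i + 1:05d}"] = {
            "iclass": iclass, "enh_subclass": subclass, "mediated": mediated,
        }

    # --- DE table ------------------------------------------------------------
    if config.n_de_genes < config.n_de_up + config.n_de_down:
        raise SimError("n_de_genes smaller than planted up+down counts")
    de_ids = [g.gene_id for g in genes][:config.n_de_genes]
    de_ids += [f"x{i + 1:04d}" for i in range(config.n_de_genes - len(de_ids))]
    perm_de = rng.permutation(config.n_de_genes)
    de_status = {}
    for r, i in enumerate(perm_de):
        if r < config.n_de_up:
            de_status[de_ids[i]] = "up"
        elif r < config.n_de_up + config.n_de_down:
            de_status[de_ids[i]] = "down"
        else:
            de_status[de_ids[i]] = "ns"
    de_rows = []
    for gid in de_ids:
        status = de_status[gid]
        if status == "up":
            fc = float(rng.uniform(1.4, 3.0))
            p = float(rng.uniform(1e-6, 0.04))
        elif status == "down":
            fc = 1.0 / float(rng.uniform(1.4, 3.0))
            p = float(rng.uniform(1e-6, 0.04))
        elif rng.random() < 0.5:  # ns via small effect
            fc = float(rng.uniform(0.85, 1.15))
            p = float(rng.uniform(0.0, 1.0))
        else:  # ns via non-significant p
            fc = float(rng.uniform(0.5, 2.0))
            p = float(rng.uniform(0.06, 0.99))
        de_rows.append((gid, round(fc, 6), format(p, ".6g")))

    # --- write the bundle ----------------------------------------------------
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _p(key, filename):
        paths[key] = outdir / filename
        return paths[key]

    sizes.write(_p("chrom_sizes", "chrom.sizes"))
    write_gene_table(genes, _p("genes", "genes.tsv"))
    tf_a.write_bed(_p("tf_a", "tf_a.bed"))
    tf_b.write_bed(_p("tf_b", "tf_b.bed"))
    for key, ps in marks.items():
        ps.write_bed(_p(key, f"{key}.bed"))
    PeakSet("SE", se_list).write_bed(_p("se", "se.bed"))
    PeakSet("TE", te_list).write_bed(_p("te", "te.bed"))
    med1_track.write_bedgraph(_p("med1_track", "med1.bedgraph"))
    tfa_track.write_bedgraph(_p("tfa_track", "tfa.bedgraph"))
    write_interactions(calls, _p("interactions", "interactions.tsv"))
    with open(_p("de_table", "de.tsv"), "w") as fh:
        fh.write("gene_id\tfold_change\tp_value\n")
        for gid, fc, p in de_rows:
            fh.write(f"{gid}\t{fc}\t{p}\n")

    feature_counts = {"promoter": n_prom, "gene_body": n_body, "intergenic": n_int}
    iclass_counts = {"promoter_promoter": n_pp, "promoter_enhancer": n_pe,
                     "promoter_other": n_po}
    n = config.n_tf_peaks
    manifest = {
        "schema_version": 1,
        "config": asdict(config),
        "chrom_sizes": dict(sizes),
        "files": {k: v.name for k, v in paths.items()},
        "peaks": {p["name"]: {"state": state_of[p["name"]],
                              "feature": p["feature"],
                              "cobound": p["name"] in cobound}
                  for p in peaks},
        "state_counts": state_counts,
        "state_fractions": {s: state_counts[s] / n for s in STATE_NAMES},
        "feature_counts": feature_counts,
        "feature_fractions": {k: v / n for k, v in feature_counts.items()},
        "cobind": {
            "fraction_a": len(cobound) / n,
            "n_cobound": len(cobound),
            "by_state": dict(config.cobind_by_state),
        },
        "enhancer_classes": {**{iv.name: "super" for iv in se_list},
                             **te_classes},
        "tf_bound_se": tf_bound_se,
        "se_genes": se_gene_truth,
        "interactions": truth_int,
        "interaction_class_counts": iclass_counts,
        "interaction_class_fractions": {k: v / config.n_interactions
                                        for k, v in iclass_counts.items()},
        "mediated_count": m_pp + m_pe + m_po,
        "mediated_fraction": (m_pp + m_pe + m_po) / config.n_interactions,
        "de_status": de_status,
        "de_counts": {"up": config.n_de_up, "down": config.n_de_down,
                      "ns": config.n_de_genes - config.n_de_up - config.n_de_down},
        "tracks": {
            "med1": {"se_amplitude": se_amp, "te_amplitude": config.te_amplitude,
                     "fold": config.se_te_signal_fold,
                     "total_signal": med1_track.total_signal},
            "tfa": {"tf_amplitude": config.tf_amplitude,
                    "total_signal": tfa_track.total_signal},
        },
        "zones": zone_info,
    }
    manifest_path = _p("manifest", "manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return SimBundle(directory=outdir, paths=paths, manifest=manifest)


def load_bundle(directory: str | Path) -> SimBundle:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    paths = {k: directory / v for k, v in manifest["files"].items()}
    return SimBundle(directory=directory, paths=paths, manifest=manifest)


_DEGRADABLE = ("tf_a", "tf_b", "h3k4me3", "h3k27me3", "h3k4me1", "h3k27ac",
               "se", "te")


def degrade(
    bundle: SimBundle,
    jitter_bp: int = 0,
    dropout: float = 0.0,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SimBundle:
    """Robustness fixture: jitter peak positions and drop entries at random.

    Every interval in the BED peak files is shifted by a uniform offset in
    ``[-jitter_bp, +jitter_bp]`` (length preserved, clipped to the
    chromosome) and retained with probability ``1 - dropout``.  The copied
    manifest records the dropped entity names per file.  With
    ``jitter_bp = 0, dropout = 0`` the degraded bundle equals the original.
    """
    from .core import read_bed

    if not 0 <= dropout < 1:
        raise ValidationError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir) if outdir is not None else \
        bundle.directory.with_name(bundle.directory.name + "_degraded")
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = ChromSizes(bundle.manifest["chrom_sizes"])
    dropped: dict[str, list[str]] = {}
    new_paths = {}
    for key, src in bundle.paths.items():
        dst = outdir / src.name
        if key in _DEGRADABLE:
            ps = read_bed(src, dialect="bed6")
            kept = []
            dropped[key] = []
            for iv in ps:
                if dropout > 0 and rng.random() < dropout:
                    dropped[key].append(iv.name)
                    continue
                if jitter_bp > 0:
                    off = int(rng.integers(-jitter_bp, jitter_bp + 1))
                    lo, hi = 0, sizes[iv.chrom] - iv.length
                    s = min(max(iv.start + off, lo), hi)
                    iv = replace(iv, start=s, end=s + iv.length)
                kept.append(iv)
            PeakSet(ps.label, kept).write_bed(dst)
        elif key == "manifest":
            continue
        else:
            shutil.copyfile(src, dst)
        new_paths[key] = dst
    manifest = json.loads(json.dumps(bundle.manifest))  # deep copy
    manifest["degraded"] = {"jitter_bp": jitter_bp, "dropout": dropout,
                            "seed": seed, "dropped": dropped}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    new_paths["manifest"] = mpath
    return SimBundle(directory=outdir, paths=new_paths, manifest=manifest)
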