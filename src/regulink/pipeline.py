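"""Stage orchestration: run the full analysis from a config and emit a report.

Stages (dependency order): ``classify``, ``annotate``, ``profile``,
``enhancers``, ``cobind`` (needs classify), ``interactions`` (needs
enhancers), ``de`` (needs classify + annotate).  Requesting a stage without
its dependencies is an error raised before anything executes.  Reruns with
the same config and inputs are byte-identical: one seeded RNG namespace per
stage, no timestamps, JSON with sorted keys.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .cobinding import conditional_fraction, intersect_peaksets, overlap_ci
from .core import (
    ChromSizes,
    PeakSet,
    ValidationError,
    read_bed,
    read_bedgraph,
    read_gene_table,
)
from .enhancers import assign_se_genes, classify_enhancers, write_class_bed
from .expression import call_de, class_de_summary, geneset_overlap, read_de_table
from .interactions import (
    classify_interactions,
    factor_enrichment_in_mediated,
    peaks_at_interactions,
    read_interactions,
)
from .peak_state import (
    STATES,
    annotate_features,
    assign_target_genes,
    classify_states,
    promoter_regions,
    write_state_table,
)
from .signal_density import compare_density, metaprofile, region_density, write_profile_tsv

__all__ = ["RunConfig", "PipelineError", "STAGE_ORDER", "run_pipeline"]

STAGE_ORDER = ("classify", "annotate", "profile", "enhancers", "cobind",
               "interactions", "de")
STAGE_DEPS = {
    "cobind": ("classify",),
    "interactions": ("enhancers",),
    "de": ("classify", "annotate"),
}

INPUT_KEYS = ("chrom_sizes", "genes", "tf_a", "tf_b", "h3k4me3", "h3k27me3",
              "h3k4me1", "h3k27ac", "se", "te", "med1_track", "tfa_track",
              "interactions", "de_table")


class PipelineError(ValidationError):
    """Configuration or stage-dependency problem."""


@dataclass
class RunConfig:
    paths: dict[str, str]
    out_dir: str
    promoter_halfwidth: int = 3000
    fc_threshold: float = 1.3
    p_threshold: float = 0.05
    n_draws: int = 100
    seed: int = 0
    min_overlap_bp: int = 1
    profile_radius: int = 2000
    profile_bin: int = 50
    se_gene_max_distance: int = 100_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_bundle(cls, bundle, out_dir: str | Path, **overrides) -> "RunConfig":
        """Point a config at a synthetic study bundle (see `regulink.simulate`)."""
        paths = {k: str(v) for k, v in bundle.paths.items() if k in INPUT_KEYS}
        return cls(paths=paths, out_dir=str(out_dir), **overrides)

    def validate(self, stages: Sequence[str]) -> None:
        needed = set()
        stage_inputs = {
            "classify": ("tf_a", "h3k4me3", "h3k27me3"),
            "annotate": ("tf_a", "genes", "chrom_sizes"),
            "profile": ("tf_a", "tfa_track", "med1_track", "se", "te"),
            "enhancers": ("se", "te", "h3k27ac", "h3k4me1", "h3k27me3", "genes"),
            "cobind": ("tf_a", "tf_b", "se", "chrom_sizes"),
            "interactions": ("interactions", "genes", "tf_a", "tf_b"),
            "de": ("de_table",),
        }
        for st in stages:
            needed.update(stage_inputs[st])
        missing = [k for k in sorted(needed) if k not in self.paths]
        if missing:
            raise PipelineError(f"config missing input paths: {missing}")
        absent = [k for k in sorted(needed) if not Path(self.paths[k]).exists()]
        if absent:
            raise PipelineError(
                f"referenced input files do not exist: "
                f"{[self.paths[k] for k in absent]}"
            )
        if self.promoter_halfwidth <= 0 or self.n_draws < 2:
            raise PipelineError("promoter_halfwidth must be > 0 and n_draws >= 2")
        if not (0 < self.p_threshold <= 1) or self.fc_threshold <= 0:
            raise PipelineError("bad DE thresholds")


class _Context:
    """Lazily loaded inputs shared between stages."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self._cache: dict[str, object] = {}
        self.state_calls = None
        self.annotations = None
        self.targets = None
        self.enh_calls = None

    def sizes(self) -> ChromSizes:
        return self._get("chrom_sizes", lambda p: ChromSizes.read(p))

    def genes(self):
        return self._get("genes", read_gene_table)

    def peaks(self, key: str) -> PeakSet:
        return self._get(key, lambda p: read_bed(p, dialect="bed6", label=key))

    def track(self, key: str):
        return self._get(key, read_bedgraph)

    def _get(self, key, loader):
        if key not in self._cache:
            self._cache[key] = loader(self.cfg.paths[key])
        return self._cache[key]


def _stage_classify(ctx: _Context, out: Path) -> dict:
    cfg = ctx.cfg
    calls, summary = classify_states(
        ctx.peaks("tf_a"), ctx.peaks("h3k4me3"), ctx.peaks("h3k27me3"),
        min_overlap_bp=cfg.min_overlap_bp,
    )
    ctx.state_calls = calls
    for state in STATES:
        subset = PeakSet(state, (c.peak for c in calls if c.state == state))
        subset.write_bed(out / f"tf_a_state_{state}.bed")
    return {"n": summary.n, "counts": summary.counts,
            "fractions": summary.fractions}


def _stage_annotate(ctx: _Context, out: Path) -> dict:
    cfg = ctx.cfg
    peaks = ctx.peaks("tf_a")
    annotations, summary = annotate_features(
        peaks, ctx.genes(), scheme="three_way",
        halfwidth=cfg.promoter_halfwidth, sizes=ctx.sizes(),
        min_overlap_bp=cfg.min_overlap_bp,
    )
    ctx.annotations = annotations
    ctx.targets = assign_target_genes(peaks, ctx.genes(),
                                      halfwidth=cfg.promoter_halfwidth,
                                      sizes=ctx.sizes())
    if ctx.state_calls is not None:
        write_state_table(ctx.state_calls, annotations, out / "tf_a_annotated.tsv")
    else:
        with open(out / "tf_a_annotated.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tname\tcategory\tgenes\n")
            for ann in annotations:
                iv = ann.peak
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                         f"{ann.category}\t{','.join(ann.assigned_genes)}\n")
    return {"n": summary.n, "counts": summary.counts,
            "percentages": summary.percentages,
            "n_target_genes": len(ctx.targets.gene_to_peaks)}


def _stage_profile(ctx: _Context, out: Path) -> dict:
    cfg = ctx.cfg
    profile = metaprofile(ctx.track("tfa_track"), ctx.peaks("tf_a"),
                          radius=cfg.profile_radius, bin_size=cfg.profile_bin,
                          sizes=ctx.sizes())
    write_profile_tsv(profile, out / "tfa_metaprofile.tsv")
    med1 = ctx.track("med1_track")
    dens_se = region_density(med1, ctx.peaks("se"))
    dens_te = region_density(med1, ctx.peaks("te"))
    with open(out / "med1_density.tsv", "w") as fh:
        fh.write("set\tchrom\tstart\tend\tname\tdensity\n")
        for label, dens in (("SE", dens_se), ("TE", dens_te)):
            for d in dens:
                iv = d.region
                fh.write(f"{label}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                         f"{format(d.density, '.10g')}\n")
    cmp_ = compare_density(dens_se, dens_te)
    return {"profile_bins": len(profile.positions),
            "profile_peak_value": float(profile.values.max()),
            "median_se_density": cmp_.median_a,
            "median_te_density": cmp_.median_b,
            "se_te_fold": cmp_.fold,
            "rank_sum_p": cmp_.p_value,
            "n_se": cmp_.n_a, "n_te": cmp_.n_b}


def _stage_enhancers(ctx: _Context, out: Path) -> dict:
    cfg = ctx.cfg
    se, te = ctx.peaks("se"), ctx.peaks("te")
    regions = PeakSet("enhancer_regions", list(se) + list(te))
    calls, counts = classify_enhancers(regions, se, ctx.peaks("h3k27ac"),
                                       ctx.peaks("h3k4me1"), ctx.peaks("h3k27me3"))
    ctx.enh_calls = calls
    write_class_bed(calls, out / "enhancer_classes.bed")
    se_genes = assign_se_genes(se, ctx.genes(),
                               max_distance=cfg.se_gene_max_distance)
    with open(out / "se_genes.tsv", "w") as fh:
        fh.write("se\tgene_id\tdistance\ttie\n")
        for name in sorted(se_genes):
            a = se_genes[name]
            fh.write(f"{name}\t{a.gene_id}\t{a.distance}\t{int(a.tie)}\n")
    ctx._cache["se_gene_map"] = se_genes
    return {"class_counts": counts, "n_se_genes_assigned": len(se_genes)}


def _stage_cobind(ctx: _Context, out: Path) -> dict:
    cfg = ctx.cfg
    tf_a, tf_b = ctx.peaks("tf_a"), ctx.peaks("tf_b")
    co = intersect_peaksets(tf_a, tf_b)
    co.co_set.write_bed(out / "cobinding_sites.bed")
    strata = {}
    for state in STATES:
        idx = [i for i, c in enumerate(ctx.state_calls) if c.state == state]
        strata[state] = tf_a.subset(idx, label=state)
    cond = conditional_fraction(strata, tf_b)
    ci = overlap_ci(tf_a, ctx.peaks("se"), ctx.sizes(), n_draws=cfg.n_draws,
                    seed=cfg.seed)
    ci.to_json(out / "tf_a_se_overlap_ci.json")
    return {
        "fraction_a": co.fraction_a, "fraction_b": co.fraction_b,
        "n_a": co.n_a, "n_b": co.n_b, "n_cobound": len(co.co_set),
        "conditional_fractions": cond.fractions,
        "conditional_counts": {k: list(v) for k, v in cond.counts.items()},
        "pooled_fraction": cond.pooled_fraction,
        "se_overlap_ci": {"observed": ci.observed, "ci_low": ci.ci_low,
                          "ci_high": ci.ci_high, "empirical_p": ci.empirical_p,
                          "n_draws": ci.n_draws, "seed": ci.seed},
    }


def _stage_interactions(ctx: _Context, out: Path) -> dict:
    cfg = ctx.cfg
    calls = read_interactions(ctx.cfg.paths["interactions"])
    promoters = promoter_regions(ctx.genes(), halfwidth=cfg.promoter_halfwidth,
                                 sizes=ctx.sizes())
    tf_a, tf_b = ctx.peaks("tf_a"), ctx.peaks("tf_b")
    classified, counts = classify_interactions(
        calls, promoters, ctx.enh_calls, tf_sets={"tf_a": tf_a, "tf_b": tf_b},
    )
    n = len(classified)
    mediated, mediated_fraction = peaks_at_interactions(classified, tf_a,
                                                        where="either")
    enrich = factor_enrichment_in_mediated(classified, mediated, tf_b)
    with open(out / "interactions_classified.tsv", "w") as fh:
        fh.write("bait_chrom\tbait_start\tbait_end\tbait_genes\toe_chrom\t"
                 "oe_start\toe_end\tscore\tclass\tenh_subclass\t"
                 "inter_chromosomal\ttf_a_anchor\n")
        for c in classified:
            i = c.interaction
            fh.write(
                f"{i.bait.chrom}\t{i.bait.start}\t{i.bait.end}\t"
                f"{';'.join(i.bait_genes)}\t{i.other_end.chrom}\t"
                f"{i.other_end.start}\t{i.other_end.end}\t{format(i.score, 'g')}\t"
                f"{c.iclass}\t{c.enh_subclass or '.'}\t{int(i.inter_chromosomal)}\t"
                f"{int(c.tf_at_bait.get('tf_a', False) or c.tf_at_other_end.get('tf_a', False))}\n"
            )
    subclass_counts: dict[str, int] = {}
    for c in classified:
        if c.enh_subclass is not None:
            subclass_counts[c.enh_subclass] = subclass_counts.get(c.enh_subclass, 0) + 1
    return {
        "n": n, "class_counts": counts,
        "class_fractions": {k: v / n for k, v in counts.items()},
        "enh_subclass_counts": subclass_counts,
        "mediated_count": len(mediated),
        "mediated_fraction": mediated_fraction,
        "tf_b_enrichment": {
            "fraction_mediated": enrich.fraction_mediated,
            "fraction_all": enrich.fraction_all,
            "ratio": enrich.ratio, "p_value": enrich.p_value,
        },
    }


def _stage_de(ctx: _Context, out: Path) -> dict:
    cfg = ctx.cfg
    table = read_de_table(cfg.paths["de_table"])
    records, counts = call_de(table, fc_threshold=cfg.fc_threshold,
                              p_threshold=cfg.p_threshold)
    with open(out / "de_status.tsv", "w") as fh:
        fh.write("gene_id\tfold_change\tp_value\tstatus\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{format(r.fold_change, 'g')}\t"
                     f"{format(r.p_value, 'g')}\t{r.status}\n")
    gene_sets: dict[str, set[str]] = {"tf_targets": set(ctx.targets.gene_to_peaks)}
    if ctx.state_calls is not None and ctx.annotations is not None:
        by_state: dict[str, set[str]] = {s: set() for s in STATES}
        for call, peak_genes in zip(
            ctx.state_calls,
            (ctx.targets.peak_to_genes.get(i, ())
             for i in range(len(ctx.state_calls))),
        ):
            by_state[call.state].update(peak_genes)
        for s in STATES:
            gene_sets[f"targets_{s}"] = by_state[s]
    summaries = class_de_summary(gene_sets, records)
    result = {
        "n": counts.n, "counts": {"up": counts.n_up, "down": counts.n_down,
                                  "ns": counts.n_ns},
        "gene_sets": {label: asdict(s) for label, s in sorted(summaries.items())},
    }
    se_gene_map = ctx._cache.get("se_gene_map")
    if se_gene_map:
        down = {r.gene_id for r in records if r.status == "down"}
        se_genes = {a.gene_id for a in se_gene_map.values()}
        k, p = geneset_overlap(se_genes, down, universe_size=counts.n)
        result["se_down_overlap"] = {"n_overlap": k, "p": p,
                                     "n_se_genes": len(se_genes),
                                     "n_down": len(down)}
    return result


_STAGE_FN = {
    "classify": _stage_classify,
    "annotate": _stage_annotate,
    "profile": _stage_profile,
    "enhancers": _stage_enhancers,
    "cobind": _stage_cobind,
    "interactions": _stage_interactions,
    "de": _stage_de,
}


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute the requested stages in dependency order and write report.json."""
    stages = list(STAGE_ORDER) if stages is None else list(stages)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    requested = set(stages)
    for st in stages:
        missing = [d for d in STAGE_DEPS.get(st, ()) if d not in requested]
        if missing:
            raise PipelineError(f"stage {st!r} requires {missing}")
    config.validate(stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx = _Context(config)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    for st in STAGE_ORDER:
        if st not in requested:
            continue
        try:
            report["stages"][st] = _STAGE_FN[st](ctx, out)
        except Exception:
            report["stages"][st] = {"failed": True}
            (out / "report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n")
            raise
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
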