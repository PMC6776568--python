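# regulink

Integrative regulatory-genomics analysis for the question: *does a
transcription factor act as an activator through super-enhancers?*  The
package links a factor's ChIP-seq peaks to chromatin state, genomic
compartment, enhancer class, 3D promoter contacts, and knockdown expression
changes — the evidence chain used to argue that a nominally repressive factor
(e.g. a Polycomb PRC1.6 subunit in mouse embryonic stem cells) in fact
activates pluripotency and proliferation genes via super-enhancer-dependent
chromatin interactions.

It is a library first (importable API plus `examples/` scripts), with a thin
`regulink` command-line wrapper for running whole pipelines on file bundles.

## What it computes

Given TF and histone-mark peak sets (BED), a gene table, coverage tracks
(bedGraph), SE/TE region lists, promoter-capture interaction calls, and a
per-gene differential-expression table:

- **Chromatin-state classification.** Each TF peak is called
  *active* (H3K4me3 only), *bivalent* (H3K4me3 + H3K27me3),
  *repressive* (H3K27me3 only), or *unmarked*, by ≥1 bp overlap.
- **Compartment annotation.** Promoter (TSS ± 3 kb) > gene body > intergenic,
  with target genes assigned through the promoter-window rule.
- **Signal density.** Peak-centred metaprofiles and per-region density
  d = (Σ signal / N_total × 10⁶) / L in reads per million per base, with the
  SE vs TE contrast summarised by the median fold and a two-sided Wilcoxon
  rank-sum test.
- **Co-binding statistics.** Fraction of factor-A peaks overlapped by
  factor B, stratified by chromatin state, and an empirical 95% confidence
  interval for any overlap count from *n* random draws (uniform re-placement
  of the query intervals; percentile interval over the null counts;
  p = (1 + #{draws ≥ obs}) / (n + 1)).
- **Interaction classification.** Promoter-capture calls become
  promoter-promoter, promoter-enhancer (with enhancer subclass:
  super / active / intermediate / poised), or promoter-other, and are flagged
  *mediated* when the factor binds an anchor.
- **Knockdown DE linkage.** A gene is up (down) when fold change > 1.3
  (< 1/1.3) with p < 0.05, both strict; gene-set enrichment uses the
  one-sided hypergeometric tail.
- **Synthetic studies.** `simulate_study` writes a complete miniature study
  (3 × 10 Mb genome, 300 genes, 2000 TF peaks, marks, SE/TE lists, coverage,
  500 interactions, a 1000-gene DE table) with every planted label recorded
  in a ground-truth manifest, so each stage is testable exactly.
  `stitch_and_rank` additionally offers ROSE-style SE calling (stitch within
  12.5 kb, rank by signal, cut at the tangent point of slope (max−min)/n).

## Worked example

```sh
python examples/01_simulate_and_classify.py
```

```text
2000 TF peaks
  active_k4me3        50.0%   (planted 50%)
  bivalent            20.0%   (planted 20%)
  repressive_k27me3   20.0%   (planted 20%)
  unmarked            10.0%   (planted 10%)
genomic distribution (promoter window +-3 kb):
  promoter      1.0%
  gene_body    29.0%
  intergenic   70.0%
```

Half the factor's peaks sit in active chromatin and 70% are intergenic — the
profile of an enhancer-associated activator rather than a promoter-bound
repressor.  `examples/02_se_te_density.py` then shows the coactivator-density
contrast:

```text
median SE density 3.123 / median TE density 1.036  (per million per bp)
fold = 3.015, rank-sum p = 2.87e-11 (n = 30 SE vs 30 TE)
```

The fold recovers the planted 3× amplitude ratio under Poisson noise, and the
rank-sum test confirms that super-enhancer signal dominates.  The remaining
examples cover co-binding with the resampling CI, interaction classification
and per-gene contact queries, and the knockdown DE join.

Equivalent shell usage:

```sh
regulink simulate --seed 1 --out study/
regulink run --bundle study/ --out results/ --seed 1
```

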