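"""Apply the knockdown DE rule and join it onto peak-derived gene sets.

A gene is called up (down) when its knockdown/control fold change is strictly
above 1.3 (below 1/1.3) with p strictly below 0.05.  The hypergeometric tail
asks whether SE-associated genes are enriched among the downregulated set.
"""

import tempfile

from regulink import (
    ChromSizes, SimConfig, assign_se_genes, assign_target_genes, call_de,
    class_de_summary, geneset_overlap, read_bed, read_de_table,
    read_gene_table, simulate_study,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = simulate_study(SimConfig(seed=1), tmp)
    genes = read_gene_table(bundle.paths["genes"])
    sizes = ChromSizes.read(bundle.paths["chrom_sizes"])
    records, counts = call_de(read_de_table(bundle.paths["de_table"]))
    targets = assign_target_genes(read_bed(bundle.paths["tf_a"]), genes,
                                  sizes=sizes)
    se_genes = {a.gene_id for a in
                assign_se_genes(read_bed(bundle.paths["se"]), genes).values()}
    summary = class_de_summary({"tf_targets": targets.target_genes(),
                                "se_genes": se_genes}, records)
    down = {r.gene_id for r in records if r.status == "down"}
    k, p = geneset_overlap(se_genes, down, universe_size=counts.n)

print(f"DE calls over {counts.n} genes: {counts.n_up} up, "
      f"{counts.n_down} down, {counts.n_ns} ns")
for label, s in summary.items():
    print(f"  {label:<11} n={s.n:3d} measured={s.n_measured:3d} "
          f"down={s.frac_down:.1%} up={s.frac_up:.1%}")
print(f"SE-gene / downregulated overlap: {k} genes, hypergeometric p = {p:.3g}")
# The 120/80 up/down counts are the planted truth.  On this null bundle the
# SE genes are not preferentially downregulated, so p is unremarkable.
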