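"""Classify promoter-capture interactions and query one gene's contacts.

Every other end is tested against promoters first (promoter-promoter), then
against classified enhancer regions (promoter-enhancer, carrying the
enhancer subclass), else it is promoter-other.  "Mediated" interactions have
the factor of interest bound at either anchor.
"""

import tempfile

from regulink import (
    ChromSizes, SimConfig, classify_enhancers, classify_interactions,
    gene_interactions, peaks_at_interactions, read_bed, read_gene_table,
    read_interactions, simulate_study, PeakSet,
)
from regulink.peak_state import promoter_regions

with tempfile.TemporaryDirectory() as tmp:
    bundle = simulate_study(SimConfig(seed=1), tmp)
    calls = read_interactions(bundle.paths["interactions"])
    genes = read_gene_table(bundle.paths["genes"])
    sizes = ChromSizes.read(bundle.paths["chrom_sizes"])
    se, te = read_bed(bundle.paths["se"]), read_bed(bundle.paths["te"])
    enh_calls, _ = classify_enhancers(
        PeakSet("regions", list(se) + list(te)), se,
        read_bed(bundle.paths["h3k27ac"]), read_bed(bundle.paths["h3k4me1"]),
        read_bed(bundle.paths["h3k27me3"]))
    classified, counts = classify_interactions(
        calls, promoter_regions(genes, sizes=sizes), enh_calls)
    mediated, frac = peaks_at_interactions(
        classified, read_bed(bundle.paths["tf_a"]), where="either")
    gene = calls[0].bait_genes[0]
    report = gene_interactions(gene, classified)

n = len(classified)
print(f"{n} promoter-associated interactions:")
for cls, k in counts.items():
    print(f"  {cls:<18} {k:4d}  ({k / n:.0%})")
print(f"TF-mediated (factor at an anchor): {len(mediated)} ({frac:.0%})")
print(f"gene {gene}: {len(report)} interaction(s), classes "
      f"{[r.call.iclass for r in report]}, distances "
      f"{[int(r.distance) for r in report]} bp")
# Promoter-promoter contacts dominate (60%), and 40% of all interactions have
# the factor at an anchor - both planted values, recovered exactly.
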