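"""Co-binding of two factors, stratified by chromatin state, with a
shuffled-null 95% confidence interval for an overlap count.

The CI comes from re-placing the query intervals uniformly at random and
reading the 2.5th/97.5th percentiles of the null overlap counts; the
empirical p uses the add-one rule so it is never exactly zero.
"""

import tempfile

from regulink import (
    ChromSizes, SimConfig, classify_states, conditional_fraction,
    intersect_peaksets, overlap_ci, read_bed, simulate_study,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = simulate_study(SimConfig(seed=1), tmp)
    tf_a = read_bed(bundle.paths["tf_a"])
    tf_b = read_bed(bundle.paths["tf_b"])
    sizes = ChromSizes.read(bundle.paths["chrom_sizes"])
    co = intersect_peaksets(tf_a, tf_b)
    calls, _ = classify_states(tf_a, read_bed(bundle.paths["h3k4me3"]),
                               read_bed(bundle.paths["h3k27me3"]))
    strata = {}
    for state in ("active_k4me3", "repressive_k27me3"):
        idx = [i for i, c in enumerate(calls) if c.state == state]
        strata[state] = tf_a.subset(idx, label=state)
    cond = conditional_fraction(strata, tf_b)
    ci = overlap_ci(tf_a, read_bed(bundle.paths["se"]), sizes,
                    n_draws=1000, seed=1)

print(f"co-binding: {co.fraction_a:.1%} of factor A peaks carry factor B")
for state, frac in cond.fractions.items():
    print(f"  {state:<18} {frac:.1%}")
print(f"A-peaks overlapping SEs: observed {ci.observed}, "
      f"null 95% CI [{ci.ci_low:.0f}, {ci.ci_high:.0f}], "
      f"empirical p = {ci.empirical_p:.4f}")
# Factor B prefers A's active-chromatin sites (70% vs 50%) - the conditional
# co-binding asymmetry the pipeline is built to expose.  The CI line shows
# where the observed SE overlap falls relative to random placement.
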