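"""Contrast coactivator signal density at super-enhancers vs typical enhancers.

Densities are reads-per-million-per-base, so the planted 3x amplitude fold
survives library-size normalization; the Wilcoxon rank-sum test quantifies
the separation of the two density distributions.
"""

import tempfile

from regulink import (
    SimConfig, compare_density, read_bed, read_bedgraph, region_density,
    simulate_study,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = simulate_study(SimConfig(seed=1), tmp)
    med1 = read_bedgraph(bundle.paths["med1_track"])
    dens_se = region_density(med1, read_bed(bundle.paths["se"]))
    dens_te = region_density(med1, read_bed(bundle.paths["te"]))

cmp_ = compare_density(dens_se, dens_te)
print(f"median SE density {cmp_.median_a:.3f} / median TE density "
      f"{cmp_.median_b:.3f}  (per million per bp)")
print(f"fold = {cmp_.fold:.3f}, rank-sum p = {cmp_.p_value:.2e} "
      f"(n = {cmp_.n_a} SE vs {cmp_.n_b} TE)")
# The fold sits at ~3 (the planted amplitude ratio, here with Poisson noise),
# and the tiny p-value says SE signal stochastically dominates TE signal.
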