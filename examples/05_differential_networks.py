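"""Testing two cell groups for differential network structure.

Case and control cells share identical marginal expression, but the
case group carries a 10-gene correlated block the control group lacks.
Networks are computed on the pooled cells (construction conditions on
cell type, never on the tested grouping), split by group, and compared
with sLED (localising, with DN-gene extraction) and DISTp (omnibus).
"""

import numpy as np

from loccsn import (
    BlockSpec,
    ExpressionMatrix,
    SimDesign,
    compute_group_networks,
    distp_test,
    simulate_two_groups,
    sled_test,
    threshold_adjacency,
)

design = SimDesign(
    n_cells=(200, 200), n_genes=20,
    blocks_group1=(),  # control: no block
    blocks_group2=(BlockSpec(tuple(range(10)), 0.7),),  # case: block
    seed=5,
)
em = simulate_two_groups(design)

pooled = ExpressionMatrix(
    em.values, em.gene_ids, em.cell_ids,
    cell_type=np.asarray(["all"] * em.n_cells, dtype=object),
)
nets = threshold_adjacency(compute_group_networks(pooled)["all"], alpha=0.05)
labs = np.asarray(em.cell_type)
control = nets.subset_cells(np.flatnonzero(labs == "group1"), "control")
case = nets.subset_cells(np.flatnonzero(labs == "group2"), "case")

sled = sled_test(control, case, mode="csn", n_perm=500, seed=6)
dist = distp_test(control, case, n_perm=500, seed=6)

print(f"sLED-CSN: statistic={sled.statistic:.3f}, p={sled.p_value:.4f}, "
      f"sparsity={sled.sparsity}")
print(f"DN genes (90% of signal): {sled.dn_genes}")
print(f"DISTp:    statistic={dist.statistic:.3f}, p={dist.p_value:.4f}")
# Both tests reject; the DN genes localise the difference to the
# perturbed block (g0..g9) even though no gene differs in mean
# expression between the groups.
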