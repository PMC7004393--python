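"""Enumerate the Elementary Growth States of a minimal self-replicator.

The cell has one internal precursor, two alternative import enzymes and
a ribosome.  At fixed metabolite concentration x and growth rate mu,
the balanced-growth equations are linear in the ribosome-allocation
vector alpha; the nonnegative solutions form a polytope whose vertices
are the Elementary Growth States (EGSs).
"""

import numpy as np

from egmodes import (concentrations_from_allocation, decompose_into_egs,
                     density, enumerate_egs, two_enzyme_model)

model = two_enzyme_model()
x, mu = np.array([0.2]), 0.5

egs_list = enumerate_egs(model, x, mu)
names = model.protein_names
print(f"growth states at x = {x[0]}, mu = {mu}:")
for i, egs in enumerate(egs_list, 1):
    support = ", ".join(names[j] for j in sorted(egs.support))
    print(f"  EGS {i}: support = {{{support}}}, "
          f"alpha = {np.round(egs.alpha, 4)}, |alpha| = {egs.alpha.sum():.4f}")

# every balanced-growth state is a convex mixture of these vertices;
# reconstructing its concentrations always fills the cell volume exactly
mix = 0.3 * egs_list[0].alpha + 0.7 * egs_list[1].alpha
weights = decompose_into_egs(mix, egs_list)
state = concentrations_from_allocation(model, mix, x, mu)
print(f"mixture 0.3/0.7 recovered with weights {np.round(weights, 3)}")
print(f"total volume fraction of the mixed state: "
      f"{density(model, state.x, state.e, state.r):.12f}")
print("(= 1: the constant-density constraint is satisfied identically)")
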