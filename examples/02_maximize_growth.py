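"""Maximise balanced growth rate: vertices win, constraints mix them.

At fixed metabolite concentrations, growth rate mu is feasible iff a
linear program in the allocation vector has a solution, so the maximal
mu is found by feasibility bisection.  The optimum sits at a polytope
vertex — a single Elementary Growth State.  Each extra enzyme-capacity
constraint can force the optimum to blend in (at most) one more state.
"""

import numpy as np

from egmodes import (EnzymeConstraint, concentrations_from_allocation,
                     max_growth_at_fixed_x, two_enzyme_model)

model = two_enzyme_model()   # enzyme 1 is faster (k_cat 12 vs 5)
x = np.array([0.2])
names = model.protein_names

free = max_growth_at_fixed_x(model, x)
print(f"unconstrained: mu_max = {free.mu_max:.6f}, support = "
      f"{sorted(names[j] for j in free.support)}")
print(f"  -> a single growth mode: the faster enzyme plus the ribosome")

# budget scan: more allocatable ribosome never hurts
for lam in (0.2, 0.5, 1.0):
    res = max_growth_at_fixed_x(model, x, lam=lam, decompose=False)
    print(f"budget lambda = {lam}: mu_max = {res.mu_max:.6f}")

# cap the winning enzyme below its optimal level: the optimum becomes a
# mixture of two growth states (one extra state per binding constraint)
state = concentrations_from_allocation(model, free.alpha, x, free.mu_max)
cap = EnzymeConstraint(weights=np.array([1.0, 0.0, 0.0]),
                       cap=0.5 * state.e[0], label="enz1 capacity")
capped = max_growth_at_fixed_x(model, x, constraints=[cap])
print(f"with a binding enzyme-capacity cap: mu_max = {capped.mu_max:.6f}")
print(f"  active constraints: {capped.active_constraints}")
print("  optimal mixture:")
for egs, w in capped.decomposition:
    print(f"    weight {w:.3f} on support "
          f"{sorted(names[j] for j in egs.support)}")
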