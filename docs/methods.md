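# Methods

## Model class and assumptions

`egmodes` treats a population of cells in balanced growth: all
intensive quantities (concentrations) constant, all extensive
quantities growing exponentially at rate μ.  The cell content is an
ideal solution — volume is the ρ/σ-weighted sum of copy numbers — so
concentrations satisfy the unit-density identity Σρx + Σσe + σ_r r = 1
and μ equals the specific volume-production rate.  Catalysis is linear
in the catalyst: v_j = e_j f_j(x) for enzymes, w_j = r α_j g_j(x) for
the ribosome, with all metabolite dependence in the saturation
functions.  This linearity is what makes the balanced-growth equations
linear in the allocation vector α and the whole linear-programming
machinery applicable.  mRNA, transcription and the division cycle are
not modelled; external nutrient and stressor levels are parameters
inside the rate laws, not state variables.

Rate-law kinds shipped: `constant`, `irreversible_mm` (product of
Michaelis–Menten saturations), `reversible_mm` (saturating forward
minus damped saturating reverse term; may be negative), `diffusion`
(k·(x_ext − x), catalyst-free transport), and a multiplicative
non-competitive inhibition factor 1/(1 + x_i/K_I) attachable to any
law.  The registry is extensible by string key.  We deliberately use a
saturating reverse term rather than a raw mass-action ratio so that
evaluation is finite for every x ≥ 0.

## The balanced-growth system

Eliminating e and r from the steady-state conditions gives, at fixed
(x, μ), the linear system B(x, μ) α = μ u_{m+1} with

    B_kj      = ((x_k a_j − P_kj) f_j/μ + x_k b_j + M_kj) g_j,  j ≤ n
    B_k,(n+1) = (x_k b_{n+1} + M_k,(n+1)) g_{n+1}
    B_{m+1}   = (0, …, 0, g_{n+1}),

the last row forcing the ribosome to replicate itself at rate μ.  The
ribosome concentration is recovered as r = μ/D(α) with
D(α) = Σ_{j≤n}(a_j f_j/μ + b_j)α_j g_j + b_{n+1}α_{n+1}g_{n+1}, and
e_j = r α_j g_j/μ.  Any exact solution automatically satisfies the
unit-density identity (ρ-weighted summation of the steady-state
equations); the test suite checks this to 1e-8 on hundreds of random
balanced states, and typically observes machine precision.

**Spontaneous reactions.** Catalyst-free rates s_l(x) (e.g. passive
membrane diffusion of a toxin) contribute d_k = Σ_l S_kl s_l to
metabolite balances and c_s = Σ_l (ρ·S_l) s_l to volume production.
Substituting 1/r = D(α)/(μ − c_s) keeps the system exactly linear: the
row formulas above hold with x_k replaced by
γ_k = (μ x_k − d_k)/(μ − c_s), which reduces to x_k when no
spontaneous reactions exist.  We chose this exact substitution over an
approximate affine treatment because it preserves the polytope
structure unchanged — enumeration, decomposition and all LPs work
identically — and because it is verifiable: the reconstructed states
zero the full dynamical system to machine precision.  It requires
μ > c_s (spontaneous swelling alone is not growth); `build_system`
rejects the contrary case explicitly.

**Zero-concentration metabolites.** A metabolite with x_k = 0 has no
dilution term and its row does not count towards the rank/basis
bookkeeping (such rows can otherwise destroy the generic full-rank
property).  Its mass balance must still hold, however: a row that is
not identically zero is kept as a feasibility condition in the LPs and
as a post-filter in vertex enumeration.  With physically sensible rate
laws — a law consuming metabolite k vanishes at x_k = 0 — these rows
are identically zero and drop out on their own; the distinction only
matters for deliberately idealised kinetics (e.g. constant rate laws),
where ignoring the row would let the optimiser "grow" by consuming an
absent metabolite.

**Row reduction.** Linearly dependent rows are removed greedily on the
augmented matrix [B | rhs] (ribosome row seeded first and always
kept).  A row dependent in B but independent in the augmented sense
marks an inconsistent system; this is recorded (`consistent = False`,
empty polytope) rather than raised.  Default tolerances: residuals
1e-8 absolute, rank decisions 1e-10 relative, support membership
strictly above 1e-9; all configurable at call sites.

## Vertex enumeration and modes

Vertices are enumerated exhaustively: every column subset of size
rank(B_active) containing the ribosome column, solved as a square
system, kept when the basic solution is nonnegative and the full
constraint residual is within tolerance.  Duplicate vertices from
degenerate bases are merged by rounding α to 12 significant digits,
with all bases recorded.  Exhaustive enumeration is exact and, at the
coarse-grained sizes this package targets (n ≲ 15), fast; genome-scale
enumeration is out of scope.  The allocation budget |α| ≤ λ is *not*
part of the polytope here — vertices are intrinsic to the equality
system — and is applied only in the optimisation layer.

Modes are support-equivalence classes of vertices, model-scoped.
Continuation of a nondegenerate vertex (support = basis) holds the
basis fixed and re-solves the square system along a straight path in
(x, μ); because the system is linear in α this one solve *is* the
Newton step of the implicit-function construction.  A basic variable
crossing zero is bracketed by bisection (60 halvings) and reported as
the boundary where the mode ceases to exist.

## Optimisation

At fixed x, the feasible growth rates form an interval reached from
below, so μ_max is found by LP-feasibility bisection: bracket by
doubling (with a geometric scan when the starting guess is infeasible,
since spontaneous volume influx can impose a lower feasibility edge),
then 100 halvings or relative width 1e-8.  Equality rows are
equilibrated, with nonzero right-hand sides normalised to exactly 1 so
solver feasibility tolerances keep their meaning at small μ; every
witness is re-verified against the constraint rows independently of
the solver status.  Enzyme-capacity constraints Σ w_j e_j ≤ C are
rewritten exactly into linear constraints on α via
e_j = α_j g_j·r/μ; the returned optimiser is decomposed into vertices
of the unconstrained polytope with a Carathéodory reduction, giving at
most K+1 states for K extra constraints.  An independent route to the
same number — bisection on "some enumerated vertex fits the budget" —
is used as a cross-check in the tests; the two agree to the bisection
tolerance on every random model tried.

The outer problem over metabolite concentrations has no known
convexity structure, and no global claim is made.  The search is
multistart Nelder–Mead over log10 x (default bounds 10⁻⁴–10⁰, volume
budget Σρx < 1 enforced, concentrations at the lower bound snapped to
exactly zero so boundary optima are reachable).  Candidate starts are
pre-screened by cheap fixed-μ feasibility probes, since an infeasible
start sees only a flat penalty landscape; `extra_starts` lets a
parameter sweep warm-start each level from the previous optimum.  The
whole search is a pure function of the seed.

## EFM bridge

For a vertex with basis D, the precursor-consumption vector φ = M w
appended as a virtual biomass column gives P_φ = [P_D −φ].  When P_φ
has full row rank its nullspace is one-dimensional; the spanning
vector scaled to unit biomass component is the approximating flux
mode, and the vertex's fluxes satisfy P_φ[v; 1] = μx, so v deviates
from the mode by O(μ) (the metabolite-dilution correction).
Rank-deficient P_φ is reported as an error — the approximation
hypothesis genuinely fails there and no fallback is defined.  The
in-mode bound μ_ub is the supply/demand ratio of a building block
consumed by ribosome synthesis (default: the first such metabolite;
the choice is irrelevant exactly when the constant-composition
hypothesis holds), and the explicit allocation α_j(μ) scales all
metabolic fractions by H(x, μ) = const·μ²/(μ_ub − μ) while
α_{n+1} = μ/g_{n+1}.  The model-wide `negligible_dilution` flag drops
the μx_k dilution terms from the metabolite rows, realising the regime
in which these formulas are exact; the tests verify the closed form
against fresh enumeration of the dilution-free system to 1e-6 and the
bound's feasibility bracket to 1e-4.

## Fixtures and the random-model generator

`two_enzyme_model` is the minimal self-replicator: one precursor, two
alternative import enzymes with distinct catalytic constants (so the
growth optimum is unique), Michaelis–Menten translation.
`toxin_model` has four precursors in an anabolic chain, an external
toxin entering by catalyst-free diffusion and inhibiting every
catalyst (K_I = 0.2), and a degrading protein.  All its synthesis
columns share one amino-acid composition, so the constant-composition
regime holds exactly.  The toxin's molar volume is set four orders of
magnitude below the macromolecules' so that passive influx does not
register as growth.  Quantitative parameters of this fixture are the
package's own documented choices, selected once to reproduce the
qualitative stress-response switch; only qualitative behaviour is
asserted about it.

The random generator builds a backbone chain (import → x1 → … → x_m)
plus random alternative routes, building-block costs on a random
metabolite subset always including the chain end, ρ and σ drawn so
synthesis is near volume-conserving (b ≥ 0, markup 1.0–1.4), and
rejection-samples until vertex enumeration certifies a feasible
(x, μ) probe.  Generation is a pure function of the seed and models
serialise byte-identically.  What the synthetic models emulate is the
*structure* of self-fabrication (closed autocatalytic stoichiometry,
saturating kinetics, volume bookkeeping); they do not emulate measured
kinetic constants, realistic network breadth, compartments, or noise —
so passing tests demonstrate correctness of the theory's
implementation, not quantitative prediction for any organism.

## Problem sizes and determinism

The shipped test and acceptance runs use 20–25 random models with
m ≤ 4, n ≤ 6, ~120 random balanced states for the density identity,
9-point μ-grids over two decades for the O(μ) law, and 2–3 toxin
levels with 3 warm-started multistarts (maxiter 100) for the
stress-response switch — sizes at which every check is exact or
resolved far below its tolerance.  All randomness flows from explicit
seeds; identical invocations produce identical outputs.

## Known limitations

- Exhaustive basis enumeration scales combinatorially; no
  double-description or genome-scale path is provided.
- The outer optimisation is a local multistart search; reported optima
  are "best found".
- Degenerate vertices are merged but continuation requires a
  nondegenerate starting vertex.
- Reversible rate laws use a saturating reverse term, not full
  thermodynamic (Haldane) consistency, and no thermodynamic
  feasibility checking is performed.
- The μ_ub/α(μ) formulas are exact only under negligible metabolite
  dilution and constant precursor composition; outside that regime
  they are upper-bound/approximation statements.
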