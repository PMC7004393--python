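"""Growth-rate maximisation under allocation and enzyme-capacity limits.

The central optimisation problem is

    max_{x, alpha} { mu : B(x, mu) alpha = mu u_{m+1},
                          |alpha| <= lambda, alpha >= 0 },

optionally with extra linear enzyme-capacity constraints
``sum_j w_j e_j <= C`` (finite membrane area, compartment volumes...).
Because mu enters B nonlinearly, the problem is solved by *feasibility
bisection*: at fixed x, growth rate mu is feasible iff the linear
program { alpha >= 0, B alpha = mu u, |alpha| <= lambda, constraints }
has a solution, and the set of feasible mu is an interval reached from
below.  The maximal growth rate is attained at a vertex of the
constrained polytope — an Elementary Growth State when no extra
constraints bind, and a convex combination of at most K+1 EGSs when K
extra constraints are added.

The outer problem over metabolite concentrations x is non-convex with
no known structure; a seeded multistart Nelder-Mead search over
log-concentrations reports the best optimum found, with no global
claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog, minimize

from .balance import (RESIDUAL_TOL, build_system, reduce_rows)
from .enumeration import EGS, decompose_into_egs, enumerate_egs, support_of
from .model import WholeCellModel, evaluate_rate_laws, volume_coefficients

__all__ = [
    "EnzymeConstraint",
    "OptimizationResult",
    "SearchConfig",
    "constraint_to_allocation",
    "feasible_at_mu",
    "min_total_allocation",
    "max_growth_at_fixed_x",
    "max_growth_by_enumeration",
    "maximize_growth",
]


@dataclass(frozen=True)
class EnzymeConstraint:
    """A capacity constraint sum_j weights_j e_j <= cap on catalyst
    concentrations (index n+1 = ribosome)."""

    weights: np.ndarray  # (n+1,), >= 0, at least one positive
    cap: float
    label: str = "capacity"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if not np.any(w > 0):
            raise ValueError("constraint needs at least one positive weight")
        if not self.cap > 0:
            raise ValueError("cap must be > 0")

    def evaluate(self, e: np.ndarray, r: float) -> float:
        """sum_j w_j e_j + w_{n+1} r  (compare against cap)."""
        return float(self.weights[:-1] @ e + self.weights[-1] * r)


@dataclass
class OptimizationResult:
    """Outcome of a growth-rate maximisation."""

    mu_max: float
    alpha: Optional[np.ndarray]
    x: np.ndarray
    feasible: bool
    support: frozenset = frozenset()
    active_constraints: List[str] = field(default_factory=list)
    decomposition: List[Tuple[EGS, float]] = field(default_factory=list)
    diagnostics: Dict = field(default_factory=dict)


def constraint_to_allocation(model: WholeCellModel,
                             constraint: EnzymeConstraint,
                             x: Sequence[float],
                             mu: float) -> np.ndarray:
    """Rewrite sum_j w_j e_j <= cap as coefficients c with c . alpha <= 0.

    At balanced growth e_j = alpha_j g_j(x) * r / mu and
    r/mu = (1 - c_s/mu)/D(alpha) with D(alpha) linear in alpha, so the
    capacity constraint becomes linear in alpha:

        sum_{j<=n} (w_j - C'(a_j f_j/mu + b_j)) alpha_j g_j
          + (w_{n+1} - C' b_{n+1}) alpha_{n+1} g_{n+1} <= 0,

    with C' = cap * mu/(mu - c_s)  (= cap without spontaneous reactions).
    """
    if not mu > 0:
        raise ValueError("mu must be > 0")
    x = np.asarray(x, dtype=float)
    fvals, gvals = evaluate_rate_laws(model, x)
    vol = volume_coefficients(model)
    _, c_s = model.spontaneous_production(x)
    cap_eff = constraint.cap * mu / (mu - c_s)
    n = model.n
    coeffs = np.empty(n + 1)
    coeffs[:n] = (constraint.weights[:n]
                  - cap_eff * (vol.a * fvals / mu + vol.b[:n])) * gvals[:n]
    coeffs[n] = (constraint.weights[n] - cap_eff * vol.b[n]) * gvals[n]
    return coeffs


def _allocation_lp(model: WholeCellModel,
                   x: Sequence[float],
                   mu: float,
                   lam: Optional[float],
                   constraints: Sequence[EnzymeConstraint]):
    """Minimise |alpha| over the (constrained) balanced-growth polytope.

    Returns (alpha or None, scipy result).  The minimiser is a vertex of
    the constrained polytope.
    """
    try:
        system = reduce_rows(build_system(model, x, mu))
    except ValueError:
        return None, None
    if not system.consistent:
        return None, None
    rows = system.constraint_rows()
    A_eq = system.B[rows]
    b_eq = system.rhs[rows]
    # row equilibration: harmless rescaling, helps at small/large mu;
    # a nonzero right-hand side is normalised to exactly 1 so solver
    # feasibility tolerances keep their meaning at small mu
    scale = np.where(np.abs(b_eq) > 0, np.abs(b_eq),
                     np.abs(A_eq).max(axis=1))
    scale[scale == 0] = 1.0
    A_eq = A_eq / scale[:, None]
    b_eq = b_eq / scale

    ncols = system.n_cols
    A_ub, b_ub = [], []
    if lam is not None:
        A_ub.append(np.ones(ncols))
        b_ub.append(lam)
    for con in constraints:
        row = constraint_to_allocation(model, con, x, mu)
        rs = np.abs(row).max()
        A_ub.append(row / (rs if rs > 0 else 1.0))
        b_ub.append(0.0)
    res = linprog(c=np.ones(ncols), A_eq=A_eq, b_eq=b_eq,
                  A_ub=np.array(A_ub) if A_ub else None,
                  b_ub=np.array(b_ub) if b_ub else None,
                  bounds=[(0, None)] * ncols, method="highs")
    if not res.success:
        return None, res
    # certify the witness independently of the solver status
    if np.abs(A_eq @ res.x - b_eq).max() > 1e-7:
        return None, res
    return res.x, res


def feasible_at_mu(model: WholeCellModel,
                   x: Sequence[float],
                   mu: float,
                   lam: Optional[float] = None,
                   constraints: Sequence[EnzymeConstraint] = (),
                   ) -> Tuple[bool, Optional[np.ndarray]]:
    """Can the cell grow balanced at rate mu with metabolite levels x?

    Checks LP feasibility of { alpha >= 0, B alpha = mu u,
    |alpha| <= lam, capacity constraints }; the witness, when feasible,
    is a vertex of the constrained polytope (the minimal-|alpha| one).
    """
    if lam is None:
        lam = model.lam
    alpha, _ = _allocation_lp(model, x, mu, lam, constraints)
    if alpha is None:
        return False, None
    if alpha.sum() > lam + 1e-9:
        return False, None
    return True, alpha


def min_total_allocation(model: WholeCellModel,
                         x: Sequence[float],
                         mu: float) -> np.ndarray:
    """The allocation of minimal total ribosome fraction |alpha| at
    (x, mu), ignoring the budget.  A vertex of the polytope, hence an
    EGS.  Raises when the polytope is empty."""
    alpha, res = _allocation_lp(model, x, mu, lam=None, constraints=())
    if alpha is None:
        msg = res.message if res is not None else "system not constructible"
        raise ValueError(f"balanced-growth polytope is empty at mu={mu}: {msg}")
    return alpha


def _caratheodory_reduce(V: np.ndarray, w: np.ndarray,
                         tol: float = 1e-11) -> np.ndarray:
    """Reduce convex weights to an affinely independent support.

    Repeatedly removes a weight using a null vector of the supported
    columns of [V; 1], preserving V w and sum w = 1.
    """
    w = w.copy()
    A = np.vstack([V, np.ones((1, V.shape[1]))])
    while True:
        S = np.nonzero(w > tol)[0]
        if len(S) <= 1:
            break
        sub = A[:, S]
        if np.linalg.matrix_rank(sub, tol=1e-9) == len(S):
            break
        # null vector z: sub @ z = 0
        _, _, vh = np.linalg.svd(sub)
        z = vh[-1]
        steps = [w[S[i]] / z[i] for i in range(len(S)) if z[i] > tol]
        if not steps:
            z = -z
            steps = [w[S[i]] / z[i] for i in range(len(S)) if z[i] > tol]
        t = min(steps)
        w[S] = w[S] - t * z
        w[w < tol] = 0.0
    return w


def max_growth_at_fixed_x(model: WholeCellModel,
                          x: Sequence[float],
                          lam: Optional[float] = None,
                          constraints: Sequence[EnzymeConstraint] = (),
                          mu0: float = 1e-3,
                          rel_tol: float = 1e-8,
                          max_iter: int = 100,
                          decompose: bool = True) -> OptimizationResult:
    """Maximal balanced growth rate at fixed metabolite concentrations.

    Feasibility bisection on mu: the bracket grows by doubling from mu0
    (halving downward if mu0 itself is infeasible), then shrinks to
    relative tolerance.  The returned allocation is the last feasible
    witness, a vertex of the constrained polytope; it is decomposed into
    EGSs of the unconstrained polytope (at most K+1 of them for K extra
    constraints).
    """
    if lam is None:
        lam = model.lam
    x = np.asarray(x, dtype=float)

    def feas(mu: float):
        return feasible_at_mu(model, x, mu, lam, constraints)

    mu = mu0
    ok, alpha = feas(mu)
    if not ok:
        # the feasible set may lie entirely above or below mu0 (e.g. a
        # lower feasibility edge from spontaneous volume influx): scan a
        # geometric grid for any feasible point
        for exponent in range(1, 31):
            for mu_try in (mu0 * 2.0 ** exponent, mu0 * 2.0 ** -exponent):
                ok, alpha = feas(mu_try)
                if ok:
                    mu = mu_try
                    break
            if ok:
                break
        if not ok:
            return OptimizationResult(mu_max=0.0, alpha=None, x=x,
                                      feasible=False,
                                      diagnostics={"reason": "no growth"})
    mu_lo, witness = mu, alpha
    doublings = 0
    while ok and doublings < 60:
        mu_lo, witness = mu, alpha
        mu *= 2.0
        ok, alpha = feas(mu)
        doublings += 1
    mu_hi = mu

    iters = 0
    while (mu_hi - mu_lo) > rel_tol * mu_hi and iters < max_iter:
        mid = 0.5 * (mu_lo + mu_hi)
        ok, alpha = feas(mid)
        if ok:
            mu_lo, witness = mid, alpha
        else:
            mu_hi = mid
        iters += 1

    alpha_star = witness
    support = frozenset(support_of(alpha_star))
    active = [con.label for con in constraints
              if constraint_to_allocation(model, con, x, mu_lo)
              @ alpha_star > -1e-7]
    decomposition: List[Tuple[EGS, float]] = []
    if decompose:
        egs_list = enumerate_egs(model, x, mu_lo)
        if egs_list:
            try:
                V = np.column_stack([s.alpha for s in egs_list])
                w = decompose_into_egs(alpha_star, egs_list, tol=1e-6)
                w = _caratheodory_reduce(V, w)
                decomposition = [(egs_list[i], float(w[i]))
                                 for i in np.nonzero(w > 1e-9)[0]]
            except ValueError:
                pass  # witness may sit just outside hull at bisection tol
    return OptimizationResult(
        mu_max=mu_lo, alpha=alpha_star, x=x, feasible=True,
        support=support, active_constraints=active,
        decomposition=decomposition,
        diagnostics={"iterations": iters, "bracket": (mu_lo, mu_hi),
                     "lam": lam})


def max_growth_by_enumeration(model: WholeCellModel,
                              x: Sequence[float],
                              lam: Optional[float] = None,
                              mu0: float = 1e-3,
                              rel_tol: float = 1e-8,
                              ) -> Tuple[float, Optional[EGS]]:
    """Independent route to the maximal growth rate at fixed x:
    bisection on "some enumerated EGS fits the budget |alpha| <= lam".

    By the vertex-optimality theorem this must agree with
    :func:`max_growth_at_fixed_x` (no extra constraints); it is used as
    a cross-check and for per-mode boundary studies.
    """
    if lam is None:
        lam = model.lam

    def best_egs(mu: float) -> Optional[EGS]:
        try:
            cands = [s for s in enumerate_egs(model, x, mu)
                     if s.alpha.sum() <= lam + 1e-9]
        except ValueError:
            return None
        if not cands:
            return None
        return min(cands, key=lambda s: s.alpha.sum())

    mu, doublings = mu0, 0
    egs = best_egs(mu)
    mu_lo, keeper = 0.0, None
    if egs is not None:
        while egs is not None and doublings < 60:
            mu_lo, keeper = mu, egs
            mu *= 2.0
            egs = best_egs(mu)
            doublings += 1
        mu_hi = mu
    else:
        while egs is None and doublings < 40:
            mu /= 2.0
            egs = best_egs(mu)
            doublings += 1
        if egs is None:
            return 0.0, None
        mu_lo, keeper = mu, egs
        mu_hi = mu * 2.0
    for _ in range(100):
        if (mu_hi - mu_lo) <= rel_tol * mu_hi:
            break
        mid = 0.5 * (mu_lo + mu_hi)
        egs = best_egs(mid)
        if egs is not None:
            mu_lo, keeper = mid, egs
        else:
            mu_hi = mid
    return mu_lo, keeper


@dataclass
class SearchConfig:
    """Configuration of the outer search over metabolite concentrations.

    Bounds are in log10 concentration units and apply to every
    metabolite; the metabolite volume budget sum_k rho_k x_k < 1 is
    enforced on every candidate.  Determinism: the whole search is a
    pure function of `seed`.
    """

    log10_bounds: Tuple[float, float] = (-4.0, 0.0)
    n_starts: int = 6
    seed: int = 0
    maxiter: int = 150
    coarse_rel_tol: float = 1e-4
    final_rel_tol: float = 1e-8


def maximize_growth(model: WholeCellModel,
                    lam: Optional[float] = None,
                    constraints: Sequence[EnzymeConstraint] = (),
                    config: Optional[SearchConfig] = None,
                    extra_starts: Sequence[Sequence[float]] = (),
                    ) -> OptimizationResult:
    """Best balanced growth rate over metabolite concentrations.

    Multistart Nelder-Mead over log10 x, each evaluation being a
    feasibility bisection at fixed x.  Reports the best optimum found;
    the problem has no known convexity structure, so no global claim is
    made.  Deterministic given `config.seed`.

    ``extra_starts`` prepends user-chosen concentration vectors to the
    random starts — useful for warm-starting a parameter sweep from the
    previous optimum (continuation in an environmental parameter).
    """
    if config is None:
        config = SearchConfig()
    if lam is None:
        lam = model.lam
    rng = np.random.default_rng(config.seed)
    lo, hi = config.log10_bounds
    m = model.m

    def clip_volume(x: np.ndarray) -> np.ndarray:
        vol = float(model.rho @ x)
        if vol >= 0.9:
            x = x * (0.9 / vol)
        return x

    def decode(logx: np.ndarray) -> np.ndarray:
        # a metabolite pushed to the lower bound is treated as absent
        # (x_k = 0), making zero-concentration optima reachable
        x = 10.0 ** logx
        x[logx <= lo] = 0.0
        return x

    warm_mu = [1e-3]  # bracket seed carried between evaluations

    def objective(logx: np.ndarray) -> float:
        if np.any(logx < lo - 4) or np.any(logx > hi + 2):
            return 1e6
        x = decode(logx)
        if model.rho @ x >= 1.0:
            return 1e6
        res = max_growth_at_fixed_x(model, x, lam, constraints,
                                    mu0=warm_mu[0],
                                    rel_tol=config.coarse_rel_tol,
                                    decompose=False)
        if not res.feasible:
            return 1e6
        warm_mu[0] = max(1e-3, 0.5 * res.mu_max)
        return -res.mu_max

    def quick_feasible(x: np.ndarray) -> bool:
        return any(feasible_at_mu(model, x, mu_probe, lam, constraints)[0]
                   for mu_probe in (0.01, 0.1, 0.3, 1.0, 3.0))

    floor = 10.0 ** (lo - 0.5)

    # prefer starts that already admit balanced growth: an infeasible
    # start sees a flat penalty landscape and cannot move
    starts: List[np.ndarray] = [
        np.maximum(np.asarray(s, dtype=float), floor)
        for s in extra_starts]
    target = config.n_starts + len(starts)
    for _ in range(30 * config.n_starts):
        if len(starts) >= target:
            break
        cand = clip_volume(10.0 ** rng.uniform(lo, hi, size=m))
        if quick_feasible(cand):
            starts.append(cand)
    while len(starts) < target:
        starts.append(clip_volume(10.0 ** rng.uniform(lo, hi, size=m)))

    best_val, best_logx = np.inf, None
    evals = 0
    for x0 in starts:
        start = np.log10(x0)
        out = minimize(objective, start, method="Nelder-Mead",
                       options={"maxiter": config.maxiter,
                                "xatol": 1e-3, "fatol": 1e-7})
        evals += out.nfev
        if out.fun < best_val:
            best_val, best_logx = out.fun, out.x

    if best_logx is None or best_val >= 1e6:
        return OptimizationResult(mu_max=0.0, alpha=None,
                                  x=np.zeros(m), feasible=False,
                                  diagnostics={"reason": "all starts "
                                               "infeasible",
                                               "evaluations": evals})
    x_best = decode(best_logx)
    final = max_growth_at_fixed_x(model, x_best, lam, constraints,
                                  rel_tol=config.final_rel_tol)
    final.diagnostics.update({"evaluations": evals,
                              "n_starts": config.n_starts,
                              "seed": config.seed})
    return final
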