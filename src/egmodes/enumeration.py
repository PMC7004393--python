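"""Elementary Growth States and Modes.

An Elementary Growth State (EGS) is a vertex of the balanced-growth
polytope

    P_{x,mu} = { alpha >= 0 : B(x, mu) alpha = mu u_{m+1} },

i.e. a basic feasible solution of the linear system at fixed metabolite
concentrations x and growth rate mu.  Every balanced-growth allocation
is a convex combination of the EGSs at its (x, mu).  Two EGSs computed
at different (x, mu) but sharing the same *support* (set of expressed
proteins) belong to the same Elementary Growth Mode (EGM) — the
invariant, network-level object.

Vertices are enumerated exhaustively over feasible bases: every column
subset of size rank(B_active) that contains the ribosome column (the
ribosome must always be made) and whose square restriction is
invertible with a nonnegative basic solution.  This is exact and, at
the coarse-grained model sizes this package targets, fast.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from .balance import (RESIDUAL_TOL, BalancedGrowthSystem, build_system,
                      reduce_rows, residual)
from .model import WholeCellModel

__all__ = [
    "EGS",
    "EGM",
    "ContinuationResult",
    "enumerate_egs",
    "support_of",
    "decompose_into_egs",
    "egm_classes",
    "continue_egs",
]

#: absolute tolerance below which an allocation entry counts as zero
SUPPORT_TOL = 1e-9


@dataclass
class EGS:
    """A vertex of the balanced-growth polytope at context (x, mu)."""

    alpha: np.ndarray            # (n+1,), >= 0
    basis: Tuple[int, ...]       # feasible basis D, contains index n
    support: frozenset           # indices with alpha_j > tol
    x: np.ndarray
    mu: float
    residual_norm: float
    all_bases: List[Tuple[int, ...]] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        """True when the support is a strict subset of the basis."""
        return self.support != frozenset(self.basis)


@dataclass
class EGM:
    """Equivalence class of EGSs sharing a support."""

    support: frozenset
    members: List[EGS] = field(default_factory=list)


@dataclass
class ContinuationResult:
    """Outcome of continuing an EGS along a path in (x, mu)."""

    success: bool
    egs: Optional[EGS] = None
    boundary_fraction: Optional[float] = None   # path parameter in [0, 1]
    boundary_mu: Optional[float] = None
    boundary_x: Optional[np.ndarray] = None
    message: str = ""


def support_of(alpha: Sequence[float], tol: float = SUPPORT_TOL) -> Set[int]:
    """Indices with alpha_j strictly greater than tol (0-based)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < -tol):
        raise ValueError("alpha has entries below -tol")
    return {int(j) for j in np.nonzero(alpha > tol)[0]}


def _round_key(alpha: np.ndarray, digits: int = 12) -> Tuple[float, ...]:
    """Dedup key: alpha rounded to `digits` significant digits."""
    scale = np.abs(alpha).max()
    if scale == 0:
        return tuple(alpha)
    q = 10.0 ** (digits - 1 - int(np.floor(np.log10(scale))))
    return tuple(np.round(alpha * q) / q)


def enumerate_egs(model: WholeCellModel,
                  x: Sequence[float],
                  mu: float,
                  tol: float = RESIDUAL_TOL,
                  system: Optional[BalancedGrowthSystem] = None,
                  ) -> List[EGS]:
    """All vertices of the balanced-growth polytope at (x, mu).

    The allocation budget |alpha| <= lambda is *not* applied here: the
    polytope is defined by the equality system and alpha >= 0 alone.
    An empty list signals that no balanced growth is possible at this
    (x, mu).
    """
    if system is None:
        system = reduce_rows(build_system(model, x, mu))
    elif system.rank is None:
        system = reduce_rows(system)
    if not system.consistent:
        return []
    A = system.active_matrix()
    b = system.active_rhs()
    nrows, ncols = A.shape
    rib = ncols - 1
    if nrows > ncols:
        return []

    found: Dict[Tuple[float, ...], EGS] = {}
    for others in itertools.combinations(
            [j for j in range(ncols) if j != rib], nrows - 1):
        D = (*others, rib)
        sub = A[:, D]
        try:
            alpha_d = np.linalg.solve(sub, b)
        except np.linalg.LinAlgError:
            continue
        # guard against near-singular solves
        if not np.all(np.isfinite(alpha_d)):
            continue
        if np.any(alpha_d < -tol * max(1.0, np.abs(alpha_d).max())):
            continue
        alpha = np.zeros(ncols)
        alpha[list(D)] = np.clip(alpha_d, 0.0, None)
        rows = system.constraint_rows()
        res = float(np.abs(system.B[rows] @ alpha - system.rhs[rows]).max())
        if res > tol * max(1.0, np.abs(b).max()):
            continue
        key = _round_key(alpha)
        if key in found:
            found[key].all_bases.append(D)
            continue
        found[key] = EGS(alpha=alpha, basis=D,
                         support=frozenset(support_of(alpha)),
                         x=np.asarray(x, dtype=float), mu=mu,
                         residual_norm=res, all_bases=[D])
    return sorted(found.values(), key=lambda s: sorted(s.support))


def decompose_into_egs(alpha: Sequence[float],
                       egs_list: Sequence[EGS],
                       tol: float = RESIDUAL_TOL) -> np.ndarray:
    """Convex weights expressing alpha as a combination of the EGSs.

    Solves the LP feasibility problem sum_i w_i alpha_i = alpha,
    sum_i w_i = 1, w >= 0.  Raises ValueError when alpha lies outside
    the convex hull (it is then not a balanced-growth solution at this
    (x, mu)).
    """
    alpha = np.asarray(alpha, dtype=float)
    if not egs_list:
        raise ValueError("no EGSs supplied")
    V = np.column_stack([s.alpha for s in egs_list])
    A_eq = np.vstack([V, np.ones((1, V.shape[1]))])
    b_eq = np.concatenate([alpha, [1.0]])
    res = linprog(c=np.zeros(V.shape[1]), A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * V.shape[1], method="highs")
    if not res.success:
        raise ValueError(
            "alpha is not a convex combination of the supplied EGSs "
            f"(LP status: {res.message})")
    w = res.x
    err = float(np.abs(V @ w - alpha).max())
    if err > max(tol, 1e3 * RESIDUAL_TOL * max(1.0, np.abs(alpha).max())):
        raise ValueError(f"decomposition reconstruction error {err:.3g} "
                         "exceeds tolerance")
    return w


def egm_classes(egs_collections: Iterable[EGS]) -> List[EGM]:
    """Partition EGSs (from one or more contexts) by exact support."""
    classes: Dict[frozenset, EGM] = {}
    for egs in egs_collections:
        classes.setdefault(egs.support, EGM(support=egs.support))
        classes[egs.support].members.append(egs)
    return sorted(classes.values(), key=lambda c: sorted(c.support))


def _solve_on_basis(model: WholeCellModel,
                    x: np.ndarray,
                    mu: float,
                    basis: Tuple[int, ...]) -> np.ndarray:
    """Solve the square active system restricted to a fixed basis."""
    system = reduce_rows(build_system(model, x, mu))
    if system.rank != len(basis):
        raise np.linalg.LinAlgError(
            f"active rank {system.rank} != |basis| {len(basis)} "
            f"at mu = {mu}")
    A = system.active_matrix()[:, list(basis)]
    alpha_d = np.linalg.solve(A, system.active_rhs())
    alpha = np.zeros(system.n_cols)
    alpha[list(basis)] = alpha_d
    return alpha


def continue_egs(model: WholeCellModel,
                 egs: EGS,
                 target_x: Sequence[float],
                 target_mu: float,
                 steps: int = 20,
                 tol: float = SUPPORT_TOL) -> ContinuationResult:
    """Continue an EGS along a straight path to (target_x, target_mu).

    The basis D is held fixed; at each step the square active system
    B_D alpha_D = mu u is re-solved (the system is linear in alpha, so
    this is the exact Newton step of the implicit-function construction,
    whose Jacobian is B_D itself).  If a basic variable crosses zero the
    boundary is bracketed by bisection and reported: past it, the mode
    ceases to exist.  Requires a nondegenerate vertex (support == basis).
    """
    if egs.degenerate:
        raise ValueError("continuation requires support == basis "
                         "(nondegenerate vertex)")
    x0, mu0 = egs.x, egs.mu
    x1 = np.asarray(target_x, dtype=float)
    basis = egs.basis

    def point(t: float) -> Tuple[np.ndarray, float]:
        return (1 - t) * x0 + t * x1, (1 - t) * mu0 + t * target_mu

    def solve(t: float) -> np.ndarray:
        xt, mut = point(t)
        return _solve_on_basis(model, xt, mut, basis)

    prev_t = 0.0
    for i in range(1, steps + 1):
        t = i / steps
        alpha = solve(t)
        if np.min(alpha[list(basis)]) <= tol:
            # bracket the boundary between prev_t (feasible) and t
            lo, hi = prev_t, t
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if np.min(solve(mid)[list(basis)]) > tol:
                    lo = mid
                else:
                    hi = mid
            xb, mub = point(lo)
            return ContinuationResult(
                success=False, boundary_fraction=lo, boundary_mu=mub,
                boundary_x=xb,
                message="a basic allocation crossed zero; the mode "
                        "ceases to exist past this point")
        prev_t = t

    xt, mut = point(1.0)
    system = reduce_rows(build_system(model, xt, mut))
    res = float(np.abs(residual(system, alpha)[system.active_rows]).max())
    new = EGS(alpha=alpha, basis=basis,
              support=frozenset(support_of(alpha)),
              x=xt, mu=mut, residual_norm=res, all_bases=[basis])
    return ContinuationResult(success=True, egs=new)
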