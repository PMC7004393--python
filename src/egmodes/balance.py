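"""The balanced-growth linear system in ribosome-allocation variables.

At fixed metabolite concentrations x and growth rate mu, demanding that
all concentrations are steady (x_dot = e_dot = r_dot = 0) while the cell
grows at rate mu reduces the whole-cell model to a *linear* system in the
allocation vector alpha:

    B(x, mu) alpha = mu u_{m+1},      alpha >= 0,

with, for metabolite row k <= m and metabolic column j <= n,

    B_kj      = ((x_k a_j - P_kj) f_j(x)/mu + x_k b_j + M_kj) g_j(x),
    B_k,(n+1) = (x_k b_{n+1} + M_k,(n+1)) g_{n+1}(x),

and a final ribosome row (0, ..., 0, g_{n+1}(x)) enforcing
``alpha_{n+1} g_{n+1}(x) = mu`` (the ribosome must replicate itself at
rate mu).  The nonnegative solutions form a convex polytope whose
vertices are the Elementary Growth States.

Catalyst-free (spontaneous) reactions with rates s_l(x) keep the system
exactly linear: writing d_k for their net production of metabolite k and
c_s for their net volume production, eliminating the ribosome
concentration gives the same row formulas with x_k replaced by

    gamma_k = (mu x_k - d_k) / (mu - c_s),

which reduces to x_k when no spontaneous reactions exist.

Rows for metabolites with x_k = 0 (and no spontaneous production) are
not valid constraints and are excluded; linearly dependent rows are
removed by :func:`reduce_rows` so that a feasible basis is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np

from .model import (GrowthState, WholeCellModel, evaluate_rate_laws,
                    volume_coefficients)

__all__ = [
    "BalancedGrowthSystem",
    "build_system",
    "reduce_rows",
    "residual",
    "concentrations_from_allocation",
    "fluxes_from_state",
    "allocation_denominator",
]

#: default absolute tolerance on balanced-growth residuals
RESIDUAL_TOL = 1e-8
#: default relative tolerance for rank decisions
RANK_TOL = 1e-10


@dataclass
class BalancedGrowthSystem:
    """B(x, mu) with bookkeeping of valid and independent rows.

    ``B`` has shape (m+1, n+1); the last row is the ribosome row.  Row
    indices in ``invalid_rows`` correspond to zero-concentration
    metabolites and are no constraints at all; ``active_rows`` lists the
    linearly independent valid rows (always ending with row m, the
    ribosome row).  ``consistent`` is False when a dependent metabolite
    row conflicts with the rows kept (the polytope is then empty).
    """

    x: np.ndarray
    mu: float
    B: np.ndarray
    rhs: np.ndarray
    active_rows: List[int]
    invalid_rows: List[int]
    fvals: np.ndarray
    gvals: np.ndarray
    rank: Optional[int] = None
    consistent: bool = True

    @property
    def m(self) -> int:
        return self.B.shape[0] - 1

    @property
    def n_cols(self) -> int:
        return self.B.shape[1]

    def active_matrix(self) -> np.ndarray:
        return self.B[self.active_rows, :]

    def active_rhs(self) -> np.ndarray:
        return self.rhs[self.active_rows]

    def constraint_rows(self) -> List[int]:
        """Rows any true balanced-growth solution must satisfy.

        Zero-concentration rows carry no dilution term and do not count
        towards the rank/basis bookkeeping, but an absent metabolite
        still may not be net-consumed or net-produced: rows that are
        not identically zero remain feasibility conditions.  With
        physically sensible rate laws (a law consuming metabolite k
        vanishes at x_k = 0) such rows are identically zero and drop
        out on their own.
        """
        scale = max(np.abs(self.B).max(), 1.0)
        extra = [k for k in self.invalid_rows
                 if np.abs(self.B[k]).max() > 1e-12 * scale]
        return sorted(set(self.active_rows) | set(extra))


def build_system(model: WholeCellModel,
                 x: Sequence[float],
                 mu: float) -> BalancedGrowthSystem:
    """Assemble B(x, mu) and the right-hand side mu u_{m+1}.

    Raises for mu <= 0 (the construction divides by mu) and, when
    spontaneous reactions are present, for mu <= c_s(x) (spontaneous
    volume production alone cannot sustain growth of catalysts).
    """
    if not mu > 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    x = np.asarray(x, dtype=float)
    fvals, gvals = evaluate_rate_laws(model, x)
    vol = volume_coefficients(model)
    m, n = model.m, model.n

    d, c_s = model.spontaneous_production(x)
    if model.spontaneous and mu <= c_s:
        raise ValueError(
            f"mu = {mu} <= spontaneous volume production c_s = {c_s}; "
            "no positive ribosome concentration is possible")

    # dilution term mu*x_k is dropped in negligible-dilution mode
    diluted = np.zeros(m) if model.negligible_dilution else mu * x
    if model.spontaneous:
        gamma = (diluted - d) / (mu - c_s)
    else:
        gamma = diluted / mu

    B = np.zeros((m + 1, n + 1))
    for j in range(n):
        B[:m, j] = ((gamma * vol.a[j] - model.P[:, j]) * fvals[j] / mu
                    + gamma * vol.b[j] + model.M[:, j]) * gvals[j]
    B[:m, n] = (gamma * vol.b[n] + model.M[:, n]) * gvals[n]
    B[m, n] = gvals[n]

    rhs = np.zeros(m + 1)
    rhs[m] = mu

    invalid = [k for k in range(m) if x[k] == 0 and d[k] == 0]
    active = [k for k in range(m) if k not in invalid] + [m]
    return BalancedGrowthSystem(x=x, mu=mu, B=B, rhs=rhs,
                                active_rows=active, invalid_rows=invalid,
                                fvals=fvals, gvals=gvals)


def reduce_rows(system: BalancedGrowthSystem,
                tol: float = RANK_TOL) -> BalancedGrowthSystem:
    """Drop linearly dependent rows from the active set.

    The ribosome row is seeded first and always retained.  Independence
    is decided on the augmented matrix [B | rhs]: a metabolite row whose
    B-part is dependent on the kept rows but whose augmented row is not
    marks an inconsistent system (empty polytope), which is recorded in
    ``consistent`` rather than raised.
    """
    aug = np.column_stack([system.B, system.rhs])
    scale = np.abs(aug).max()
    if scale == 0:
        scale = 1.0

    kept: List[int] = [system.m]  # ribosome row first
    basis = aug[[system.m], :] / scale
    consistent = True
    for k in system.active_rows:
        if k == system.m:
            continue
        row = aug[k] / scale
        row_b = system.B[k] / scale
        # residual of the row after projecting on the kept rows
        coeff, *_ = np.linalg.lstsq(basis.T, row, rcond=None)
        res_aug = np.linalg.norm(row - coeff @ basis)
        if res_aug > tol * max(1.0, np.linalg.norm(row)):
            kept.append(k)
            basis = np.vstack([basis, row])
        else:
            coeff_b, *_ = np.linalg.lstsq(
                basis[:, :-1].T, row_b, rcond=None)
            res_b = np.linalg.norm(row_b - coeff_b @ basis[:, :-1])
            if res_b <= tol * max(1.0, np.linalg.norm(row_b)):
                continue  # genuinely redundant
            consistent = False  # dependent in B but not in [B | rhs]
    kept_sorted = sorted(k for k in kept if k != system.m) + [system.m]
    return replace(system, active_rows=kept_sorted,
                   rank=len(kept_sorted), consistent=consistent)


def residual(system: BalancedGrowthSystem,
             alpha: Sequence[float]) -> np.ndarray:
    """Full residual B alpha - mu u_{m+1}, length m+1.

    Zero (within tolerance) on the active rows iff alpha is a balanced
    growth solution at (x, mu).  Entries for invalid rows (zero
    metabolite concentration) are reported but are not constraints.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (system.n_cols,):
        raise ValueError(
            f"alpha must have length {system.n_cols}, got {alpha.shape}")
    return system.B @ alpha - system.rhs


def active_residual_norm(system: BalancedGrowthSystem,
                         alpha: Sequence[float]) -> float:
    """Infinity norm of the residual restricted to active rows."""
    return float(np.abs(residual(system, alpha)[system.active_rows]).max())


def allocation_denominator(model: WholeCellModel,
                           alpha: Sequence[float],
                           x: Sequence[float],
                           mu: float) -> float:
    """D(alpha) = sum_{j<=n} (a_j f_j/mu + b_j) alpha_j g_j
                  + b_{n+1} alpha_{n+1} g_{n+1}.

    The ribosome concentration at balanced growth is
    r = (mu - c_s) / D(alpha)  (c_s = 0 without spontaneous reactions).
    """
    alpha = np.asarray(alpha, dtype=float)
    fvals, gvals = evaluate_rate_laws(model, x)
    vol = volume_coefficients(model)
    n = model.n
    terms = (vol.a * fvals / mu + vol.b[:n]) * alpha[:n] * gvals[:n]
    return float(terms.sum() + vol.b[n] * alpha[n] * gvals[n])


def concentrations_from_allocation(model: WholeCellModel,
                                   alpha: Sequence[float],
                                   x: Sequence[float],
                                   mu: float) -> GrowthState:
    """Reconstruct the full phenotype (x, e, r, v, w) from alpha.

    r = (mu - c_s)/D(alpha) and e_j = r alpha_j g_j(x)/mu.  If alpha
    solves the balanced-growth system, the resulting state has total
    volume fraction 1.  Raises if the denominator admits no positive
    ribosome concentration.
    """
    alpha = np.asarray(alpha, dtype=float)
    x = np.asarray(x, dtype=float)
    if alpha.shape != (model.n + 1,):
        raise ValueError(f"alpha must have length {model.n + 1}")
    fvals, gvals = evaluate_rate_laws(model, x)
    denom = allocation_denominator(model, alpha, x, mu)
    _, c_s = model.spontaneous_production(x)
    if denom <= 0 or mu <= c_s:
        raise ValueError(
            "no positive ribosome concentration for this allocation "
            f"(D(alpha) = {denom:.3g}, mu - c_s = {mu - c_s:.3g})")
    r = (mu - c_s) / denom
    e = r * alpha[:model.n] * gvals[:model.n] / mu
    v = e * fvals
    w = r * alpha * gvals
    return GrowthState(x=x, e=e, r=r, alpha=alpha, mu=mu, v=v, w=w)


def fluxes_from_state(model: WholeCellModel,
                      state: GrowthState) -> tuple:
    """Recompute (v, w) from concentrations: v_j = e_j f_j, w_j = r a_j g_j.

    At balanced growth w_j = mu e_j for j <= n and
    alpha_{n+1} g_{n+1}(x) = mu.
    """
    fvals, gvals = evaluate_rate_laws(model, state.x)
    v = state.e * fvals
    w = state.r * state.alpha * gvals
    return v, w
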