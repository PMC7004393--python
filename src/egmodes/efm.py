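"""Relating Elementary Growth States to Elementary Flux Modes.

An EGS carries a metabolic flux vector v and synthesis fluxes w.  Its
total precursor consumption is phi = M w.  Appending -phi as a virtual
biomass column to the support-restricted metabolic stoichiometry P_D
gives a matrix P_phi = [P_D  -phi] whose one-dimensional nullspace (when
P_phi has full rank) is spanned by the unique appropriately scaled EFM
V (last entry normalised to 1).  The EGS fluxes satisfy

    P_phi [v; 1] = mu x,

so v = V_n + O(mu): the flux pattern of a self-fabricating mode is the
EFM of the metabolic network with the right biomass reaction, up to a
metabolite-dilution correction of order mu.

When additionally the precursor composition is constant
(phi(x, mu) = h(x, mu) phi0, the "constant amino-acid composition"
regime) and metabolite dilution is negligible (mu x_k ~ 0), the growth
dependence of the whole allocation vector becomes explicit:

    alpha_j(mu) = H(x, mu) V_j / (f_j(x) g_j(x)),   j <= n,
    alpha_{n+1}(mu) g_{n+1}(x) = mu,

with H(x, mu) = [M_{k,n+1} / sum_j M_kj alpha0_j g_j] * mu^2/(mu_ub - mu)
diverging at the in-mode growth bound

    mu_ub = sum_j P_kj f_j alpha0_j g_j / sum_j M_kj alpha0_j g_j,

the rate at which building-block demand outpaces supply in the
subnetwork (k is any metabolite consumed by ribosome synthesis).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import null_space

from .balance import concentrations_from_allocation
from .enumeration import EGS
from .model import GrowthState, WholeCellModel, evaluate_rate_laws

__all__ = [
    "EFMApproximation",
    "GrowthScaling",
    "precursor_consumption",
    "approximating_efm",
    "growth_upper_bound",
    "allocation_at_growth_rate",
    "proportional_composition_check",
    "enumerate_efms",
]


@dataclass
class EFMApproximation:
    """The EFM approximating one EGS, and its O(mu) error."""

    phi: np.ndarray          # (m,) precursor consumption M w
    P_phi: np.ndarray        # [P_D  -phi]
    V: np.ndarray            # nullspace vector, last entry scaled to 1
    V_n: np.ndarray          # metabolic part of V (on the support D)
    metabolic_columns: Tuple[int, ...]   # reaction indices of P_D columns
    error: float             # || v_D - V_n ||
    mu: float


@dataclass
class GrowthScaling:
    """Explicit growth-rate dependence of an EGS under negligible
    metabolite dilution and constant precursor composition."""

    egs: EGS
    metabolite_index: int
    mu_ub: float
    h_prefactor: float       # M_{k,n+1} / sum_j M_kj alpha0_j g_j

    def H(self, mu: float) -> float:
        if not 0 < mu < self.mu_ub:
            raise ValueError(f"mu must lie in (0, mu_ub = {self.mu_ub:.6g})")
        return self.h_prefactor * mu ** 2 / (self.mu_ub - mu)


def precursor_consumption(model: WholeCellModel,
                          state: GrowthState) -> np.ndarray:
    """phi = M w: total metabolite consumption by protein and ribosome
    synthesis."""
    return model.M @ state.w


def approximating_efm(model: WholeCellModel,
                      egs: EGS,
                      x: Optional[Sequence[float]] = None,
                      mu: Optional[float] = None) -> EFMApproximation:
    """The unique appropriately scaled EFM of [P_D  -phi] for an EGS.

    Raises when [P_D -phi] is rank-deficient (the approximation
    hypothesis fails; no fallback is defined).
    """
    x = egs.x if x is None else np.asarray(x, dtype=float)
    mu = egs.mu if mu is None else mu
    state = concentrations_from_allocation(model, egs.alpha, x, mu)
    phi = precursor_consumption(model, state)

    cols = tuple(sorted(j for j in egs.basis if j < model.n))
    P_D = model.P[:, cols]
    P_phi = np.column_stack([P_D, -phi])
    rank = np.linalg.matrix_rank(P_phi, tol=1e-10 * max(
        1.0, np.abs(P_phi).max()))
    if rank < model.m:
        raise ValueError(
            f"[P_D -phi] has rank {rank} < m = {model.m}; the EFM "
            "approximation hypothesis fails for this EGS")
    ns = null_space(P_phi)
    if ns.shape[1] != 1:
        raise ValueError(f"nullspace of [P_D -phi] has dimension "
                         f"{ns.shape[1]}, expected 1")
    V = ns[:, 0]
    if abs(V[-1]) < 1e-12:
        raise ValueError("EFM has zero biomass component; cannot scale")
    V = V / V[-1]

    v_D = state.v[list(cols)]
    error = float(np.linalg.norm(v_D - V[:-1]))
    # consistency: P_phi [v_D; 1] = mu x
    check = P_phi @ np.concatenate([v_D, [1.0]]) - mu * x
    if np.abs(check).max() > 1e-6 * max(1.0, np.abs(state.v).max()):
        raise ValueError("EGS fluxes violate the restricted steady-state "
                         f"identity (max dev {np.abs(check).max():.3g})")
    return EFMApproximation(phi=phi, P_phi=P_phi, V=V, V_n=V[:-1],
                            metabolic_columns=cols, error=error, mu=mu)


def _ribosome_precursor_index(model: WholeCellModel,
                              k: Optional[int]) -> int:
    if k is None:
        candidates = np.nonzero(model.M[:, model.n] > 0)[0]
        return int(candidates[0])
    if model.M[k, model.n] <= 0:
        raise ValueError(
            f"metabolite {model.metabolites[k]!r} is not consumed by "
            "ribosome synthesis (M[k, n+1] = 0): yields no information")
    return k


def growth_upper_bound(model: WholeCellModel,
                       alpha0: Sequence[float],
                       x: Sequence[float],
                       k: Optional[int] = None) -> float:
    """In-mode growth bound from building-block k's supply/demand ratio:

    mu_ub = sum_j P_kj f_j alpha0_j g_j / sum_j M_kj alpha0_j g_j.

    Invariant to rescaling of alpha0.  Default k: the first metabolite
    consumed by ribosome synthesis.
    """
    alpha0 = np.asarray(alpha0, dtype=float)
    x = np.asarray(x, dtype=float)
    k = _ribosome_precursor_index(model, k)
    fvals, gvals = evaluate_rate_laws(model, x)
    n = model.n
    weights = alpha0[:n] * gvals[:n]
    supply = float(model.P[k, :] @ (fvals * weights))
    demand = float(model.M[k, :n] @ weights)
    if demand <= 0:
        raise ValueError(f"zero building-block demand for metabolite "
                         f"{model.metabolites[k]!r} under this allocation")
    return supply / demand


def growth_scaling(model: WholeCellModel,
                   egs: EGS,
                   k: Optional[int] = None) -> GrowthScaling:
    """Package mu_ub and the H(x, mu) prefactor for a reference EGS."""
    k = _ribosome_precursor_index(model, k)
    mu_ub = growth_upper_bound(model, egs.alpha, egs.x, k)
    _, gvals = evaluate_rate_laws(model, egs.x)
    n = model.n
    demand = float(model.M[k, :n] @ (egs.alpha[:n] * gvals[:n]))
    pref = model.M[k, n] / demand
    return GrowthScaling(egs=egs, metabolite_index=k, mu_ub=mu_ub,
                         h_prefactor=pref)


def allocation_at_growth_rate(model: WholeCellModel,
                              alpha0: Sequence[float],
                              x: Sequence[float],
                              mu: float,
                              k: Optional[int] = None) -> np.ndarray:
    """Closed-form allocation alpha(mu) within one mode, 0 < mu < mu_ub.

    All metabolic fractions scale by the common factor H(x, mu); the
    ribosome fraction is mu/g_{n+1}(x).  Valid in the
    negligible-dilution, constant-composition regime.
    """
    alpha0 = np.asarray(alpha0, dtype=float)
    x = np.asarray(x, dtype=float)
    k = _ribosome_precursor_index(model, k)
    mu_ub = growth_upper_bound(model, alpha0, x, k)
    if not 0 < mu < mu_ub:
        raise ValueError(f"mu = {mu} outside (0, mu_ub = {mu_ub:.6g})")
    fvals, gvals = evaluate_rate_laws(model, x)
    n = model.n
    demand = float(model.M[k, :n] @ (alpha0[:n] * gvals[:n]))
    H = (model.M[k, n] / demand) * mu ** 2 / (mu_ub - mu)
    # V_j/(f_j g_j) has the direction of alpha0's metabolic part; fix the
    # scale via the reference context so alpha(mu0) == alpha0 when the
    # reference itself satisfies the regime.
    alpha = np.zeros(n + 1)
    # e_j proportional to V_j/f_j with common factor h; alpha_j = H V_j/(f_j g_j).
    # The reference EGS pins V: alpha0_j = H(mu0) V_j/(f_j g_j) =>
    # V_j/(f_j g_j) = alpha0_j / H(mu0), hence alpha_j(mu) = alpha0_j H(mu)/H(mu0).
    mu0 = None
    # Reference growth rate: recover from alpha0's ribosome row if possible
    mu0 = alpha0[n] * gvals[n]
    if not 0 < mu0 < mu_ub:
        raise ValueError("reference allocation's ribosome fraction does "
                         "not encode a growth rate inside (0, mu_ub)")
    H0 = (model.M[k, n] / demand) * mu0 ** 2 / (mu_ub - mu0)
    alpha[:n] = alpha0[:n] * (H / H0)
    alpha[n] = mu / gvals[n]
    return alpha


def proportional_composition_check(model: WholeCellModel,
                                   states: Sequence[GrowthState],
                                   ) -> Tuple[np.ndarray, float]:
    """Fit phi(state) ~ h * phi0 per state; report (h-profile, max
    relative residual).

    A small residual certifies the constant-composition regime in which
    a single EFM approximates every state of the mode.  phi0 is the
    first state's precursor-consumption vector.
    """
    if not states:
        raise ValueError("need at least one state")
    phi0 = precursor_consumption(model, states[0])
    norm0 = float(phi0 @ phi0)
    if norm0 == 0:
        raise ValueError("reference precursor consumption is zero")
    hs, devs = [], []
    for st in states:
        phi = precursor_consumption(model, st)
        h = float(phi @ phi0) / norm0
        hs.append(h)
        devs.append(np.linalg.norm(phi - h * phi0)
                    / max(np.linalg.norm(phi), 1e-300))
    return np.array(hs), float(max(devs))


def enumerate_efms(stoich: np.ndarray,
                   fixed_flux_index: int,
                   tol: float = 1e-9) -> List[np.ndarray]:
    """Vertices of { v >= 0 : S v = 0, v_fixed = 1 }: the EFMs of an
    irreversible network at fixed biomass flux.

    Exhaustive basis enumeration, intended for desk-scale networks
    (used to compare metabolic-only flux modes with growth modes).
    """
    S = np.atleast_2d(np.asarray(stoich, dtype=float))
    m, n = S.shape
    A = np.vstack([S, np.eye(n)[fixed_flux_index]])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    rank = np.linalg.matrix_rank(A)
    # reduce to independent rows (keep the fixed-flux row)
    rows = [m]
    for i in range(m):
        cand = rows + [i]
        if np.linalg.matrix_rank(A[cand]) > np.linalg.matrix_rank(A[rows]):
            rows.append(i)
    A_r, b_r = A[rows], b[rows]
    k = len(rows)
    found = {}
    for cols in itertools.combinations(range(n), k):
        sub = A_r[:, cols]
        try:
            sol = np.linalg.solve(sub, b_r)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(sol)) or np.any(sol < -tol):
            continue
        v = np.zeros(n)
        v[list(cols)] = np.clip(sol, 0.0, None)
        if np.abs(A_r @ v - b_r).max() > 1e-8:
            continue
        key = tuple(np.round(v, 9))
        found.setdefault(key, v)
    return list(found.values())
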