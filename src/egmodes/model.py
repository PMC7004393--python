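"""Whole-cell model data structures and the growth-rate/density formulas.

The model describes a self-fabricating cell with m metabolites (vector x),
n enzymes (vector e) and a ribosome (scalar r).  Metabolic reaction j runs
at rate ``v_j = e_j f_j(x)``; the ribosome synthesises protein j at rate
``w_j = r alpha_j g_j(x)`` where ``alpha_j`` is the fraction of the active
ribosome pool allocated to protein j (j = n+1 is the ribosome itself).
Stoichiometry splits into P (m x n, metabolic, any sign) and M
(m x (n+1), building-block consumption per protein synthesised; negative
entries are synthesis byproducts such as ADP).

Each species carries a molar volume (rho for metabolites, sigma for
proteins); the cell is an ideal solution with unit total volume fraction,

    sum_k rho_k x_k + sum_j sigma_j e_j + sigma_{n+1} r = 1,

and the balanced growth rate equals the net specific volume production

    mu = sum_j a_j e_j f_j(x) + r sum_j b_j alpha_j g_j(x)  (+ spontaneous),

with a_j = sum_k rho_k P_kj (net volume change per unit flux of reaction j)
and b_j = sigma_j - sum_k rho_k M_kj (net volume change per mole of
protein j made).

Optionally the model carries catalyst-free ("spontaneous") reactions with
rates s_l(x), e.g. passive membrane diffusion of a toxin; they enter the
metabolite balances and the volume production like any other reaction but
have no enzyme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .ratelaws import RateLaw

__all__ = [
    "SpontaneousReaction",
    "WholeCellModel",
    "VolumeCoefficients",
    "GrowthState",
    "evaluate_rate_laws",
    "volume_coefficients",
    "growth_rate_from_state",
    "density",
]

RIBOSOME = "ribosome"


@dataclass(frozen=True)
class SpontaneousReaction:
    """A catalyst-free reaction: stoichiometric column and rate s(x)."""

    name: str
    stoich: np.ndarray  # length m, any sign
    rate: RateLaw


@dataclass
class WholeCellModel:
    """A self-fabricating whole-cell model.

    Attributes
    ----------
    metabolites : list of str, length m
    reactions : list of str, length n  (metabolic reaction == enzyme names)
    P : (m, n) metabolic stoichiometry
    M : (m, n+1) building-block consumption per synthesis reaction;
        column n+1 is the ribosome's own synthesis
    f : n metabolic rate laws
    g : n+1 translation rate laws (per protein, last = ribosome)
    rho : (m,) metabolite molar volumes, > 0
    sigma : (n+1,) protein/ribosome molar volumes, > 0
    lam : ribosome allocation budget, |alpha| <= lam <= 1
    spontaneous : optional catalyst-free reactions
    negligible_dilution : drop the mu*x_k metabolite-dilution terms from
        the balanced-growth metabolite rows (the regime in which the
        explicit growth-rate dependence of an allocation vector and the
        in-mode growth bound mu_ub become exact)
    """

    metabolites: List[str]
    reactions: List[str]
    P: np.ndarray
    M: np.ndarray
    f: List[RateLaw]
    g: List[RateLaw]
    rho: np.ndarray
    sigma: np.ndarray
    lam: float = 1.0
    spontaneous: List[SpontaneousReaction] = field(default_factory=list)
    negligible_dilution: bool = False

    def __post_init__(self) -> None:
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        self.rho = np.asarray(self.rho, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.validate()

    # -- dimensions ----------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.metabolites)

    @property
    def n(self) -> int:
        return len(self.reactions)

    @property
    def protein_names(self) -> List[str]:
        return [*self.reactions, RIBOSOME]

    def validate(self) -> None:
        m, n = self.m, self.n
        if self.P.shape != (m, n):
            raise ValueError(f"P must be {(m, n)}, got {self.P.shape}")
        if self.M.shape != (m, n + 1):
            raise ValueError(f"M must be {(m, n + 1)}, got {self.M.shape}")
        if len(self.f) != n:
            raise ValueError(f"need {n} metabolic rate laws, got {len(self.f)}")
        if len(self.g) != n + 1:
            raise ValueError(
                f"need {n + 1} translation rate laws, got {len(self.g)}")
        if self.rho.shape != (m,) or np.any(self.rho <= 0):
            raise ValueError("rho must be length m and strictly positive")
        if self.sigma.shape != (n + 1,) or np.any(self.sigma <= 0):
            raise ValueError("sigma must be length n+1 and strictly positive")
        if not (0 < self.lam <= 1):
            raise ValueError("lambda must lie in (0, 1]")
        if not np.any(self.M[:, n] > 0):
            raise ValueError("ribosome synthesis must consume at least one "
                             "building block (some M[k, n+1] > 0)")
        for law in (*self.f, *self.g):
            if law.max_index() >= m:
                raise ValueError("rate law references metabolite index "
                                 f"{law.max_index()} but m = {m}")
        for sp in self.spontaneous:
            st = np.asarray(sp.stoich, dtype=float)
            if st.shape != (m,):
                raise ValueError(
                    f"spontaneous reaction {sp.name!r}: stoich must be length m")
        if np.any(self.M < 0):
            warnings.warn("M has negative entries (synthesis byproducts); "
                          "accepted and used as-is", stacklevel=2)

    # -- spontaneous-reaction helpers ---------------------------------
    def spontaneous_rates(self, x: np.ndarray) -> np.ndarray:
        return np.array([sp.rate(x) for sp in self.spontaneous])

    def spontaneous_production(self, x: np.ndarray) -> Tuple[np.ndarray, float]:
        """Net metabolite production d(x) and volume production c_s(x)
        of the catalyst-free reactions at metabolite vector x."""
        d = np.zeros(self.m)
        c_s = 0.0
        for sp in self.spontaneous:
            rate = sp.rate(x)
            st = np.asarray(sp.stoich, dtype=float)
            d += st * rate
            c_s += float(self.rho @ st) * rate
        return d, c_s


@dataclass(frozen=True)
class VolumeCoefficients:
    """Net volume production coefficients.

    a_j = sum_k rho_k P_kj : volume change per unit flux of reaction j.
    b_j = sigma_j - sum_k rho_k M_kj : volume change per mole of protein j.
    """

    a: np.ndarray  # (n,)
    b: np.ndarray  # (n+1,)


def volume_coefficients(model: WholeCellModel) -> VolumeCoefficients:
    a = model.rho @ model.P
    b = model.sigma - model.rho @ model.M
    return VolumeCoefficients(a=np.asarray(a, float), b=np.asarray(b, float))


@dataclass
class GrowthState:
    """A full phenotype at (candidate) balanced growth."""

    x: np.ndarray       # (m,) metabolite concentrations
    e: np.ndarray       # (n,) enzyme concentrations
    r: float            # ribosome concentration
    alpha: np.ndarray   # (n+1,) ribosome allocation fractions
    mu: float           # growth rate
    v: np.ndarray       # (n,) metabolic fluxes, v_j = e_j f_j(x)
    w: np.ndarray       # (n+1,) synthesis fluxes, w_j = r alpha_j g_j(x)


def evaluate_rate_laws(model: WholeCellModel,
                       x: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Evaluate all f_j(x) and g_j(x) at a metabolite vector x >= 0."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.m,):
        raise ValueError(f"x must have length m = {model.m}, got {x.shape}")
    if np.any(x < 0):
        raise ValueError("metabolite concentrations must be >= 0")
    fvals = np.array([law(x) for law in model.f])
    gvals = np.array([law(x) for law in model.g])
    return fvals, gvals


def growth_rate_from_state(model: WholeCellModel,
                           x: Sequence[float],
                           e: Sequence[float],
                           r: float,
                           alpha: Sequence[float]) -> float:
    """Growth rate as the net specific volume production of the state.

    mu = sum_j a_j e_j f_j(x) + r sum_j b_j alpha_j g_j(x) + c_s(x),
    where c_s is the volume production of any spontaneous reactions.
    May be <= 0 for non-growing states.
    """
    x = np.asarray(x, float)
    e = np.asarray(e, float)
    alpha = np.asarray(alpha, float)
    if e.shape != (model.n,) or alpha.shape != (model.n + 1,):
        raise ValueError("dimension mismatch in e or alpha")
    fvals, gvals = evaluate_rate_laws(model, x)
    vol = volume_coefficients(model)
    _, c_s = model.spontaneous_production(x)
    mu = float(vol.a @ (e * fvals) + r * (vol.b @ (alpha * gvals)) + c_s)
    return mu


def density(model: WholeCellModel,
            x: Sequence[float],
            e: Sequence[float],
            r: float) -> float:
    """Total volume fraction sum rho_k x_k + sum sigma_j e_j + sigma_r r.

    Equals 1 at every balanced growth state with mu > 0.
    """
    x = np.asarray(x, float)
    e = np.asarray(e, float)
    return float(model.rho @ x + model.sigma[:-1] @ e + model.sigma[-1] * r)
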