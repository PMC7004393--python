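"""Kinetic rate laws for metabolic and translation reactions.

Every reaction rate in the whole-cell model factorises as
``v_j = e_j * f_j(x)`` (enzymes) or ``w_j = r * alpha_j * g_j(x)``
(ribosome-catalysed synthesis): the catalyst enters linearly and all
metabolite dependence lives in the saturation function ``f_j`` / ``g_j``.
This module provides those saturation functions.

Supported kinds
---------------
``constant``
    Returns ``k_cat`` regardless of the metabolite vector.  Used for
    reactions saturated by a fixed external substrate.
``irreversible_mm``
    ``k_cat * prod_s x_s / (K_s + x_s)`` over the listed substrates.
``reversible_mm``
    Irreversible forward term minus a saturating mass-action back term,
    ``k_cat * (prod_s x_s/(K_s+x_s) - (1/k_eq) * prod_p x_p/(K_p+x_p))``.
    May be negative when products dominate.

Any kind may additionally carry multiplicative inhibition factors
``1 / (1 + x_i / K_I)`` (non-competitive inhibition), used e.g. for a
toxin that slows every catalyst in the cell.  External nutrient
saturation is folded into the ``scale`` prefactor, so environmental
concentrations are parameters of the law rather than state variables.

New kinds can be registered with :func:`register_rate_law`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping

import numpy as np

__all__ = ["RateLaw", "register_rate_law", "RATE_LAW_KINDS"]


def _eval_constant(law: "RateLaw", x: np.ndarray) -> float:
    return law.k_cat


def _saturation(pairs: Mapping[int, float], x: np.ndarray) -> float:
    out = 1.0
    for idx, km in pairs.items():
        out *= x[idx] / (km + x[idx])
    return out


def _eval_irreversible_mm(law: "RateLaw", x: np.ndarray) -> float:
    return law.k_cat * _saturation(law.substrates, x)


def _eval_reversible_mm(law: "RateLaw", x: np.ndarray) -> float:
    fwd = _saturation(law.substrates, x)
    back = _saturation(law.products, x) / law.k_eq
    return law.k_cat * (fwd - back)


def _eval_diffusion(law: "RateLaw", x: np.ndarray) -> float:
    # passive transport k_cat * (x_ext - x_s); signed, used for
    # catalyst-free membrane diffusion
    (idx,) = law.substrates
    return law.k_cat * (law.external - x[idx])


RATE_LAW_KINDS: Dict[str, Callable[["RateLaw", np.ndarray], float]] = {
    "constant": _eval_constant,
    "irreversible_mm": _eval_irreversible_mm,
    "reversible_mm": _eval_reversible_mm,
    "diffusion": _eval_diffusion,
    # historical alias: an inhibited law is an irreversible MM law whose
    # `inhibitors` mapping is non-empty
    "inhibited": _eval_irreversible_mm,
}


def register_rate_law(kind: str,
                      fn: Callable[["RateLaw", np.ndarray], float]) -> None:
    """Register an evaluation function for a new rate-law kind."""
    RATE_LAW_KINDS[kind] = fn


@dataclass(frozen=True)
class RateLaw:
    """A saturation function f(x) (or g(x)) of the metabolite vector.

    Parameters
    ----------
    kind:
        One of :data:`RATE_LAW_KINDS`.
    k_cat:
        Catalytic rate constant, time^-1; must be > 0.
    substrates:
        Mapping metabolite index -> half-saturation constant K_M.
    products:
        Mapping metabolite index -> K_M for the reverse term
        (``reversible_mm`` only).
    k_eq:
        Equilibrium-like damping constant for the reverse term.
    inhibitors:
        Mapping metabolite index -> K_I; each contributes a factor
        ``1/(1 + x_i/K_I)``.
    scale:
        Fixed multiplicative factor, e.g. the saturation level of an
        external nutrient that is a parameter, not a state variable.
    external:
        Fixed external concentration for the ``diffusion`` kind.
    """

    kind: str
    k_cat: float
    substrates: Mapping[int, float] = field(default_factory=dict)
    products: Mapping[int, float] = field(default_factory=dict)
    k_eq: float = 1.0
    inhibitors: Mapping[int, float] = field(default_factory=dict)
    scale: float = 1.0
    external: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in RATE_LAW_KINDS:
            raise ValueError(f"unknown rate-law kind {self.kind!r}; "
                             f"known: {sorted(RATE_LAW_KINDS)}")
        if not self.k_cat > 0:
            raise ValueError("k_cat must be > 0")
        for name, mapping in (("substrates", self.substrates),
                              ("products", self.products),
                              ("inhibitors", self.inhibitors)):
            for idx, k in mapping.items():
                if not k > 0:
                    raise ValueError(
                        f"{name}[{idx}]: constant must be > 0, got {k}")

    def __call__(self, x: np.ndarray) -> float:
        """Evaluate the saturation function at metabolite vector x >= 0."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("metabolite concentrations must be >= 0")
        value = RATE_LAW_KINDS[self.kind](self, x) * self.scale
        for idx, ki in self.inhibitors.items():
            value /= 1.0 + x[idx] / ki
        if not np.isfinite(value):
            raise FloatingPointError(
                f"rate law {self.kind!r} evaluated to a non-finite value")
        return float(value)

    def max_index(self) -> int:
        """Largest metabolite index this law references (-1 if none)."""
        idxs = [*self.substrates, *self.products, *self.inhibitors]
        return max(idxs) if idxs else -1
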