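"""Built-in fixture models and a seeded random-model generator.

Three sources of test models, none requiring external data:

* :func:`two_enzyme_model` — the minimal self-replicator: one internal
  precursor, two alternative enzymes importing it from a fixed external
  nutrient, and the ribosome.  Its balanced-growth polytope is a line
  segment with exactly two vertices (one per enzyme).
* :func:`toxin_model` — a five-metabolite network (two intermediates,
  two amino acids, one toxin).  The toxin diffuses passively over the
  membrane, inhibits every catalyst, and can be destroyed by a
  dedicated protein that contributes nothing to growth directly.
* :func:`random_model` — seeded generator of connected whole-cell
  models with a certified feasible balanced-growth point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .enumeration import enumerate_egs
from .model import SpontaneousReaction, WholeCellModel
from .ratelaws import RateLaw

__all__ = [
    "two_enzyme_model",
    "toxin_model",
    "RandomModelSpec",
    "random_model",
    "random_model_with_probe",
]


def two_enzyme_model(k_cat1: float = 12.0, k_cat2: float = 5.0,
                     negligible_dilution: bool = False) -> WholeCellModel:
    """Self-replicator with one precursor and two alternative enzymes.

    Both enzymes import the precursor from a fixed external nutrient
    (folded into their catalytic constants); enzyme 1 is strictly
    faster by default so the growth-maximising mode is unique.
    Translation is Michaelis-Menten in the precursor.
    """
    mm = dict(substrates={0: 0.1})
    return WholeCellModel(
        metabolites=["precursor"],
        reactions=["enz1", "enz2"],
        P=np.array([[1.0, 1.0]]),
        M=np.array([[1.0, 1.0, 4.0]]),
        f=[RateLaw("constant", k_cat1), RateLaw("constant", k_cat2)],
        g=[RateLaw("irreversible_mm", 6.0, **mm),
           RateLaw("irreversible_mm", 6.0, **mm),
           RateLaw("irreversible_mm", 2.0, **mm)],
        rho=np.array([0.3]),
        sigma=np.array([0.35, 0.35, 1.3]),
        lam=1.0,
        negligible_dilution=negligible_dilution,
    )


def toxin_model(toxin_outside: float = 0.0,
                k_inhibition: float = 0.2,
                k_diffusion: float = 0.5) -> WholeCellModel:
    """Five-metabolite network with a diffusing, growth-inhibiting toxin.

    Metabolites: two precursors (imported nutrient carbon, an
    intermediate), two amino acids, and an intracellular toxin.  Four
    proteins run the anabolic chain; a fifth degrades the toxin.  The
    toxin enters by catalyst-free membrane diffusion at level
    ``toxin_outside`` and multiplies every catalytic rate (metabolic
    and ribosomal) by 1/(1 + x_tox/K_I).

    All protein synthesis consumes the two amino acids in the same
    ratio, so the precursor composition is constant across modes.
    """
    TOX = 4
    inh = {TOX: k_inhibition}
    f = [
        # import: external nutrient -> c1 (nutrient level folded in k_cat)
        RateLaw("constant", 10.0, inhibitors=inh),
        # c1 -> c2
        RateLaw("irreversible_mm", 8.0, substrates={0: 0.1}, inhibitors=inh),
        # c2 -> aa1
        RateLaw("irreversible_mm", 8.0, substrates={1: 0.1}, inhibitors=inh),
        # c2 -> aa2
        RateLaw("irreversible_mm", 8.0, substrates={1: 0.1}, inhibitors=inh),
        # toxin -> (exported/destroyed)
        RateLaw("irreversible_mm", 25.0, substrates={TOX: 0.05},
                inhibitors=inh),
    ]
    # translation: MM in both amino acids, inhibited by the toxin
    tl = dict(substrates={2: 0.1, 3: 0.1}, inhibitors=inh)
    g = [RateLaw("irreversible_mm", 5.0, **tl) for _ in range(4)] + [
        RateLaw("irreversible_mm", 5.0, **tl),      # toxin-degrading protein
        RateLaw("irreversible_mm", 1.6, **tl),      # ribosome
    ]
    P = np.array([
        #  imp  cnv  aa1  aa2  deg
        [1.0, -1.0, 0.0, 0.0, 0.0],   # c1
        [0.0, 1.0, -1.0, -1.0, 0.0],  # c2
        [0.0, 0.0, 1.0, 0.0, 0.0],    # aa1
        [0.0, 0.0, 0.0, 1.0, 0.0],    # aa2
        [0.0, 0.0, 0.0, 0.0, -1.0],   # toxin
    ])
    # identical amino-acid composition for every protein; ribosome is 4x
    col = np.array([0.0, 0.0, 0.5, 0.5, 0.0])
    M = np.column_stack([col] * 5 + [4.0 * col])
    # the toxin is a small molecule: volumetrically negligible, so the
    # passive influx does not register as growth
    rho = np.array([0.1, 0.1, 0.1, 0.1, 1e-4])
    # sigma slightly above the volume of the consumed amino acids
    sigma = np.array([0.11, 0.11, 0.11, 0.11, 0.11, 0.44])
    spontaneous = [SpontaneousReaction(
        name="toxin_influx",
        stoich=np.array([0.0, 0.0, 0.0, 0.0, 1.0]),
        rate=RateLaw("diffusion", k_diffusion, substrates={TOX: 1.0},
                     external=toxin_outside))]
    return WholeCellModel(
        metabolites=["c1", "c2", "aa1", "aa2", "toxin"],
        reactions=["import", "convert", "aa1_synth", "aa2_synth",
                   "toxin_degrade"],
        P=P, M=M, f=f, g=g, rho=rho, sigma=sigma, lam=1.0,
        spontaneous=spontaneous,
    )


@dataclass(frozen=True)
class RandomModelSpec:
    """Parameters of the seeded random-model generator."""

    m: int = 3
    n: int = 4
    seed: int = 0
    extra_edge_prob: float = 0.7     # density of non-chain reactions
    kcat_range: Tuple[float, float] = (2.0, 12.0)
    km_range: Tuple[float, float] = (0.05, 0.5)
    rho_range: Tuple[float, float] = (0.05, 0.2)
    sigma_markup: Tuple[float, float] = (1.0, 1.4)
    building_fraction: float = 0.5
    byproduct_prob: float = 0.15
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.n < self.m:
            raise ValueError("need at least as many reactions as "
                             "metabolites (n >= m)")


def _attempt(spec: RandomModelSpec, rng: np.random.Generator,
             ) -> WholeCellModel:
    m, n = spec.m, spec.n
    P = np.zeros((m, n))
    f: List[RateLaw] = []

    def kcat() -> float:
        return float(rng.uniform(*spec.kcat_range))

    def km() -> float:
        return float(rng.uniform(*spec.km_range))

    # backbone: import -> x0 -> x1 -> ... -> x_{m-1}
    P[0, 0] = 1.0
    f.append(RateLaw("constant", kcat()))
    for i in range(1, m):
        P[i - 1, i] = -1.0
        P[i, i] = 1.0
        f.append(RateLaw("irreversible_mm", kcat(),
                         substrates={i - 1: km()}))
    # extra reactions: alternative producers
    for j in range(m, n):
        tgt = int(rng.integers(0, m))
        if tgt == 0 or rng.random() > spec.extra_edge_prob:
            # alternative import
            P[tgt, j] = float(rng.choice([1.0, 2.0]))
            f.append(RateLaw("constant", kcat()))
        else:
            src = int(rng.integers(0, tgt))
            P[src, j] = -1.0
            P[tgt, j] = float(rng.choice([1.0, 2.0]))
            f.append(RateLaw("irreversible_mm", kcat(),
                             substrates={src: km()}))

    # building blocks: always the chain end, plus a random subset
    n_blocks = max(1, int(round(spec.building_fraction * m)))
    blocks = {m - 1}
    while len(blocks) < n_blocks:
        blocks.add(int(rng.integers(0, m)))
    blocks = sorted(blocks)

    M = np.zeros((m, n + 1))
    for j in range(n + 1):
        size = 4.0 if j == n else 1.0  # ribosome is a big protein
        for k in blocks:
            M[k, j] = size * float(rng.choice([1.0, 2.0]))
        if j < n and rng.random() < spec.byproduct_prob:
            nonblocks = [k for k in range(m) if k not in blocks]
            if nonblocks:
                M[int(rng.choice(nonblocks)), j] = -0.5

    g = [RateLaw("irreversible_mm", kcat(), substrates={m - 1: km()})
         for _ in range(n + 1)]
    rho = rng.uniform(*spec.rho_range, size=m)
    sigma = (rho @ np.abs(M)) * rng.uniform(*spec.sigma_markup, size=n + 1)
    return WholeCellModel(
        metabolites=[f"x{i + 1}" for i in range(m)],
        reactions=[f"rxn{j + 1}" for j in range(n)],
        P=P, M=M, f=f, g=g, rho=rho, sigma=sigma, lam=1.0,
    )


def random_model_with_probe(spec: RandomModelSpec,
                            ) -> Tuple[WholeCellModel, np.ndarray, float]:
    """Generate a random model plus a certified (x, mu) at which at
    least one Elementary Growth State exists.

    Rejection-samples model candidates and probe points until the
    vertex enumeration certifies feasibility; deterministic given
    ``spec.seed``.  Raises RuntimeError at the retry cap.
    """
    for attempt in range(spec.max_retries):
        rng = np.random.default_rng((spec.seed, attempt))
        try:
            model = _attempt(spec, rng)
        except ValueError:
            continue
        for _ in range(4):
            x = rng.uniform(0.05, 0.5, size=spec.m)
            vol = float(model.rho @ x)
            if vol >= 0.4:
                x *= 0.4 / vol
            for mu in (0.05, 0.2, 0.8):
                try:
                    if enumerate_egs(model, x, mu):
                        return model, x, mu
                except (ValueError, FloatingPointError):
                    continue
    raise RuntimeError(
        f"no feasible random model found in {spec.max_retries} attempts; "
        "the generator spec is too restrictive")


def random_model(spec: RandomModelSpec) -> WholeCellModel:
    """Seeded random whole-cell model with certified balanced-growth
    feasibility (see :func:`random_model_with_probe`)."""
    model, _, _ = random_model_with_probe(spec)
    return model
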