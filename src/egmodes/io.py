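"""Model configuration files and result serialisation.

Models are stored as versioned YAML documents that refer to species and
reactions by *name*, never by index.  The schema is validated strictly
(unknown keys are rejected with the offending field path) before the
in-memory model is built.  Writing is canonical — the same model always
serialises to the same bytes — so write(read(f)) is a stable round trip
and seeded generators produce byte-identical files.

Example document::

    format_version: 1
    lambda: 1.0
    metabolites:
      - {name: precursor, rho: 0.3, concentration: 0.2}
    reactions:
      - name: enz1
        stoich: {precursor: 1.0}
        rate: {kind: constant, k_cat: 12.0}
        sigma: 0.35
        synthesis_cost: {precursor: 1.0}
        translation_rate:
          {kind: irreversible_mm, k_cat: 6.0, substrates: {precursor: 0.1}}
    ribosome:
      sigma: 1.3
      synthesis_cost: {precursor: 4.0}
      translation_rate:
        {kind: irreversible_mm, k_cat: 2.0, substrates: {precursor: 0.1}}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .enumeration import EGS
from .model import SpontaneousReaction, WholeCellModel
from .optimize import EnzymeConstraint, OptimizationResult
from .ratelaws import RateLaw

__all__ = [
    "read_model", "write_model", "model_to_dict", "model_from_dict",
    "read_constraints", "egs_table", "result_to_dict",
]

FORMAT_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RateLawSpec(_Strict):
    kind: str
    k_cat: float
    substrates: Dict[str, float] = Field(default_factory=dict)
    products: Dict[str, float] = Field(default_factory=dict)
    k_eq: float = 1.0
    inhibitors: Dict[str, float] = Field(default_factory=dict)
    scale: float = 1.0
    external: float = 0.0


class MetaboliteSpec(_Strict):
    name: str
    rho: float
    concentration: float = 0.0   # probe/initial concentration


class ReactionSpec(_Strict):
    name: str
    stoich: Dict[str, float]
    rate: RateLawSpec
    sigma: float
    synthesis_cost: Dict[str, float]
    translation_rate: RateLawSpec


class RibosomeSpec(_Strict):
    sigma: float
    synthesis_cost: Dict[str, float]
    translation_rate: RateLawSpec


class SpontaneousSpec(_Strict):
    name: str
    stoich: Dict[str, float]
    rate: RateLawSpec


class ConstraintSpec(_Strict):
    label: str
    weights: Dict[str, float]
    cap: float


class SolverSpec(_Strict):
    residual_tol: float = 1e-8
    rank_tol: float = 1e-10
    seed: int = 0


class ModelConfig(_Strict):
    format_version: int
    lam: float = Field(default=1.0, alias="lambda")
    negligible_dilution: bool = False
    metabolites: List[MetaboliteSpec]
    reactions: List[ReactionSpec]
    ribosome: RibosomeSpec
    spontaneous: List[SpontaneousSpec] = Field(default_factory=list)
    constraints: List[ConstraintSpec] = Field(default_factory=list)
    solver: SolverSpec = Field(default_factory=SolverSpec)

    model_config = ConfigDict(extra="forbid", populate_by_name=True)


def _law_from_spec(spec: RateLawSpec, index: Dict[str, int],
                   where: str) -> RateLaw:
    def remap(d: Dict[str, float]) -> Dict[int, float]:
        out = {}
        for name, value in d.items():
            if name not in index:
                raise ValueError(
                    f"{where}: unknown metabolite {name!r} in rate law")
            out[index[name]] = value
        return out

    return RateLaw(kind=spec.kind, k_cat=spec.k_cat,
                   substrates=remap(spec.substrates),
                   products=remap(spec.products), k_eq=spec.k_eq,
                   inhibitors=remap(spec.inhibitors), scale=spec.scale,
                   external=spec.external)


def _column(d: Dict[str, float], index: Dict[str, int], m: int,
            where: str) -> np.ndarray:
    col = np.zeros(m)
    for name, coeff in d.items():
        if name not in index:
            raise ValueError(f"{where}: references unknown metabolite "
                             f"{name!r}")
        col[index[name]] = coeff
    return col


def model_from_dict(doc: dict) -> WholeCellModel:
    """Build and validate a model from a parsed config document."""
    try:
        cfg = ModelConfig.model_validate(doc)
    except ValidationError as err:
        raise ValueError(f"invalid model config:\n{err}") from None
    if cfg.format_version != FORMAT_VERSION:
        raise ValueError(f"unsupported format_version {cfg.format_version} "
                         f"(this reader supports {FORMAT_VERSION})")
    met_names = [ms.name for ms in cfg.metabolites]
    if len(set(met_names)) != len(met_names):
        raise ValueError("duplicate metabolite names")
    index = {name: i for i, name in enumerate(met_names)}
    m, n = len(met_names), len(cfg.reactions)

    P = np.zeros((m, n))
    M = np.zeros((m, n + 1))
    f, g = [], []
    sigma = np.zeros(n + 1)
    for j, rx in enumerate(cfg.reactions):
        where = f"reaction {rx.name!r}"
        P[:, j] = _column(rx.stoich, index, m, where)
        M[:, j] = _column(rx.synthesis_cost, index, m, where)
        f.append(_law_from_spec(rx.rate, index, where))
        g.append(_law_from_spec(rx.translation_rate, index, where))
        sigma[j] = rx.sigma
    M[:, n] = _column(cfg.ribosome.synthesis_cost, index, m, "ribosome")
    g.append(_law_from_spec(cfg.ribosome.translation_rate, index,
                            "ribosome"))
    sigma[n] = cfg.ribosome.sigma

    spontaneous = [
        SpontaneousReaction(
            name=sp.name,
            stoich=_column(sp.stoich, index, m,
                           f"spontaneous reaction {sp.name!r}"),
            rate=_law_from_spec(sp.rate, index,
                                f"spontaneous reaction {sp.name!r}"))
        for sp in cfg.spontaneous]

    return WholeCellModel(
        metabolites=met_names,
        reactions=[rx.name for rx in cfg.reactions],
        P=P, M=M, f=f, g=g,
        rho=np.array([ms.rho for ms in cfg.metabolites]),
        sigma=sigma, lam=cfg.lam, spontaneous=spontaneous,
        negligible_dilution=cfg.negligible_dilution)


def read_model(path: Union[str, Path]) -> WholeCellModel:
    """Read and validate a model config file (strict schema)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: not a mapping document")
    return model_from_dict(doc)


def probe_concentrations(path: Union[str, Path]) -> np.ndarray:
    """The probe/initial metabolite concentrations stored in a config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg = ModelConfig.model_validate(doc)
    return np.array([ms.concentration for ms in cfg.metabolites])


def read_constraints(path: Union[str, Path],
                     model: WholeCellModel) -> List[EnzymeConstraint]:
    """Read enzyme-capacity constraints (standalone file or model config)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc.get("constraints", doc) if isinstance(doc, dict) else doc
    names = model.protein_names
    out = []
    for entry in entries:
        spec = ConstraintSpec.model_validate(entry)
        w = np.zeros(model.n + 1)
        for name, weight in spec.weights.items():
            if name not in names:
                raise ValueError(f"constraint {spec.label!r}: unknown "
                                 f"protein {name!r}")
            w[names.index(name)] = weight
        out.append(EnzymeConstraint(weights=w, cap=spec.cap,
                                    label=spec.label))
    return out


def _law_to_dict(law: RateLaw, names: Sequence[str]) -> dict:
    doc = {"kind": law.kind, "k_cat": float(law.k_cat)}
    for key, mapping in (("substrates", law.substrates),
                         ("products", law.products),
                         ("inhibitors", law.inhibitors)):
        if mapping:
            doc[key] = {names[i]: float(v) for i, v in sorted(mapping.items())}
    if law.k_eq != 1.0:
        doc["k_eq"] = float(law.k_eq)
    if law.scale != 1.0:
        doc["scale"] = float(law.scale)
    if law.external != 0.0:
        doc["external"] = float(law.external)
    return doc


def _sparse(col: np.ndarray, names: Sequence[str]) -> dict:
    return {names[i]: float(col[i]) for i in np.nonzero(col)[0]}


def model_to_dict(model: WholeCellModel,
                  concentrations: Optional[Sequence[float]] = None) -> dict:
    """Canonical plain-dict form of a model (inverse of model_from_dict)."""
    names = model.metabolites
    conc = (np.zeros(model.m) if concentrations is None
            else np.asarray(concentrations, dtype=float))
    doc = {
        "format_version": FORMAT_VERSION,
        "lambda": float(model.lam),
        "metabolites": [
            {"name": name, "rho": float(model.rho[i]),
             "concentration": float(conc[i])}
            for i, name in enumerate(names)],
        "reactions": [
            {"name": rx,
             "stoich": _sparse(model.P[:, j], names),
             "rate": _law_to_dict(model.f[j], names),
             "sigma": float(model.sigma[j]),
             "synthesis_cost": _sparse(model.M[:, j], names),
             "translation_rate": _law_to_dict(model.g[j], names)}
            for j, rx in enumerate(model.reactions)],
        "ribosome": {
            "sigma": float(model.sigma[model.n]),
            "synthesis_cost": _sparse(model.M[:, model.n], names),
            "translation_rate": _law_to_dict(model.g[model.n], names)},
    }
    if model.negligible_dilution:
        doc["negligible_dilution"] = True
    if model.spontaneous:
        doc["spontaneous"] = [
            {"name": sp.name,
             "stoich": _sparse(np.asarray(sp.stoich), names),
             "rate": _law_to_dict(sp.rate, names)}
            for sp in model.spontaneous]
    return doc


def write_model(model: WholeCellModel, path: Union[str, Path],
                concentrations: Optional[Sequence[float]] = None) -> None:
    """Write the canonical YAML form of a model."""
    doc = model_to_dict(model, concentrations)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)


def model_yaml(model: WholeCellModel) -> str:
    """Canonical YAML text of a model (embedded in result files)."""
    return yaml.safe_dump(model_to_dict(model), sort_keys=False)


def egs_table(egs_list: Sequence[EGS], model: WholeCellModel) -> str:
    """TSV table of EGSs: context (x, mu), then alpha by protein name."""
    names = model.protein_names
    header = (["mu"] + [f"x_{m}" for m in model.metabolites]
              + [f"alpha_{p}" for p in names] + ["support"])
    lines = ["\t".join(header)]
    for s in egs_list:
        row = ([f"{s.mu:.12g}"] + [f"{xi:.12g}" for xi in s.x]
               + [f"{a:.12g}" for a in s.alpha]
               + [",".join(names[j] for j in sorted(s.support))])
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def result_to_dict(result: OptimizationResult,
                   model: WholeCellModel) -> dict:
    """JSON-serialisable form of an optimisation result."""
    names = model.protein_names
    doc = {
        "mu_max": result.mu_max,
        "feasible": result.feasible,
        "x": {m: float(v) for m, v in zip(model.metabolites, result.x)},
        "alpha": (None if result.alpha is None else
                  {p: float(a) for p, a in zip(names, result.alpha)}),
        "support": sorted(names[j] for j in result.support),
        "active_constraints": result.active_constraints,
        "decomposition": [
            {"support": sorted(names[j] for j in egs.support),
             "weight": w}
            for egs, w in result.decomposition],
        "diagnostics": {k: v for k, v in result.diagnostics.items()
                        if isinstance(v, (int, float, str, list, tuple))},
    }
    return doc
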