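"""Constraint-based metabolic model containers.

A :class:`MetabolicModel` is a stoichiometric network: metabolites (rows of
the stoichiometric matrix S), reactions (columns, each with flux bounds and
a GPR rule), and an objective vector c over reactions (normally the biomass
reaction).  Models are plain in-memory objects; SBML/JSON I/O lives in
:mod:`slscan.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np

from .gpr import GprExpression, parse_gpr


class ModelValidationError(ValueError):
    pass


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str = ""


@dataclass
class Reaction:
    """One column of S: stoichiometry, flux bounds, GPR, objective weight."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GprExpression = field(default_factory=GprExpression)
    objective_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            # permitted at construction (used to model infeasibility) but
            # flagged by validate(); the LP layer handles it gracefully.
            pass
        if not math.isfinite(self.objective_coefficient):
            raise ModelValidationError(
                f"reaction {self.id}: objective coefficient must be finite"
            )

    @property
    def boundary(self) -> bool:
        """Exchange/demand/sink: touches a single metabolite (one-sided)."""
        return len(self.stoichiometry) <= 1

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,  # immutable
            objective_coefficient=self.objective_coefficient,
        )


@dataclass
class MetabolicModel:
    id: str
    metabolites: Dict[str, Metabolite]
    reactions: List[Reaction]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")

    # -- indexing -----------------------------------------------------------
    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.reactions:
            out |= r.gpr.genes()
        return out

    @property
    def objective_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.objective_coefficient != 0.0]

    @property
    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.boundary]

    # -- numerics -----------------------------------------------------------
    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense S with one row per metabolite, one column per reaction."""
        met_ids = list(self.metabolites)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                if met not in met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {met}"
                    )
                S[met_index[met], j] = coef
        return S, met_ids, self.reaction_ids

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        l = np.array([r.lower_bound for r in self.reactions], dtype=float)
        u = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return l, u

    def objective_vector(self) -> np.ndarray:
        return np.array([r.objective_coefficient for r in self.reactions])

    # -- structure ----------------------------------------------------------
    def validate(self) -> List[str]:
        """Structural checks; returns a list of problems (empty = clean)."""
        problems: List[str] = []
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                problems.append(f"reaction {r.id}: lower_bound > upper_bound")
            if not r.stoichiometry and not r.boundary:
                problems.append(f"reaction {r.id}: empty stoichiometry")
            for met in r.stoichiometry:
                if met not in self.metabolites:
                    problems.append(
                        f"reaction {r.id}: unknown metabolite {met}"
                    )
        if not self.objective_reactions:
            problems.append("no objective reaction set")
        return problems

    def copy(self, new_id: Optional[str] = None) -> "MetabolicModel":
        return MetabolicModel(
            id=new_id or self.id,
            metabolites={k: replace(v) for k, v in self.metabolites.items()},
            reactions=[r.copy() for r in self.reactions],
        )

    def subset(self, reaction_ids: Iterable[str], new_id: Optional[str] = None) -> "MetabolicModel":
        """Sub-model restricted to ``reaction_ids``; orphan metabolites pruned."""
        keep = set(reaction_ids)
        rxns = [r.copy() for r in self.reactions if r.id in keep]
        used = {m for r in rxns for m in r.stoichiometry}
        mets = {k: replace(v) for k, v in self.metabolites.items() if k in used}
        return MetabolicModel(id=new_id or f"{self.id}_sub", metabolites=mets, reactions=rxns)


@dataclass
class FluxSolution:
    """Outcome of an LP over a model: status, flux vector, objective value."""

    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    fluxes: Dict[str, float]
    objective_value: float = float("nan")

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def l1_norm(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))

    def support(self, tol: float = 1e-6) -> Set[str]:
        return {rid for rid, v in self.fluxes.items() if abs(v) > tol}
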