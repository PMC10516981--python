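"""Flux balance analysis, L1-minimal flux, and gene-deletion simulation.

FBA solves the LP

    maximize   c^T x
    subject to S x = 0,   l <= x <= u

with x the reaction flux vector.  The L1 (taxicab) minimisation re-solves
the network with the biomass flux pinned to its FBA optimum while
minimising sum(|v|), giving a parsimonious flux distribution whose support
defines the knockout (KO) gene list.

All LPs use the HiGHS solver via scipy (single-threaded, deterministic).
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import FluxSolution, MetabolicModel

#: flux magnitudes below this are treated as zero when reading LP supports
FLUX_SUPPORT_TOL = 1e-6


class NoObjectiveError(ValueError):
    """The model has no reaction with a nonzero objective coefficient."""


class ObjectivePinningError(RuntimeError):
    """The L1 problem is infeasible only because of the pinned objective."""


class NonViableModelError(RuntimeError):
    """Wild-type growth is non-positive; deletion ratios are undefined."""


_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


def _solve_lp(
    cost: np.ndarray,
    A_eq: Optional[np.ndarray],
    b_eq: Optional[np.ndarray],
    bounds: List[Tuple[float, float]],
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
):
    return linprog(
        cost,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )


def solve_fba(model: MetabolicModel) -> FluxSolution:
    """Maximise the model objective (biomass) at steady state.

    Raises :class:`NoObjectiveError` if no objective coefficient is set;
    solver failure is reported through ``FluxSolution.status``, never as a
    silent zero.
    """
    c = model.objective_vector()
    if not np.any(c):
        raise NoObjectiveError(f"model {model.id!r} has no objective reaction")
    S, _, rxn_ids = model.stoichiometric_matrix()
    l, u = model.bounds_arrays()
    if np.any(l > u):
        return FluxSolution(status="infeasible", fluxes={})
    res = _solve_lp(-c, S, np.zeros(S.shape[0]), list(zip(l, u)))
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxSolution(status=status, fluxes={})
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxSolution(status="optimal", fluxes=fluxes, objective_value=float(c @ res.x))


def fix_tolerance(target: float) -> float:
    """Half-width of the band in which the pinned objective must lie."""
    return 1e-6 * max(1.0, abs(target))


def solve_l1_min(model: MetabolicModel, target_objective: float) -> FluxSolution:
    """Minimise sum(|v|) subject to Sx=0, bounds, and c^T x pinned to
    ``target_objective`` (within ``fix_tolerance``).

    Uses the standard split reformulation x = p - q, p,q >= 0, minimising
    sum(p + q).  Raises :class:`ObjectivePinningError` when the pin alone
    makes the problem infeasible (the unpinned network is feasible).
    """
    c = model.objective_vector()
    S, _, rxn_ids = model.stoichiometric_matrix()
    l, u = model.bounds_arrays()
    m, n = S.shape
    tol = fix_tolerance(target_objective)

    # variables: [p (n), q (n)], x = p - q
    cost = np.ones(2 * n)
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    # bounds on x expressed as inequalities: l <= p - q <= u
    A_box = np.hstack([np.eye(n), -np.eye(n)])
    A_ub = np.vstack(
        [
            A_box,  # p - q <= u
            -A_box,  # -(p - q) <= -l
            np.hstack([-c, c])[None, :],  # -c.x <= -(target - tol)
            np.hstack([c, -c])[None, :],  # c.x <= target + tol
        ]
    )
    b_ub = np.concatenate([u, -l, [-(target_objective - tol)], [target_objective + tol]])
    bounds = [(0.0, None)] * (2 * n)
    res = _solve_lp(cost, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        if status == "infeasible":
            base = solve_fba(model)
            if base.status in ("optimal", "unbounded"):
                raise ObjectivePinningError(
                    f"objective cannot be pinned to {target_objective} "
                    f"(network itself is feasible)"
                )
        return FluxSolution(status=status, fluxes={})
    x = res.x[:n] - res.x[n:]
    fluxes = dict(zip(rxn_ids, x))
    return FluxSolution(status="optimal", fluxes=fluxes, objective_value=float(c @ x))


def flux_support_genes(
    model: MetabolicModel,
    solution: FluxSolution,
    tol: float = FLUX_SUPPORT_TOL,
) -> Set[str]:
    """Genes behind the reactions carrying flux: union of GPR leaves over
    reactions with |flux| > tol.  Reactions without a GPR contribute none."""
    if not solution.optimal:
        raise ValueError("flux support requires an optimal solution")
    genes: Set[str] = set()
    for rxn in model.reactions:
        if abs(solution.fluxes.get(rxn.id, 0.0)) > tol and not rxn.gpr.always_active:
            genes |= rxn.gpr.genes()
    return genes


def apply_gene_knockout(model: MetabolicModel, genes: Set[str]) -> MetabolicModel:
    """Close (bounds -> 0) every reaction whose GPR evaluates false with
    ``genes`` removed.  Returns a new model; unknown gene ids are inert."""
    ko = model.copy()
    for rxn in ko.reactions:
        if not rxn.gpr.always_active and not rxn.gpr.evaluate(genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return ko


def _ratio(objective: float, wild_type: float) -> float:
    return max(objective, 0.0) / wild_type  # clip solver noise below zero


def single_gene_deletion_ratios(
    model: MetabolicModel,
    genes: Iterable[str],
    wild_type: Optional[FluxSolution] = None,
) -> Dict[str, float]:
    """KO/WT growth ratio for each gene: 1 = no effect, 0 = lethal.

    Infeasible knockout models score 0; genes absent from every GPR score 1
    (their knockout closes nothing).  Raises :class:`NonViableModelError`
    when the wild-type optimum is not positive.
    """
    wt = wild_type if wild_type is not None else solve_fba(model)
    if not wt.optimal or wt.objective_value <= 0:
        raise NonViableModelError(
            f"model {model.id!r} wild-type objective is not positive"
        )
    ratios: Dict[str, float] = {}
    model_genes = model.genes
    for g in genes:
        if g not in model_genes:
            ratios[g] = 1.0
            continue
        sol = solve_fba(apply_gene_knockout(model, {g}))
        if not sol.optimal:
            ratios[g] = 0.0
        else:
            ratios[g] = min(_ratio(sol.objective_value, wt.objective_value), 1.0)
    return ratios


def exhaustive_double_deletion_sl(
    model: MetabolicModel, cutoff: float = 0.01
) -> Set[FrozenSet[str]]:
    """Naive exhaustive double-deletion synthetic-lethal search.

    A pair {gi, gj} is SL when each single deletion leaves growth above
    ``cutoff`` (as a fraction of wild type) but the double deletion drops
    it to ``cutoff`` or below.  Single-lethal genes are excluded.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    wt = solve_fba(model)
    if not wt.optimal or wt.objective_value <= 0:
        raise NonViableModelError(
            f"model {model.id!r} wild-type objective is not positive"
        )
    genes = sorted(model.genes)
    singles = single_gene_deletion_ratios(model, genes, wild_type=wt)
    viable = [g for g in genes if singles[g] > cutoff]
    pairs: Set[FrozenSet[str]] = set()
    for gi, gj in itertools.combinations(viable, 2):
        sol = solve_fba(apply_gene_knockout(model, {gi, gj}))
        ratio = _ratio(sol.objective_value, wt.objective_value) if sol.optimal else 0.0
        if ratio <= cutoff:
            pairs.add(frozenset((gi, gj)))
    return pairs
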