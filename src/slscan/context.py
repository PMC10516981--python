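"""Context-specific model extraction from expression data (iMAT-style).

Expression (log2 TPM) is mapped onto reactions through GPR rules
(AND -> min, OR -> max), reactions are classified highly / lowly /
moderately expressed against an (LB, UB) threshold pair, and an iMAT MILP
extracts the sub-network that maximises the number of highly-expressed
reactions carrying flux plus lowly-expressed reactions silenced.  A grid
search over threshold pairs picks the first pair that yields a
growth-viable extraction.  Quality control covers blocked reactions and a
metabolic-functionality benchmark against size-matched random sub-models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .fba import solve_fba
from .gpr import GeneLeaf, GprNode
from .model import MetabolicModel, Reaction

logger = logging.getLogger(__name__)

#: minimum flux for a "highly expressed" reaction to count as active in iMAT
IMAT_EPSILON = 0.1
#: FBA objective above this counts as non-zero growth in the grid search
OBJECTIVE_ZERO_TOL = 1e-6
#: demand flux a functionality task must reach to pass
EPSILON_TASK = 1e-4
#: |flux| above this marks a reaction as used in the MILP solution
_ACTIVE_TOL = 1e-6

#: sentinel for reactions with no GPR (never rewarded nor penalised)
UNMAPPED = None


class ExtractionError(RuntimeError):
    """The iMAT MILP is infeasible for the given classification."""


class NoViableThresholdsError(RuntimeError):
    """No threshold pair in the grid produced a growth-viable model."""


@dataclass
class ExpressionProfile:
    """Per-cell-line gene expression (log2 TPM semantics)."""

    cell_line_id: str
    values: Dict[str, float]


@dataclass
class ReactionExpressionVector:
    """One expression value per reaction; ``None`` marks unmapped (no GPR)."""

    values: Dict[str, Optional[float]]

    def mapped_values(self) -> np.ndarray:
        return np.array([v for v in self.values.values() if v is not None])


@dataclass(frozen=True)
class ThresholdPair:
    lb: float
    ub: float

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(f"threshold lb ({self.lb}) exceeds ub ({self.ub})")


@dataclass
class FunctionalityTask:
    """Can the network synthesise ``target`` from the listed inputs?"""

    id: str
    inputs: List[str]
    target: str


@dataclass
class ConstructionReport:
    """QC summary of one context model build."""

    passed_tasks: int
    random_pass_counts: List[int]
    blocked_reactions: List[str]
    biomass_value: float
    seed: Optional[int] = None

    @property
    def success(self) -> bool:
        """True iff passed_tasks exceeds at least 99% of the random counts."""
        n = len(self.random_pass_counts)
        if n == 0:
            return False
        exceeded = sum(self.passed_tasks > c for c in self.random_pass_counts)
        return exceeded >= int(np.ceil(0.99 * n))


@dataclass
class VerificationReport:
    blocked_reactions: List[str]
    biomass_value: float
    structural_problems: List[str]

    @property
    def consistent(self) -> bool:
        return (
            not self.blocked_reactions
            and not self.structural_problems
            and self.biomass_value > 0
        )


# ---------------------------------------------------------------------------
# expression -> reaction mapping
# ---------------------------------------------------------------------------

def _aggregate_gpr(node: GprNode, values: Mapping[str, float]) -> Optional[float]:
    # AND -> min, OR -> max over leaves that have expression; genes missing
    # from the profile are ignored (a wholly missing rule maps to None).
    if isinstance(node, GeneLeaf):
        return values.get(node.gene)
    child = [v for v in (_aggregate_gpr(c, values) for c in node.children) if v is not None]
    if not child:
        return None
    return min(child) if node.op == "and" else max(child)


def map_expression_to_reactions(
    model: MetabolicModel, profile: ExpressionProfile
) -> ReactionExpressionVector:
    """Build the reaction expression vector: GPR AND -> min, OR -> max.

    Reactions with no GPR, or whose genes are all absent from the profile,
    get the unmapped sentinel (``None``).
    """
    out: Dict[str, Optional[float]] = {}
    for rxn in model.reactions:
        if rxn.gpr.always_active:
            out[rxn.id] = UNMAPPED
        else:
            out[rxn.id] = _aggregate_gpr(rxn.gpr.root, profile.values)
    return ReactionExpressionVector(values=out)


def classify_reactions(
    vec: ReactionExpressionVector, thr: ThresholdPair
) -> Dict[str, str]:
    """Partition reactions into ``high`` (>= UB), ``low`` (<= LB) and
    ``moderate`` (in between, or unmapped)."""
    classes: Dict[str, str] = {}
    for rid, v in vec.values.items():
        if v is None:
            classes[rid] = "moderate"
        elif v >= thr.ub:
            classes[rid] = "high"
        elif v <= thr.lb:
            classes[rid] = "low"
        else:
            classes[rid] = "moderate"
    return classes


# ---------------------------------------------------------------------------
# iMAT MILP
# ---------------------------------------------------------------------------

def _imat_milp(
    model: MetabolicModel,
    classes: Mapping[str, str],
    epsilon: float,
) -> Tuple[np.ndarray, float]:
    """Solve the iMAT MILP; returns (flux vector, indicator score).

    maximise  #high reactions with |flux| >= epsilon
            + #low  reactions with flux == 0
    s.t. Sx = 0, l <= x <= u.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    l, u = model.bounds_arrays()
    m, n = S.shape
    high = [j for j, rid in enumerate(rxn_ids) if classes.get(rid) == "high"]
    low = [j for j, rid in enumerate(rxn_ids) if classes.get(rid) == "low"]

    # variables: v (n) | y_fwd per high | y_rev per reversible high | z per low
    rev_high = [j for j in high if l[j] < -epsilon / 2]
    n_yf, n_yr, n_z = len(high), len(rev_high), len(low)
    ntot = n + n_yf + n_yr + n_z
    off_yf, off_yr, off_z = n, n + n_yf, n + n_yf + n_yr

    cost = np.zeros(ntot)
    cost[off_yf:] = -1.0  # maximise indicator sum

    rows: List[np.ndarray] = []
    lo: List[float] = []
    hi: List[float] = []

    def add(row: np.ndarray, lb: float, ub: float) -> None:
        rows.append(row)
        lo.append(lb)
        hi.append(ub)

    for i in range(m):
        row = np.zeros(ntot)
        row[:n] = S[i]
        add(row, 0.0, 0.0)

    for k, j in enumerate(high):
        # forward activation: v_j + y (l_j - eps) >= l_j
        row = np.zeros(ntot)
        row[j] = 1.0
        row[off_yf + k] = l[j] - epsilon
        add(row, l[j], np.inf)
    for k, j in enumerate(rev_high):
        # reverse activation: v_j + y (u_j + eps) <= u_j
        row = np.zeros(ntot)
        row[j] = 1.0
        row[off_yr + k] = u[j] + epsilon
        add(row, -np.inf, u[j])
        # at most one direction counted
        row2 = np.zeros(ntot)
        row2[off_yf + high.index(j)] = 1.0
        row2[off_yr + k] = 1.0
        add(row2, -np.inf, 1.0)
    for k, j in enumerate(low):
        # z = 1 forces v_j = 0: l_j(1-z) <= v_j <= u_j(1-z)
        row = np.zeros(ntot)
        row[j] = 1.0
        row[off_z + k] = l[j]
        add(row, l[j], np.inf)
        row2 = np.zeros(ntot)
        row2[j] = 1.0
        row2[off_z + k] = u[j]
        add(row2, -np.inf, u[j])

    A = csr_matrix(np.vstack(rows)) if rows else csr_matrix((0, ntot))
    constraints = LinearConstraint(A, np.array(lo), np.array(hi))
    var_lo = np.concatenate([l, np.zeros(ntot - n)])
    var_hi = np.concatenate([u, np.ones(ntot - n)])
    integrality = np.concatenate([np.zeros(n), np.ones(ntot - n)])
    res = milp(
        c=cost,
        constraints=constraints,
        bounds=Bounds(var_lo, var_hi),
        integrality=integrality,
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0 or res.x is None:
        raise ExtractionError(f"iMAT MILP did not solve (status {res.status})")
    return res.x[:n], -float(res.fun)


def imat_extract(
    model: MetabolicModel,
    classes: Mapping[str, str],
    core: Set[str],
    epsilon: float = IMAT_EPSILON,
) -> MetabolicModel:
    """Extract the context-specific sub-model selected by the iMAT MILP.

    The returned model keeps every core reaction plus every reaction
    carrying nonzero flux in the MILP optimum; orphan metabolites are
    pruned.  ``core`` must contain the objective (biomass) reaction.
    """
    objective_ids = {r.id for r in model.objective_reactions}
    if not objective_ids <= core:
        raise ValueError("core must include the objective (biomass) reaction")
    v, _score = _imat_milp(model, classes, epsilon)
    rxn_ids = model.reaction_ids
    keep = set(core)
    keep |= {rid for rid, f in zip(rxn_ids, v) if abs(f) > _ACTIVE_TOL}
    sub = model.subset(keep, new_id=f"{model.id}_ctx")
    check = solve_fba(sub)
    if check.status not in ("optimal", "unbounded"):
        raise ExtractionError(
            f"extracted model admits no feasible FBA (status {check.status})"
        )
    return sub


# ---------------------------------------------------------------------------
# threshold grid search
# ---------------------------------------------------------------------------

def default_threshold_grid(vec: ReactionExpressionVector) -> List[ThresholdPair]:
    """Quantile threshold grid over mapped reaction expression values,
    evaluated in a fixed order: (q25,q75), (q25,q90), (q10,q75), (q10,q90),
    (q50,q75)."""
    vals = vec.mapped_values()
    if vals.size == 0:
        raise ValueError("no mapped reactions; cannot build a threshold grid")
    q = {p: float(np.quantile(vals, p / 100)) for p in (10, 25, 50, 75, 90)}
    pairs = [(25, 75), (25, 90), (10, 75), (10, 90), (50, 75)]
    return [ThresholdPair(lb=q[a], ub=q[b]) for a, b in pairs]


def threshold_grid_search(
    model: MetabolicModel,
    profile: ExpressionProfile,
    grid: Optional[Sequence[ThresholdPair]] = None,
    core: Optional[Set[str]] = None,
    epsilon: float = IMAT_EPSILON,
) -> Tuple[ThresholdPair, MetabolicModel]:
    """Return the first (LB, UB) pair whose iMAT extraction grows.

    Iterates ``grid`` in order; for each pair classifies reactions,
    extracts, and accepts the pair iff the extracted model's FBA optimum
    exceeds ``OBJECTIVE_ZERO_TOL``.  Raises
    :class:`NoViableThresholdsError` when the grid is exhausted.
    """
    vec = map_expression_to_reactions(model, profile)
    if grid is None:
        grid = default_threshold_grid(vec)
    if not grid:
        raise ValueError("threshold grid is empty")
    if core is None:
        core = {r.id for r in model.objective_reactions}
    for thr in grid:
        classes = classify_reactions(vec, thr)
        try:
            ctx = imat_extract(model, classes, core=core, epsilon=epsilon)
        except ExtractionError:
            logger.debug("thresholds %s: extraction failed", thr)
            continue
        sol = solve_fba(ctx)
        if sol.optimal and sol.objective_value > OBJECTIVE_ZERO_TOL:
            return thr, ctx
        logger.debug("thresholds %s: extracted model does not grow", thr)
    raise NoViableThresholdsError(
        f"no threshold pair in the grid yields a growing model for "
        f"{profile.cell_line_id!r}"
    )


# ---------------------------------------------------------------------------
# model QC
# ---------------------------------------------------------------------------

def find_blocked_reactions(model: MetabolicModel, tol: float = 1e-7) -> List[str]:
    """Reactions that carry zero flux in every feasible steady state,
    found by per-reaction flux maximisation/minimisation LPs."""
    from scipy.optimize import linprog

    S, _, rxn_ids = model.stoichiometric_matrix()
    l, u = model.bounds_arrays()
    blocked = []
    b_eq = np.zeros(S.shape[0])
    bounds = list(zip(l, u))
    for j, rid in enumerate(rxn_ids):
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        hi = linprog(-c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
        if hi.status == 0 and -hi.fun > tol:
            continue
        lo = linprog(c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
        if lo.status == 0 and lo.fun < -tol:
            continue
        blocked.append(rid)
    return blocked


def verify_context_model(model: MetabolicModel) -> VerificationReport:
    """Structural + flux-consistency report: blocked reactions, biomass
    FBA value, and field-level problems."""
    problems = model.validate()
    try:
        sol = solve_fba(model)
        biomass = sol.objective_value if sol.optimal else 0.0
    except Exception as exc:  # e.g. no objective
        problems.append(str(exc))
        biomass = 0.0
    blocked = find_blocked_reactions(model) if not problems else []
    return VerificationReport(
        blocked_reactions=blocked,
        biomass_value=float(biomass),
        structural_problems=problems,
    )


# ---------------------------------------------------------------------------
# functionality tasks
# ---------------------------------------------------------------------------

def _task_passes(model: MetabolicModel, task: FunctionalityTask) -> bool:
    if task.target not in model.metabolites:
        return False
    work = model.copy()
    for rxn in work.reactions:
        if rxn.boundary:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        rxn.objective_coefficient = 0.0
    for met in task.inputs:
        if met in work.metabolites:
            work.reactions.append(
                Reaction(
                    id=f"_task_in_{met}",
                    stoichiometry={met: 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                )
            )
    work.reactions.append(
        Reaction(
            id="_task_demand",
            stoichiometry={task.target: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            objective_coefficient=1.0,
        )
    )
    sol = solve_fba(work)
    return sol.optimal and sol.objective_value >= EPSILON_TASK


def run_functionality_tasks(
    model: MetabolicModel, tasks: Sequence[FunctionalityTask]
) -> int:
    """Number of tasks passed: a task passes iff the target metabolite can
    be produced at >= EPSILON_TASK flux with only the task inputs
    importable (existing exchanges closed)."""
    return sum(_task_passes(model, t) for t in tasks)


def random_model_benchmark(
    generic: MetabolicModel,
    size: int,
    tasks: Sequence[FunctionalityTask],
    n: int = 100,
    seed: int = 0,
) -> List[int]:
    """Task pass counts for ``n`` random sub-models of ``generic`` with
    ``size`` reactions each.  Exchange reactions and the biomass reaction
    are always retained; the remaining slots are drawn uniformly without
    replacement (seeded)."""
    if size > len(generic.reactions):
        raise ValueError("size exceeds the generic model's reaction count")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    always = {r.id for r in generic.exchange_reactions}
    always |= {r.id for r in generic.objective_reactions}
    pool = [r.id for r in generic.reactions if r.id not in always]
    n_draw = max(0, min(size - len(always), len(pool)))
    counts = []
    for _ in range(n):
        chosen = set(rng.choice(pool, size=n_draw, replace=False)) if n_draw else set()
        sub = generic.subset(always | chosen)
        counts.append(run_functionality_tasks(sub, tasks))
    return counts


def construction_report(
    context_model: MetabolicModel,
    generic: MetabolicModel,
    tasks: Sequence[FunctionalityTask],
    n_random: int = 100,
    seed: int = 0,
) -> ConstructionReport:
    """Full QC: task count for the context model, the random benchmark,
    blocked reactions and biomass.  ``success`` applies the
    better-than-99%-of-random rule."""
    verification = verify_context_model(context_model)
    passed = run_functionality_tasks(context_model, tasks)
    randoms = random_model_benchmark(
        generic, size=len(context_model.reactions), tasks=tasks, n=n_random, seed=seed
    )
    return ConstructionReport(
        passed_tasks=passed,
        random_pass_counts=randoms,
        blocked_reactions=verification.blocked_reactions,
        biomass_value=verification.biomass_value,
        seed=seed,
    )
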