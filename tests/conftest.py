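import numpy as np
import pytest

from slscan.fixtures import make_toy_model
from slscan.model import MetabolicModel, Metabolite, Reaction


@pytest.fixture
def toy_parallel():
    return make_toy_model("parallel")


@pytest.fixture
def toy_linear():
    return make_toy_model("linear")


@pytest.fixture
def toy_branched():
    return make_toy_model("branched")


def random_network(rng: np.random.Generator) -> MetabolicModel:
    """Small random consistent network: a metabolite chain with random
    capacities and occasional skip reactions, import at the head, an
    objective export at the tail.  Always bounded and feasible."""
    k = int(rng.integers(3, 7))
    mets = {f"M{i}": Metabolite(id=f"M{i}") for i in range(k)}
    reactions = [
        Reaction("IMP", {"M0": 1.0}, 0.0, float(rng.uniform(1, 20))),
    ]
    for i in range(k - 1):
        reactions.append(
            Reaction(
                f"C{i}",
                {f"M{i}": -1.0, f"M{i+1}": 1.0},
                0.0,
                float(rng.uniform(1, 20)),
                gpr=f"g{i}",
            )
        )
    # occasional skip edges widen the LP beyond a pure chain
    for i in range(k - 2):
        if rng.uniform() < 0.5:
            reactions.append(
                Reaction(
                    f"S{i}",
                    {f"M{i}": -1.0, f"M{i+2}": 1.0},
                    0.0,
                    float(rng.uniform(1, 20)),
                )
            )
    reactions.append(
        Reaction("OBJ", {f"M{k-1}": -1.0}, 0.0, 1000.0, objective_coefficient=1.0)
    )
    return MetabolicModel(id=f"rand{rng.integers(1e6)}", metabolites=mets, reactions=reactions)


def cobra_fba_objective(model: MetabolicModel) -> float:
    """Independent FBA oracle: solve the same model through cobrapy/GLPK."""
    from slscan.io import to_cobra

    cm = to_cobra(model)
    cm.solver = "glpk"
    sol = cm.optimize()
    assert sol.status == "optimal"
    return float(sol.objective_value)
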