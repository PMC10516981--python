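"""Deterministic toy models and seeded synthetic datasets.

Three fixed toy networks exercise every solver path:

``parallel`` (TOY-P)
    A is imported (cap 10) and converted to biomass precursor B either
    directly (R1, gene g1) or via C (R2a gene g2, then R2b gene "g3 or
    g4").  FBA optimum 10; knocking out g1 alone reroutes through C, so
    only the {g1, g2} double deletion is lethal.

``linear`` (TOY-L)
    A single A -> B path gated by the complex "gA and gB" (cap 5); either
    gene alone is lethal.

``branched``
    A 10-reaction variant with one structurally blocked dead-end reaction.

The planted-SL generator emulates the study's input formats (expression
CSV, MAF-like mutation table) around the ``parallel`` network: in mutated
cell lines the driver's backup route is transcriptionally silenced, so the
partner gene becomes essential only there.  The null generator breaks the
mutation-expression link, for false-positive calibration.

All fixtures are pure functions of their arguments; randomness uses
numpy's default PCG64 generator with per-fixture seeds derived from
(seed, crc32(fixture name)).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import MetabolicModel, Metabolite, Reaction
from .scan import MutationMatrix

#: expression jitter half-width (log2 scale); small enough never to cross
#: the toy LB/UB thresholds
JITTER = 0.1

#: (LB, UB) threshold pair separating the toy low/high expression levels
TOY_THRESHOLDS = (2.0, 5.0)


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng((int(seed), zlib.crc32(name.encode())))


def _mets(*ids: str) -> Dict[str, Metabolite]:
    return {m: Metabolite(id=m) for m in ids}


def make_toy_model(name: str) -> MetabolicModel:
    """Return one of the fixed toy networks: ``parallel``, ``linear`` or
    ``branched`` (see module docstring)."""
    if name == "parallel":
        return MetabolicModel(
            id="TOY-P",
            metabolites=_mets("A", "B", "C"),
            reactions=[
                Reaction("EX_A", {"A": 1.0}, 0, 10),
                Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 1000, gpr="g1"),
                Reaction("R2a", {"A": -1.0, "C": 1.0}, 0, 1000, gpr="g2"),
                Reaction("R2b", {"C": -1.0, "B": 1.0}, 0, 1000, gpr="g3 or g4"),
                Reaction("BIO", {"B": -1.0}, 0, 1000, objective_coefficient=1.0),
            ],
        )
    if name == "linear":
        return MetabolicModel(
            id="TOY-L",
            metabolites=_mets("A", "B"),
            reactions=[
                Reaction("EX_A", {"A": 1.0}, 0, 5),
                Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 1000, gpr="gA and gB"),
                Reaction("BIO", {"B": -1.0}, 0, 1000, objective_coefficient=1.0),
            ],
        )
    if name == "branched":
        return MetabolicModel(
            id="TOY-B",
            metabolites=_mets("A", "B", "C", "D", "E", "X"),
            reactions=[
                Reaction("EX_A", {"A": 1.0}, 0, 10),
                Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 1000, gpr="g1"),
                Reaction("R2a", {"A": -1.0, "C": 1.0}, 0, 1000, gpr="g2"),
                Reaction("R2b", {"C": -1.0, "B": 1.0}, 0, 1000, gpr="g3 or g4"),
                Reaction("R3", {"B": -1.0, "D": 1.0}, 0, 1000, gpr="g5"),
                Reaction("R4", {"C": -1.0, "D": 1.0}, 0, 1000, gpr="g6"),
                Reaction("R5", {"A": -1.0, "D": 1.0}, 0, 1000, gpr="g10"),
                Reaction("R6", {"D": -1.0, "E": 1.0}, 0, 1000, gpr="g7 and g8"),
                Reaction("DEAD", {"E": -1.0, "X": 1.0}, 0, 1000, gpr="g9"),
                Reaction("BIO", {"E": -1.0}, 0, 1000, objective_coefficient=1.0),
            ],
        )
    raise ValueError(f"unknown toy model {name!r}")


# ---------------------------------------------------------------------------
# planted-SL dataset
# ---------------------------------------------------------------------------

@dataclass
class PlantedSLScenario:
    """Conditions for a planted synthetic-lethal dataset on TOY-P."""

    n_cell_lines: int = 20
    driver: str = "g2"
    partner: str = "g1"
    fraction_mutated: float = 0.5
    expression_high: float = 10.0
    expression_low: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.driver == self.partner:
            raise ValueError("driver and partner must differ")
        if not (0.0 < self.fraction_mutated < 1.0):
            raise ValueError("fraction_mutated must lie in (0, 1)")


@dataclass
class PlantedTruth:
    driver: str
    partner: str
    mutated_lines: List[str]


def _line_names(n: int) -> List[str]:
    return [f"CL{i:03d}" for i in range(n)]


def generate_planted_sl_dataset(
    scenario: PlantedSLScenario,
) -> Tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Expression matrix, MAF-like mutation table, and the planted truth.

    Mutated lines carry a damaging MAF record for the driver, and the whole
    backup route (the driver gene and its downstream isozymes) is
    transcriptionally silenced there, so context extraction drops the route
    and the partner becomes essential; wild lines express every gene
    highly.  Small seeded jitter (±0.1 log2 units) is added everywhere.
    """
    s = scenario
    rng = _rng(s.seed, "planted")
    lines = _line_names(s.n_cell_lines)
    n_mut = int(round(s.n_cell_lines * s.fraction_mutated))
    mutated = sorted(rng.choice(lines, size=n_mut, replace=False))

    genes = ["g1", "g2", "g3", "g4"]
    backup_route = {s.driver} | ({"g3", "g4"} if s.driver == "g2" else set())
    expr = pd.DataFrame(
        s.expression_high + rng.uniform(-JITTER, JITTER, size=(len(genes), len(lines))),
        index=genes,
        columns=lines,
    )
    for cl in mutated:
        for g in sorted(backup_route):
            expr.loc[g, cl] = s.expression_low + rng.uniform(-JITTER, JITTER)

    maf_rows = []
    for cl in mutated:
        maf_rows.append(
            {
                "Hugo_Symbol": s.driver,
                "Tumor_Sample_Barcode": cl,
                "Variant_Classification": "Nonsense_Mutation",
                "isDeleterious": "True",
            }
        )
    # benign passenger rows: never damaging, never on the driver
    for cl in lines:
        if rng.uniform() < 0.3:
            maf_rows.append(
                {
                    "Hugo_Symbol": str(rng.choice([g for g in genes if g != s.driver])),
                    "Tumor_Sample_Barcode": cl,
                    "Variant_Classification": "Silent",
                    "isDeleterious": "False",
                }
            )
    maf = pd.DataFrame(maf_rows)
    truth = PlantedTruth(driver=s.driver, partner=s.partner, mutated_lines=list(mutated))
    return expr, maf, truth


def planted_mutation_matrix(
    maf: pd.DataFrame, genes: List[str], cell_lines: List[str]
) -> MutationMatrix:
    """Damaging-mutation matrix from the fixture MAF (same rule as io.read_maf)."""
    damaging = maf[maf["isDeleterious"].astype(str).str.lower() == "true"]
    calls = pd.DataFrame(False, index=genes, columns=cell_lines)
    for _, row in damaging.iterrows():
        g, cl = row["Hugo_Symbol"], row["Tumor_Sample_Barcode"]
        if g in calls.index and cl in calls.columns:
            calls.loc[g, cl] = True
    return MutationMatrix(calls=calls, provenance="synthetic planted fixture")


# ---------------------------------------------------------------------------
# null dataset
# ---------------------------------------------------------------------------

def generate_null_dataset(
    n_cell_lines: int, seed: int = 0
) -> Tuple[pd.DataFrame, MutationMatrix]:
    """Dataset with no SL structure: mutation labels ~ Bernoulli(0.5) per
    gene and cell line, expression states drawn independently of them."""
    if n_cell_lines < 8:
        raise ValueError("need at least 8 cell lines for a null scan")
    rng = _rng(seed, "null")
    lines = _line_names(n_cell_lines)
    genes = ["g1", "g2", "g3", "g4"]
    expr = pd.DataFrame(
        10.0 + rng.uniform(-JITTER, JITTER, size=(len(genes), len(lines))),
        index=genes,
        columns=lines,
    )
    # backup route silenced in a random half of lines, independent of the
    # mutation calls, so KO scores vary without any driver association
    for cl in lines:
        if rng.uniform() < 0.5:
            for g in ("g2", "g3", "g4"):
                expr.loc[g, cl] = 1.0 + rng.uniform(-JITTER, JITTER)
    calls = pd.DataFrame(
        rng.uniform(size=(len(genes), len(lines))) < 0.5,
        index=genes,
        columns=lines,
    )
    return expr, MutationMatrix(calls=calls, provenance="synthetic null fixture")


# ---------------------------------------------------------------------------
# end-to-end convenience wrappers
# ---------------------------------------------------------------------------

def planted_scan(scenario: PlantedSLScenario):
    """Run the full simulated pipeline on a planted dataset: context models
    -> KO-score matrix -> mutation-stratified scan.  Returns
    (SLResultTable, PlantedTruth)."""
    from .context import ThresholdPair
    from .pipeline import build_cell_line_models
    from .scan import build_ko_score_matrix, slscan_scan

    expr, maf, truth = generate_planted_sl_dataset(scenario)
    generic = make_toy_model("parallel")
    grid = [ThresholdPair(*TOY_THRESHOLDS)]
    models = build_cell_line_models(generic, expr, grid=grid)
    scores = build_ko_score_matrix(models, sorted(generic.genes))
    mutations = planted_mutation_matrix(maf, scores.genes, scores.cell_lines)
    table = slscan_scan(scores, mutations, seed=scenario.seed)
    return table, truth


def null_scan(n_cell_lines: int, seed: int = 0):
    """Full simulated pipeline on a null dataset; returns the SLResultTable."""
    from .context import ThresholdPair
    from .pipeline import build_cell_line_models
    from .scan import build_ko_score_matrix, slscan_scan

    expr, mutations = generate_null_dataset(n_cell_lines, seed=seed)
    generic = make_toy_model("parallel")
    grid = [ThresholdPair(*TOY_THRESHOLDS)]
    models = build_cell_line_models(generic, expr, grid=grid)
    scores = build_ko_score_matrix(models, sorted(generic.genes))
    return slscan_scan(scores, mutations, seed=seed)
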