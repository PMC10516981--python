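"""Readers and writers for the pipeline's file formats.

Metabolic models: SBML Level 3 + FBC (delegated to cobrapy/libsbml) and a
JSON dialect with fields ``metabolites``, ``reactions`` (id, metabolites,
lower_bound, upper_bound, gene_reaction_rule, objective_coefficient) and
``genes``.  Tabular inputs: expression CSV (first column gene id, remaining
columns cell lines, log2 TPM), MAF-like mutation tables, dependency
matrices, functionality-task files, and GMT gene-set files.

Gene identifiers are opaque strings throughout; numeric entrez.transcript
ids ("1234.1") survive every round trip unmodified.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import pandas as pd

from .context import ExpressionProfile, FunctionalityTask
from .enrich import GeneSetCollection
from .model import MetabolicModel, Metabolite, Reaction
from .scan import MutationMatrix
from .validation import DependencyMatrix

PathLike = Union[str, Path]

#: MAF Variant_Classification values treated as damaging when no explicit
#: deleterious flag is present
DAMAGING_CLASSES = frozenset(
    {
        "Nonsense_Mutation",
        "Nonsense",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Nonstop",
        "De_novo_Start_OutOfFrame",
    }
)


# ---------------------------------------------------------------------------
# model JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string(),
                "objective_coefficient": r.objective_coefficient,
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
    }


def model_from_dict(data: Mapping) -> MetabolicModel:
    metabolites = {
        m["id"]: Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", ""),
            formula=m.get("formula", ""),
        )
        for m in data["metabolites"]
    }
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            gpr=r.get("gene_reaction_rule", ""),
            objective_coefficient=float(r.get("objective_coefficient", 0.0)),
        )
        for r in data["reactions"]
    ]
    return MetabolicModel(
        id=data.get("id", "model"), metabolites=metabolites, reactions=reactions
    )


def write_json_model(model: MetabolicModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_json_model(path: PathLike) -> MetabolicModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (also used as the FBA oracle in tests)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        mid: cobra.Metabolite(
            mid, name=m.name, compartment=m.compartment or "c", formula=m.formula or None
        )
        for mid, m in model.metabolites.items()
    }
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        cr.gene_reaction_rule = r.gpr.to_string()
        rxns.append(cr)
    cm.add_reactions(rxns)
    cm.objective = {
        cm.reactions.get_by_id(r.id): r.objective_coefficient
        for r in model.objective_reactions
    }
    return cm


def from_cobra(cm) -> MetabolicModel:
    from cobra.util.solver import linear_reaction_coefficients

    coeffs = {r.id: c for r, c in linear_reaction_coefficients(cm).items()}
    metabolites = {
        m.id: Metabolite(
            id=m.id, name=m.name or "", compartment=m.compartment or "",
            formula=m.formula or "",
        )
        for m in cm.metabolites
    }
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: v for m, v in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            gpr=r.gene_reaction_rule or "",
            objective_coefficient=coeffs.get(r.id, 0.0),
        )
        for r in cm.reactions
    ]
    return MetabolicModel(id=cm.id or "model", metabolites=metabolites, reactions=reactions)


def read_sbml_model(path: PathLike) -> MetabolicModel:
    from cobra.io import read_sbml_model as _read

    return from_cobra(_read(str(path)))


def write_sbml_model(model: MetabolicModel, path: PathLike) -> None:
    from cobra.io import write_sbml_model as _write

    _write(to_cobra(model), str(path))


def read_model(path: PathLike) -> MetabolicModel:
    """Dispatch on extension: .json -> JSON dialect, .xml/.sbml -> SBML."""
    p = Path(path)
    if p.suffix == ".json":
        return read_json_model(p)
    if p.suffix in (".xml", ".sbml"):
        return read_sbml_model(p)
    raise ValueError(f"unrecognised model format: {p.suffix!r}")


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def read_expression_csv(path: PathLike) -> pd.DataFrame:
    """Gene x cell-line expression matrix (log2 TPM); first column gene id."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_expression_csv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index_label="gene")


def expression_profiles(df: pd.DataFrame) -> Dict[str, ExpressionProfile]:
    return {
        cl: ExpressionProfile(cell_line_id=cl, values=df[cl].to_dict())
        for cl in df.columns
    }


def read_maf(
    path: PathLike,
    gene_column: str = "Hugo_Symbol",
    sample_column: str = "Tumor_Sample_Barcode",
    class_column: str = "Variant_Classification",
    deleterious_column: Optional[str] = "isDeleterious",
    damaging_classes: Iterable[str] = DAMAGING_CLASSES,
    cell_lines: Optional[Sequence[str]] = None,
    genes: Optional[Sequence[str]] = None,
) -> MutationMatrix:
    """Collapse a MAF-like variant table to a boolean damaging-mutation
    matrix (genes x cell lines).

    A variant is damaging if its deleterious flag is true, else if its
    variant classification is in ``damaging_classes``.  ``cell_lines`` and
    ``genes``, when given, fix the matrix axes (absent entries = False).
    """
    sep = "\t" if str(path).endswith((".tsv", ".maf", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    damaging_classes = set(damaging_classes)
    damaging = pd.Series(False, index=df.index)
    if deleterious_column and deleterious_column in df.columns:
        flag = df[deleterious_column].astype(str).str.lower().isin(("true", "1", "yes"))
        damaging |= flag
    if class_column in df.columns:
        damaging |= df[class_column].isin(damaging_classes)
    hits = df[damaging]
    calls = (
        hits.groupby([gene_column, sample_column]).size().unstack(fill_value=0) > 0
    )
    if genes is not None:
        calls = calls.reindex(index=list(genes), fill_value=False)
    if cell_lines is not None:
        calls = calls.reindex(columns=list(cell_lines), fill_value=False)
    calls.index.name = None
    calls.columns.name = None
    rule = f"deleterious_flag|classes={sorted(damaging_classes)}"
    return MutationMatrix(calls=calls, provenance=f"{path};rule={rule}")


def read_dependency_csv(path: PathLike, kind: str = "crispr") -> DependencyMatrix:
    """Entity x cell-line viability matrix; first column entity id."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return DependencyMatrix(values=df, kind=kind)


def read_compound_targets(path: PathLike) -> Dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


# ---------------------------------------------------------------------------
# functionality tasks
# ---------------------------------------------------------------------------

def read_tasks(path: PathLike) -> List[FunctionalityTask]:
    """Task file: CSV with columns id, inputs (';'-separated), target — or
    JSON list of {id, inputs, target}."""
    p = Path(path)
    if p.suffix == ".json":
        data = json.loads(p.read_text())
        return [
            FunctionalityTask(id=t["id"], inputs=list(t["inputs"]), target=t["target"])
            for t in data
        ]
    df = pd.read_csv(p, dtype=str)
    tasks = []
    for _, row in df.iterrows():
        inputs = [s for s in str(row["inputs"]).split(";") if s and s != "nan"]
        tasks.append(FunctionalityTask(id=row["id"], inputs=inputs, target=row["target"]))
    return tasks


def write_tasks(tasks: Sequence[FunctionalityTask], path: PathLike) -> None:
    pd.DataFrame(
        {
            "id": [t.id for t in tasks],
            "inputs": [";".join(t.inputs) for t in tasks],
            "target": [t.target for t in tasks],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: PathLike) -> GeneSetCollection:
    sets: Dict[str, Set[str]] = {}
    descriptions: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:50]!r}")
        name, desc, members = parts[0], parts[1], parts[2:]
        sets[name] = {g for g in members if g}
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + sorted(members))
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
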