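"""End-to-end pipeline: model build -> KO scan -> SL scan -> validation ->
enrichment, driven by a YAML config with resumable per-stage outputs."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from . import io as sio
from .context import ThresholdPair, threshold_grid_search
from .enrich import preranked_gsea, build_ranked_list, process_frequency
from .fba import exhaustive_double_deletion_sl
from .model import MetabolicModel
from .scan import KOScoreMatrix, SLResultTable, build_ko_score_matrix, slscan_scan
from .validation import concordance_report, screen_sl_scan

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6e"

_DEFAULT_PARAMS: Dict[str, object] = {
    "alpha": 0.05,
    "filter_mean": 0.95,
    "epsilon": 0.1,
    "cutoff": 0.01,
    "seed": 0,
    "min_mutated_lines": 2,
    "noise_lo": 1e-12,
    "noise_hi": 1e-11,
    "n_perm": 1000,
    "grid": None,  # list of [lb, ub] pairs; None -> quantile default
}

_PATH_KEYS = {"model", "expression", "mutations", "dependency", "gene_sets", "output_dir"}


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every violation."""


@dataclass
class PipelineConfig:
    cancer: str
    paths: Dict[str, object]
    parameters: Dict[str, object]

    @property
    def output_dir(self) -> Path:
        return Path(str(self.paths["output_dir"]))

    def grid(self) -> Optional[List[ThresholdPair]]:
        g = self.parameters.get("grid")
        if g is None:
            return None
        return [ThresholdPair(lb=float(a), ub=float(b)) for a, b in g]

    def to_dict(self) -> dict:
        return {"cancer": self.cancer, "paths": dict(self.paths), "parameters": dict(self.parameters)}


def _validate(cancer: str, paths: Mapping, params: Mapping) -> List[str]:
    problems = []
    for key in paths:
        if key not in _PATH_KEYS:
            problems.append(f"unknown path key {key!r}")
    for req in ("model", "expression", "mutations", "output_dir"):
        if req not in paths:
            problems.append(f"missing required path {req!r}")
    for key in params:
        if key not in _DEFAULT_PARAMS:
            problems.append(f"unknown parameter {key!r}")
    def num(key):
        return float(params[key]) if key in params else float(_DEFAULT_PARAMS[key])
    if not (0 < num("alpha") <= 1):
        problems.append("alpha must lie in (0, 1]")
    if not (0 < num("filter_mean") <= 1):
        problems.append("filter_mean must lie in (0, 1]")
    if not (0 < num("cutoff") < 1):
        problems.append("cutoff must lie in (0, 1)")
    if num("noise_lo") > num("noise_hi"):
        problems.append("noise_lo exceeds noise_hi")
    for req in ("model", "expression", "mutations"):
        p = paths.get(req)
        if p is not None and not Path(str(p)).exists():
            problems.append(f"path {req!r} does not exist: {p}")
    return problems


def make_config(
    cancer: str, paths: Mapping, parameters: Optional[Mapping] = None
) -> PipelineConfig:
    params = dict(_DEFAULT_PARAMS)
    params.update(parameters or {})
    problems = _validate(cancer, paths, parameters or {})
    if problems:
        raise ConfigError("; ".join(problems))
    return PipelineConfig(cancer=cancer, paths=dict(paths), parameters=params)


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Parse + validate a YAML pipeline config; defaults filled in."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - {"cancer", "paths", "parameters"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    return make_config(
        cancer=str(data.get("cancer", "")),
        paths=data.get("paths", {}),
        parameters=data.get("parameters", {}),
    )


def write_config(config: PipelineConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def build_cell_line_models(
    generic: MetabolicModel,
    expression: pd.DataFrame,
    grid: Optional[Sequence[ThresholdPair]] = None,
    epsilon: float = 0.1,
) -> Dict[str, MetabolicModel]:
    """One context-specific model per expression column (cell line)."""
    profiles = sio.expression_profiles(expression)
    models = {}
    for cell_line, profile in profiles.items():
        _thr, ctx = threshold_grid_search(generic, profile, grid=grid, epsilon=epsilon)
        ctx.id = f"{generic.id}_{cell_line}"
        models[cell_line] = ctx
    return models


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

STAGES = ["build_models", "ko_scan", "slscan", "validate", "enrich"]


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run all stages in order, writing per-stage CSV outputs and a JSON
    manifest.  Stages whose outputs already exist are skipped unless
    ``force``.  A stage failure aborts the run; earlier outputs remain."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    models_dir = out / "models"
    manifest: dict = {
        "cancer": config.cancer,
        "parameters": dict(config.parameters),
        "stages": {},
    }
    params = config.parameters
    seed = int(params["seed"])

    def stage_done(name: str, status: str, **info) -> None:
        manifest["stages"][name] = {"status": status, **info}
        logger.info("stage %s: %s %s", name, status, info)

    t0 = time.time()
    generic = sio.read_model(config.paths["model"])
    expression = sio.read_expression_csv(config.paths["expression"])

    # -- build_models -------------------------------------------------------
    models_dir.mkdir(exist_ok=True)
    expected = {cl: models_dir / f"{cl}.json" for cl in expression.columns}
    if not force and all(p.exists() for p in expected.values()):
        models = {cl: sio.read_json_model(p) for cl, p in expected.items()}
        stage_done("build_models", "skipped", n_models=len(models))
    else:
        models = build_cell_line_models(
            generic, expression, grid=config.grid(), epsilon=float(params["epsilon"])
        )
        for cl, model in models.items():
            sio.write_json_model(model, expected[cl])
        stage_done("build_models", "completed", n_models=len(models))

    # -- ko_scan ------------------------------------------------------------
    ko_path = out / "ko_scores.csv"
    universe = sorted(generic.genes)
    if not force and ko_path.exists() and manifest["stages"]["build_models"]["status"] == "skipped":
        scores = KOScoreMatrix(scores=pd.read_csv(ko_path, index_col=0))
        stage_done("ko_scan", "skipped", shape=list(scores.scores.shape))
    else:
        scores = build_ko_score_matrix(models, universe)
        scores.scores.to_csv(ko_path, index_label="gene", float_format=FLOAT_FORMAT)
        stage_done("ko_scan", "completed", shape=list(scores.scores.shape))

    # -- slscan -------------------------------------------------------------
    mutations = sio.read_maf(
        config.paths["mutations"],
        cell_lines=list(expression.columns),
        genes=universe,
    )
    sl_table = slscan_scan(
        scores,
        mutations,
        alpha=float(params["alpha"]),
        seed=seed,
        min_mutated_lines=int(params["min_mutated_lines"]),
        filter_mean=float(params["filter_mean"]),
        cancer=config.cancer,
    )
    df = sl_table.table.copy()
    df.insert(0, "cancer", config.cancer)
    _write_table(df, out / "sl_results.csv")
    stage_done("slscan", "completed", n_pairs=len(sl_table), n_skipped=len(sl_table.skipped))

    # -- validate -----------------------------------------------------------
    dep_paths = config.paths.get("dependency") or {}
    if not dep_paths:
        stage_done("validate", "skipped", reason="no dependency matrices configured")
    else:
        reports = {}
        for kind, path in dict(dep_paths).items():
            dep = sio.read_dependency_csv(path, kind=kind)
            screen = screen_sl_scan(
                dep, mutations, alpha=float(params["alpha"]),
                min_mutated_lines=int(params["min_mutated_lines"]),
                cancer=config.cancer,
            )
            _write_table(screen.table, out / f"screen_{kind}.csv")
            reports[kind] = concordance_report(
                {config.cancer: (sl_table, screen)}, alpha=float(params["alpha"])
            ).assign(screen=kind)
        _write_table(pd.concat(reports.values(), ignore_index=True), out / "validation.csv")
        stage_done("validate", "completed", screens=sorted(dep_paths))

    # -- enrich -------------------------------------------------------------
    gmt_path = config.paths.get("gene_sets")
    if not gmt_path:
        stage_done("enrich", "skipped", reason="no gene sets configured")
    else:
        sets = sio.read_gmt(gmt_path)
        drivers = sorted(set(sl_table.table["driver_gene"]))
        per_driver = {}
        for d in drivers:
            try:
                ranked = build_ranked_list(d, sl_table)
            except ValueError:
                continue
            per_driver[d] = preranked_gsea(
                ranked, sets, n_perm=int(params["n_perm"]), seed=seed
            )
        freq = process_frequency(per_driver, alpha=float(params["alpha"]))
        _write_table(freq, out / "enrichment.csv")
        stage_done("enrich", "completed", n_drivers=len(per_driver), n_sets=len(sets.sets))

    manifest["runtime_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def double_deletion_baseline(
    model: MetabolicModel, cutoff: float = 0.01
) -> pd.DataFrame:
    """Naive exhaustive double-deletion SL baseline as a two-column table."""
    pairs = sorted(tuple(sorted(p)) for p in exhaustive_double_deletion_sl(model, cutoff))
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
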