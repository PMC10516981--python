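"""The SL-scan statistical screen.

Per cell line, the support of the L1-minimal optimal flux vector is mapped
through GPR rules to a knockout (KO) gene list; simulating each knockout
yields a KO-score matrix of post/pre-knockout growth ratios (1 = no effect,
0 = lethal; genes outside a line's KO list default to 1).  Cell lines are
then stratified by the damaging-mutation status of each driver gene — a
metabolic gene damaged in at least ``min_mutated_lines`` lines — and a
two-sample t-test compares KO scores between mutated and wild-type groups
for every (driver, KO gene) pair, with Benjamini-Hochberg control over the
whole scan.

Two details mirror the screening procedure: driver genes whose mutated-group
mean KO score exceeds 0.95 are assigned p = 1 without testing (their
knockouts are inert in the mutated lines), and tiny uniform noise
(1e-12..1e-11) is added to both groups so that constant KO ratios (zero
variance, common in metabolic simulations) still yield a defined t-test.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fba import flux_support_genes, single_gene_deletion_ratios, solve_fba, solve_l1_min
from .model import MetabolicModel

logger = logging.getLogger(__name__)

FILTER_MEAN = 0.95
NOISE_LO = 1e-12
NOISE_HI = 1e-11


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class KOScoreMatrix:
    """Genes x cell lines matrix of KO/WT growth ratios in [0, 1]."""

    scores: pd.DataFrame  # index = genes, columns = cell lines

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("KO scores must lie in [0, 1]")

    @property
    def genes(self) -> List[str]:
        return list(self.scores.index)

    @property
    def cell_lines(self) -> List[str]:
        return list(self.scores.columns)


@dataclass
class MutationMatrix:
    """Boolean genes x cell lines matrix: True = >=1 damaging mutation."""

    calls: pd.DataFrame  # bool, index = genes, columns = cell lines
    provenance: str = ""

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(bool)

    @property
    def genes(self) -> List[str]:
        return list(self.calls.index)

    @property
    def cell_lines(self) -> List[str]:
        return list(self.calls.columns)


@dataclass
class SLTestResult:
    driver: str
    ko_gene: str
    t: float
    p: float
    fdr: float
    mean_mut: float
    mean_wt: float
    n_mut: int
    n_wt: int
    filtered: bool


RESULT_COLUMNS = [
    "driver_gene", "ko_gene", "t", "p", "fdr",
    "mean_mut", "mean_wt", "n_mut", "n_wt", "filtered",
]


@dataclass
class SLResultTable:
    """One row per tested (driver, KO gene) pair, plus scan metadata."""

    table: pd.DataFrame  # RESULT_COLUMNS
    alpha: float = 0.05
    seed: Optional[int] = None
    cancer: str = ""
    skipped: List[Tuple[str, str, str]] = field(default_factory=list)

    def significant_pairs(self, alpha: Optional[float] = None) -> Set[Tuple[str, str]]:
        a = self.alpha if alpha is None else alpha
        sig = self.table[self.table["fdr"] <= a]
        return set(zip(sig["driver_gene"], sig["ko_gene"]))

    def tested_pairs(self) -> Set[Tuple[str, str]]:
        return set(zip(self.table["driver_gene"], self.table["ko_gene"]))

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# KO gene list + score matrix
# ---------------------------------------------------------------------------

def derive_ko_gene_list(context_model: MetabolicModel, tol: float = 1e-6) -> Set[str]:
    """KO gene list of a cell line: FBA optimum -> L1-minimal flux at that
    optimum -> genes of the flux-carrying reactions (via GPR)."""
    wt = solve_fba(context_model)
    if not wt.optimal or wt.objective_value <= 0:
        raise ValueError(
            f"context model {context_model.id!r} has non-positive FBA optimum"
        )
    parsimonious = solve_l1_min(context_model, wt.objective_value)
    return flux_support_genes(context_model, parsimonious, tol=tol)


def build_ko_score_matrix(
    models: Mapping[str, MetabolicModel],
    universe: Sequence[str],
) -> KOScoreMatrix:
    """Simulate single-gene knockouts per cell line over its KO gene list;
    every other gene of ``universe`` scores 1 (no inhibitory effect)."""
    universe = list(universe)
    columns = {}
    for cell_line, model in models.items():
        try:
            ko_genes = derive_ko_gene_list(model)
        except ValueError as exc:
            raise ValueError(f"cell line {cell_line!r}: {exc}") from exc
        ratios = single_gene_deletion_ratios(model, sorted(ko_genes & set(universe)))
        col = pd.Series(1.0, index=universe, name=cell_line)
        for g, r in ratios.items():
            col[g] = min(max(r, 0.0), 1.0)
        columns[cell_line] = col
    return KOScoreMatrix(scores=pd.DataFrame(columns))


# ---------------------------------------------------------------------------
# drivers & the t-test
# ---------------------------------------------------------------------------

def identify_driver_genes(
    mutations: MutationMatrix, min_mutated_lines: int = 2
) -> Set[str]:
    """Genes with a damaging mutation in at least ``min_mutated_lines``
    cell lines."""
    if min_mutated_lines < 1:
        raise ValueError("min_mutated_lines must be >= 1")
    counts = mutations.calls.sum(axis=1)
    return set(counts.index[counts >= min_mutated_lines])


def _pair_seed(seed: int, driver: str, ko_gene: str) -> int:
    # stable across platforms and scan iteration order
    return zlib.crc32(f"{seed}|{driver}|{ko_gene}".encode()) & 0x7FFFFFFF


def slscan_test_pair(
    scores_mut: Sequence[float],
    scores_wt: Sequence[float],
    filter_mean: float = FILTER_MEAN,
    noise_lo: float = NOISE_LO,
    noise_hi: float = NOISE_HI,
    seed: int = 0,
) -> Tuple[float, float, bool]:
    """One (driver, KO gene) comparison: (t, p, filtered).

    If the mutated-group mean exceeds ``filter_mean`` the pair is filtered
    (t = 0, p = 1) without testing.  Otherwise seeded uniform noise in
    [noise_lo, noise_hi) is added to every observation and a pooled
    two-sample Student t-test (two-sided) is computed; t's sign follows
    mean(mut) - mean(wt).
    """
    mut = np.asarray(scores_mut, dtype=float)
    wt = np.asarray(scores_wt, dtype=float)
    if mut.size < 2 or wt.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if mut.mean() > filter_mean:
        return 0.0, 1.0, True
    rng = np.random.default_rng(seed)
    mut = mut + rng.uniform(noise_lo, noise_hi, size=mut.size)
    wt = wt + rng.uniform(noise_lo, noise_hi, size=wt.size)
    t, p = stats.ttest_ind(mut, wt, equal_var=True)
    return float(t), float(p), False


def bh_adjust(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def slscan_scan(
    scores: KOScoreMatrix,
    mutations: MutationMatrix,
    alpha: float = 0.05,
    seed: int = 0,
    min_mutated_lines: int = 2,
    filter_mean: float = FILTER_MEAN,
    cancer: str = "",
) -> SLResultTable:
    """Full mutation-stratified scan over all (driver, KO gene) pairs.

    Drivers are restricted to genes in the KO-score universe (metabolic
    genes).  Pairs where either stratum has fewer than 2 cell lines are
    skipped (logged, excluded from the BH family); filtered pairs enter the
    family with p = 1.  FDR is adjusted across all tested pairs of the scan.
    """
    shared = [c for c in scores.cell_lines if c in set(mutations.cell_lines)]
    if not shared:
        raise ValueError("score and mutation matrices share no cell lines")
    drivers = sorted(
        identify_driver_genes(mutations, min_mutated_lines) & set(scores.genes)
    )
    if not drivers:
        logger.warning("no driver genes identified; returning empty table")
        return SLResultTable(
            table=pd.DataFrame(columns=RESULT_COLUMNS), alpha=alpha,
            seed=seed, cancer=cancer,
        )
    score_df = scores.scores[shared]
    mut_df = mutations.calls.reindex(
        index=drivers, columns=shared, fill_value=False
    )
    rows = []
    skipped: List[Tuple[str, str, str]] = []
    for driver in drivers:
        mask = mut_df.loc[driver].to_numpy()
        n_mut, n_wt = int(mask.sum()), int((~mask).sum())
        if n_mut < 2 or n_wt < 2:
            for ko_gene in scores.genes:
                skipped.append((driver, ko_gene, f"stratum too small ({n_mut} mut / {n_wt} wt)"))
            continue
        mut_block = score_df.loc[:, mask]
        wt_block = score_df.loc[:, ~mask]
        for ko_gene in scores.genes:
            t, p, filtered = slscan_test_pair(
                mut_block.loc[ko_gene].to_numpy(),
                wt_block.loc[ko_gene].to_numpy(),
                filter_mean=filter_mean,
                seed=_pair_seed(seed, driver, ko_gene),
            )
            rows.append(
                {
                    "driver_gene": driver,
                    "ko_gene": ko_gene,
                    "t": t,
                    "p": p,
                    "mean_mut": float(mut_block.loc[ko_gene].mean()),
                    "mean_wt": float(wt_block.loc[ko_gene].mean()),
                    "n_mut": n_mut,
                    "n_wt": n_wt,
                    "filtered": filtered,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p"].tolist())
    else:
        table["fdr"] = []
    table = table.reindex(columns=RESULT_COLUMNS)
    return SLResultTable(
        table=table, alpha=alpha, seed=seed, cancer=cancer, skipped=skipped
    )
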