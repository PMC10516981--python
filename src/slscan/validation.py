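"""Validation of predicted SL pairs against perturbation screens.

The same mutation-stratified t-test scheme is applied to experimental
dependency matrices (CRISPR gene effect, shRNA ATARiS, PRISM log-fold
change; lower = stronger killing).  Concordance between the model-based
scan and a screen scan is summarised as a 2x2 overlap over the commonly
tested pairs and assessed with a one-sided (upper tail, inclusive)
hypergeometric enrichment test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .scan import RESULT_COLUMNS, MutationMatrix, SLResultTable, bh_adjust, identify_driver_genes

logger = logging.getLogger(__name__)


@dataclass
class DependencyMatrix:
    """Entities (genes or compounds) x cell lines viability matrix."""

    values: pd.DataFrame  # index = entities, columns = cell lines; NaN allowed
    kind: str = "crispr"  # "crispr" | "shrna" | "prism"

    @property
    def entities(self) -> List[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> List[str]:
        return list(self.values.columns)


@dataclass
class ContingencyCounts:
    """Inputs of the enrichment test: significant-pair counts and overlap."""

    n_method: int
    n_screen: int
    overlap: int
    universe: int

    def __post_init__(self) -> None:
        if self.overlap > min(self.n_method, self.n_screen):
            raise ValueError("overlap exceeds one of the marginal counts")
        if max(self.n_method, self.n_screen) > self.universe:
            raise ValueError("marginal count exceeds the universe")
        if min(self.n_method, self.n_screen, self.overlap, self.universe) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EnrichmentResult:
    counts: ContingencyCounts
    p: float


# ---------------------------------------------------------------------------
# screen scan
# ---------------------------------------------------------------------------

def screen_sl_scan(
    dep: DependencyMatrix,
    mutations: MutationMatrix,
    alpha: float = 0.05,
    min_mutated_lines: int = 2,
    cancer: str = "",
) -> SLResultTable:
    """Mutation-stratified t-test scan on an experimental screen.

    Unlike the simulated scan there is no mean filter and no noise
    injection — screen scores carry natural variance.  Missing values are
    dropped pairwise; a pair is tested only if both strata retain >= 2
    observations.  BH-FDR is computed across all tested pairs.
    """
    shared = [c for c in dep.cell_lines if c in set(mutations.cell_lines)]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared cell lines")
    drivers = sorted(identify_driver_genes(mutations, min_mutated_lines))
    dep_df = dep.values[shared]
    mut_df = mutations.calls.reindex(index=drivers, columns=shared, fill_value=False)
    rows = []
    skipped: List[Tuple[str, str, str]] = []
    for driver in drivers:
        mask = mut_df.loc[driver].to_numpy()
        for entity in dep.entities:
            vals = dep_df.loc[entity].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            mut = vals[mask & ok]
            wt = vals[~mask & ok]
            if mut.size < 2 or wt.size < 2:
                skipped.append((driver, entity, f"stratum too small ({mut.size}/{wt.size})"))
                continue
            if np.var(mut) == 0 and np.var(wt) == 0 and mut.mean() == wt.mean():
                t, p = 0.0, 1.0  # identical constant groups
            else:
                t, p = stats.ttest_ind(mut, wt, equal_var=True)
            rows.append(
                {
                    "driver_gene": driver,
                    "ko_gene": entity,
                    "t": float(t),
                    "p": float(p),
                    "mean_mut": float(mut.mean()),
                    "mean_wt": float(wt.mean()),
                    "n_mut": int(mut.size),
                    "n_wt": int(wt.size),
                    "filtered": False,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p"].tolist())
    else:
        table["fdr"] = []
    table = table.reindex(columns=RESULT_COLUMNS)
    return SLResultTable(table=table, alpha=alpha, cancer=cancer, skipped=skipped)


# ---------------------------------------------------------------------------
# concordance + hypergeometric enrichment
# ---------------------------------------------------------------------------

def concordance(
    method_table: SLResultTable,
    screen_table: SLResultTable,
    alpha: float = 0.05,
) -> ContingencyCounts:
    """Overlap of significant pairs over the universe of pairs tested by
    BOTH tables."""
    universe = method_table.tested_pairs() & screen_table.tested_pairs()
    if not universe:
        raise ValueError("the two tables share no tested pairs")
    m_sig = method_table.significant_pairs(alpha) & universe
    s_sig = screen_table.significant_pairs(alpha) & universe
    return ContingencyCounts(
        n_method=len(m_sig),
        n_screen=len(s_sig),
        overlap=len(m_sig & s_sig),
        universe=len(universe),
    )


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_enrichment(counts: ContingencyCounts) -> EnrichmentResult:
    """Upper-tail hypergeometric test, inclusive: p = P(X >= overlap).

    X counts screen-significant pairs among the method-significant draws:
    population = universe, successes = n_screen, draws = n_method.  The
    tail is summed exactly in log space (log-binomials via gammaln).
    """
    N, K, n, k = counts.universe, counts.n_screen, counts.n_method, counts.overlap
    if k == 0:
        return EnrichmentResult(counts=counts, p=1.0)
    ks = np.arange(k, min(K, n) + 1, dtype=float)
    log_pmf = _log_binom(K, ks) + _log_binom(N - K, n - ks) - _log_binom(N, np.array(n, dtype=float))
    p = float(np.exp(logsumexp(log_pmf)))
    return EnrichmentResult(counts=counts, p=min(p, 1.0))


def concordance_report(
    per_cancer: Mapping[str, Tuple[SLResultTable, SLResultTable]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per cancer: enrichment p and the four overlap counts."""
    rows = []
    for cancer, (method_table, screen_table) in per_cancer.items():
        counts = concordance(method_table, screen_table, alpha)
        enr = hypergeometric_enrichment(counts)
        rows.append(
            {
                "cancer": cancer,
                "enrichment_p": enr.p,
                "n_sl_method": counts.n_method,
                "n_sl_screen": counts.n_screen,
                "overlap": counts.overlap,
                "total": counts.universe,
            }
        )
    return pd.DataFrame(rows)


def map_compounds_to_targets(
    table: SLResultTable, compound_targets: Mapping[str, str]
) -> SLResultTable:
    """Annotate a PRISM-style table (entities = compounds) with target
    genes; rows whose compound has no mapping are dropped."""
    df = table.table.copy()
    df["target_gene"] = df["ko_gene"].map(dict(compound_targets))
    df = df[df["target_gene"].notna()].reset_index(drop=True)
    return SLResultTable(
        table=df, alpha=table.alpha, seed=table.seed, cancer=table.cancer
    )
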