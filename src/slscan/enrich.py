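"""Per-driver ranked partner lists and preranked gene-set enrichment.

For each driver gene, its SL partner genes are ranked by the absolute t
statistic from the scan; the driver itself is appended with the mean of
its partners' t statistics.  Enrichment of a gene set in such a list uses
the weighted Kolmogorov-Smirnov running-sum statistic (weight exponent 1)
with a gene-label permutation null.  Recurrence of a biological process
across drivers is summarised by counting drivers for which the set is
significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .scan import SLResultTable, bh_adjust

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 2
N_PERM_DEFAULT = 1000


@dataclass
class RankedGeneList:
    """(gene, score) pairs sorted by descending |score|, for one driver."""

    driver: str
    entries: List[Tuple[str, float]]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(genes) != len(set(genes)):
            raise ValueError("ranked list contains duplicate genes")

    @property
    def genes(self) -> List[str]:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries])


@dataclass
class GeneSetCollection:
    sets: Dict[str, Set[str]]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")


@dataclass
class GseaResult:
    set_name: str
    es: float
    p: float
    n_hits: int


def _sort_key(item: Tuple[str, float]):
    gene, score = item
    # descending |score|; ties: larger raw score first, then gene id
    return (-abs(score), -score, gene)


def build_ranked_list(driver: str, table: SLResultTable) -> RankedGeneList:
    """Partner genes of ``driver`` with their t statistics, plus the driver
    itself scored with the mean partner t, sorted by descending |t|."""
    sub = table.table[table.table["driver_gene"] == driver]
    sub = sub[sub["ko_gene"] != driver]
    if sub.empty:
        raise ValueError(f"driver {driver!r} has no tested pairs in the table")
    entries = list(zip(sub["ko_gene"], sub["t"].astype(float)))
    entries.append((driver, float(np.mean([t for _, t in entries]))))
    entries.sort(key=_sort_key)
    return RankedGeneList(driver=driver, entries=entries)


def _enrichment_score(
    ranked_scores: np.ndarray, hit_mask: np.ndarray
) -> float:
    """Weighted-KS enrichment score: max deviation of the running sum with
    hit increments proportional to |score| and uniform miss decrements."""
    n = ranked_scores.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict, non-empty subset")
    weights = np.abs(ranked_scores)
    hit_total = weights[hit_mask].sum()
    if hit_total == 0:
        # all hit scores are zero: fall back to unweighted increments
        increments = np.where(hit_mask, 1.0 / n_hits, -1.0 / (n - n_hits))
    else:
        increments = np.where(
            hit_mask, weights / hit_total, -1.0 / (n - n_hits)
        )
    running = np.cumsum(increments)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranked: RankedGeneList,
    sets: GeneSetCollection,
    n_perm: int = N_PERM_DEFAULT,
    seed: int = 0,
    min_set_size: int = MIN_SET_SIZE,
) -> List[GseaResult]:
    """Preranked GSEA over every set; p = fraction of seeded gene-label
    permutations with |ES| at least as extreme.  Sets with fewer than
    ``min_set_size`` genes in the list, or covering the whole list, are
    skipped with a log entry."""
    genes = ranked.genes
    scores = ranked.scores
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    results: List[GseaResult] = []
    for name, members in sets.sets.items():
        hit_idx = [gene_pos[g] for g in members if g in gene_pos]
        if len(hit_idx) < min_set_size:
            logger.info("gene set %s: overlap %d < %d, skipped", name, len(hit_idx), min_set_size)
            continue
        if len(hit_idx) == n:
            logger.info("gene set %s covers the whole list, skipped", name)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[hit_idx] = True
        es = _enrichment_score(scores, mask)
        n_hits = len(hit_idx)
        count = 0
        for _ in range(n_perm):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[rng.choice(n, size=n_hits, replace=False)] = True
            if abs(_enrichment_score(scores, perm_mask)) >= abs(es):
                count += 1
        # add-one permutation estimator: valid (never 0) and near-uniform
        # under the null
        p = (count + 1) / (n_perm + 1) if n_perm > 0 else float("nan")
        results.append(GseaResult(set_name=name, es=es, p=p, n_hits=n_hits))
    return results


def process_frequency(
    results: Mapping[str, Sequence[GseaResult]],
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Count, per gene set, the drivers for which it is significant
    (p <= alpha, optionally BH-adjusted within each driver); sorted by
    descending frequency then set name."""
    counts: Dict[str, int] = {}
    for _driver, res in results.items():
        if not res:
            continue
        ps = [r.p for r in res]
        if adjust:
            ps = bh_adjust(ps)
        for r, p in zip(res, ps):
            if p <= alpha:
                counts[r.set_name] = counts.get(r.set_name, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["set_name", "frequency"])
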