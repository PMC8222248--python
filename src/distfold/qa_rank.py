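"""Model quality assessment: consensus, distance-map and combined rankings.

Three complementary selection strategies for a pool of candidate models of
one target: (1) pairwise-similarity consensus — a model scores the mean
TM-score against every other model, so members of the dominant structural
cluster rise to the top; (2) distance ranking — agreement between the
predicted distance map and each model's observed map; (3) rank averaging of
any stored score columns, including externally supplied single-model scores
(e.g. an energy-function column loaded from a TSV).  All stored columns are
oriented so that higher is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distmat import DistanceMap, map_agreement
from .metrics import tm_score
from .structio import Structure


@dataclass
class RankingTable:
    """Per-model scores from one or more rankers plus a combined rank.

    Each score column is oriented higher = better; each rank column is the
    corresponding 1 = best ranking (ties share the mean rank).
    """

    model_ids: list[str]
    scores: pd.DataFrame = field(default=None)
    combined_rank: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scores is None:
            self.scores = pd.DataFrame(index=pd.Index(self.model_ids, name="model_id"))

    def add_column(self, name: str, values: np.ndarray | list[float], ascending: bool = False) -> None:
        """Store a score column; set ``ascending=True`` if lower raw values are better."""
        vals = np.asarray(values, dtype=float)
        if len(vals) != len(self.model_ids):
            raise ValueError("score vector length mismatch")
        if ascending:
            vals = -vals
        self.scores[name] = vals

    def ranks(self, column: str) -> pd.Series:
        """1 = best ranks for a stored column (average ranks on ties)."""
        if column not in self.scores.columns:
            raise KeyError(f"unknown score column {column!r}")
        return self.scores[column].rank(ascending=False, method="average")

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        for col in self.scores.columns:
            out[f"rank_{col}"] = self.ranks(col)
        if self.combined_rank is not None:
            out["combined_rank"] = self.combined_rank
        return out


def consensus_rank(models: list[Structure]) -> np.ndarray:
    """Pairwise-similarity consensus score per model.

    score(m) = mean TM-score between m and every other model in the pool.
    Models must be index-aligned (same target sequence); the pairwise matrix
    is computed once and symmetrized.
    """
    n = len(models)
    if n < 2:
        raise ValueError("consensus ranking needs at least 2 models")
    L = models[0].L
    if any(m.L != L for m in models):
        raise ValueError("all models must have equal length")
    sim = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            t = tm_score(models[a], models[b]).tm_score
            sim[a, b] = sim[b, a] = t
    np.fill_diagonal(sim, 0.0)
    return sim.sum(axis=1) / (n - 1)


def distance_rank(models: list[Structure], pred: DistanceMap, **kwargs) -> np.ndarray:
    """Distance-based score per model: agreement with the predicted map."""
    return np.array([map_agreement(pred, m, **kwargs) for m in models])


def combine_ranks(
    table: RankingTable,
    columns: list[str],
    weights: list[float] | None = None,
) -> pd.Series:
    """Weighted mean of per-column ranks; ascending combined rank is the final order.

    Ties in the combined rank are broken by the first listed column's score
    (higher first), then by model id.  The result is stored on the table and
    returned.
    """
    if not columns:
        raise ValueError("no columns given")
    for c in columns:
        if c not in table.scores.columns:
            raise KeyError(f"unknown score column {c!r}")
    if weights is None:
        weights = [1.0] * len(columns)
    if len(weights) != len(columns):
        raise ValueError("weights length mismatch")
    rank_mat = np.column_stack([table.ranks(c).to_numpy() for c in columns])
    combined = rank_mat @ (np.asarray(weights) / np.sum(weights))
    table.combined_rank = pd.Series(combined, index=table.scores.index, name="combined_rank")
    return table.combined_rank


def select_top(table: RankingTable, k: int = 5) -> list[str]:
    """The first k model ids by combined rank (ties broken as documented)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if table.combined_rank is None:
        raise ValueError("combine_ranks must be called first")
    n = len(table.model_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds pool size {n}")
    first_col = table.scores.columns[0]
    order = pd.DataFrame({
        "combined": table.combined_rank,
        "tie": -table.scores[first_col],
        "mid": table.scores.index,
    }).sort_values(["combined", "tie", "mid"], kind="mergesort")
    return order.index[:k].tolist()


def load_external_scores(path, table: RankingTable, column: str = "external",
                         ascending: bool = False) -> None:
    """Load a per-model score TSV (model_id<TAB>score) into a table column."""
    df = pd.read_csv(path, sep="\t", header=None, names=["model_id", "score"],
                     comment="#").set_index("model_id")
    missing = [m for m in table.model_ids if m not in df.index]
    if missing:
        raise KeyError(f"external scores missing for models: {missing}")
    table.add_column(column, df.loc[table.model_ids, "score"].to_numpy(), ascending=ascending)
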