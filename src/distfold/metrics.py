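"""Structure-comparison metrics and CASP-style Z-score aggregation.

TM-score and GDT_TS are computed on index-aligned CA traces (models and
natives share the target sequence in this toolkit, so no sequence alignment
is needed).  Both metrics require an optimal superposition over residue
subsets; we use a fragment-seeded iterative search: every superposition is
seeded by least-squares fitting a contiguous fragment, then refined by
repeatedly re-superposing on the set of residues currently within a distance
cutoff until the set stabilizes.  The production search seeds from fragment
lengths {L, L/2, L/4, 4}; tests compare it against an exhaustive-seed oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import Structure

logger = logging.getLogger(__name__)

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
D0_FLOOR = 0.5


@dataclass
class MetricReport:
    """Global similarity metrics between a model and a reference structure."""

    tm_score: float | None = None
    gdt_ts: float | None = None
    rmsd: float | None = None
    L_ref: int | None = None
    d0: float | None = None


def kabsch_rmsd(
    a: Structure | np.ndarray,
    b: Structure | np.ndarray,
    subset: np.ndarray | list[int] | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of a onto b (proper rotation only).

    Returns (rmsd, rotation, translation) such that ``a @ R.T + t`` best fits
    b in the least-squares sense over ``subset`` (all residues by default).
    Reflections are excluded, so mirror images keep a nonzero RMSD.
    """
    xa = a.ca_coords if isinstance(a, Structure) else np.asarray(a, dtype=float)
    xb = b.ca_coords if isinstance(b, Structure) else np.asarray(b, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError(f"coordinate shapes differ: {xa.shape} vs {xb.shape}")
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        xa, xb = xa[subset], xb[subset]
    if xa.shape[0] < 3:
        raise ValueError("superposition needs at least 3 residues")
    R, t = _fit_rigid(xa, xb)
    diff = xa @ R.T + t - xb
    rmsd = float(np.sqrt((diff ** 2).sum() / xa.shape[0]))
    return rmsd, R, t


def _fit_rigid(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch: proper rotation R and translation t minimizing |xa R^T + t - xb|^2."""
    ca_, cb_ = xa.mean(axis=0), xb.mean(axis=0)
    H = (xa - ca_).T @ (xb - cb_)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = cb_ - ca_ @ R.T
    return R, t


def tm_d0(L_ref: int) -> float:
    """TM-score normalization scale d0(L) = 1.24 (L-15)^(1/3) - 1.8, floored at 0.5 Å."""
    if L_ref < 16:
        return D0_FLOOR
    return max(D0_FLOOR, 1.24 * (L_ref - 15) ** (1.0 / 3.0) - 1.8)


EXHAUSTIVE_BELOW_L = 33


def _seed_fragments(L: int, lengths: list[int] | None = None, exhaustive: bool = False):
    """Contiguous fragments used to seed superpositions.

    Short chains (L < 33) always get the full enumeration — every fragment of
    every length >= 4 — because it is cheap and the score is discrete enough
    there that a missed pose costs whole GDT points.  Longer chains use a
    decimated set: lengths {L, L/2, L/4, 4} with half-overlapping starts.
    ``exhaustive=True`` forces the full enumeration at any length.
    """
    if exhaustive or L < EXHAUSTIVE_BELOW_L:
        return [(start, flen)
                for flen in range(4, L + 1)
                for start in range(L - flen + 1)]
    frags: list[tuple[int, int]] = []
    if lengths is None:
        lengths = sorted({L, max(4, L // 2), max(4, L // 4), 4}, reverse=True)
    for flen in lengths:
        flen = max(4, min(flen, L))
        step = max(1, flen // 2)
        starts = list(range(0, L - flen + 1, step))
        if starts[-1] != L - flen:
            starts.append(L - flen)
        frags.extend((s, flen) for s in starts)
    return sorted(set(frags))


def _refine_trajectory(
    xm: np.ndarray, xn: np.ndarray, seed_idx: np.ndarray, cutoff: float, max_iter: int = 20
):
    """Iteratively re-superpose on the within-``cutoff`` residue set.

    Yields the per-residue distance vector after *every* superposition (the
    best-scoring pose along a trajectory is not always the converged one).
    Stops when the set stabilizes or drops below 3 residues.
    """
    idx = seed_idx
    prev: set[int] = set()
    for _ in range(max_iter):
        _, R, t = kabsch_rmsd(xm, xn, subset=idx)
        d = np.linalg.norm(xm @ R.T + t - xn, axis=1)
        yield d
        new = np.flatnonzero(d <= cutoff)
        if len(new) < 3:
            return
        cur = set(new.tolist())
        if cur == prev:
            return
        prev = cur
        idx = new


def _search_distances(xm: np.ndarray, xn: np.ndarray, cutoffs, exhaustive: bool):
    """Yield distance vectors from every seeded refinement at every cutoff."""
    L = xm.shape[0]
    for start, flen in _seed_fragments(L, exhaustive=exhaustive):
        seed = np.arange(start, start + flen)
        for cutoff in cutoffs:
            yield from _refine_trajectory(xm, xn, seed, cutoff)


def tm_score(model: Structure, native: Structure, exhaustive: bool = False) -> MetricReport:
    """Template-modeling score of ``model`` against ``native`` in (0, 1].

    TM = max over searched superpositions of (1/L_ref) Σ_i 1/(1+(d_i/d0)^2)
    with L_ref = native length and d0 = 1.24 (L_ref-15)^(1/3) - 1.8.  A score
    >= 0.5 indicates the two structures share a fold; 1.0 means identity.
    By contract the normalization uses the native length, so the score is
    asymmetric for unequal-length inputs (not supported here).
    """
    if model.L != native.L:
        raise ValueError("index-aligned scoring requires equal lengths")
    L = native.L
    if L < 16:
        raise ValueError("TM-score d0 formula needs L >= 16; use kabsch_rmsd for short chains")
    d0 = tm_d0(L)
    cutoffs = (max(4.5, d0), 8.0)
    xm, xn = model.ca_coords, native.ca_coords
    best = 0.0
    for d in _search_distances(xm, xn, cutoffs, exhaustive):
        score = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
        if score > best:
            best = score
    return MetricReport(tm_score=best, L_ref=L, d0=d0)


def gdt_ts(model: Structure, native: Structure, exhaustive: bool = False) -> float:
    """Global distance test (total score) in percent.

    Mean over the 1, 2, 4 and 8 Å cutoffs of the maximal fraction of residues
    that can be superposed within the cutoff, maximized over the same
    fragment-seeded search used for the TM-score.
    """
    if model.L != native.L:
        raise ValueError("index-aligned scoring requires equal lengths")
    L = native.L
    if L < 4:
        raise ValueError("GDT_TS needs L >= 4")
    xm, xn = model.ca_coords, native.ca_coords
    best = {c: 0 for c in GDT_CUTOFFS}
    # every pose from every cutoff's refinement is a candidate for all cutoffs
    for d in _search_distances(xm, xn, GDT_CUTOFFS, exhaustive):
        for c in GDT_CUTOFFS:
            n_within = int(np.sum(d <= c))
            if n_within > best[c]:
                best[c] = n_within
    return 100.0 * float(np.mean([best[c] / L for c in GDT_CUTOFFS]))


def score_pair(model: Structure, native: Structure) -> MetricReport:
    """Convenience: TM-score, GDT_TS and all-residue RMSD in one report."""
    rep = tm_score(model, native)
    rep.gdt_ts = gdt_ts(model, native)
    rep.rmsd = kabsch_rmsd(model, native)[0]
    return rep


def zscore_rank(
    raw: pd.DataFrame,
    weights: dict[str, float] | None = None,
    floor: float = -2.0,
    discard_below_floor: bool = True,
) -> dict[str, pd.DataFrame | pd.Series]:
    """CASP-assessor-style Z-score aggregation over targets.

    ``raw`` is a tidy table with columns ``predictor``, ``target`` and one
    column per metric.  Per model the raw score is the weighted sum of the
    metric columns (default weights gdt_ts=1, qcs=1, molprobity=0.1; a metric
    whose lower values are better should be negated by the caller — the sign
    convention is deliberately not assumed here).  Per target the raw scores
    are standardized to z = (raw - mean) / sd across predictors; contributions
    with z < ``floor`` are discarded (contribute 0) when
    ``discard_below_floor``, otherwise clipped to the floor.  Missing
    predictions contribute 0.  Returns the per-target z matrix, the summed
    contributions per predictor (descending = final ranking) and the raw
    combined scores.
    """
    if weights is None:
        weights = {"gdt_ts": 1.0, "qcs": 1.0, "molprobity": 0.1}
    missing = [c for c in weights if c not in raw.columns]
    if missing:
        raise KeyError(f"metric columns not in table: {missing}")
    df = raw.copy()
    df["raw_score"] = sum(w * df[c] for c, w in weights.items())
    counts = df.groupby("target")["predictor"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"targets with < 2 predictors: {bad}")

    def _z(group: pd.Series) -> pd.Series:
        sd = group.std(ddof=0)
        if sd == 0:
            logger.warning("zero score spread on a target; all z set to 0")
            return pd.Series(0.0, index=group.index)
        return (group - group.mean()) / sd

    df["z"] = df.groupby("target")["raw_score"].transform(_z)
    if discard_below_floor:
        df["z_contrib"] = df["z"].where(df["z"] >= floor, 0.0)
    else:
        df["z_contrib"] = df["z"].clip(lower=floor)
    z_matrix = df.pivot(index="predictor", columns="target", values="z")
    sums = (
        df.pivot(index="predictor", columns="target", values="z_contrib")
        .fillna(0.0)  # missing predictions contribute 0
        .sum(axis=1)
        .sort_values(ascending=False)
    )
    raw_matrix = df.pivot(index="predictor", columns="target", values="raw_score")
    return {"z": z_matrix, "sum_z": sums, "raw": raw_matrix}
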