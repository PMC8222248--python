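"""Inter-residue distance maps: construction, comparison and contact statistics.

A DistanceMap is the interchange unit between distance predictors and the
folding / ranking stages: a symmetric L×L matrix of real-valued distances
with a validity mask and optional per-pair confidence.  By CASP convention
a *contact* is a residue pair within 8 Å (CB atoms, CA for glycine) and
*long-range* means sequence separation >= 24.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structio import FormatError, Structure

CONTACT_CUTOFF = 8.0
LONG_RANGE_SEP = 24
DEFAULT_D_MAX = 16.0


@dataclass
class DistanceMap:
    """Symmetric matrix of predicted or observed inter-residue distances (Å).

    ``mask[i, j]`` is True where d[i, j] carries a value; the diagonal is
    always masked out.  ``confidence`` (in [0, 1]) is optional and used to
    weight restraints and agreement scores.  ``atom_mode`` records which atom
    the distances refer to; CB falls back to CA for glycine.
    """

    d: np.ndarray
    mask: np.ndarray
    confidence: np.ndarray | None = None
    atom_mode: str = "CA"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        L = self.d.shape[0]
        if self.d.shape != (L, L):
            raise ValueError(f"distance matrix must be square, got {self.d.shape}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (L, L):
            raise ValueError("mask shape mismatch")
        np.fill_diagonal(self.mask, False)
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        dm = np.where(self.mask, self.d, 0.0)
        if not np.allclose(dm, dm.T, atol=1e-6):
            raise ValueError("distance matrix must be symmetric on masked-in entries")
        vals = self.d[self.mask]
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals <= 0)):
            raise ValueError("masked-in distances must be finite and > 0")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (L, L):
                raise ValueError("confidence shape mismatch")
            conf = self.confidence[self.mask]
            if conf.size and (np.any(conf < 0) or np.any(conf > 1)):
                raise ValueError("confidence must lie in [0, 1]")
        if self.atom_mode not in ("CA", "CB"):
            raise ValueError("atom_mode must be 'CA' or 'CB'")

    @property
    def L(self) -> int:
        return self.d.shape[0]


@dataclass
class ContactStats:
    """Precision of the top-L/2 long-range contact predictions."""

    precision_top_L_half_long: float
    n_evaluated: int


def _scoring_coords(s: Structure, atom_mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue coordinates for the requested atom with a validity flag.

    In CB mode glycine (and residues lacking a CB) fall back to CA.
    """
    if atom_mode == "CA":
        return s.ca_coords, np.ones(s.L, dtype=bool)
    coords = s.ca_coords.copy()
    if s.cb_coords is not None and s.cb_mask is not None:
        coords[s.cb_mask] = s.cb_coords[s.cb_mask]
    return coords, np.ones(s.L, dtype=bool)


def map_from_structure(s: Structure, atom_mode: str = "CA") -> DistanceMap:
    """Compute the observed distance map of a structure."""
    coords, valid = _scoring_coords(s, atom_mode)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    mask = valid[:, None] & valid[None, :]
    np.fill_diagonal(mask, False)
    return DistanceMap(d=d, mask=mask, atom_mode=atom_mode)


def _ranked_pairs(pred: DistanceMap, separation_min: int, rank_by: str) -> list[tuple[int, int]]:
    """Candidate pairs i<j with |i-j| >= separation_min, best-first.

    Ranking is by descending confidence or by ascending predicted distance;
    ties break on (i, j) lexicographic order so results are deterministic.
    """
    L = pred.L
    iu, ju = np.triu_indices(L, k=separation_min)
    keep = pred.mask[iu, ju]
    iu, ju = iu[keep], ju[keep]
    if rank_by == "auto":
        rank_by = "confidence" if pred.confidence is not None else "distance"
    if rank_by == "confidence":
        if pred.confidence is None:
            raise ValueError("map carries no confidence to rank by")
        key = -pred.confidence[iu, ju]
    elif rank_by == "distance":
        key = pred.d[iu, ju]
    else:
        raise ValueError("rank_by must be 'auto', 'confidence' or 'distance'")
    order = np.lexsort((ju, iu, key))
    return list(zip(iu[order].tolist(), ju[order].tolist()))


def contact_precision(
    pred: DistanceMap,
    native: Structure,
    separation_min: int = LONG_RANGE_SEP,
    contact_cutoff: float = CONTACT_CUTOFF,
    rank_by: str = "auto",
) -> ContactStats:
    """Precision of the top floor(L/2) long-range contacts against a native structure.

    Pairs are ranked by confidence (descending) or predicted distance
    (ascending); ``rank_by='auto'`` uses confidence when the map carries one.
    Rank by distance when the confidence reflects distance *error* rather
    than contact probability (a confidently predicted 30 Å pair is a
    confident non-contact).  A prediction counts as correct when the native
    distance (CB convention matching ``pred.atom_mode``) is <=
    ``contact_cutoff``.
    """
    if pred.L != native.L:
        raise ValueError(f"map length {pred.L} != native length {native.L}")
    pairs = _ranked_pairs(pred, separation_min, rank_by)
    if not pairs:
        raise ValueError("no eligible pairs at the requested sequence separation")
    n_top = max(1, pred.L // 2)
    top = pairs[:n_top]
    native_map = map_from_structure(native, atom_mode=pred.atom_mode)
    hits = sum(1 for i, j in top if native_map.d[i, j] <= contact_cutoff)
    return ContactStats(precision_top_L_half_long=hits / len(top), n_evaluated=len(top))


def map_agreement(
    pred: DistanceMap,
    model: Structure,
    separation_min: int = 0,
    d_max: float = DEFAULT_D_MAX,
    kernel_width: float = 2.0,
) -> float:
    """Similarity in (0, 1] between a predicted map and a model's observed map.

    Scorable pairs are masked-in, |i-j| >= separation_min and predicted
    distance <= d_max.  Each pair contributes a bounded Lorentzian-style
    kernel 1 / (1 + ((d_model - d_pred) / w)^2) with width w = 2 Å, weighted
    by confidence when present, so no single outlier pair can dominate.
    The score is 1 exactly when the model reproduces every scorable distance.
    """
    if pred.L != model.L:
        raise ValueError(f"map length {pred.L} != model length {model.L}")
    obs = map_from_structure(model, atom_mode=pred.atom_mode)
    iu, ju = np.triu_indices(pred.L, k=max(1, separation_min))
    keep = pred.mask[iu, ju] & obs.mask[iu, ju] & (pred.d[iu, ju] <= d_max)
    iu, ju = iu[keep], ju[keep]
    if iu.size == 0:
        raise ValueError("no scorable pairs (mask, separation and d_max leave nothing)")
    resid = (obs.d[iu, ju] - pred.d[iu, ju]) / kernel_width
    kernel = 1.0 / (1.0 + resid ** 2)
    if pred.confidence is not None:
        w = pred.confidence[iu, ju]
        if w.sum() <= 0:
            raise ValueError("all scorable pairs have zero confidence")
        return float(np.average(kernel, weights=w))
    return float(kernel.mean())


def write_map(dm: DistanceMap, path: str | Path, fmt: str = "matrix_txt") -> None:
    """Write a map as a plain-text matrix (-1 = masked) or a CASP-RR-style pair list."""
    path = Path(path)
    if fmt == "matrix_txt":
        out = np.where(dm.mask, dm.d, -1.0)
        np.savetxt(path, out, fmt="%.4f")
    elif fmt == "rr_pairs":
        lines = []
        iu, ju = np.triu_indices(dm.L, k=1)
        keep = dm.mask[iu, ju]
        for i, j in zip(iu[keep].tolist(), ju[keep].tolist()):
            conf = 1.0 if dm.confidence is None else dm.confidence[i, j]
            d = dm.d[i, j]
            # 1-based indices on output per the RR convention
            lines.append(f"{i + 1} {j + 1} {d:.4f} {d:.4f} {conf:.4f}\n")
        path.write_text("".join(lines))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_map(path: str | Path, fmt: str = "matrix_txt", L: int | None = None) -> DistanceMap:
    """Read a distance map written by :func:`write_map`.

    ``matrix_txt``: whitespace-separated square matrix, -1 or NaN marks a
    masked entry.  ``rr_pairs``: lines "i j d_lower d_upper confidence" with
    1-based indices (L required, or inferred from the largest index);
    the stored distance is the midpoint of [d_lower, d_upper].
    """
    path = Path(path)
    if fmt == "matrix_txt":
        d = np.loadtxt(path, ndmin=2)
        if d.shape[0] != d.shape[1]:
            raise FormatError(f"{path}: matrix is {d.shape[0]}x{d.shape[1]}, not square")
        mask = np.isfinite(d) & (d > 0)
        d = np.where(mask, d, 1.0)
        mask &= mask.T
        return DistanceMap(d=d, mask=mask)
    if fmt == "rr_pairs":
        entries: dict[tuple[int, int], tuple[float, float]] = {}
        max_idx = 0
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            parts = line.split()
            if not parts or parts[0].upper() in ("PFRMAT", "TARGET", "MODEL", "END"):
                continue
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected 'i j lo hi conf'")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            lo, hi, conf = float(parts[2]), float(parts[3]), float(parts[4])
            if i < 0 or j < 0 or i == j:
                raise FormatError(f"{path}:{lineno}: bad indices {i + 1}, {j + 1}")
            key = (min(i, j), max(i, j))
            val = ((lo + hi) / 2.0, conf)
            if key in entries and not np.allclose(entries[key], val):
                raise FormatError(f"{path}:{lineno}: conflicting duplicate for pair {key}")
            entries[key] = val
            max_idx = max(max_idx, i, j)
        if L is None:
            L = max_idx + 1
        elif max_idx >= L:
            raise FormatError(f"{path}: index {max_idx + 1} out of range for L={L}")
        d = np.ones((L, L))
        mask = np.zeros((L, L), dtype=bool)
        conf_m = np.zeros((L, L))
        for (i, j), (dist, conf) in entries.items():
            if dist <= 0:
                raise FormatError(f"{path}: non-positive distance for pair ({i + 1}, {j + 1})")
            d[i, j] = d[j, i] = dist
            mask[i, j] = mask[j, i] = True
            conf_m[i, j] = conf_m[j, i] = min(max(conf, 0.0), 1.0)
        return DistanceMap(d=d, mask=mask, confidence=conf_m)
    raise ValueError(f"unknown format {fmt!r}")
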