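"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's code paths: superposition is Horn's
quaternion eigenvalue method (not SVD Kabsch), and the fragment search is an
exhaustive enumeration with its own refinement loop.
"""

from __future__ import annotations

import numpy as np

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)


def quaternion_rotation(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing |xa R^T + t - xb|^2 (Horn 1987)."""
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    a = xa - ca
    b = xb - cb
    M = a.T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(K)
    w, x, y, z = vecs[:, -1]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = cb - ca @ R.T
    return R, t


def quaternion_rmsd(xa: np.ndarray, xb: np.ndarray) -> float:
    R, t = quaternion_rotation(xa, xb)
    return float(np.sqrt(np.mean(np.sum((xa @ R.T + t - xb) ** 2, axis=1))))


def _all_poses(xm: np.ndarray, xn: np.ndarray, cutoff: float):
    """Per-residue distance vectors from exhaustively seeded refinements."""
    L = len(xm)
    for flen in range(4, L + 1):
        for start in range(L - flen + 1):
            idx = np.arange(start, start + flen)
            prev: set[int] = set()
            for _ in range(20):
                R, t = quaternion_rotation(xm[idx], xn[idx])
                d = np.linalg.norm(xm @ R.T + t - xn, axis=1)
                yield d
                new = np.flatnonzero(d <= cutoff)
                if len(new) < 3:
                    break
                cur = set(new.tolist())
                if cur == prev:
                    break
                prev = cur
                idx = new


def tm_oracle(xm: np.ndarray, xn: np.ndarray) -> float:
    """Exhaustive-seed TM-score with d0 = 1.24 (L-15)^(1/3) - 1.8 (floor 0.5)."""
    L = len(xn)
    d0 = max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)
    best = 0.0
    for cutoff in (max(4.5, d0), 8.0):
        for d in _all_poses(xm, xn, cutoff):
            best = max(best, float(np.mean(1.0 / (1.0 + (d / d0) ** 2))))
    return best


def gdt_oracle(xm: np.ndarray, xn: np.ndarray) -> float:
    """Exhaustive-seed GDT_TS in percent; every pose scores every cutoff."""
    L = len(xm)
    best = {c: 0 for c in GDT_CUTOFFS}
    for cutoff in GDT_CUTOFFS:
        for d in _all_poses(xm, xn, cutoff):
            for c in GDT_CUTOFFS:
                best[c] = max(best[c], int(np.sum(d <= c)))
    return 100.0 * float(np.mean([best[c] / L for c in GDT_CUTOFFS]))
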