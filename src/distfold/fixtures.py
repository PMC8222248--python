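"""Deterministic synthetic fixtures: structures, noisy maps, decoys, MSAs, hits.

Every generator is a pure function of its parameters and seed, so the whole
toolkit is testable without external databases, trained distance predictors
or real PDB entries.  Ground-truth chains use the standard CA virtual bond
length of 3.8 Å and are self-avoiding (non-sequential CA pairs > 3.5 Å).

The noise model for predicted maps — i.i.d. Gaussian error per residue pair,
a fraction of long-range entries corrupted to uniform random distances, and
a confidence that decays with the true error — is a stylized stand-in for
the error characteristics of a learned distance predictor; it reproduces the
rank structure (confident pairs are accurate) but not the spatially
correlated error patterns of real predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .distmat import LONG_RANGE_SEP, DistanceMap, map_from_structure
from .domains import TemplateHit
from .msa_stats import MSA
from .structio import Structure

BOND = 3.8
HELIX_RISE = 1.5
HELIX_TWIST = np.radians(100.0)
# radius chosen so consecutive CA spacing is exactly the 3.8 Å virtual bond
HELIX_RADIUS = np.sqrt(BOND ** 2 - HELIX_RISE ** 2) / (2.0 * np.sin(HELIX_TWIST / 2.0))

TOPOLOGIES = ("ideal_helix", "helix_bundle", "random_coil", "zigzag")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Parameters of a synthetic ground-truth fixture."""

    L: int
    topology: str = "helix_bundle"
    seed: int = 0
    noise_sigma: float = 0.0
    corrupt_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}")
        if self.L < 8:
            raise ValueError("fixtures need L >= 8")
        if self.noise_sigma < 0 or not 0 <= self.corrupt_frac <= 1:
            raise ValueError("noise_sigma >= 0 and corrupt_frac in [0, 1] required")


def _helix_points(n: int, phase: float = 0.0, right_handed: bool = True) -> np.ndarray:
    """Ideal helix along +z: rise 1.5 Å, 100°/residue, CA spacing exactly 3.8 Å."""
    i = np.arange(n)
    sign = 1.0 if right_handed else -1.0
    phi = phase + sign * HELIX_TWIST * i
    return np.column_stack([
        HELIX_RADIUS * np.cos(phi),
        HELIX_RADIUS * np.sin(phi),
        HELIX_RISE * i,
    ])


def _arc_linker(a: np.ndarray, b: np.ndarray, n_points: int, bulge_dir: np.ndarray,
                bond: float = BOND) -> np.ndarray:
    """``n_points`` intermediate points on a circular arc from a to b with equal
    chord lengths ``bond`` (so the linker keeps ideal CA spacing)."""
    k = n_points + 1  # number of bonds
    g = float(np.linalg.norm(b - a))
    if g >= k * bond:
        raise ValueError("anchors too far apart for the linker length")

    def chord_ratio(alpha: float) -> float:
        return np.sin(k * alpha / 2.0) / np.sin(alpha / 2.0) - g / bond

    alpha = scipy.optimize.brentq(chord_ratio, 1e-9, 2.0 * np.pi / k - 1e-9)
    R = bond / (2.0 * np.sin(alpha / 2.0))
    total = k * alpha  # full arc angle; may exceed pi for long linkers
    # plane frame: u along the chord, v along the bulge
    u = (b - a) / g
    v = bulge_dir - np.dot(bulge_dir, u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise ValueError("bulge direction parallel to the chord")
    v = v / nv
    mid = (a + b) / 2.0
    h = np.sqrt(max(R ** 2 - (g / 2.0) ** 2, 0.0))
    # try both center placements and sweep directions; keep the arc whose
    # midpoint lies on the bulge side
    for center in (mid - h * v, mid + h * v):
        ta = np.arctan2(np.dot(a - center, v), np.dot(a - center, u))
        tb = np.arctan2(np.dot(b - center, v), np.dot(b - center, u))
        for sweep in (-total, total):
            if abs((ta + sweep - tb + np.pi) % (2.0 * np.pi) - np.pi) > 1e-6:
                continue
            thetas = ta + sweep * np.arange(1, k) / k
            pts = center + R * (np.cos(thetas)[:, None] * u + np.sin(thetas)[:, None] * v)
            apex = center + R * (np.cos(ta + sweep / 2.0) * u + np.sin(ta + sweep / 2.0) * v)
            if np.dot(apex - mid, v) > 0:
                return pts
    raise RuntimeError("arc construction failed")  # unreachable for valid anchors


def _make_zigzag(L: int) -> np.ndarray:
    """Planar extended chain: CA spacing 3.8 Å, all residues in the z = 0 plane."""
    ax = 3.3
    ay = np.sqrt(BOND ** 2 - ax ** 2)
    i = np.arange(L)
    return np.column_stack([ax * i, ay * (i % 2), np.zeros(L)])


def _make_coil(L: int, rng: np.random.Generator, max_restarts: int = 200) -> np.ndarray:
    """Self-avoiding pseudo-dihedral walk with bond length 3.8 Å.

    Bond angles are drawn in 85-145 degrees and dihedrals uniformly; each
    placement is retried until no non-sequential pair comes within 3.5 Å.
    """
    for _ in range(max_restarts):
        coords = np.zeros((L, 3))
        coords[1] = [BOND, 0.0, 0.0]
        theta = np.radians(rng.uniform(85.0, 145.0))
        coords[2] = coords[1] + BOND * np.array([-np.cos(theta), np.sin(theta), 0.0])
        ok = True
        for i in range(3, L):
            placed = False
            for _attempt in range(60):
                theta = np.radians(rng.uniform(85.0, 145.0))
                phi = rng.uniform(-np.pi, np.pi)
                b1 = coords[i - 1] - coords[i - 2]
                b2 = coords[i - 2] - coords[i - 3]
                e1 = b1 / np.linalg.norm(b1)
                n1 = np.cross(b2, b1)
                if np.linalg.norm(n1) < 1e-9:
                    n1 = np.cross(b1, np.array([0.0, 0.0, 1.0]))
                n1 = n1 / np.linalg.norm(n1)
                m1 = np.cross(n1, e1)
                d = (-np.cos(theta) * e1
                     + np.sin(theta) * (np.cos(phi) * m1 + np.sin(phi) * n1))
                cand = coords[i - 1] + BOND * d
                dist = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                if np.all(dist > 3.5):
                    coords[i] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return coords
    raise RuntimeError("self-avoiding walk exceeded its retry budget; try a smaller L")


def _make_bundle(L: int, rng: np.random.Generator) -> np.ndarray:
    """2-3 roughly antiparallel helices connected by arc linkers."""
    n_helices = 2 if L < 48 else 3
    linker_len = 4
    n_link = linker_len * (n_helices - 1)
    base = (L - n_link) // n_helices
    lengths = [base] * n_helices
    lengths[-1] += (L - n_link) - base * n_helices
    sep = 9.8
    axis_xy = [(0.0, 0.0), (sep, 0.0), (sep / 2.0, sep * np.sqrt(3.0) / 2.0)]
    phase = rng.uniform(0.0, 2.0 * np.pi)
    chunks: list[np.ndarray] = []
    prev_end = None
    for k in range(n_helices):
        n = lengths[k]
        pts = _helix_points(n, phase=phase + k * 1.7)
        if k % 2 == 1:  # antiparallel: flip the helix through the xz plane is
            # a reflection (wrong chirality); rotate 180° about x instead
            pts = pts @ np.diag([1.0, -1.0, -1.0])
            pts[:, 2] -= pts[0, 2] - (lengths[k - 1] - 1) * HELIX_RISE
        cx, cy = axis_xy[k]
        pts[:, 0] += cx
        pts[:, 1] += cy
        if prev_end is not None:
            bulge = np.array([0.0, 0.0, 1.0 if k % 2 == 1 else -1.0])
            link = _arc_linker(prev_end, pts[0], linker_len, bulge)
            chunks.append(link)
        chunks.append(pts)
        prev_end = pts[-1]
    return np.vstack(chunks)


def make_structure(spec: FixtureSpec) -> Structure:
    """Generate a ground-truth CA chain for the requested topology (pure in spec)."""
    rng = np.random.default_rng(spec.seed)
    if spec.topology == "ideal_helix":
        coords = _helix_points(spec.L)
    elif spec.topology == "zigzag":
        coords = _make_zigzag(spec.L)
    elif spec.topology == "random_coil":
        coords = _make_coil(spec.L, rng)
    else:
        coords = _make_bundle(spec.L, rng)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=spec.L))
    return Structure(f"{spec.topology}_L{spec.L}_s{spec.seed}", seq, coords)


def make_noisy_map(
    s: Structure,
    noise_sigma: float = 0.0,
    corrupt_frac: float = 0.0,
    seed: int = 0,
) -> DistanceMap:
    """A synthetic 'predicted' distance map: truth + noise + corruption.

    One Gaussian perturbation (sigma = ``noise_sigma``) is drawn per
    unordered residue pair and mirrored, so the map stays symmetric and the
    per-pair error is exactly N(0, sigma²).  A ``corrupt_frac`` fraction of
    long-range pairs is replaced by uniform draws in [4, 20] Å.  Confidence
    is exp(-err²/8) truncated to [0.05, 1], where err is the actual error of
    that entry, emulating a predictor that knows when it is unsure.
    Distances are floored at 2 Å.
    """
    rng = np.random.default_rng(seed)
    true = map_from_structure(s, atom_mode="CA")
    L = true.L
    d = true.d.copy()
    iu, ju = np.triu_indices(L, k=1)
    keep = true.mask[iu, ju]
    iu, ju = iu[keep], ju[keep]
    noise = rng.normal(0.0, noise_sigma, size=iu.size) if noise_sigma > 0 else np.zeros(iu.size)
    vals = true.d[iu, ju] + noise
    if corrupt_frac > 0:
        lr = (ju - iu) >= LONG_RANGE_SEP
        lr_idx = np.flatnonzero(lr)
        n_corrupt = int(round(corrupt_frac * lr_idx.size))
        if n_corrupt:
            chosen = rng.choice(lr_idx, size=n_corrupt, replace=False)
            vals[chosen] = rng.uniform(4.0, 20.0, size=n_corrupt)
    vals = np.maximum(vals, 2.0)
    err = vals - true.d[iu, ju]
    conf_vals = np.clip(np.exp(-(err ** 2) / 8.0), 0.05, 1.0)
    d[iu, ju] = vals
    d[ju, iu] = vals
    conf = np.zeros((L, L))
    conf[iu, ju] = conf_vals
    conf[ju, iu] = conf_vals
    return DistanceMap(d=d, mask=true.mask.copy(), confidence=conf, atom_mode="CA")


def _reidealize(coords: np.ndarray, bond: float = BOND) -> np.ndarray:
    """Chain re-scaling pass: restore exact consecutive spacing, keeping directions."""
    out = coords.copy()
    for i in range(1, len(coords)):
        step = coords[i] - coords[i - 1]
        norm = np.linalg.norm(step)
        if norm < 1e-9:
            step, norm = np.array([bond, 0.0, 0.0]), bond
        out[i] = out[i - 1] + step * (bond / norm)
    return out


def make_decoys(
    s: Structure,
    sigmas: list[float],
    n_per_sigma: int = 5,
    seed: int = 0,
) -> list[Structure]:
    """Decoy pool: native + i.i.d. Gaussian coordinate noise per sigma level.

    Each decoy is re-idealized to 3.8 Å consecutive spacing; its model_id
    records the noise level, e.g. ``decoy_s1.0_r3``.
    """
    rng = np.random.default_rng(seed)
    decoys = []
    for sigma in sigmas:
        for rep in range(n_per_sigma):
            noise = rng.normal(0.0, sigma, size=s.ca_coords.shape) if sigma > 0 else 0.0
            coords = _reidealize(s.ca_coords + noise)
            decoys.append(Structure(f"decoy_s{sigma:g}_r{rep}", s.sequence, coords))
    return decoys


def make_hits(L: int, pattern: list[tuple[int, int, float]]) -> list[TemplateHit]:
    """Template hits from (start, end, e_value) triples (0-based half-open)."""
    hits = []
    for k, (start, end, e_value) in enumerate(pattern):
        if end > L:
            raise ValueError(f"hit [{start}, {end}) exceeds target length {L}")
        hits.append(TemplateHit(f"tmpl{k}", start, end, e_value))
    return hits


def make_msa(query: str, n_rows: int, mutation_rate: float, seed: int = 0) -> MSA:
    """Gap-free alignment: the query plus rows with i.i.d. point mutations.

    Each non-query position mutates with probability ``mutation_rate`` to a
    uniformly random different amino acid, so the expected pairwise identity
    between two mutated rows is (1-r)² + r²/19.
    """
    rng = np.random.default_rng(seed)
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    q = np.frombuffer(query.upper().encode(), dtype="S1")
    rows = [query.upper()]
    for _ in range(n_rows - 1):
        mutate = rng.random(len(q)) < mutation_rate
        row = q.copy()
        if mutate.any():
            # draw a replacement different from the original at each site
            repl = rng.integers(0, 19, size=int(mutate.sum()))
            orig_idx = np.searchsorted(aa, row[mutate])
            repl = np.where(repl >= orig_idx, repl + 1, repl)
            row[mutate] = aa[repl]
        rows.append(row.tobytes().decode())
    return MSA(rows=rows, target_id="query")
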