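"""Effective-sequence-count (Neff) diagnostics for multiple sequence alignments.

Neff measures the non-redundant depth of an MSA: each sequence is weighted
by the inverse of the number of sequences at least ``identity_threshold``
identical to it (itself included), and Neff is the sum of the weights.  The
alignment is first projected onto the query columns (columns where the first
row, the target, is not gapped); identity between two rows is the fraction
of matching symbols over their mutually non-gapped query columns.  Deep,
diverse alignments drive the quality of predicted distance maps, so log Neff
is a standard difficulty diagnostic for distance-guided modeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structio import FormatError

GAP = "-"
DEFAULT_IDENTITY_THRESHOLD = 0.8


@dataclass
class MSA:
    """An alignment: equal-length rows, row 0 is the query/target."""

    rows: list[str]
    target_id: str = "query"

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty MSA")
        self.rows = [r.upper() for r in self.rows]
        width = len(self.rows[0])
        for k, r in enumerate(self.rows):
            if len(r) != width:
                raise FormatError(f"MSA row {k} has length {len(r)}, expected {width}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def query_columns(self) -> np.ndarray:
        """Indices of columns where the query row is not gapped."""
        q = np.frombuffer(self.rows[0].encode(), dtype="S1")
        return np.flatnonzero(q != GAP.encode())

    def to_matrix(self) -> np.ndarray:
        """Byte matrix of the alignment projected onto query columns."""
        cols = self.query_columns()
        mat = np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(self.n_rows, -1)
        return mat[:, cols]


def read_msa(path: str | Path) -> MSA:
    """Read a FASTA/A3M-style alignment; lowercase insert-state columns are stripped."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no records")
    rows = []
    target_id = records[0].id
    for rec in records:
        raw = str(rec.seq)
        # a3m convention: lowercase letters are insertions relative to the query
        rows.append("".join(c for c in raw if not c.islower()).replace(".", "-").upper())
    return MSA(rows=rows, target_id=target_id)


def neff(msa: MSA, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> float:
    """Effective number of sequences after identity-based down-weighting.

    weight(r) = 1 / |{rows with identity >= threshold to r}| (self included);
    Neff = sum of weights.  Always in [1, N].
    """
    mat = msa.to_matrix()
    n = mat.shape[0]
    gap = GAP.encode()
    nongap = mat != gap
    counts = np.zeros(n, dtype=int)
    for r in range(n):
        both = nongap[r] & nongap  # (n, Lq)
        matches = ((mat[r] == mat) & both).sum(axis=1)
        aligned = both.sum(axis=1)
        ident = np.where(aligned > 0, matches / np.maximum(aligned, 1), 0.0)
        similar = ident >= identity_threshold
        similar[r] = True  # identity to self is 1 even for an all-gap row
        counts[r] = int(similar.sum())
    weights = 1.0 / counts
    return float(weights.sum())


def log_neff(msa: MSA, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> float:
    """Natural log of Neff (the standard axis for MSA-depth plots)."""
    return float(np.log(neff(msa, identity_threshold)))
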