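"""Split a target into modeling domains from template-hit coverage.

When part of a target has significant structural templates and another
sizeable region (> 40 residues by default) does not, the target is split
into template-based (TBM) and template-free (FM) modeling units, each
modeled independently.  Coverage is the union of the target intervals of
hits passing the E-value significance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_E_VALUE_MAX = 1e-3
MIN_FM_LEN = 40


@dataclass
class TemplateHit:
    """One target-template alignment: 0-based half-open target interval and E-value."""

    template_id: str
    target_start: int
    target_end: int
    e_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.target_start < self.target_end:
            raise ValueError(f"bad interval [{self.target_start}, {self.target_end})")
        if self.e_value <= 0:
            raise ValueError("E-value must be > 0")


@dataclass
class DomainSegmentation:
    """Ordered (start, end, label) segments partitioning [0, L); labels alternate TBM/FM."""

    segments: list[tuple[int, int, str]]
    L: int

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty segmentation")
        pos = 0
        prev_label = None
        for start, end, label in self.segments:
            if start != pos or end <= start or label not in ("TBM", "FM"):
                raise ValueError(f"segments must partition [0, {self.L}) contiguously")
            if label == prev_label:
                raise ValueError("adjacent segments must have different labels")
            pos = end
            prev_label = label
        if pos != self.L:
            raise ValueError("segments must cover the full target")

    def labels_per_residue(self) -> np.ndarray:
        out = np.empty(self.L, dtype="<U3")
        for start, end, label in self.segments:
            out[start:end] = label
        return out


def split_domains(
    L: int,
    hits: list[TemplateHit],
    e_value_max: float = DEFAULT_E_VALUE_MAX,
    min_fm_len: int = MIN_FM_LEN,
    min_tbm_len: int = MIN_FM_LEN,
) -> DomainSegmentation:
    """Partition a target of length L into TBM and FM segments.

    A residue is covered when any hit with E-value <= ``e_value_max``
    aligns over it.  Maximal uncovered runs longer than ``min_fm_len``
    become FM segments; shorter uncovered runs are absorbed into the
    adjacent TBM region (the left one when both flank).  A TBM segment
    shorter than ``min_tbm_len`` that touches an FM segment is too small to
    be its own modeling unit and is merged into that FM neighbor (the left
    one when both flank).  With no significant hit the whole target is one
    FM segment; with no qualifying uncovered run it is one TBM segment.
    """
    if L <= 0:
        raise ValueError("target length must be positive")
    covered = np.zeros(L, dtype=bool)
    for h in hits:
        if h.target_end > L:
            raise ValueError(f"hit {h.template_id} extends past target length {L}")
        if h.e_value <= e_value_max:
            covered[h.target_start:h.target_end] = True

    if not covered.any():
        return DomainSegmentation([(0, L, "FM")], L)

    # maximal uncovered runs longer than min_fm_len become FM
    fm_runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for pos in range(L + 1):
        if pos < L and not covered[pos]:
            if not in_run:
                in_run, start = True, pos
        else:
            if in_run and pos - start > min_fm_len:
                fm_runs.append((start, pos))
            in_run = False
    if not fm_runs:
        return DomainSegmentation([(0, L, "TBM")], L)

    segments: list[tuple[int, int, str]] = []
    pos = 0
    for start, end in fm_runs:
        if start > pos:
            segments.append((pos, start, "TBM"))
        segments.append((start, end, "FM"))
        pos = end
    if pos < L:
        segments.append((pos, L, "TBM"))

    # sub-threshold TBM islands merge into a flanking FM segment (left preferred)
    changed = True
    while changed:
        changed = False
        for k, (start, end, label) in enumerate(segments):
            if label != "TBM" or end - start >= min_tbm_len:
                continue
            left_fm = k > 0 and segments[k - 1][2] == "FM"
            right_fm = k + 1 < len(segments) and segments[k + 1][2] == "FM"
            if left_fm:
                ls, _, _ = segments[k - 1]
                segments[k - 1: k + 1] = [(ls, end, "FM")]
            elif right_fm:
                _, re_, _ = segments[k + 1]
                segments[k: k + 2] = [(start, re_, "FM")]
            else:
                continue
            # coalesce any FM segments made adjacent by the merge
            merged: list[tuple[int, int, str]] = []
            for seg in segments:
                if merged and merged[-1][2] == seg[2]:
                    merged[-1] = (merged[-1][0], seg[1], seg[2])
                else:
                    merged.append(seg)
            segments = merged
            changed = True
            break
    return DomainSegmentation(segments, L)


def read_hits(path: str | Path) -> list[TemplateHit]:
    """Read a hit table TSV: template_id, target_start, target_end, e_value (0-based half-open)."""
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        tid, s, e, ev = line.split("\t")
        hits.append(TemplateHit(tid, int(s), int(e), float(ev)))
    return hits


def write_segments(seg: DomainSegmentation, sequence: str, out_dir: str | Path,
                   target_id: str = "target") -> list[Path]:
    """Write the segmentation TSV plus one FASTA per segment; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{target_id}.domains.tsv"
    lines = ["# start\tend\tlabel\n"]
    paths = [tsv]
    for k, (start, end, label) in enumerate(seg.segments):
        lines.append(f"{start}\t{end}\t{label}\n")
        fasta = out_dir / f"{target_id}.d{k}.{label}.fasta"
        fasta.write_text(f">{target_id}.d{k} {label} {start}-{end}\n{sequence[start:end]}\n")
        paths.append(fasta)
    tsv.write_text("".join(lines))
    return paths
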