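"""Core structural data model and PDB/FASTA I/O.

The toolkit scores and folds on reduced residue representations: one CA
coordinate per residue, with an optional CB (absent for glycine).  Residues
are indexed 0-based and contiguously; original PDB residue numbers are kept
only so written files remain traceable to their source.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA1_TO_3["X"] = "UNK"
VALID_AA = set(AA3_TO_1.values()) | {"X"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Sequence:
    """A target amino-acid sequence (length conventionally called L)."""

    target_id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_AA
        if bad:
            raise FormatError(f"invalid amino-acid codes {sorted(bad)} in {self.target_id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """An ordered residue chain with CA (and optionally CB) coordinates in Å.

    ``cb_mask[i]`` is False where no CB exists (glycine, or absent in the
    source file); the corresponding ``cb_coords`` row is undefined.
    """

    model_id: str
    sequence: str
    ca_coords: np.ndarray  # (L, 3) float
    cb_coords: np.ndarray | None = None  # (L, 3) float, rows valid per cb_mask
    cb_mask: np.ndarray | None = None  # (L,) bool
    residue_numbers: np.ndarray | None = None  # original author numbering

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        L = len(self.sequence)
        if self.ca_coords.shape != (L, 3):
            raise ValueError(
                f"ca_coords shape {self.ca_coords.shape} does not match sequence length {L}"
            )
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, L + 1)
        else:
            self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
            if self.residue_numbers.shape != (L,):
                raise ValueError("residue_numbers length mismatch")
            if L > 1 and not np.all(np.diff(self.residue_numbers) > 0):
                raise ValueError("residue_numbers must be strictly increasing")
        if self.cb_coords is not None:
            self.cb_coords = np.asarray(self.cb_coords, dtype=float)
            if self.cb_coords.shape != (L, 3):
                raise ValueError("cb_coords shape mismatch")
            if self.cb_mask is None:
                self.cb_mask = np.ones(L, dtype=bool)
        if self.cb_mask is not None:
            self.cb_mask = np.asarray(self.cb_mask, dtype=bool)
            # glycine has no beta carbon by definition
            gly = np.frombuffer(self.sequence.encode(), dtype="S1") == b"G"
            self.cb_mask = self.cb_mask & ~gly
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValueError(f"invalid residue codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def L(self) -> int:
        return len(self.sequence)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly moved copy (x -> x @ R.T + t)."""
        ca = self.ca_coords @ rotation.T + translation
        cb = None
        if self.cb_coords is not None:
            cb = self.cb_coords @ rotation.T + translation
        return Structure(
            self.model_id, self.sequence, ca, cb,
            None if self.cb_mask is None else self.cb_mask.copy(),
            self.residue_numbers.copy(),
        )

    def check_chain_sanity(self, max_gap: float = 20.0) -> None:
        """Reject chains whose consecutive CA-CA distances fall outside (0, max_gap) Å."""
        if self.L < 2:
            return
        d = np.linalg.norm(np.diff(self.ca_coords, axis=0), axis=1)
        if np.any(d <= 0) or np.any(d >= max_gap):
            raise ValueError(
                f"consecutive CA-CA distances outside (0, {max_gap}) Å: "
                f"min={d.min():.2f}, max={d.max():.2f}"
            )


def read_pdb(path: str | Path, chain: str | None = None) -> Structure:
    """Read the first model of a PDB file into a CA/CB Structure.

    Only one chain is read (the first, or the one named by ``chain``); hetero
    residues are skipped, alternate locations other than '' / 'A' are ignored,
    and residues without a CA atom are dropped with a warning.
    """
    import gemmi

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    target = None
    for ch in model:
        if chain is None or ch.name == chain:
            target = ch
            break
    if target is None:
        raise FormatError(f"{path}: chain {chain!r} not found")

    seq: list[str] = []
    ca_rows: list[list[float]] = []
    cb_rows: list[list[float]] = []
    cb_ok: list[bool] = []
    numbers: list[int] = []
    seen: set[tuple[int, str]] = set()
    for res in target:
        if res.het_flag == "H":
            continue
        key = (res.seqid.num, res.seqid.icode or " ")
        if key in seen:  # altloc duplicates collapse in file order
            continue
        seen.add(key)
        ca = None
        cb = None
        for atom in res:
            if atom.altloc not in ("\0", "", " ", "A"):
                continue
            if atom.name == "CA":
                ca = atom.pos
            elif atom.name == "CB":
                cb = atom.pos
        if ca is None:
            logger.warning("%s: residue %s %s has no CA atom; skipped", path, res.name, key)
            continue
        code = AA3_TO_1.get(res.name)
        if code is None:
            logger.warning("%s: unknown residue %s mapped to X", path, res.name)
            code = "X"
        seq.append(code)
        ca_rows.append([ca.x, ca.y, ca.z])
        if cb is not None and code != "G":
            cb_rows.append([cb.x, cb.y, cb.z])
            cb_ok.append(True)
        else:
            cb_rows.append([0.0, 0.0, 0.0])
            cb_ok.append(False)
        numbers.append(res.seqid.num)

    if not seq:
        raise FormatError(f"{path}: no CA atoms found")
    numbers_arr = np.asarray(numbers)
    if len(numbers_arr) > 1 and not np.all(np.diff(numbers_arr) > 0):
        # insertion codes / renumbering: fall back to file order
        numbers_arr = np.arange(1, len(numbers_arr) + 1)
    return Structure(
        model_id=path.stem,
        sequence="".join(seq),
        ca_coords=np.asarray(ca_rows),
        cb_coords=np.asarray(cb_rows),
        cb_mask=np.asarray(cb_ok),
        residue_numbers=numbers_arr,
    )


_ATOM_FMT = (
    "ATOM  {serial:5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}{resnum:4d}{icode:1s}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-column PDB ATOM records (CA, then CB where valid)."""
    if s.L == 0:
        raise ValueError("cannot write an empty structure")
    path = Path(path)
    lines = []
    serial = 0
    for i, aa in enumerate(s.sequence):
        res3 = AA1_TO_3.get(aa, "UNK")
        num = int(s.residue_numbers[i])
        serial += 1
        x, y, z = s.ca_coords[i]
        lines.append(_ATOM_FMT.format(
            serial=serial, name=" CA ", alt=" ", res=res3, chain="A",
            resnum=num, icode=" ", x=x, y=y, z=z, occ=1.0, b=0.0, elem="C",
        ))
        if s.cb_mask is not None and s.cb_mask[i]:
            serial += 1
            x, y, z = s.cb_coords[i]
            lines.append(_ATOM_FMT.format(
                serial=serial, name=" CB ", alt=" ", res=res3, chain="A",
                resnum=num, icode=" ", x=x, y=y, z=z, occ=1.0, b=0.0, elem="C",
            ))
    lines.append("TER\nEND\n")
    path.write_text("".join(lines))


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into a list of Sequence records (order preserved)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return [Sequence(rec.id, str(rec.seq).upper()) for rec in records]
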