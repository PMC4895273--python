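"""RSA labels from DSSP accessibility and buried/exposed thresholding.

Relative solvent accessibility (RSA) of a residue is its absolute
solvent-accessible surface area (ASA, the DSSP ``ACC`` field, in square
angstroms) divided by the maximum accessibility of that residue type in an
extended Gly-X-Gly tripeptide, clamped to [0, 1].

The default maximum-accessibility table is the Rost & Sander (1994)
Gly-X-Gly lineage; published tables differ by a few percent per residue, so
every output records which table was used and a custom table can be
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "MaxAsaTable",
    "ROST_SANDER_1994",
    "DsspResidue",
    "read_dssp",
    "asa_to_rsa",
    "rsa_track_from_dssp",
    "two_state",
    "two_state_vector",
]

# Rost & Sander (1994), Gly-X-Gly extended tripeptide maxima (A^2).
_ROST_SANDER_VALUES: Dict[str, float] = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}


@dataclass(frozen=True)
class MaxAsaTable:
    """Named per-residue-type maximum solvent accessibility table (A^2)."""

    name: str
    values: Dict[str, float]

    def __post_init__(self) -> None:
        missing = set("ARNDCQEGHILKMFPSTWYV") - set(self.values)
        if missing:
            raise ValueError(f"max-ASA table lacks residues {sorted(missing)}")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("max-ASA values must be positive")

    def max_asa(self, residue_type: str, permissive: bool = False) -> Optional[float]:
        v = self.values.get(residue_type.upper())
        if v is None and not permissive:
            raise KeyError(f"unknown residue type {residue_type!r} in max-ASA table")
        return v


ROST_SANDER_1994 = MaxAsaTable("rost_sander_1994", _ROST_SANDER_VALUES)


@dataclass(frozen=True)
class DsspResidue:
    chain: str
    residue: str          # one-letter code, Cys half-cystines mapped to C
    acc: float            # ASA in A^2


def read_dssp(path) -> List[DsspResidue]:
    """Parse a classic fixed-column DSSP file.

    Only the residue identity and the ACC column are consumed.  Chain-break
    rows ('!' in the amino-acid column) are skipped; lowercase letters
    (disulfide-bonded cysteines) are mapped to 'C'.
    """
    residues: List[DsspResidue] = []
    in_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not in_data:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_data = True
                continue
            if len(line.rstrip("\n")) < 38:
                raise ValueError(f"{path}:{lineno}: DSSP residue line too short")
            aa = line[13]
            if aa == "!":
                continue  # chain break
            if aa.islower():
                aa = "C"
            chain = line[11].strip() or "A"
            try:
                acc = float(line[34:38])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unreadable ACC field")
            residues.append(DsspResidue(chain=chain, residue=aa, acc=acc))
    if not in_data:
        raise ValueError(f"{path}: no DSSP data header ('#  RESIDUE' line) found")
    if not residues:
        raise ValueError(f"{path}: no residue rows after the data header")
    return residues


def asa_to_rsa(
    asa: float,
    residue_type: str,
    table: MaxAsaTable = ROST_SANDER_1994,
    permissive: bool = False,
) -> Optional[float]:
    """ASA (A^2) to relative accessibility, clamped to [0, 1].

    Clamping absorbs real-structure cases where DSSP ASA exceeds the
    tripeptide maximum.  Unknown residue types raise unless ``permissive``
    (then ``None`` is returned so callers can skip the residue).
    """
    if asa < 0:
        raise ValueError("ASA must be non-negative")
    mx = table.max_asa(residue_type, permissive=permissive)
    if mx is None:
        return None
    return float(np.clip(asa / mx, 0.0, 1.0))


def rsa_track_from_dssp(
    path,
    sequence: Optional[str] = None,
    table: MaxAsaTable = ROST_SANDER_1994,
    permissive: bool = False,
) -> pd.DataFrame:
    """Per-residue RSA labels from a DSSP file.

    Returns a DataFrame (index, residue, asa, rsa, max_asa_table); rows with
    residue types absent from the table are dropped under ``permissive``.
    """
    residues = read_dssp(path)
    if sequence is not None and len(residues) != len(sequence):
        raise ValueError(
            f"{path}: DSSP has {len(residues)} residues but sequence has "
            f"{len(sequence)}"
        )
    rows = []
    for i, r in enumerate(residues):
        rsa = asa_to_rsa(r.acc, r.residue, table=table, permissive=permissive)
        if rsa is None:
            continue
        rows.append((i, r.residue, r.acc, rsa))
    df = pd.DataFrame(rows, columns=["index", "residue", "asa", "rsa"])
    df["max_asa_table"] = table.name
    return df


def two_state(rsa: float, threshold: float) -> str:
    """Buried/exposed call: buried iff RSA < threshold percent."""
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must lie in (0, 100) percent")
    return "buried" if rsa < threshold / 100.0 else "exposed"


def two_state_vector(rsa: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean exposed mask (True = exposed) at a percent threshold."""
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must lie in (0, 100) percent")
    return np.asarray(rsa, dtype=float) >= threshold / 100.0
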