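"""Synthetic protein fixtures with a planted feature-to-RSA relationship.

The generator emits, per protein, the full set of input files the real
pipeline consumes — FASTA, PSI-BLAST ASCII PSSM, PSIPRED ``.ss2``, a
disorder track, a DSSP-style file and a polar-fraction sidecar TSV — with
mutually consistent lengths, so every reader and the end-to-end pipeline is
testable without external programs or downloads.

The planted model: each residue carries a latent exposure code c_i in
[0, 1]; the true burial signal is the moving average of c over a
``window_span``-residue neighbourhood, stretched around 0.5, and the
labelled RSA is that signal plus Gaussian noise clipped to [0, 1].  The
sequence-side tracks encode c_i at the residue's own position only:

* PSSM: the first log-odds column is a quantized affine image of c_i (the
  remaining columns are uninformative integer noise); the information
  content decreases with c_i (conserved residues are buried).
* Secondary structure: helix and strand probabilities decrease with c_i.
* Disorder: the disordered probability increases with c_i (unstructured
  regions are highly solvent-exposed).

Because the label depends on the *neighbourhood* of c while the tracks
encode only the residue's own c_i, a predictor needs a window at least
``2 * window_span + 1`` wide to see the full signal — mirroring why window
size matters for real accessibility prediction.  ``signal="linear_mix"``
plants the same map without neighbour mixing; ``signal="none"`` draws RSA
independently of all tracks (a null dataset).

Everything is driven by one seeded generator; identical specs produce
byte-identical files.  Track values are rounded to the precision written to
disk, so in-memory records and re-parsed files agree exactly; the only
label quantization is DSSP's integer ACC column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd

from .accessibility import MaxAsaTable, ROST_SANDER_1994
from .features import AMINO_ACIDS, ProteinRecord

__all__ = ["FixtureSpec", "generate", "generate_records", "worked_example"]

# Kyte-Doolittle hydropathy, used to draw polar fractions anti-correlated
# with hydrophobicity.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 20
    length_range: Tuple[int, int] = (60, 140)
    seed: int = 0
    noise_sd: float = 0.05
    signal: str = "burial_code"   # burial_code | linear_mix | none
    window_span: int = 3          # neighbourhood radius of the planted signal

    def __post_init__(self) -> None:
        if self.signal not in ("burial_code", "linear_mix", "none"):
            raise ValueError(f"unknown signal kind {self.signal!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.length_range[0] < 2 * self.window_span + 1:
            raise ValueError("proteins shorter than the planted signal window")


def _moving_average(x: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average over +-span residues with edge shrinkage."""
    if span == 0:
        return x.copy()
    kernel = np.ones(2 * span + 1)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _make_record(
    pid: str, rng: np.random.Generator, spec: FixtureSpec,
    table: MaxAsaTable,
) -> ProteinRecord:
    n = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))

    c = rng.uniform(0.0, 1.0, size=n)  # latent per-residue exposure code
    if spec.signal == "burial_code":
        b = _moving_average(c, spec.window_span)
    elif spec.signal == "linear_mix":
        b = c.copy()
    else:
        b = rng.uniform(0.0, 1.0, size=n)  # label independent of the tracks
    # stretch around the midpoint so the signal spans most of [0, 1]
    b = np.clip(0.5 + 1.8 * (b - 0.5), 0.0, 1.0)
    rsa = np.clip(b + rng.normal(0.0, spec.noise_sd, size=n), 0.0, 1.0)

    # PSSM: column 0 encodes c, the rest is integer noise
    pssm = rng.integers(-6, 7, size=(n, 20)).astype(float)
    pssm[:, 0] = np.round(8.0 * (c - 0.5))
    info = np.round(np.clip(2.0 * (1.0 - c) + rng.normal(0, 0.1, n), 0.0, None), 2)

    helix = np.clip(0.70 * (1.0 - c) + rng.normal(0, 0.04, n), 0.0, 1.0)
    strand = np.clip(0.20 * (1.0 - c) + rng.normal(0, 0.04, n), 0.0, 1.0)
    coil = np.clip(1.0 - helix - strand, 0.0, 1.0)
    ss = np.round(np.column_stack([coil, helix, strand]), 3)

    dis = np.clip(0.8 * c + 0.1 + rng.normal(0, 0.04, n), 0.0, 1.0)
    diso = np.round(np.column_stack([dis, 1.0 - dis]), 3)

    kd = np.array([_KD[a] for a in seq])
    polar = np.round(
        np.clip(0.5 - kd / 9.0 + rng.normal(0, 0.08, n), 0.0, 1.0), 3
    )

    # quantize RSA exactly as the DSSP writer will (integer ACC)
    max_asa = np.array([table.values[a] for a in seq])
    acc = np.round(rsa * max_asa)
    rsa_q = np.clip(acc / max_asa, 0.0, 1.0)

    return ProteinRecord(
        id=pid,
        sequence=seq,
        pssm=pssm,
        pssm_info=info,
        ss_probs=ss,
        diso_probs=diso,
        rsa=rsa_q,
        polar_fraction=polar,
    )


def generate_records(
    spec: FixtureSpec, table: MaxAsaTable = ROST_SANDER_1994
) -> List[ProteinRecord]:
    """In-memory fixture proteins (same content the file writers emit)."""
    rng = np.random.default_rng(spec.seed)
    width = max(3, len(str(spec.n_proteins)))
    return [
        _make_record(f"synth{str(i + 1).zfill(width)}", rng, spec, table)
        for i in range(spec.n_proteins)
    ]


# --------------------------------------------------------------------------
# file writers (dialects accepted by the real readers)
# --------------------------------------------------------------------------

def _write_fasta(rec: ProteinRecord, path: Path) -> None:
    lines = [f">{rec.id}"]
    for i in range(0, len(rec.sequence), 60):
        lines.append(rec.sequence[i:i + 60])
    path.write_text("\n".join(lines) + "\n")


def _write_pssm(rec: ProteinRecord, path: Path) -> None:
    buf = io.StringIO()
    buf.write(
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
    )
    buf.write("           " + "  ".join(AMINO_ACIDS) + "   " + "  ".join(AMINO_ACIDS) + "\n")
    rng = np.random.default_rng(len(rec.sequence))  # cosmetic percentage block
    perc = rng.integers(0, 100, size=(len(rec.sequence), 20))
    for i, aa in enumerate(rec.sequence):
        scores = " ".join(f"{int(v):3d}" for v in rec.pssm[i])
        ps = " ".join(f"{int(v):3d}" for v in perc[i])
        buf.write(
            f"{i + 1:5d} {aa}  {scores}  {ps}  {rec.pssm_info[i]:5.2f} {0.10:5.2f}\n"
        )
    buf.write("\n                      K         Lambda\n")
    path.write_text(buf.getvalue())


def _write_ss2(rec: ProteinRecord, path: Path) -> None:
    buf = io.StringIO()
    buf.write("# PSIPRED VFORMAT (PSIPRED V4.0)\n\n")
    for i, aa in enumerate(rec.sequence):
        c, h, e = rec.ss_probs[i]
        letter = "CHE"[int(np.argmax(rec.ss_probs[i]))]
        buf.write(f"{i + 1:4d} {aa} {letter}   {c:.3f}  {h:.3f}  {e:.3f}\n")
    path.write_text(buf.getvalue())


def _write_diso(rec: ProteinRecord, path: Path) -> None:
    buf = io.StringIO()
    buf.write("# Per-residue disorder prediction\n")
    for i, aa in enumerate(rec.sequence):
        d, o = rec.diso_probs[i]
        buf.write(f"{i + 1:5d} {aa} {d:.3f} {o:.3f}\n")
    path.write_text(buf.getvalue())


def _write_dssp(
    rec: ProteinRecord, path: Path, table: MaxAsaTable
) -> None:
    """DSSP-minimal dialect: a real header line and residue rows that place
    the chain, amino acid and ACC in the classic column spans."""
    buf = io.StringIO()
    buf.write("==== Secondary Structure Definition (synthetic fixture) ====\n")
    buf.write(f"  {len(rec.sequence)}  1  0  0  0  TOTAL NUMBER OF RESIDUES\n")
    buf.write("  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N\n")
    for i, aa in enumerate(rec.sequence):
        acc = int(round(float(rec.rsa[i]) * table.values[aa]))
        line = f"{i + 1:5d}{i + 1:5d} A {aa}" + " " * 20 + f"{acc:4d}"
        buf.write(line + "\n")
    path.write_text(buf.getvalue())


def _write_polar(rec: ProteinRecord, path: Path) -> None:
    df = pd.DataFrame(
        {
            "id": rec.id,
            "index": np.arange(len(rec.sequence)),
            "F": [f"{v:.3f}" for v in rec.polar_fraction],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def generate(
    spec: FixtureSpec, outdir, table: MaxAsaTable = ROST_SANDER_1994
) -> Path:
    """Write a complete fixture manifest directory; returns the manifest path.

    The manifest is a TSV with columns (id, fasta, pssm, ss2, diso, dssp,
    polarF), paths relative to the manifest location.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_records(spec, table)
    rows = []
    for rec in records:
        _write_fasta(rec, outdir / f"{rec.id}.fasta")
        _write_pssm(rec, outdir / f"{rec.id}.pssm")
        _write_ss2(rec, outdir / f"{rec.id}.ss2")
        _write_diso(rec, outdir / f"{rec.id}.diso")
        _write_dssp(rec, outdir / f"{rec.id}.dssp", table)
        _write_polar(rec, outdir / f"{rec.id}.polarF.tsv")
        rows.append(
            {
                "id": rec.id,
                "fasta": f"{rec.id}.fasta",
                "pssm": f"{rec.id}.pssm",
                "ss2": f"{rec.id}.ss2",
                "diso": f"{rec.id}.diso",
                "dssp": f"{rec.id}.dssp",
                "polarF": f"{rec.id}.polarF.tsv",
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


# --------------------------------------------------------------------------
# hand-specified worked example
# --------------------------------------------------------------------------

def worked_example() -> Tuple[ProteinRecord, List[str]]:
    """A fixed 12-residue protein with hand-written tracks.

    Returns the record and the expected side-chain environment class of each
    residue (from its rsa/polar_fraction pair), used in unit tests and docs.
    """
    seq = "MKVLAGRWYDTE"
    n = len(seq)
    pssm = np.zeros((n, 20))
    pssm[:, 0] = np.linspace(-4, 4, n).round()     # planted ramp in column A
    pssm[:, 1] = [1, -1] * (n // 2)                # alternating column R
    info = np.linspace(2.0, 0.0, n).round(2)
    ss = np.tile([0.2, 0.6, 0.2], (n, 1))
    diso = np.column_stack([np.linspace(0, 1, n), np.linspace(1, 0, n)]).round(3)
    rsa = np.array(
        [0.05, 0.05, 0.08, 0.20, 0.20, 0.30, 0.36, 0.40, 0.70, 0.08, 0.35, 0.90]
    )
    polar = np.array(
        [0.40, 0.50, 0.60, 0.60, 0.70, 0.67, 0.10, 0.90, 0.50, 0.44, 0.66, 0.30]
    )
    record = ProteinRecord(
        id="worked", sequence=seq, pssm=pssm, pssm_info=info,
        ss_probs=ss, diso_probs=diso, rsa=rsa, polar_fraction=polar,
    )
    expected_classes = [
        "B1", "B2", "B3", "P1", "P2", "P2", "E", "E", "E", "B1", "P1", "E",
    ]
    return record, expected_classes
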