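"""Per-residue feature tracks and sliding-window encoding.

A residue is described by the concatenation of five feature families over a
window of L = 2l + 1 consecutive positions centred on it:

==========  =========================================  ========
family      source                                     columns
==========  =========================================  ========
PSSM        PSI-BLAST log-odds, logistic-normalized    20 * L
SS          PSIPRED 3-state probabilities (C, H, E)     3 * L
DISO        DISOPRED disorder/order probabilities       2 * L
SCE         side-chain environment propensity 6-vector       6
CS          conservation (PSSM information content,          L
            min-max scaled on the training set)
==========  =========================================  ========

Window positions falling outside the chain are padded with neutral values
(0.5 for normalized PSSM, 1/3 for SS, 0.5 for DISO and CS).

The side-chain environment of a residue with known structure is one of six
classes combining burial level (RSA cut at 0.09 and 0.36) with the polar
fraction F of side-chain area covered by polar atoms (cuts 0.45/0.58 inside
the buried class, 0.67 inside the partially buried class).  Because RSA and
F are unknown at prediction time, the encoder learns, on the labelled
training proteins, the propensity of each amino-acid type for the six
classes and encodes every residue by its type's propensity vector — a
sequence-only proxy for the structural environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AMINO_ACIDS",
    "SCE_CLASSES",
    "ProteinRecord",
    "WindowConfig",
    "EncodedDataset",
    "logistic_normalize",
    "read_fasta",
    "read_pssm",
    "read_ss2",
    "read_diso",
    "read_polar_fraction",
    "side_chain_class",
    "estimate_sce_propensities",
    "sce_feature",
    "ConservationScaler",
    "conservation_track",
    "encode",
    "ResidueFeatureEncoder",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
SCE_CLASSES = ("B1", "B2", "B3", "P1", "P2", "E")
ALL_FAMILIES = ("PSSM", "SS", "DISO", "SCE", "CS")

_PAD = {"PSSM": 0.5, "SS": 1.0 / 3.0, "DISO": 0.5, "CS": 0.5}


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """One protein's sequence plus aligned per-residue feature tracks.

    All present tracks must have one row per residue.  ``rsa`` and
    ``polar_fraction`` are only needed for training labels / SCE estimation.
    """

    id: str
    sequence: str
    pssm: Optional[np.ndarray] = None        # (n, 20) log-odds
    pssm_info: Optional[np.ndarray] = None   # (n,) information content
    ss_probs: Optional[np.ndarray] = None    # (n, 3) C, H, E
    diso_probs: Optional[np.ndarray] = None  # (n, 2) disordered, ordered
    rsa: Optional[np.ndarray] = None         # (n,) in [0, 1]
    polar_fraction: Optional[np.ndarray] = None  # (n,) in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        for name in ("pssm", "pssm_info", "ss_probs", "diso_probs", "rsa",
                     "polar_fraction"):
            track = getattr(self, name)
            if track is None:
                continue
            track = np.asarray(track, dtype=float)
            setattr(self, name, track)
            if track.shape[0] != n:
                raise ValueError(
                    f"protein {self.id!r}: track {name} has {track.shape[0]} "
                    f"rows for a {n}-residue sequence"
                )
            if not np.isfinite(track).all():
                raise ValueError(f"protein {self.id!r}: non-finite values in {name}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window configuration: half-width l, window length L = 2l + 1."""

    half_width: int = 3
    include: Tuple[str, ...] = ALL_FAMILIES
    windowed_conservation: bool = True

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        unknown = set(self.include) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")

    @property
    def window_length(self) -> int:
        return 2 * self.half_width + 1

    @classmethod
    def from_window_length(cls, L: int, **kw) -> "WindowConfig":
        if L % 2 != 1 or L < 1:
            raise ValueError("window length L must be odd and >= 1")
        return cls(half_width=(L - 1) // 2, **kw)

    def n_columns(self) -> int:
        L = self.window_length
        n = 0
        if "PSSM" in self.include:
            n += 20 * L
        if "SS" in self.include:
            n += 3 * L
        if "DISO" in self.include:
            n += 2 * L
        if "SCE" in self.include:
            n += 6
        if "CS" in self.include:
            n += L if self.windowed_conservation else 1
        return n


@dataclass
class EncodedDataset:
    """Flat residue-by-feature design matrix with provenance.

    ``groups`` carries the protein id of every row so that cross-validation
    can split by protein; ``residues`` the amino-acid letter (for per-type
    error profiling).
    """

    X: np.ndarray
    column_labels: List[str]
    groups: np.ndarray
    residues: np.ndarray
    y: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.column_labels):
            raise ValueError("column label count does not match X")
        if np.isnan(self.X).any():
            raise ValueError("NaN in encoded design matrix")

    @property
    def n_rows(self) -> int:
        return int(self.X.shape[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_labels)
        df.insert(0, "protein", self.groups)
        df.insert(1, "residue", self.residues)
        if self.y is not None:
            df["rsa"] = self.y
        return df

    @staticmethod
    def concatenate(parts: Sequence["EncodedDataset"]) -> "EncodedDataset":
        if not parts:
            raise ValueError("no datasets to concatenate")
        labels = parts[0].column_labels
        for p in parts[1:]:
            if p.column_labels != labels:
                raise ValueError("datasets have incompatible columns")
        ys = [p.y for p in parts]
        y = None if any(v is None for v in ys) else np.concatenate(ys)
        return EncodedDataset(
            X=np.vstack([p.X for p in parts]),
            column_labels=list(labels),
            groups=np.concatenate([p.groups for p in parts]),
            residues=np.concatenate([p.residues for p in parts]),
            y=y,
        )


# --------------------------------------------------------------------------
# file readers
# --------------------------------------------------------------------------

def read_fasta(path) -> List[Tuple[str, str]]:
    """All (id, sequence) pairs of a FASTA file, uppercased."""
    out = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_pssm(path, sequence: Optional[str] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Parse a PSI-BLAST ASCII PSSM.

    Accepts the checkpoint-style ASCII dialect: header lines, then one row
    per residue carrying the position index, the residue letter, 20 integer
    log-odds scores, (optionally) 20 weighted-percentage columns, the
    information content and the relative gapless weight.

    Returns ``(scores, info)`` with ``scores`` an (n, 20) float array of the
    log-odds columns and ``info`` the (n,) information-content column.  When
    ``sequence`` is given, residue letters are cross-checked against it.
    """
    scores: List[List[float]] = []
    info: List[float] = []
    letters: List[str] = []
    last_good = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if len(tok) < 22 or not tok[0].isdigit():
                continue  # header, ruler or footer line
            if len(tok) not in (22, 24, 42, 44):
                raise _parse_error(
                    path, lineno,
                    f"unexpected field count {len(tok)} in PSSM row",
                )
            try:
                row = [float(v) for v in tok[2:22]]
                if len(tok) >= 44:
                    inf = float(tok[42])
                elif len(tok) == 42:
                    inf = float(tok[-1])
                elif len(tok) == 24:
                    inf = float(tok[22])
                else:
                    inf = float(tok[-1]) if len(tok) > 22 else 0.0
            except ValueError:
                raise _parse_error(path, lineno, "non-numeric cell in PSSM row")
            idx = int(tok[0])
            if idx != len(scores) + 1:
                raise _parse_error(
                    path, lineno,
                    f"position index {idx} out of order (last good row: "
                    f"{last_good})",
                )
            scores.append(row)
            info.append(inf)
            letters.append(tok[1])
            last_good = lineno
    if not scores:
        raise ValueError(f"{path}: no PSSM data rows found (last good line: 0)")
    if sequence is not None:
        if len(scores) != len(sequence):
            raise ValueError(
                f"{path}: PSSM has {len(scores)} rows but sequence has "
                f"{len(sequence)} residues"
            )
        mism = [
            i for i, (a, b) in enumerate(zip(letters, sequence))
            if a != b and a != "X" and b != "X"
        ]
        if mism:
            raise ValueError(
                f"{path}: residue letters disagree with sequence at "
                f"positions {mism[:5]}"
            )
    return np.asarray(scores, dtype=float), np.asarray(info, dtype=float)


def read_ss2(path, sequence: Optional[str] = None) -> np.ndarray:
    """Parse a PSIPRED ``.ss2`` file into an (n, 3) array of C/H/E
    probabilities.  Header/comment lines are skipped."""
    rows: List[List[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if len(tok) < 6 or not tok[0].isdigit():
                if rows:
                    raise _parse_error(path, lineno, "malformed .ss2 data row")
                continue
            try:
                rows.append([float(tok[3]), float(tok[4]), float(tok[5])])
            except ValueError:
                raise _parse_error(path, lineno, "non-numeric probability in .ss2")
    if not rows:
        raise ValueError(f"{path}: no .ss2 data rows found")
    probs = np.asarray(rows, dtype=float)
    if sequence is not None and probs.shape[0] != len(sequence):
        raise ValueError(
            f"{path}: .ss2 has {probs.shape[0]} rows but sequence has "
            f"{len(sequence)} residues"
        )
    return probs


def read_diso(path, sequence: Optional[str] = None) -> np.ndarray:
    """Parse per-residue disorder output into an (n, 2) array of
    (disordered, ordered) probabilities.

    Accepts whitespace-delimited rows ``index residue p_disordered
    [p_ordered]``; with a single probability column the ordered probability
    is its complement.
    """
    rows: List[List[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0].startswith("#") or not tok[0].isdigit():
                continue
            try:
                if len(tok) >= 4:
                    rows.append([float(tok[2]), float(tok[3])])
                elif len(tok) == 3:
                    p = float(tok[2])
                    rows.append([p, 1.0 - p])
                else:
                    raise ValueError
            except ValueError:
                raise _parse_error(path, lineno, "malformed disorder data row")
    if not rows:
        raise ValueError(f"{path}: no disorder data rows found")
    probs = np.asarray(rows, dtype=float)
    if sequence is not None and probs.shape[0] != len(sequence):
        raise ValueError(
            f"{path}: disorder track has {probs.shape[0]} rows but sequence "
            f"has {len(sequence)} residues"
        )
    return probs


def read_polar_fraction(path, sequence: Optional[str] = None) -> np.ndarray:
    """Sidecar TSV (id, index, F) with the per-residue polar fraction of the
    side-chain area; returns the (n,) F vector ordered by index."""
    df = pd.read_csv(path, sep="\t")
    need = {"index", "F"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: polar-fraction TSV needs columns {sorted(need)}")
    df = df.sort_values("index")
    f = df["F"].to_numpy(dtype=float)
    if sequence is not None and f.shape[0] != len(sequence):
        raise ValueError(
            f"{path}: polar-fraction track has {f.shape[0]} rows but sequence "
            f"has {len(sequence)} residues"
        )
    if ((f < 0) | (f > 1)).any():
        raise ValueError(f"{path}: polar fraction outside [0, 1]")
    return f


# --------------------------------------------------------------------------
# feature primitives
# --------------------------------------------------------------------------

def logistic_normalize(x):
    """Standard logistic squashing 1 / (1 + exp(-x)) mapping scores to (0, 1)."""
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


def side_chain_class(rsa: float, polar_fraction: float) -> str:
    """Six-class side-chain environment of a residue with known structure.

    Burial: B (buried) for RSA < 0.09, P (partially buried) for
    0.09 <= RSA < 0.36, E (exposed) for RSA >= 0.36.  B subdivides on the
    polar fraction F at 0.45 and 0.58 (B1/B2/B3), P at 0.67 (P1/P2).
    """
    if not (0.0 <= rsa <= 1.0) or not (0.0 <= polar_fraction <= 1.0):
        raise ValueError("rsa and polar_fraction must lie in [0, 1]")
    if rsa >= 0.36:
        return "E"
    if rsa >= 0.09:
        return "P1" if polar_fraction < 0.67 else "P2"
    if polar_fraction < 0.45:
        return "B1"
    if polar_fraction < 0.58:
        return "B2"
    return "B3"


def estimate_sce_propensities(
    records: Sequence[ProteinRecord], smoothing: float = 1.0
) -> pd.DataFrame:
    """Per-residue-type propensity for the six side-chain environment classes.

    Estimated from labelled training proteins (needs ``rsa`` and
    ``polar_fraction`` tracks) as add-one-smoothed relative frequencies;
    rows sum to 1.  Types never seen keep the uniform prior.
    """
    types = list(AMINO_ACIDS) + ["X"]
    counts = pd.DataFrame(
        smoothing, index=types, columns=list(SCE_CLASSES), dtype=float
    )
    seen = False
    for rec in records:
        if rec.rsa is None or rec.polar_fraction is None:
            continue
        seen = True
        for aa, r, f in zip(rec.sequence, rec.rsa, rec.polar_fraction):
            aa = aa if aa in AMINO_ACIDS else "X"
            counts.loc[aa, side_chain_class(float(r), float(f))] += 1.0
    if not seen:
        raise ValueError(
            "no training protein carries both rsa and polar_fraction tracks"
        )
    return counts.div(counts.sum(axis=1), axis=0)


def sce_feature(record: ProteinRecord, propensity_table: pd.DataFrame) -> np.ndarray:
    """(n, 6) matrix: each residue's type propensity vector; unknown letters
    fall back to the uniform 1/6 vector."""
    uniform = np.full(6, 1.0 / 6.0)
    out = np.empty((len(record), 6), dtype=float)
    for i, aa in enumerate(record.sequence):
        if aa in propensity_table.index:
            out[i] = propensity_table.loc[aa].to_numpy(dtype=float)
        elif "X" in propensity_table.index and aa not in AMINO_ACIDS:
            out[i] = propensity_table.loc["X"].to_numpy(dtype=float)
        else:
            out[i] = uniform
    return out


class ConservationScaler:
    """Min-max scaler for the PSSM information-content column.

    Bounds are learned on the training set and reused at prediction time;
    out-of-range test values are clipped to [0, 1].  A degenerate constant
    column maps to 0.5.
    """

    def __init__(self) -> None:
        self.lo_: Optional[float] = None
        self.hi_: Optional[float] = None

    def fit(self, info_tracks: Sequence[np.ndarray]) -> "ConservationScaler":
        values = np.concatenate([np.asarray(t, dtype=float) for t in info_tracks])
        if values.size == 0:
            raise ValueError("no information-content values to fit on")
        self.lo_ = float(values.min())
        self.hi_ = float(values.max())
        return self

    def transform(self, info: np.ndarray) -> np.ndarray:
        if self.lo_ is None:
            raise ValueError("ConservationScaler is not fitted")
        info = np.asarray(info, dtype=float)
        if self.hi_ <= self.lo_:
            return np.full(info.shape, 0.5)
        return np.clip((info - self.lo_) / (self.hi_ - self.lo_), 0.0, 1.0)


def conservation_track(
    pssm_info: np.ndarray, scaler: ConservationScaler
) -> np.ndarray:
    """Per-residue conservation score in [0, 1] from the information column."""
    return scaler.transform(pssm_info)


# --------------------------------------------------------------------------
# window assembly
# --------------------------------------------------------------------------

def _window_stack(track: np.ndarray, half_width: int, pad_value: float) -> np.ndarray:
    """Stack each residue's (2l+1)-window of a (n, c) track into (n, (2l+1)*c),
    padding beyond the termini with ``pad_value``."""
    track = np.asarray(track, dtype=float)
    if track.ndim == 1:
        track = track[:, None]
    n, c = track.shape
    l = half_width
    padded = np.full((n + 2 * l, c), pad_value, dtype=float)
    padded[l:l + n] = track
    # window offset -l .. +l for residue i is padded[i .. i+2l]
    return np.hstack([padded[k:k + n] for k in range(2 * l + 1)])


def _window_labels(family: str, channels: Sequence[str], half_width: int) -> List[str]:
    labels = []
    for off in range(-half_width, half_width + 1):
        for ch in channels:
            labels.append(f"{family}[{off:+d}].{ch}")
    return labels


def encode(
    record: ProteinRecord,
    cfg: WindowConfig,
    propensity_table: Optional[pd.DataFrame] = None,
    conservation_scaler: Optional[ConservationScaler] = None,
) -> EncodedDataset:
    """Encode one protein into per-residue feature rows.

    Concatenates, per enabled family, the residue-centred window of the
    (normalized) track; see the module docstring for the layout.  Raises if
    an enabled family's track (or auxiliary table) is missing.
    """
    l = cfg.half_width
    blocks: List[np.ndarray] = []
    labels: List[str] = []

    if "PSSM" in cfg.include:
        if record.pssm is None:
            raise ValueError(f"protein {record.id!r}: PSSM track missing")
        norm = logistic_normalize(record.pssm)
        blocks.append(_window_stack(norm, l, _PAD["PSSM"]))
        labels += _window_labels("PSSM", list(AMINO_ACIDS), l)
    if "SS" in cfg.include:
        if record.ss_probs is None:
            raise ValueError(f"protein {record.id!r}: SS track missing")
        blocks.append(_window_stack(record.ss_probs, l, _PAD["SS"]))
        labels += _window_labels("SS", ["C", "H", "E"], l)
    if "DISO" in cfg.include:
        if record.diso_probs is None:
            raise ValueError(f"protein {record.id!r}: DISO track missing")
        blocks.append(_window_stack(record.diso_probs, l, _PAD["DISO"]))
        labels += _window_labels("DISO", ["dis", "ord"], l)
    if "SCE" in cfg.include:
        if propensity_table is None:
            raise ValueError(
                f"protein {record.id!r}: SCE enabled but no propensity table"
            )
        blocks.append(sce_feature(record, propensity_table))
        labels += [f"SCE.{c}" for c in SCE_CLASSES]
    if "CS" in cfg.include:
        if record.pssm_info is None:
            raise ValueError(f"protein {record.id!r}: CS track missing (PSSM info)")
        if conservation_scaler is None:
            raise ValueError(
                f"protein {record.id!r}: CS enabled but no conservation scaler"
            )
        cs = conservation_track(record.pssm_info, conservation_scaler)
        if cfg.windowed_conservation:
            blocks.append(_window_stack(cs, l, _PAD["CS"]))
            labels += _window_labels("CS", ["info"], l)
        else:
            blocks.append(cs[:, None])
            labels += ["CS.info"]

    if not blocks:
        raise ValueError("no feature families enabled")
    X = np.hstack(blocks)
    return EncodedDataset(
        X=X,
        column_labels=labels,
        groups=np.full(len(record), record.id, dtype=object),
        residues=np.asarray(list(record.sequence), dtype=object),
        y=None if record.rsa is None else np.asarray(record.rsa, dtype=float),
    )


# --------------------------------------------------------------------------
# estimator-style encoder
# --------------------------------------------------------------------------

class ResidueFeatureEncoder(TransformerMixin, BaseEstimator):
    """Fit/transform interface over the windowed residue encoding.

    ``fit`` learns the training-set state: the side-chain environment
    propensity table (from labelled proteins) and the conservation min-max
    bounds.  ``transform`` encodes protein records into an
    :class:`EncodedDataset`; it needs sequence-side tracks only.
    """

    def __init__(
        self,
        half_width: int = 3,
        include: Tuple[str, ...] = ALL_FAMILIES,
        windowed_conservation: bool = True,
        sce_smoothing: float = 1.0,
    ):
        self.half_width = half_width
        self.include = include
        self.windowed_conservation = windowed_conservation
        self.sce_smoothing = sce_smoothing

    def _cfg(self) -> WindowConfig:
        return WindowConfig(
            half_width=self.half_width,
            include=tuple(self.include),
            windowed_conservation=self.windowed_conservation,
        )

    def fit(self, records: Sequence[ProteinRecord], y=None) -> "ResidueFeatureEncoder":
        cfg = self._cfg()
        self.propensity_table_ = None
        self.conservation_scaler_ = None
        if "SCE" in cfg.include:
            self.propensity_table_ = estimate_sce_propensities(
                records, smoothing=self.sce_smoothing
            )
        if "CS" in cfg.include:
            tracks = [r.pssm_info for r in records if r.pssm_info is not None]
            if not tracks:
                raise ValueError("CS enabled but no record has a PSSM info track")
            self.conservation_scaler_ = ConservationScaler().fit(tracks)
        self.n_columns_ = cfg.n_columns()
        return self

    def transform(self, records: Sequence[ProteinRecord]) -> EncodedDataset:
        if not hasattr(self, "n_columns_"):
            raise ValueError("ResidueFeatureEncoder is not fitted")
        cfg = self._cfg()
        parts = [
            encode(r, cfg, self.propensity_table_, self.conservation_scaler_)
            for r in records
        ]
        ds = EncodedDataset.concatenate(parts)
        if ds.X.shape[1] != self.n_columns_:
            raise AssertionError("encoded column count mismatch")
        return ds

    # serialization of the fitted state (used by the model bundle)

    def state_to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "propensity_table": (
                None
                if self.propensity_table_ is None
                else {
                    "index": list(self.propensity_table_.index),
                    "columns": list(self.propensity_table_.columns),
                    "values": self.propensity_table_.values.tolist(),
                }
            ),
            "conservation_bounds": (
                None
                if self.conservation_scaler_ is None
                else [self.conservation_scaler_.lo_, self.conservation_scaler_.hi_]
            ),
        }

    @classmethod
    def state_from_dict(cls, doc: dict) -> "ResidueFeatureEncoder":
        params = dict(doc["params"])
        params["include"] = tuple(params["include"])
        enc = cls(**params)
        pt = doc["propensity_table"]
        enc.propensity_table_ = (
            None
            if pt is None
            else pd.DataFrame(pt["values"], index=pt["index"], columns=pt["columns"])
        )
        cb = doc["conservation_bounds"]
        scaler = None
        if cb is not None:
            scaler = ConservationScaler()
            scaler.lo_, scaler.hi_ = float(cb[0]), float(cb[1])
        enc.conservation_scaler_ = scaler
        enc.n_columns_ = enc._cfg().n_columns()
        return enc
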