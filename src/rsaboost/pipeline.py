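"""End-to-end orchestration: manifests, cross-validation, grid search,
final training bundles and evaluation.

Cross-validation splits by protein, never by residue: windowed features of
neighbouring residues overlap, so residue-level splits would leak label
information across folds.  The side-chain-environment propensity table and
the conservation min-max bounds are training-set state and are re-estimated
inside each fold.

Model selection follows the published protocol: a grid search over the
window length L (3..17, step 2) and the number of boosting stages M
(100..1500, step 50), choosing the pair with the lowest cross-validated MAE
(ties break to smaller M, then smaller L).  Because boosting is stagewise,
all M values of the grid are evaluated from a single fit per (fold, L) by
truncating the stage list — the truncated model is identical to one trained
with that M.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .accessibility import MaxAsaTable, ROST_SANDER_1994, rsa_track_from_dssp
from .boosting import GradientBoostedRSA
from .features import (
    ALL_FAMILIES,
    EncodedDataset,
    ProteinRecord,
    ResidueFeatureEncoder,
    read_diso,
    read_fasta,
    read_polar_fraction,
    read_pssm,
    read_ss2,
)
from .metrics import (
    RealValueReport,
    TABLE_THRESHOLDS,
    per_residue_profile,
    real_value_report,
    two_state_table,
)

__all__ = [
    "ExperimentConfig",
    "CvResult",
    "ModelBundle",
    "load_manifest",
    "build_dataset",
    "fold_assignments",
    "cross_validate",
    "select_best",
    "grid_search",
    "train_final",
    "predict_protein",
    "evaluate",
    "DEFAULT_WINDOW_GRID",
    "DEFAULT_STAGE_GRID",
]

DEFAULT_WINDOW_GRID = tuple(range(3, 18, 2))        # L = 3, 5, ..., 17
DEFAULT_STAGE_GRID = tuple(range(100, 1501, 50))    # M = 100, 150, ..., 1500
_BUNDLE_VERSION = 1


@dataclass
class ExperimentConfig:
    """Grid, cross-validation and training settings for one experiment."""

    window_grid: Tuple[int, ...] = DEFAULT_WINDOW_GRID
    stage_grid: Tuple[int, ...] = DEFAULT_STAGE_GRID
    cv_folds: int = 5
    seed: int = 0
    thresholds: Tuple[float, ...] = TABLE_THRESHOLDS
    include: Tuple[str, ...] = ALL_FAMILIES
    learning_rate: float = 0.1
    loss: str = "huber"
    huber_alpha: float = 0.9
    max_depth: int = 4
    min_samples_leaf: int = 5
    selection: str = "mae"   # or "pcc"

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if any(L % 2 != 1 or L < 1 for L in self.window_grid):
            raise ValueError("window lengths must be odd and >= 1")
        if self.selection not in ("mae", "pcc"):
            raise ValueError("selection must be 'mae' or 'pcc'")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__
        unknown = set(doc) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_grid", "stage_grid", "thresholds", "include"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


# --------------------------------------------------------------------------
# manifest loading
# --------------------------------------------------------------------------

def load_manifest(
    path,
    with_labels: bool = True,
    table: MaxAsaTable = ROST_SANDER_1994,
    permissive: bool = False,
) -> List[ProteinRecord]:
    """Load all proteins of a manifest TSV into records.

    Columns: id, fasta, pssm, ss2, diso and optionally dssp (RSA labels) and
    polarF (polar-fraction sidecar).  Paths are resolved relative to the
    manifest.  Malformed proteins raise unless ``permissive`` (then they are
    skipped with a warning on stderr).
    """
    import sys

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty manifest")
    if "id" not in df.columns:
        raise ValueError(f"{path}: manifest needs an 'id' column")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate protein ids {dupes}")
    base = path.parent
    records: List[ProteinRecord] = []
    for _, row in df.iterrows():
        try:
            records.append(_load_protein(row, base, with_labels, table))
        except (ValueError, KeyError, OSError) as err:
            if not permissive:
                raise ValueError(f"protein {row['id']!r}: {err}") from err
            print(f"warning: skipping protein {row['id']!r}: {err}", file=sys.stderr)
    if not records:
        raise ValueError(f"{path}: no loadable proteins")
    return records


def _load_protein(
    row, base: Path, with_labels: bool, table: MaxAsaTable
) -> ProteinRecord:
    def p(col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return base / str(v)

    fasta_records = read_fasta(p("fasta"))
    seq = dict(fasta_records).get(str(row["id"]), fasta_records[0][1])
    pssm, info = read_pssm(p("pssm"), sequence=seq)
    ss = read_ss2(p("ss2"), sequence=seq)
    diso = read_diso(p("diso"), sequence=seq)
    rsa = None
    polar = None
    if with_labels:
        dssp_path = p("dssp")
        if dssp_path is not None:
            labels = rsa_track_from_dssp(dssp_path, sequence=seq, table=table)
            rsa = labels["rsa"].to_numpy()
        polar_path = p("polarF")
        if polar_path is not None:
            polar = read_polar_fraction(polar_path, sequence=seq)
    return ProteinRecord(
        id=str(row["id"]), sequence=seq, pssm=pssm, pssm_info=info,
        ss_probs=ss, diso_probs=diso, rsa=rsa, polar_fraction=polar,
    )


def build_dataset(
    records: Sequence[ProteinRecord],
    encoder: Optional[ResidueFeatureEncoder] = None,
    half_width: int = 3,
    include: Tuple[str, ...] = ALL_FAMILIES,
) -> Tuple[EncodedDataset, ResidueFeatureEncoder]:
    """Encode proteins into one design matrix.

    Fits a fresh encoder on ``records`` unless a fitted one is supplied
    (e.g. the training-fold encoder applied to held-out proteins).
    """
    if not records:
        raise ValueError("no proteins to encode")
    if encoder is None:
        encoder = ResidueFeatureEncoder(half_width=half_width, include=include)
        encoder.fit(records)
    return encoder.transform(records), encoder


# --------------------------------------------------------------------------
# cross-validation and grid search
# --------------------------------------------------------------------------

def fold_assignments(
    protein_ids: Sequence[str], n_folds: int, seed: int
) -> Dict[str, int]:
    """Seeded protein-level fold assignment; each protein sits in one fold."""
    ids = list(dict.fromkeys(protein_ids))
    if len(ids) < n_folds:
        raise ValueError(
            f"{len(ids)} proteins cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = {}
    for pos, idx in enumerate(order):
        folds[ids[idx]] = pos % n_folds
    return folds


@dataclass
class CvResult:
    """Cross-validation surface over (L, M) with the selected optimum."""

    surface: pd.DataFrame          # columns: L, M, mae, rmse, pcc, n
    best_L: int
    best_M: int
    selection: str = "mae"

    def best_row(self) -> pd.Series:
        m = (self.surface["L"] == self.best_L) & (self.surface["M"] == self.best_M)
        return self.surface[m].iloc[0]


def _model_for(cfg: ExperimentConfig, n_stages: int) -> GradientBoostedRSA:
    return GradientBoostedRSA(
        n_stages=n_stages,
        learning_rate=cfg.learning_rate,
        loss=cfg.loss,
        huber_alpha=cfg.huber_alpha,
        max_depth=cfg.max_depth,
        min_samples_leaf=cfg.min_samples_leaf,
    )


def cross_validate(
    records: Sequence[ProteinRecord],
    cfg: ExperimentConfig,
    half_width: int,
    stage_grid: Optional[Sequence[int]] = None,
) -> Tuple[pd.DataFrame, Dict[int, np.ndarray]]:
    """Protein-level k-fold CV at one window size.

    Trains once per fold at ``max(stage_grid)`` stages and evaluates every M
    of the grid by stage truncation (identical to training with that M).
    Returns the pooled metric table (one row per M) and, for each M, the
    pooled held-out predictions aligned with the pooled truth (stored under
    key -1).
    """
    if stage_grid is None:
        stage_grid = cfg.stage_grid
    stage_grid = sorted(set(int(m) for m in stage_grid))
    if any(r.rsa is None for r in records):
        raise ValueError("cross-validation requires RSA labels on every protein")
    folds = fold_assignments([r.id for r in records], cfg.cv_folds, cfg.seed)

    truth_parts: List[np.ndarray] = []
    pred_parts: Dict[int, List[np.ndarray]] = {m: [] for m in stage_grid}
    for k in range(cfg.cv_folds):
        train = [r for r in records if folds[r.id] != k]
        test = [r for r in records if folds[r.id] == k]
        if not test:
            continue
        train_ds, encoder = build_dataset(
            train, half_width=half_width, include=cfg.include
        )
        test_ds, _ = build_dataset(test, encoder=encoder)
        model = _model_for(cfg, max(stage_grid)).fit(train_ds.X, train_ds.y)
        truth_parts.append(test_ds.y)
        for m in stage_grid:
            pred_parts[m].append(model.predict_truncated(test_ds.X, m))

    truth = np.concatenate(truth_parts)
    preds = {m: np.concatenate(pred_parts[m]) for m in stage_grid}
    rows = []
    for m in stage_grid:
        rep = real_value_report(preds[m], truth)
        rows.append(
            {"L": 2 * half_width + 1, "M": m, "mae": rep.mae,
             "rmse": rep.rmse, "pcc": rep.pcc, "n": rep.n}
        )
    preds[-1] = truth
    return pd.DataFrame(rows), preds


def select_best(surface: pd.DataFrame, selection: str = "mae") -> Tuple[int, int]:
    """Argmin of the CV surface: lowest MAE (or highest PCC); ties break to
    smaller M, then smaller L (the cheaper model)."""
    ranked = surface.copy()
    if selection == "mae":
        ranked["score"] = ranked["mae"]
    elif selection == "pcc":
        ranked["score"] = -ranked["pcc"]
    else:
        raise ValueError("selection must be 'mae' or 'pcc'")
    ranked = ranked.sort_values(["score", "M", "L"], kind="stable")
    best = ranked.iloc[0]
    return int(best["L"]), int(best["M"])


def grid_search(records: Sequence[ProteinRecord], cfg: ExperimentConfig) -> CvResult:
    """Full (L, M) cross-validation surface and its argmin."""
    tables = []
    for L in cfg.window_grid:
        table, _ = cross_validate(records, cfg, half_width=(L - 1) // 2)
        tables.append(table)
    surface = pd.concat(tables, ignore_index=True)
    best_L, best_M = select_best(surface, cfg.selection)
    return CvResult(
        surface=surface, best_L=best_L, best_M=best_M, selection=cfg.selection,
    )


# --------------------------------------------------------------------------
# final model bundle
# --------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Everything needed to predict from sequence-side files alone:
    the boosted model, the fitted encoder (window config, SCE propensities,
    conservation bounds), the max-ASA table identity and the report
    thresholds."""

    model: GradientBoostedRSA
    encoder: ResidueFeatureEncoder
    max_asa_table: MaxAsaTable = ROST_SANDER_1994
    thresholds: Tuple[float, ...] = TABLE_THRESHOLDS

    def predict_record(self, record: ProteinRecord) -> np.ndarray:
        ds = self.encoder.transform([record])
        return self.model.predict(ds.X)

    def predict_table(self, record: ProteinRecord) -> pd.DataFrame:
        """Per-residue predictions: TSV-ready frame with a buried/exposed
        column per threshold."""
        rsa = self.predict_record(record)
        out = pd.DataFrame(
            {
                "id": record.id,
                "index": np.arange(len(record)),
                "residue": list(record.sequence),
                "rsa_pred": rsa,
            }
        )
        for t in self.thresholds:
            out[f"state@{t:g}%"] = np.where(
                rsa < t / 100.0, "buried", "exposed"
            )
        return out

    def to_dict(self) -> dict:
        return {
            "format_version": _BUNDLE_VERSION,
            "model": self.model.to_dict(),
            "encoder": self.encoder.state_to_dict(),
            "max_asa_table": {
                "name": self.max_asa_table.name,
                "values": self.max_asa_table.values,
            },
            "thresholds": list(self.thresholds),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelBundle":
        if doc.get("format_version") != _BUNDLE_VERSION:
            raise ValueError("unsupported bundle format version")
        return cls(
            model=GradientBoostedRSA.from_dict(doc["model"]),
            encoder=ResidueFeatureEncoder.state_from_dict(doc["encoder"]),
            max_asa_table=MaxAsaTable(
                doc["max_asa_table"]["name"], doc["max_asa_table"]["values"]
            ),
            thresholds=tuple(doc["thresholds"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_final(
    records: Sequence[ProteinRecord],
    L: int,
    M: int,
    cfg: ExperimentConfig,
    table: MaxAsaTable = ROST_SANDER_1994,
) -> ModelBundle:
    """Train on all labelled proteins at the chosen (L, M)."""
    ds, encoder = build_dataset(
        records, half_width=(L - 1) // 2, include=cfg.include
    )
    if ds.y is None:
        raise ValueError("training requires RSA labels")
    model = _model_for(cfg, M).fit(ds.X, ds.y)
    return ModelBundle(
        model=model, encoder=encoder, max_asa_table=table,
        thresholds=cfg.thresholds,
    )


def predict_protein(bundle: ModelBundle, record: ProteinRecord) -> pd.DataFrame:
    """Per-residue RSA prediction plus two-state labels per threshold."""
    return bundle.predict_table(record)


def evaluate(
    bundle: ModelBundle, records: Sequence[ProteinRecord]
) -> Dict[str, object]:
    """Real-valued and two-state reports of a bundle on labelled proteins."""
    labelled = [r for r in records if r.rsa is not None]
    if not labelled:
        raise ValueError("no labelled proteins to evaluate on")
    ds = bundle.encoder.transform(labelled)
    pred = bundle.model.predict(ds.X)
    return {
        "real_value": real_value_report(pred, ds.y),
        "two_state": two_state_table(pred, ds.y, bundle.thresholds),
        "per_residue": per_residue_profile(pred, ds.y, ds.residues),
        "pred": pred,
        "truth": ds.y,
    }
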