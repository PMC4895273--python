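"""Evaluation measures for real-valued and two-state accessibility prediction.

Real-valued quality is reported as mean absolute error (MAE) and root mean
square error (RMSE), both in percent RSA, and the Pearson correlation
coefficient (PCC).  Two-state (buried/exposed) quality at a percent RSA
threshold is reported as accuracy and the Matthews correlation coefficient
with exposed as the positive class; a degenerate confusion matrix (any zero
factor under the MCC square root) yields MCC = 0 by convention.

All RSA vectors are fractions in [0, 1] internally; percentages appear only
in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .accessibility import two_state_vector

__all__ = [
    "RealValueReport",
    "TwoStateReport",
    "mae",
    "rmse",
    "pcc",
    "real_value_report",
    "two_state_report",
    "two_state_table",
    "per_residue_profile",
    "TABLE_THRESHOLDS",
]

TABLE_THRESHOLDS = (5.0, 10.0, 20.0, 25.0, 30.0, 40.0, 50.0)


def _check_pair(pred, truth):
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise ValueError(
            f"length mismatch: pred has {pred.size}, truth has {truth.size}"
        )
    if pred.size == 0:
        raise ValueError("empty input")
    return pred, truth


def mae(pred, truth) -> float:
    """Mean absolute error in percent RSA."""
    pred, truth = _check_pair(pred, truth)
    return float(100.0 * np.mean(np.abs(pred - truth)))


def rmse(pred, truth) -> float:
    """Root mean square error in percent RSA."""
    pred, truth = _check_pair(pred, truth)
    return float(100.0 * np.sqrt(np.mean((pred - truth) ** 2)))


def pcc(pred, truth) -> float:
    """Pearson correlation coefficient between predicted and true RSA."""
    pred, truth = _check_pair(pred, truth)
    if pred.size < 2:
        raise ValueError("PCC needs at least two residues")
    dp = pred - pred.mean()
    dt = truth - truth.mean()
    denom = np.sqrt(np.sum(dp * dp) * np.sum(dt * dt))
    if denom == 0.0:
        raise ValueError("PCC undefined: an input has zero variance")
    return float(np.sum(dp * dt) / denom)


@dataclass(frozen=True)
class RealValueReport:
    mae: float      # percent
    rmse: float     # percent
    pcc: float
    n: int

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)


def real_value_report(pred, truth) -> RealValueReport:
    pred, truth = _check_pair(pred, truth)
    return RealValueReport(
        mae=mae(pred, truth), rmse=rmse(pred, truth), pcc=pcc(pred, truth),
        n=int(pred.size),
    )


@dataclass(frozen=True)
class TwoStateReport:
    threshold: float  # percent
    acc: float        # percent
    mcc: float
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)


def two_state_report(pred_rsa, truth_rsa, threshold: float) -> TwoStateReport:
    """Buried/exposed classification metrics at a percent RSA threshold.

    Both vectors are thresholded with the same rule (buried iff RSA <
    threshold); exposed is the positive class.
    """
    pred_rsa, truth_rsa = _check_pair(pred_rsa, truth_rsa)
    pe = two_state_vector(pred_rsa, threshold)
    te = two_state_vector(truth_rsa, threshold)
    tp = int(np.sum(pe & te))
    tn = int(np.sum(~pe & ~te))
    fp = int(np.sum(pe & ~te))
    fn = int(np.sum(~pe & te))
    n = tp + tn + fp + fn
    acc = 100.0 * (tp + tn) / n
    denom2 = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom2 == 0.0 else (tp * tn - fp * fn) / np.sqrt(denom2)
    return TwoStateReport(
        threshold=float(threshold), acc=acc, mcc=float(mcc),
        tp=tp, tn=tn, fp=fp, fn=fn,
    )


def two_state_table(
    pred_rsa, truth_rsa, thresholds: Sequence[float] = TABLE_THRESHOLDS
) -> pd.DataFrame:
    """Per-threshold ACC/MCC table over the standard threshold grid."""
    rows = [two_state_report(pred_rsa, truth_rsa, t).to_dict() for t in thresholds]
    return pd.DataFrame(rows)


def per_residue_profile(pred, truth, residue_types) -> pd.DataFrame:
    """Per-amino-acid-type error profile.

    Returns one row per residue type present in the data: true and predicted
    mean RSA (percent), MAE and RMSE (percent), and the residue count.
    """
    pred, truth = _check_pair(pred, truth)
    residue_types = np.asarray(residue_types, dtype=object).ravel()
    if residue_types.shape != pred.shape:
        raise ValueError("residue_types length mismatch")
    rows = []
    for aa in sorted(set(residue_types.tolist())):
        m = residue_types == aa
        rows.append(
            {
                "residue": aa,
                "true_mean_rsa": float(100.0 * truth[m].mean()),
                "pred_mean_rsa": float(100.0 * pred[m].mean()),
                "mae": mae(pred[m], truth[m]),
                "rmse": rmse(pred[m], truth[m]),
                "count": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)
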