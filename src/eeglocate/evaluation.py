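"""Validation metrics: position error, 10 mm TP/FP split, PPV, labeling.

Each prediction's position error (PE) is its Euclidean distance to the
*nearest* ground-truth electrode, irrespective of labels. A prediction
with PE above the threshold — 10 mm by default, the diameter of an
electrode cup — is a false positive; all others are true positives, so
two detections near the same electrode both count as good. A
ground-truth electrode that is nobody's nearest match among the true
positives is a miss (false negative); when both sets hold exactly 65
points this makes the FP and FN counts equal. PE statistics (mean, population
std, max) are computed over true positives only, and labeling errors are
counted among true positives whose label differs from that of their
nearest ground-truth electrode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["Metrics", "evaluate"]

DEFAULT_THRESHOLD_MM = 10.0


@dataclass
class Metrics:
    per_detection_error: np.ndarray  # (n_predictions,) mm
    mean_pe: float  # over TP, mm (nan if no TP)
    std_pe: float
    max_pe: float
    n_tp: int
    n_fp: int
    n_fn: int
    ppv: float  # percent
    n_label_errors: int  # among TP

    def to_dict(self) -> dict:
        return {
            "mean_pe_mm": self.mean_pe,
            "std_pe_mm": self.std_pe,
            "max_pe_mm": self.max_pe,
            "n_tp": self.n_tp,
            "n_fp": self.n_fp,
            "n_fn": self.n_fn,
            "ppv_percent": self.ppv,
            "n_label_errors": self.n_label_errors,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_tsv(self, path) -> None:
        """One-row table with the headline columns."""
        pd.DataFrame(
            [
                {
                    "Mean PE (mm)": self.mean_pe,
                    "Std PE (mm)": self.std_pe,
                    "Max PE (mm)": self.max_pe,
                    "FP": self.n_fp,
                    "TP": self.n_tp,
                    "PPV (%)": self.ppv,
                }
            ]
        ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def evaluate(
    predictions,
    ground_truth,
    threshold: float = DEFAULT_THRESHOLD_MM,
) -> Metrics:
    """Compare labeled predictions against a labeled ground truth.

    Both arguments need ``labels`` and ``points`` attributes (any of the
    labeled point containers in this package qualifies).

    Raises
    ------
    ValueError
        If either set is empty or the threshold is not positive.
    """
    pred_pts = np.asarray(predictions.points, dtype=float).reshape(-1, 3)
    gt_pts = np.asarray(ground_truth.points, dtype=float).reshape(-1, 3)
    pred_labels = list(predictions.labels)
    gt_labels = list(ground_truth.labels)
    if len(pred_pts) == 0 or len(gt_pts) == 0:
        raise ValueError("prediction and ground-truth sets must be non-empty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    errors, nearest = cKDTree(gt_pts).query(pred_pts, k=1)
    tp_mask = errors <= threshold
    n_tp = int(np.sum(tp_mask))
    n_fp = len(pred_pts) - n_tp
    covered = set(np.asarray(nearest)[tp_mask].tolist())
    n_fn = len(gt_pts) - len(covered)

    if n_tp:
        tp_err = errors[tp_mask]
        mean_pe = float(np.mean(tp_err))
        std_pe = float(np.std(tp_err))  # population (n divisor)
        max_pe = float(np.max(tp_err))
        n_label_errors = int(
            sum(
                pred_labels[i] != gt_labels[int(nearest[i])]
                for i in np.flatnonzero(tp_mask)
            )
        )
    else:
        mean_pe = std_pe = max_pe = float("nan")
        n_label_errors = 0

    ppv = 100.0 * n_tp / (n_tp + n_fp)
    return Metrics(
        per_detection_error=np.asarray(errors, dtype=float),
        mean_pe=mean_pe,
        std_pe=std_pe,
        max_pe=max_pe,
        n_tp=n_tp,
        n_fp=n_fp,
        n_fn=n_fn,
        ppv=ppv,
        n_label_errors=n_label_errors,
    )
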