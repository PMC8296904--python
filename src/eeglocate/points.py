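"""Labeled electrode point sets and their TSV serialization.

A :class:`LabeledPoints` is the common currency between modules: ground
truths, caps, templates and final outputs are all named 3-D positions in
millimetres. The on-disk form is a TSV with header ``label\tx\ty\tz``
(coordinates written with 4 decimal places), optionally extended with
extra per-point columns (``n_voxels``, ``provenance``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledPoints", "read_points_tsv", "write_points_tsv"]


@dataclass
class LabeledPoints:
    """Ordered named points in world millimetres."""

    labels: list[str]
    points: np.ndarray  # (n, 3) float

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.points = np.asarray(self.points, dtype=float).reshape(len(self.labels), 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels are not unique")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels) -> "LabeledPoints":
        idx = [self.index_of(l) for l in labels]
        return LabeledPoints([self.labels[i] for i in idx], self.points[idx])

    def with_points(self, points: np.ndarray) -> "LabeledPoints":
        return LabeledPoints(list(self.labels), points)

    def to_tsv(self, path) -> None:
        write_points_tsv(path, self.labels, self.points)

    @classmethod
    def from_tsv(cls, path) -> "LabeledPoints":
        labels, points, _ = read_points_tsv(path)
        return cls(labels, points)


def write_points_tsv(path, labels, points, extra: dict | None = None) -> None:
    """Write ``label\tx\ty\tz[\t...]`` with mm coordinates at 4 dp."""
    points = np.asarray(points, dtype=float)
    df = pd.DataFrame({"label": list(labels)})
    for j, axis in enumerate("xyz"):
        df[axis] = points[:, j] if len(points) else np.empty(0)
    for key, values in (extra or {}).items():
        df[key] = list(values)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_points_tsv(path):
    """Return ``(labels, points, extras)`` from a points TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    for col in ("label", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    labels = df["label"].tolist()
    points = df[["x", "y", "z"]].to_numpy(dtype=float)
    extras = {
        c: df[c].to_numpy() for c in df.columns if c not in ("label", "x", "y", "z")
    }
    return labels, points, extras
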