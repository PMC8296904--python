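"""The average EEG-cap template and the canonical 65-label montage.

The refinement stage labels electrodes by registering an average cap — a
65-point labeled cloud in a centered canonical frame — onto the subject's
detections. The template is built from several labeled ground-truth
clouds (one per subject, to absorb head-shape variability) by label-wise
generalized Procrustes analysis with similarity transforms: because the
clouds share the label set, correspondence is known and each alignment is
a closed-form paired fit; the consensus mean is iterated to convergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .points import LabeledPoints, read_points_tsv, write_points_tsv
from .registration import fit_similarity

__all__ = [
    "Template",
    "standard_label_set",
    "build_template",
    "N_ELECTRODES",
]

#: The cap carries 64 recording channels plus the AFz ground electrode.
N_ELECTRODES = 65

# Canonical montage, row by row from the forehead backwards. 64 channels
# of an extended 10-20 (10-10 subset) layout plus the AFz ground: nine
# midline sites, the 10% circumference ring, the inferior temporal pairs
# (FT9/FT10, TP9/TP10) and the interior rows.
_STANDARD_LABELS: tuple[str, ...] = (
    # prefrontal / anterior-frontal
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    # frontal
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    # fronto-central / fronto-temporal
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    # central / temporal
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    # centro-parietal / temporo-parietal
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    # parietal
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    # parieto-occipital / occipital
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)
assert len(_STANDARD_LABELS) == N_ELECTRODES
assert len(set(_STANDARD_LABELS)) == N_ELECTRODES


def standard_label_set() -> list[str]:
    """The 65 canonical electrode names (64 channels plus ground AFz)."""
    return list(_STANDARD_LABELS)


@dataclass
class Template:
    """Average cap: one point per canonical label, centroid at the origin."""

    labels: list[str]
    points: np.ndarray  # (65, 3) mm, centered

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.points = np.asarray(self.points, dtype=float).reshape(
            len(self.labels), 3
        )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("template labels are not unique")
        if np.linalg.norm(self.points.mean(axis=0)) > 1e-6:
            raise ValueError("template points are not centered at the origin")

    def __len__(self) -> int:
        return len(self.labels)

    def as_labeled_points(self) -> LabeledPoints:
        return LabeledPoints(list(self.labels), self.points.copy())

    def to_tsv(self, path) -> None:
        """Write the TSV plus a JSON sidecar describing the frame."""
        path = Path(path)
        write_points_tsv(path, self.labels, self.points)
        sidecar = {
            "n_electrodes": len(self.labels),
            "units": "mm",
            "frame": "centered",
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path) -> "Template":
        labels, points, _ = read_points_tsv(path)
        return cls(labels, points - points.mean(axis=0))


def build_template(
    clouds: Sequence[LabeledPoints],
    labels: Sequence[str] | None = None,
    max_iterations: int = 200,
    tolerance: float = 1e-6,
) -> Template:
    """Average several labeled clouds into a template.

    Every cloud must carry the full label set. Clouds are mutually aligned
    by generalized Procrustes analysis with similarity transforms, using
    the labels as the (known) correspondence: the first cloud, centered,
    seeds the consensus; each round aligns every cloud onto the current
    mean with a closed-form paired fit and recomputes the re-centered
    mean, until the mean point position moves by less than ``tolerance``
    mm. Returns the per-label average in the centered canonical frame.

    Raises
    ------
    ValueError
        For fewer than 2 clouds or a cloud missing any required label.
    """
    if len(clouds) < 2:
        raise ValueError(f"need at least 2 clouds to average, got {len(clouds)}")
    if labels is None:
        labels = list(clouds[0].labels)
    labels = list(labels)
    stacks = []
    for i, cloud in enumerate(clouds):
        missing = set(labels) - set(cloud.labels)
        if missing:
            raise ValueError(f"cloud {i} is missing labels: {sorted(missing)}")
        stacks.append(cloud.subset(labels).points)
    arr = np.stack(stacks)  # (n_clouds, n_labels, 3)

    mean = arr[0] - arr[0].mean(axis=0)
    for _ in range(max_iterations):
        aligned = np.stack(
            [fit_similarity(cloud, mean).apply(cloud) for cloud in arr]
        )
        new_mean = aligned.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tolerance:
            break
    return Template(labels, mean)
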