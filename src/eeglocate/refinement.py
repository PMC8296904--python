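"""Template-based refinement: prune, re-register, impute, label.

The network front end delivers ``n`` candidate positions where ``n`` is
not necessarily 65. This stage enforces the cap's geometry and produces
exactly one labeled position per electrode:

1. a first ICP registers the average cap template into detection space;
2. pruning keeps at most one detection per template point (each
   detection is matched to its nearest aligned template point, then
   within each template bucket only the closest detection survives);
3. a second registration is estimated from the surviving pairs — by
   default a closed-form paired fit, since pruning fixed the
   correspondence; a full nearest-neighbour ICP is available instead;
4. every template point left without a detection is imputed at its
   re-registered position.

Final labels come exclusively from the template association; whatever
provisional labels the detections carried are ignored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .points import read_points_tsv, write_points_tsv
from .registration import (
    ICPParams,
    ICPResult,
    SimilarityTransform,
    fit_similarity,
    icp,
)
from .template import Template
from .volume_detect import DetectionCloud

__all__ = [
    "LabeledElectrodeSet",
    "RefinementReport",
    "prune_detections",
    "refine",
]

MEASURED = "measured"
IMPUTED = "imputed"


@dataclass
class LabeledElectrodeSet:
    """Exactly one position per template label, in detection space.

    ``provenance[i]`` is ``"measured"`` if ``points[i]`` is one of the
    input detections and ``"imputed"`` if it was filled in from the
    registered template.
    """

    labels: list[str]
    points: np.ndarray  # (65, 3) mm
    provenance: list[str]

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.points = np.asarray(self.points, dtype=float).reshape(
            len(self.labels), 3
        )
        self.provenance = [str(p) for p in self.provenance]
        if len(self.provenance) != len(self.labels):
            raise ValueError("provenance and labels lengths differ")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels are not unique")
        bad = set(self.provenance) - {MEASURED, IMPUTED}
        if bad:
            raise ValueError(f"unknown provenance values: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def measured_mask(self) -> np.ndarray:
        return np.array([p == MEASURED for p in self.provenance])

    def to_tsv(self, path) -> None:
        write_points_tsv(
            path, self.labels, self.points, extra={"provenance": self.provenance}
        )

    @classmethod
    def from_tsv(cls, path) -> "LabeledElectrodeSet":
        labels, points, extras = read_points_tsv(path)
        prov = extras.get("provenance")
        if prov is None:
            prov = [MEASURED] * len(labels)
        return cls(labels, points, [str(p) for p in prov])


@dataclass
class RefinementReport:
    n_input_detections: int
    n_kept: int
    n_imputed: int
    icp_first: ICPResult
    icp_second: ICPResult
    discarded: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_detections": self.n_input_detections,
            "n_kept": self.n_kept,
            "n_imputed": self.n_imputed,
            "discarded": list(map(int, self.discarded)),
            "icp_first": {
                "transform": self.icp_first.transform.to_dict(),
                "rms_residual": self.icp_first.rms_residual,
                "iterations_used": self.icp_first.iterations_used,
            },
            "icp_second": {
                "transform": self.icp_second.transform.to_dict(),
                "rms_residual": self.icp_second.rms_residual,
                "iterations_used": self.icp_second.iterations_used,
            },
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def prune_detections(
    detections: np.ndarray,
    aligned_template: np.ndarray,
    distance_gate: float | None = None,
) -> list[int | None]:
    """Keep at most one detection per template point.

    Two-pass rule: (1) each detection is associated with its nearest
    template point; (2) within each template bucket only the closest
    detection is kept. Returns, per template point, the index of the kept
    detection or ``None``. With ``distance_gate`` set, a surviving pair
    farther apart than the gate (mm) is also rejected; the gate is off by
    default. Deterministic: nearest-neighbour ties resolve to the lowest
    template index and equidistant detections to the lowest detection
    index.
    """
    det = np.asarray(detections, dtype=float).reshape(-1, 3)
    tpl = np.asarray(aligned_template, dtype=float).reshape(-1, 3)
    if len(det) == 0:
        raise ValueError("no detections to prune")
    dists, nearest_tpl = cKDTree(tpl).query(det, k=1)
    kept: list[int | None] = [None] * len(tpl)
    best = np.full(len(tpl), np.inf)
    for di in range(len(det)):
        ti = int(nearest_tpl[di])
        if dists[di] < best[ti]:
            best[ti] = dists[di]
            kept[ti] = di
    if distance_gate is not None:
        kept = [
            di if di is not None and best[ti] <= distance_gate else None
            for ti, di in enumerate(kept)
        ]
    return kept


def refine(
    detections: DetectionCloud | np.ndarray,
    template: Template,
    params: ICPParams | None = None,
    second_icp: str = "paired",
    distance_gate: float | None = None,
) -> tuple[LabeledElectrodeSet, RefinementReport]:
    """Turn ``n`` detections into exactly 65 labeled electrode positions.

    The template is the moving set throughout, so imputed points land
    directly in subject (detection) space. ``second_icp`` selects how the
    post-pruning registration is estimated: ``"paired"`` (default) uses
    the pruning correspondence in one closed-form fit; ``"full"`` re-runs
    nearest-neighbour ICP between the template and the kept detections.

    Returns the labeled set and a report with counts, both transforms and
    the indices of discarded detections.
    """
    if params is None:
        params = ICPParams()
    if second_icp not in ("paired", "full"):
        raise ValueError(f"second_icp must be 'paired' or 'full', got {second_icp!r}")
    det_pts = (
        detections.points
        if isinstance(detections, DetectionCloud)
        else np.asarray(detections, dtype=float).reshape(-1, 3)
    )
    if len(det_pts) < 3:
        raise ValueError(f"need at least 3 detections, got {len(det_pts)}")
    if len(det_pts) < 20:
        warnings.warn(
            f"only {len(det_pts)} detections; refinement may be unreliable",
            stacklevel=2,
        )
    tpl_pts = template.points

    # Stage 1: register template onto detections, then prune.
    first = icp(tpl_pts, det_pts, params)
    aligned = first.transform.apply(tpl_pts)
    kept = prune_detections(det_pts, aligned, distance_gate=distance_gate)
    kept_tpl = [ti for ti, di in enumerate(kept) if di is not None]
    kept_det = [kept[ti] for ti in kept_tpl]

    # Stage 2: re-estimate the registration from the surviving pairs.
    if second_icp == "paired":
        transform2 = fit_similarity(tpl_pts[kept_tpl], det_pts[kept_det])
        resid = transform2.apply(tpl_pts[kept_tpl]) - det_pts[kept_det]
        second = ICPResult(
            transform=transform2,
            rms_residual=float(np.sqrt(np.mean(np.sum(resid * resid, axis=1)))),
            iterations_used=1,
            correspondence=np.full(len(tpl_pts), -1, dtype=int),
            residual_history=[],
        )
        second.correspondence[kept_tpl] = kept_det
    else:
        second = icp(
            tpl_pts,
            det_pts[kept_det],
            ICPParams(
                max_iterations=params.max_iterations,
                tolerance=params.tolerance,
                initialization="given",
                initial_transform=first.transform,
            ),
        )

    # Assemble: measured where a detection survived, imputed elsewhere.
    imputed_pts = second.transform.apply(tpl_pts)
    out_points = np.empty_like(tpl_pts)
    provenance: list[str] = []
    for ti in range(len(tpl_pts)):
        di = kept[ti]
        if di is None:
            out_points[ti] = imputed_pts[ti]
            provenance.append(IMPUTED)
        else:
            out_points[ti] = det_pts[di]
            provenance.append(MEASURED)

    result = LabeledElectrodeSet(list(template.labels), out_points, provenance)
    discarded = sorted(set(range(len(det_pts))) - set(kept_det))
    report = RefinementReport(
        n_input_detections=len(det_pts),
        n_kept=len(kept_det),
        n_imputed=len(tpl_pts) - len(kept_det),
        icp_first=first,
        icp_second=second,
        discarded=discarded,
    )
    return result, report
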