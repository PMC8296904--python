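"""Similarity-transform point-set registration.

Provides the closed-form least-squares similarity fit between *paired*
point sets (Umeyama's method: SVD of the cross-covariance with a
determinant sign correction and a variance-ratio scale) and the iterative
closest point (ICP) loop between *unpaired* sets, which alternates
nearest-neighbour correspondence with the closed-form fit.

Conventions
-----------
* Points are ``(n, 3)`` float arrays in millimetres.
* A :class:`SimilarityTransform` maps a point ``p`` to ``s * R @ p + t``
  with a single isotropic scale ``s > 0``, a proper rotation ``R``
  (``det R = +1``; reflections are never returned) and a translation ``t``.
* In :func:`icp` the *moving* set is mapped onto the *fixed* set; the
  returned transform takes moving-space coordinates into fixed space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SimilarityTransform",
    "ICPParams",
    "ICPResult",
    "DegenerateGeometryError",
    "fit_similarity",
    "apply_transform",
    "icp",
]

#: Scales outside this interval trigger a warning: EEG head sizes vary by
#: far less, so an extreme scale usually signals a mis-registration.
SCALE_WARN_RANGE = (0.5, 2.0)

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a point set is too degenerate to define a transform."""


@dataclass(frozen=True)
class SimilarityTransform:
    """Isotropic scale + proper rotation + translation (7 parameters)."""

    scale: float
    rotation: np.ndarray  # (3, 3), orthogonal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        s = 1.0 / self.scale
        R = self.rotation.T
        return SimilarityTransform(s, R, -s * R @ self.translation)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` first."""
        return SimilarityTransform(
            self.scale * other.scale,
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
        )

    def to_dict(self) -> dict:
        return {
            "scale": float(self.scale),
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            float(d["scale"]),
            np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            np.asarray(d["translation"], dtype=float),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimilarityTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ICPParams:
    """Knobs of the ICP loop.

    ``tolerance`` is the absolute change (mm) in RMS residual between
    successive iterations below which the loop stops. With
    ``multi_start`` enabled (the default, effective only for the
    ``centroid_and_scale`` policy), the loop is additionally restarted
    from a small fixed grid of coarse rotations and the run with the
    lowest final residual wins: plain ICP is a local optimizer and can
    lock into a neighbour-shifted correspondence once the initial
    misalignment exceeds about half the inter-electrode spacing.
    """

    max_iterations: int = 100
    tolerance: float = 1e-6
    initialization: Literal["centroid_and_scale", "identity", "given"] = (
        "centroid_and_scale"
    )
    initial_transform: SimilarityTransform | None = None
    multi_start: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.initialization == "given" and self.initial_transform is None:
            raise ValueError("initialization='given' requires initial_transform")


@dataclass
class ICPResult:
    transform: SimilarityTransform
    rms_residual: float
    iterations_used: int
    correspondence: np.ndarray  # per-moving-point index into fixed
    residual_history: list[float] = field(default_factory=list)


def _as_points(x, name: str) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{name} must have shape (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return pts


def fit_similarity(source: np.ndarray, target: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``source`` onto ``target``.

    Minimizes ``sum_i || s R source_i + t - target_i ||^2`` over scale,
    proper rotation and translation, in closed form. ``source`` and
    ``target`` are paired: row i of one corresponds to row i of the other.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 pairs or a (near-)collinear source set, where the
        rotation is not identifiable.
    """
    src = _as_points(source, "source")
    tgt = _as_points(target, "target")
    if src.shape != tgt.shape:
        raise ValueError("source and target must have equal shapes")
    n = src.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 point pairs, got {n}")

    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    ds = src - mu_s
    dt = tgt - mu_t
    var_s = float(np.sum(ds * ds)) / n
    if var_s <= 0:
        raise DegenerateGeometryError("source points are coincident")

    cov = dt.T @ ds / n
    U, D, Vt = np.linalg.svd(cov)
    # Collinear sources leave the rotation about the line unconstrained.
    if D[1] <= max(D[0], 1.0) * 1e-12:
        raise DegenerateGeometryError("source points are (near-)collinear")
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    scale = float(np.trace(np.diag(D) @ S)) / var_s
    if scale <= 0:
        raise DegenerateGeometryError("degenerate geometry yields non-positive scale")
    if not (SCALE_WARN_RANGE[0] <= scale <= SCALE_WARN_RANGE[1]):
        warnings.warn(
            f"fitted scale {scale:.3f} outside plausible range {SCALE_WARN_RANGE}",
            stacklevel=2,
        )
    t = mu_t - scale * R @ mu_s
    return SimilarityTransform(scale, R, t)


def apply_transform(transform: SimilarityTransform, points) -> np.ndarray:
    """Map each point through ``s R p + t``; order and cardinality kept."""
    return transform.apply(_as_points(points, "points"))


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _multi_start_rotations() -> list[np.ndarray]:
    """Identity plus coarse rotations about 7 well-spread axes."""
    axes = [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1),
    ]
    rots = [np.eye(3)]
    for axis in axes:
        for angle in (15.0, -15.0, 30.0, -30.0):
            rots.append(_rotation_about_axis(np.asarray(axis, float), angle))
    return rots


def _initial_transforms(
    moving: np.ndarray, fixed: np.ndarray, params: ICPParams
) -> list[SimilarityTransform]:
    if params.initialization == "identity":
        return [SimilarityTransform.identity()]
    if params.initialization == "given":
        assert params.initial_transform is not None
        return [params.initial_transform]
    # centroid_and_scale: superpose centroids, match RMS radii.
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    r_m = np.sqrt(np.mean(np.sum((moving - mu_m) ** 2, axis=1)))
    r_f = np.sqrt(np.mean(np.sum((fixed - mu_f) ** 2, axis=1)))
    s = r_f / r_m if r_m > 0 and r_f > 0 else 1.0
    rotations = _multi_start_rotations() if params.multi_start else [np.eye(3)]
    return [
        SimilarityTransform(s, R, mu_f - s * R @ mu_m) for R in rotations
    ]


def icp(moving, fixed, params: ICPParams | None = None) -> ICPResult:
    """Iterative closest point with a similarity transform.

    Alternates (1) matching every transformed moving point to its nearest
    fixed point and (2) re-fitting the full moving→fixed similarity on
    those pairs, until the RMS nearest-neighbour residual changes by less
    than ``params.tolerance`` or ``params.max_iterations`` is reached.
    The residual sequence is non-increasing by construction (each refit is
    a global optimum for the current matches). Nearest-neighbour ties are
    broken toward the lowest fixed-point index, so the result is
    deterministic for fixed inputs.
    """
    if params is None:
        params = ICPParams()
    mov = _as_points(moving, "moving")
    fix = _as_points(fixed, "fixed")
    if fix.shape[0] < 1:
        raise ValueError("fixed set is empty")
    if mov.shape[0] < 3:
        raise DegenerateGeometryError("moving set needs at least 3 points")

    tree = cKDTree(fix)
    best: tuple[float, SimilarityTransform, list[float], int] | None = None
    with warnings.catch_warnings():
        # Intermediate fits may briefly leave the plausible scale band.
        warnings.simplefilter("ignore")
        for init in _initial_transforms(mov, fix, params):
            transform = init
            history: list[float] = []
            prev = np.inf
            iterations = 0
            for iterations in range(1, params.max_iterations + 1):
                dists, corr = tree.query(transform.apply(mov), k=1)
                transform = fit_similarity(mov, fix[corr])
                resid = transform.apply(mov) - fix[corr]
                rms = float(np.sqrt(np.mean(np.sum(resid * resid, axis=1))))
                history.append(rms)
                if abs(prev - rms) < params.tolerance:
                    break
                prev = rms
            final = float(
                np.sqrt(np.mean(tree.query(transform.apply(mov), k=1)[0] ** 2))
            )
            if best is None or final < best[0]:
                best = (final, transform, history, iterations)
    assert best is not None
    rms_final, transform, history, iterations = best
    # Final correspondence under the winning transform.
    _, corr = tree.query(transform.apply(mov), k=1)
    if not (SCALE_WARN_RANGE[0] <= transform.scale <= SCALE_WARN_RANGE[1]):
        warnings.warn(
            f"ICP converged to scale {transform.scale:.3f} outside "
            f"plausible range {SCALE_WARN_RANGE}",
            stacklevel=2,
        )
    return ICPResult(
        transform=transform,
        rms_residual=float(rms_final),
        iterations_used=iterations,
        correspondence=np.asarray(corr, dtype=int),
        residual_history=list(history),
    )
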