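"""Synthetic caps, noisy detection clouds, and painted label volumes.

Stands in for the MR acquisition and network front end: what the rest of
the pipeline consumes is (a) a labeled electrode cloud per subject and
(b) a labeled volume of ~10 mm spheres on a ~0.94 mm grid. This module
generates both with the statistical structure the method assumes:

* a 65-electrode cap (64 channels + AFz ground) laid out by the classic
  proportional-arc construction of the extended 10-20 system on a
  scalp-like ellipsoid, with per-subject placement jitter;
* detection noise — an unknown subject pose (similarity transform),
  isotropic position jitter, dropped electrodes, spurious off-scalp
  blobs, and optionally scrambled provisional labels;
* a painter that rasterizes each electrode as a digital sphere with its
  own integer label, emulating the segmentation maps.

All randomness is seed-derived with one substream per noise source, so
every realization is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .points import LabeledPoints
from .registration import SimilarityTransform
from .template import Template, build_template, standard_label_set
from .volume_detect import DetectionCloud, LabeledVolume

__all__ = [
    "CapModel",
    "PerturbationSpec",
    "PerturbationTruth",
    "generate_cap",
    "perturb_cloud",
    "paint_volume",
    "training_template",
    "write_fixture_set",
]

#: Default scalp semi-axes (mm): lateral, anterior-posterior, vertical.
DEFAULT_HEAD_RADII = (90.0, 110.0, 95.0)

#: Electrode cups are 10 mm in diameter; ground truths are 5 mm-radius spheres.
DEFAULT_SPHERE_RADIUS_MM = 5.0

#: Emulated voxel spacing of the MR volumes (mm, isotropic).
DEFAULT_SPACING_MM = 0.9375

#: Inclination (degrees from vertex) of the 10% circumference ring.
_RING_INCL = 72.0

# Proportional-arc layout: each row has a midline site at the given
# inclination (degrees from the vertex, positive toward the forehead), a
# lateral endpoint on the circumference ring at the given azimuth, and
# interior sites at fractions of the midline→ring arc. Odd numbers are
# left hemisphere, even right.
_MIDLINE = (
    ("Fpz", 72.0), ("AFz", 54.0), ("Fz", 36.0), ("FCz", 18.0), ("Cz", 0.0),
    ("CPz", -18.0), ("Pz", -36.0), ("POz", -54.0), ("Oz", -72.0),
)
_ROWS = (
    # midline incl, ring azimuth, ring pair, interior (left, right, fraction)
    (72.0, 18.0, ("Fp1", "Fp2"), ()),
    (54.0, 36.0, ("AF7", "AF8"), (("AF3", "AF4", 0.5),)),
    (36.0, 54.0, ("F7", "F8"),
     (("F5", "F6", 0.75), ("F3", "F4", 0.5), ("F1", "F2", 0.25))),
    (18.0, 72.0, ("FT7", "FT8"),
     (("FC5", "FC6", 0.75), ("FC3", "FC4", 0.5), ("FC1", "FC2", 0.25))),
    (0.0, 90.0, ("T7", "T8"),
     (("C5", "C6", 0.75), ("C3", "C4", 0.5), ("C1", "C2", 0.25))),
    (-18.0, 108.0, ("TP7", "TP8"),
     (("CP5", "CP6", 0.75), ("CP3", "CP4", 0.5), ("CP1", "CP2", 0.25))),
    (-36.0, 126.0, ("P7", "P8"),
     (("P5", "P6", 0.75), ("P3", "P4", 0.5), ("P1", "P2", 0.25))),
    (-54.0, 144.0, ("PO7", "PO8"), (("PO3", "PO4", 0.5),)),
    (-72.0, 162.0, ("O1", "O2"), ()),
)
# Inferior temporal chain, one ring-step below the circumference.
_INFERIOR = (("FT9", "FT10", 72.0), ("TP9", "TP10", 108.0))


def _midline_dir(incl_deg: float) -> np.ndarray:
    a = np.deg2rad(incl_deg)
    return np.array([0.0, np.sin(a), np.cos(a)])


def _ring_dir(azimuth_deg: float, side: int, incl_deg: float = _RING_INCL):
    """Unit direction on the ring; side -1 = left, +1 = right."""
    i = np.deg2rad(incl_deg)
    phi = np.deg2rad(azimuth_deg)
    return np.array([side * np.sin(i) * np.sin(phi), np.sin(i) * np.cos(phi),
                     np.cos(i)])


def _slerp(a: np.ndarray, b: np.ndarray, f: float) -> np.ndarray:
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - f) * omega) * a + np.sin(f * omega) * b) / np.sin(omega)


def _layout_directions() -> dict[str, np.ndarray]:
    dirs: dict[str, np.ndarray] = {}
    for name, incl in _MIDLINE:
        dirs[name] = _midline_dir(incl)
    for incl, azim, (left, right), interior in _ROWS:
        mid = _midline_dir(incl)
        for side, name in ((-1, left), (1, right)):
            ring = _ring_dir(azim, side)
            dirs[name] = ring
            for lname, rname, frac in interior:
                dirs[lname if side < 0 else rname] = _slerp(mid, ring, frac)
    for left, right, azim in _INFERIOR:
        dirs[left] = _ring_dir(azim, -1, incl_deg=90.0)
        dirs[right] = _ring_dir(azim, 1, incl_deg=90.0)
    return dirs


def _project_to_ellipsoid(directions: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Scale each direction so the point satisfies the ellipsoid equation."""
    scale = 1.0 / np.sqrt(np.sum((directions / radii) ** 2, axis=-1))
    return directions * scale[..., None]


@dataclass
class CapModel:
    """Scalp ellipsoid plus the canonical electrode layout on it."""

    head_radii: tuple[float, float, float] = DEFAULT_HEAD_RADII
    labels: list[str] = field(default_factory=standard_label_set)

    def __post_init__(self) -> None:
        self.head_radii = tuple(float(r) for r in self.head_radii)
        if any(r <= 0 for r in self.head_radii):
            raise ValueError(f"head radii must be positive, got {self.head_radii}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("cap labels are not unique")
        dirs = _layout_directions()
        missing = set(self.labels) - set(dirs)
        if missing:
            raise ValueError(f"no layout direction for labels: {sorted(missing)}")
        self.layout = np.stack([dirs[l] for l in self.labels])

    def nominal_points(self) -> np.ndarray:
        """Noise-free electrode positions on the ellipsoid (mm)."""
        return _project_to_ellipsoid(self.layout, np.asarray(self.head_radii))


def generate_cap(
    model: CapModel | None = None,
    seed: int = 0,
    placement_sigma: float = 1.5,
) -> LabeledPoints:
    """One subject's cap: the canonical layout with placement jitter.

    ``placement_sigma`` (mm) is the tangential scatter of each electrode
    around its nominal site, emulating cap-positioning variability
    between subjects; points remain exactly on the scalp ellipsoid.
    Deterministic: the same seed reproduces the same cap.
    """
    if model is None:
        model = CapModel()
    radii = np.asarray(model.head_radii)
    nominal = model.nominal_points()
    rng = np.random.default_rng([int(seed), 0xCA9])
    # Angular jitter sized so the surface displacement is ~placement_sigma.
    radial = np.linalg.norm(nominal, axis=1, keepdims=True)
    dirs = model.layout + rng.normal(0.0, placement_sigma, (len(nominal), 3)) / radial
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return LabeledPoints(list(model.labels), _project_to_ellipsoid(dirs, radii))


@dataclass
class PerturbationSpec:
    """Noise model applied to a cap to emulate network detections.

    Defaults correspond to a mildly adversarial acquisition: an unknown
    pose up to 20 degrees / 20 mm with a few percent of head-size scale,
    millimetre-level detection jitter, one missed electrode and one
    spurious blob.
    """

    max_rotation_deg: float = 20.0
    scale_range: tuple[float, float] = (0.95, 1.05)
    max_translation_mm: float = 20.0
    jitter_sigma: float = 1.0
    n_drop: int = 1
    n_spurious: int = 1
    spurious_offset: tuple[float, float] = (10.0, 30.0)
    scramble_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not (0 <= self.n_drop < 65):
            raise ValueError("n_drop must be in [0, 65)")
        if self.n_spurious < 0:
            raise ValueError("n_spurious must be >= 0")


@dataclass
class PerturbationTruth:
    """Everything needed to score detections generated from a known cap."""

    transform: SimilarityTransform
    true_points: LabeledPoints  # full transformed cap, noise-free
    dropped_labels: list[str]
    kept_labels: list[str]
    spurious_indices: list[int]  # indices into the output DetectionCloud


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _draw_similarity(rng: np.random.Generator, spec: PerturbationSpec):
    angle = np.deg2rad(rng.uniform(0.0, spec.max_rotation_deg))
    R = Rotation.from_rotvec(angle * _random_unit_vector(rng)).as_matrix()
    s = rng.uniform(*spec.scale_range)
    t = rng.uniform(0.0, spec.max_translation_mm) * _random_unit_vector(rng)
    return SimilarityTransform(s, R, t)


def perturb_cloud(
    cloud: LabeledPoints,
    spec: PerturbationSpec,
    model: CapModel | None = None,
) -> tuple[DetectionCloud, PerturbationTruth]:
    """Apply pose, jitter, dropouts and spurious blobs to a labeled cap.

    The similarity transform, jitter, dropout choice, spurious placement
    and label scrambling each consume an independent seed-derived random
    stream, so e.g. the same electrodes drop regardless of jitter level.
    Spurious points are placed 10-30 mm outside the scalp ellipsoid (of
    ``model``, default geometry) and carry arbitrary provisional labels.
    Returns the detections and a truth record holding the transform, the
    noise-free transformed cap, and the identities of dropped/spurious
    points.
    """
    if model is None:
        model = CapModel()
    seed = int(spec.seed)
    rng_pose = np.random.default_rng([seed, 1])
    rng_jit = np.random.default_rng([seed, 2])
    rng_drop = np.random.default_rng([seed, 3])
    rng_spur = np.random.default_rng([seed, 4])
    rng_scram = np.random.default_rng([seed, 5])

    transform = _draw_similarity(rng_pose, spec)
    true_pts = transform.apply(cloud.points)
    noisy = true_pts + rng_jit.normal(0.0, spec.jitter_sigma, true_pts.shape)

    n = len(cloud)
    dropped = sorted(rng_drop.choice(n, size=spec.n_drop, replace=False).tolist())
    keep = [i for i in range(n) if i not in set(dropped)]
    points = [noisy[keep]]
    prov = [np.asarray([k + 1 for k in keep], dtype=int)]

    radii = np.asarray(model.head_radii)
    spurious_idx = list(range(len(keep), len(keep) + spec.n_spurious))
    if spec.n_spurious:
        spur = []
        for _ in range(spec.n_spurious):
            d = _random_unit_vector(rng_spur)
            d[2] = abs(d[2])  # keep artifacts in the cap's hemisphere
            d /= np.linalg.norm(d)
            on_scalp = _project_to_ellipsoid(d, radii)
            offset = rng_spur.uniform(*spec.spurious_offset)
            spur.append(on_scalp + offset * d)
        points.append(transform.apply(np.asarray(spur)))
        prov.append(rng_spur.integers(1, n + 1, size=spec.n_spurious))

    all_points = np.concatenate(points)
    all_prov = np.concatenate(prov)
    if spec.scramble_labels:
        all_prov = rng_scram.permutation(all_prov)

    detections = DetectionCloud(all_points, provisional_labels=all_prov)
    truth = PerturbationTruth(
        transform=transform,
        true_points=LabeledPoints(list(cloud.labels), true_pts),
        dropped_labels=[cloud.labels[i] for i in dropped],
        kept_labels=[cloud.labels[i] for i in keep],
        spurious_indices=spurious_idx,
    )
    return detections, truth


def paint_volume(
    cloud: LabeledPoints,
    grid_shape: tuple[int, int, int] | None = None,
    spacing: float = DEFAULT_SPACING_MM,
    radius: float = DEFAULT_SPHERE_RADIUS_MM,
) -> LabeledVolume:
    """Rasterize each electrode as a digital sphere with its own label.

    Electrode ``k`` (1-based position in the cloud) claims every voxel
    whose center lies within ``radius`` mm of its point; on overlap,
    later electrodes overwrite earlier ones. The affine is diagonal
    ``spacing`` with the grid centered on the cloud centroid. With
    ``grid_shape=None`` the grid is sized to fit the cloud with a margin
    of ``radius`` plus two voxels.

    Raises
    ------
    ValueError
        If any sphere would extend outside the grid.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = np.asarray(cloud.points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        shape = grid_shape or (16, 16, 16)
        affine = np.diag([spacing] * 3 + [1.0])
        return LabeledVolume(np.zeros(shape, dtype=np.int16), affine)
    centroid = pts.mean(axis=0)
    if grid_shape is None:
        extent = np.max(np.abs(pts - centroid), axis=0) + radius + 2 * spacing
        grid_shape = tuple(int(2 * np.ceil(e / spacing) + 1) for e in extent)
    shape = np.asarray(grid_shape, dtype=int)

    affine = np.eye(4)
    affine[:3, :3] = np.diag([spacing] * 3)
    affine[:3, 3] = centroid - spacing * (shape - 1) / 2.0
    origin = affine[:3, 3]

    grid = np.zeros(tuple(shape), dtype=np.int16)
    r_vox = radius / spacing
    for k, p in enumerate(pts, start=1):
        center = (p - origin) / spacing  # voxel-index coordinates
        lo = np.floor(center - r_vox).astype(int)
        hi = np.ceil(center + r_vox).astype(int)
        if np.any(lo < 0) or np.any(hi > shape - 1):
            raise ValueError(
                f"electrode {k} at {p} does not fit inside the grid with "
                f"radius {radius} mm"
            )
        ii, jj, kk = np.meshgrid(
            *(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij"
        )
        d2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
        sub = grid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        sub[d2 <= r_vox**2] = k
    return LabeledVolume(grid, affine)


def training_template(
    seed: int = 0,
    n_caps: int = 12,
    model: CapModel | None = None,
    placement_sigma: float = 1.5,
) -> Template:
    """Average cap from ``n_caps`` simulated training subjects.

    Mirrors building the template from one manually labeled ground truth
    per training subject (12 by default).
    """
    caps = [
        generate_cap(model, seed=int(seed) + i, placement_sigma=placement_sigma)
        for i in range(n_caps)
    ]
    return build_template(caps)


def write_fixture_set(out_dir, seed: int = 0, model: CapModel | None = None) -> dict:
    """Materialize a standard simulated study: 12 training caps with
    their template, and 8 test caps. Returns a manifest of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str] | str] = {"training": [], "test": []}
    caps = []
    for i in range(12):
        cap = generate_cap(model, seed=int(seed) + i)
        path = out / f"train_cap_{i:02d}.tsv"
        cap.to_tsv(path)
        caps.append(cap)
        manifest["training"].append(str(path))
    tpl = build_template(caps)
    tpl_path = out / "template.tsv"
    tpl.to_tsv(tpl_path)
    manifest["template"] = str(tpl_path)
    for i in range(8):
        cap = generate_cap(model, seed=int(seed) + 100 + i)
        path = out / f"test_cap_{i:02d}.tsv"
        cap.to_tsv(path)
        manifest["test"].append(str(path))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
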