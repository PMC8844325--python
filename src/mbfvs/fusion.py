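"""Rigid PET/CT alignment: LV-based initialization, mutual-information refinement,
and centerline transfer into PET space.

Transforms map CT world coordinates (mm) into PET world coordinates and are
stored as proper rotations plus translations; Euler angles use the ZYX
convention in the JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .imaging import AnatomyMasks, Grid, Volume
from .vessel_roi import Centerline

__all__ = [
    "RigidTransform",
    "segment_lv_from_pet",
    "register_rigid_lv",
    "refine_mutual_information",
    "transform_centerline",
    "resample_to_grid",
    "fuse_masks",
]


class FusionError(ValueError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """x_pet = R @ x_ct + t, with R proper orthonormal."""

    rotation: tuple[tuple[float, float, float], ...]
    translation: tuple[float, float, float]
    convention: str = "ct_to_pet"

    def __post_init__(self) -> None:
        r = self.matrix
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise FusionError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise FusionError("rotation must be proper (det = +1)")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def translation_vec(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls.from_matrix(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        u, _, vt = np.linalg.svd(np.asarray(rotation, dtype=float))
        r = u @ vt  # nearest orthonormal matrix
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        return cls(
            rotation=tuple(tuple(row) for row in r),
            translation=tuple(float(v) for v in translation),
        )

    @classmethod
    def from_params(
        cls,
        angles_deg: np.ndarray,
        translation_mm: np.ndarray,
        center_mm: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Rotation by ZYX Euler angles about ``center_mm`` followed by a translation."""
        r = Rotation.from_euler("ZYX", np.asarray(angles_deg, dtype=float), degrees=True).as_matrix()
        t = np.asarray(translation_mm, dtype=float)
        if center_mm is not None:
            c = np.asarray(center_mm, dtype=float)
            t = t + c - r @ c
        return cls.from_matrix(r, t)

    @property
    def angles_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.matrix).as_euler("ZYX", degrees=True)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.translation_vec
        return out if out.shape[0] > 1 else out[0]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform.from_matrix(
            self.matrix @ other.matrix,
            self.matrix @ other.translation_vec + self.translation_vec,
        )

    def inverse(self) -> "RigidTransform":
        rinv = self.matrix.T
        return RigidTransform.from_matrix(rinv, -rinv @ self.translation_vec)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation (geodesic angle)."""
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.matrix).as_rotvec())))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "angles_deg": [float(a) for a in self.angles_deg],
            "translation_mm": [float(t) for t in self.translation],
            "convention": self.convention,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        payload = json.loads(Path(path).read_text())
        t = cls.from_params(np.asarray(payload["angles_deg"]), np.asarray(payload["translation_mm"]))
        return RigidTransform(rotation=t.rotation, translation=t.translation,
                              convention=payload.get("convention", "ct_to_pet"))


# ---------------------------------------------------------------------------
# PET-side LV segmentation
# ---------------------------------------------------------------------------


def segment_lv_from_pet(pet_sum: Volume, threshold_fraction: float = 0.5) -> Volume:
    """Threshold the summed PET at a fraction of its maximum, keep the largest
    connected component (ties broken by lowest flat voxel index) and fill holes."""
    if not (0 <= threshold_fraction <= 1):
        raise FusionError("threshold_fraction must be in [0, 1]")
    data = np.asarray(pet_sum.data, dtype=float)
    vmax = data.max()
    if vmax <= 0:
        raise FusionError("summed PET has no positive values")
    if threshold_fraction == 0:
        binary = data > 0
    else:
        binary = data >= threshold_fraction * vmax
    if not np.any(binary):
        raise FusionError(
            f"threshold {threshold_fraction} x max leaves an empty mask; lower the threshold"
        )
    labels, n = ndimage.label(binary)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    candidates = np.nonzero(sizes == best_size)[0] + 1
    if candidates.size == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        first = {int(lab): np.argmax(flat == lab) for lab in candidates}
        keep = min(first, key=first.get)
    mask = labels == keep
    mask = ndimage.binary_fill_holes(mask)
    return Volume(data=mask.astype(np.uint8), grid=pet_sum.grid)


# ---------------------------------------------------------------------------
# metric helpers
# ---------------------------------------------------------------------------


def _subsample_stride(shape: tuple[int, ...], target: int = 40) -> int:
    return max(1, int(np.ceil(max(shape) / target)))


def _fixed_points(grid: Grid, stride: int) -> np.ndarray:
    ax = [np.arange(0, n, stride) for n in grid.shape]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    return grid.index_to_world(idx)


def _sample_moving(vol: Volume, pts_world: np.ndarray, order: int) -> np.ndarray:
    idx = vol.grid.world_to_index(pts_world)
    return ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), idx.T, order=order, mode="constant", cval=0.0
    )


def _soft_dice(fixed_vals: np.ndarray, moving_vals: np.ndarray) -> float:
    num = 2.0 * float(np.sum(fixed_vals * moving_vals))
    den = float(np.sum(fixed_vals) + np.sum(moving_vals))
    return num / den if den > 0 else 0.0


def _mask_overlap_metric(
    fixed_mask: Volume, moving_mask: Volume, transform: RigidTransform, stride: int
) -> float:
    pts = _fixed_points(fixed_mask.grid, stride)
    fixed_vals = np.asarray(fixed_mask.data, dtype=float)[
        tuple(np.round(fixed_mask.grid.world_to_index(pts)).astype(int).T)
    ]
    moving_pts = transform.inverse().apply(pts)
    moving_vals = _sample_moving(moving_mask, moving_pts, order=1)
    return _soft_dice(fixed_vals, moving_vals)


def _principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit long axis with sign fixed by the third moment)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered / points.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    skew = np.mean((centered @ axis) ** 3)
    if skew < 0:
        axis = -axis
    return centroid, axis


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 deg about any perpendicular axis
        perp = np.eye(3)[np.argmin(np.abs(a))]
        perp = perp - a * np.dot(perp, a)
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    s = np.linalg.norm(v)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def register_rigid_lv(lv_pet: Volume, lv_ct: Volume, max_iter: int = 6) -> RigidTransform:
    """Rigidly register the CT LV mask onto the PET LV mask.

    Centroid alignment (plus a long-axis candidate, scored by overlap)
    initializes a derivative-free refinement that maximizes the soft mask
    overlap.  Deterministic; intended for initial displacements within the
    ~15 mm / 15 degree capture range the pipeline assumes.
    """
    pet_idx = np.argwhere(np.asarray(lv_pet.data) > 0)
    ct_idx = np.argwhere(np.asarray(lv_ct.data) > 0)
    if pet_idx.shape[0] == 0 or ct_idx.shape[0] == 0:
        raise FusionError("both LV masks must be non-empty")
    if pet_idx.shape[0] <= 3 or ct_idx.shape[0] <= 3:
        raise FusionError("degenerate LV mask (<= 3 voxels)")

    pet_pts = lv_pet.grid.index_to_world(pet_idx)
    ct_pts = lv_ct.grid.index_to_world(ct_idx)
    c_pet, ax_pet = _principal_axis(pet_pts)
    c_ct, ax_ct = _principal_axis(ct_pts)

    stride = _subsample_stride(lv_pet.grid.shape)
    metric = _OverlapMetric(lv_pet, lv_ct, stride)

    candidates = [RigidTransform.from_matrix(np.eye(3), c_pet - c_ct)]
    for flip in (1.0, -1.0):
        r = _rotation_between(ax_ct, flip * ax_pet)
        candidates.append(RigidTransform.from_matrix(r, c_pet - r @ c_ct))
    init = max(candidates, key=metric)

    def cost(p):
        delta = RigidTransform.from_params(p[:3], p[3:], center_mm=c_pet)
        return -metric(delta.compose(init))

    res = minimize(
        cost,
        np.zeros(6),
        method="Powell",
        options={"maxiter": max_iter, "xtol": 1e-3, "ftol": 1e-7},
    )
    best = RigidTransform.from_params(res.x[:3], res.x[3:], center_mm=c_pet).compose(init)
    return best if metric(best) >= metric(init) else init


# ---------------------------------------------------------------------------
# mutual information refinement
# ---------------------------------------------------------------------------

_MI_BINS = 32


class _OverlapMetric:
    """Soft Dice between a fixed mask (strided) and a transformed moving mask."""

    def __init__(self, fixed_mask: Volume, moving_mask: Volume, stride: int):
        self.pts = _fixed_points(fixed_mask.grid, stride)
        self.fixed_vals = np.asarray(
            fixed_mask.data[::stride, ::stride, ::stride], dtype=float
        ).ravel()
        self.moving = moving_mask

    def __call__(self, transform: RigidTransform) -> float:
        moving_vals = _sample_moving(self.moving, transform.inverse().apply(self.pts), order=1)
        return _soft_dice(self.fixed_vals, moving_vals)


class _MIMetric:
    """Histogram MI between PET intensities and transformed anatomy labels.

    PET bin indices are precomputed on a strided fixed grid; label channels
    (myocardium / RV / LV one-hot volumes) are linearly interpolated at the
    transformed sample points so the metric varies smoothly with the pose.
    """

    def __init__(self, pet_sum: Volume, masks: AnatomyMasks, stride: int, bins: int = _MI_BINS):
        pet_vals = np.asarray(pet_sum.data[::stride, ::stride, ::stride], dtype=float).ravel()
        vmax = pet_vals.max()
        if vmax <= 0:
            raise FusionError("summed PET has no positive values")
        self.bins = bins
        self.bin_idx = np.minimum((pet_vals / vmax * bins).astype(int), bins - 1)
        self.pts = _fixed_points(pet_sum.grid, stride)
        myo = masks.myocardium
        self.channels = [
            myo.astype(float),
            masks.rv.bool().astype(float),
            masks.lv.bool().astype(float),
        ]
        self.moving_grid = masks.grid

    def __call__(self, transform: RigidTransform) -> float:
        idx = self.moving_grid.world_to_index(transform.inverse().apply(self.pts)).T
        weights = [
            ndimage.map_coordinates(ch, idx, order=1, mode="constant", cval=0.0)
            for ch in self.channels
        ]
        bg = np.clip(1.0 - np.sum(weights, axis=0), 0.0, 1.0)
        weights = [bg] + weights
        joint = np.zeros((self.bins, len(weights)))
        for c, w in enumerate(weights):
            joint[:, c] = np.bincount(self.bin_idx, weights=w, minlength=self.bins)
        joint /= joint.sum()
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        nz = joint > 0
        return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def mutual_information_metric(
    pet_sum: Volume,
    masks: AnatomyMasks,
    transform: RigidTransform,
    stride: int = 2,
    bins: int = _MI_BINS,
) -> float:
    return _MIMetric(pet_sum, masks, stride, bins)(transform)


def refine_mutual_information(
    pet_sum: Volume,
    masks: AnatomyMasks,
    init: RigidTransform,
    max_iter: int = 4,
    sweep_deg: float = 45.0,
    sweep_step_deg: float = 15.0,
) -> RigidTransform:
    """Refine a rigid transform by maximizing mutual information between the
    summed PET and a labeled rendering of the biventricular anatomy.

    A coarse sweep of the twist about the LV long axis runs first (the LV
    alone is nearly axially symmetric, so the initializer constrains that
    angle poorly), then a two-level derivative-free refinement.  The returned
    transform never scores below ``init``.
    """
    lv_idx = np.argwhere(masks.lv.bool())
    lv_pts = masks.grid.index_to_world(lv_idx)
    c_ct, axis_ct = _principal_axis(lv_pts)
    coarse = max(2, _subsample_stride(pet_sum.grid.shape, 24))
    fine = max(2, _subsample_stride(pet_sum.grid.shape, 48))
    metric_coarse = _MIMetric(pet_sum, masks, coarse)
    metric_fine = _MIMetric(pet_sum, masks, fine)

    # 1) discrete sweep over the twist angle about the (transformed) long axis
    best_t, best_m = init, metric_coarse(init)
    axis_pet = init.matrix @ axis_ct
    c_pet = init.apply(c_ct)
    for ang in np.arange(-sweep_deg, sweep_deg + sweep_step_deg / 2, sweep_step_deg):
        if abs(ang) < 1e-9:
            continue
        r = Rotation.from_rotvec(np.radians(ang) * axis_pet).as_matrix()
        twist = RigidTransform.from_matrix(r, c_pet - r @ c_pet)
        cand = twist.compose(init)
        m = metric_coarse(cand)
        if m > best_m:
            best_t, best_m = cand, m

    # 2) Powell refinement, coarse then fine sampling
    current = best_t
    for metric in (metric_coarse, metric_fine):
        center = current.apply(c_ct)

        def cost(p, _center=center, _base=current, _metric=metric):
            delta = RigidTransform.from_params(p[:3], p[3:], center_mm=_center)
            return -_metric(delta.compose(_base))

        res = minimize(
            cost,
            np.zeros(6),
            method="Powell",
            options={"maxiter": max_iter, "xtol": 1e-4, "ftol": 1e-9},
        )
        cand = RigidTransform.from_params(res.x[:3], res.x[3:], center_mm=center).compose(current)
        if metric(cand) >= metric(current):
            current = cand

    return current if metric_fine(current) >= metric_fine(init) else init


def transform_centerline(centerline: Centerline, transform: RigidTransform) -> Centerline:
    """Map a centerline pointwise into PET space (arc length is preserved exactly)."""
    return Centerline(points=transform.apply(centerline.points), vessel=centerline.vessel)


# ---------------------------------------------------------------------------
# mask transfer into PET space
# ---------------------------------------------------------------------------


def resample_to_grid(
    vol: Volume, target: Grid, transform: RigidTransform, order: int = 0, mask: bool = False
) -> Volume:
    """Resample ``vol`` (CT space) onto ``target`` (PET space) through ``transform``."""
    ax = [np.arange(n) for n in target.shape]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts_pet = target.index_to_world(idx)
    pts_ct = transform.inverse().apply(pts_pet)
    src_idx = vol.grid.world_to_index(pts_ct)
    vals = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), src_idx.T, order=order, mode="constant", cval=0.0
    )
    data = vals.reshape(target.shape)
    if mask:
        data = (data >= 0.5).astype(np.uint8)
    return Volume(data=data, grid=target)


def fuse_masks(masks: AnatomyMasks, target: Grid, transform: RigidTransform) -> AnatomyMasks:
    """Carry CT anatomy masks into the PET grid with nearest-neighbour sampling."""
    lv = resample_to_grid(masks.lv, target, transform, order=0, mask=True)
    rv = resample_to_grid(masks.rv, target, transform, order=0, mask=True)
    epi = resample_to_grid(masks.epi, target, transform, order=0, mask=True)
    rv_arr = rv.data.astype(bool) & ~lv.data.astype(bool)
    epi_arr = epi.data.astype(bool) | lv.data.astype(bool) | rv_arr
    return AnatomyMasks(
        lv=lv,
        rv=Volume(rv_arr.astype(np.uint8), target),
        epi=Volume(epi_arr.astype(np.uint8), target),
        provenance=masks.provenance,
    )
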