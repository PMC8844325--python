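"""Centerline-guided myocardial ROI discretization and time-activity curve extraction.

The myocardium subtended to a fused coronary centerline is chopped into
contiguous cubic elements (4 mm longitudinal size by default) ordered from the
base to the apex; each element's voxels feed a per-frame mean TAC.  The blood
input curve is sampled from the eroded LV cavity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging import AnatomyMasks, DynamicSeries, Grid, ImagingError, Volume

__all__ = [
    "Centerline",
    "VesselROI",
    "VesselROISet",
    "TAC",
    "subtended_rois",
    "extract_tac",
    "arterial_input_tac",
]

VESSEL_LABELS = ("LAD", "LCX", "rPDA")


class RoiError(ValueError):
    pass


@dataclass
class Centerline:
    """Ordered base-to-apex 3-D path of one coronary vessel (world mm)."""

    points: np.ndarray  # (N, 3)
    vessel: str

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise RoiError("centerline needs >= 2 points of dimension 3")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise RoiError("centerline arc length must be strictly increasing")

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length per point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the path at arc position(s) ``s`` (mm)."""
        al = self.arc_length
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty((s.size, 3))
        for ax in range(3):
            out[:, ax] = np.interp(s, al, self.points[:, ax])
        return out if out.shape[0] > 1 else out[0]

    def reversed(self) -> "Centerline":
        return Centerline(points=self.points[::-1].copy(), vessel=self.vessel)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x_mm", "y_mm", "z_mm"])
            for p in self.points:
                w.writerow([repr(float(v)) for v in p])

    @classmethod
    def from_csv(cls, path: str | Path, vessel: str) -> "Centerline":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        try:
            pts = np.array([[float(r["x_mm"]), float(r["y_mm"]), float(r["z_mm"])] for r in rows])
        except (KeyError, ValueError) as exc:
            raise RoiError(f"malformed centerline file {path}: {exc}") from exc
        return cls(points=pts, vessel=vessel)


@dataclass
class VesselROI:
    index: int
    position_mm: float  # longitudinal arc position from base
    center: np.ndarray  # world mm
    edge_mm: float
    voxels: np.ndarray  # (M, 3) int voxel indices

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.shape[0] < 1:
            raise RoiError(f"ROI {self.index} has no member voxels")


@dataclass
class VesselROISet:
    rois: list[VesselROI]
    vessel: str
    grid: Grid

    def __post_init__(self) -> None:
        if not self.rois:
            raise RoiError("empty ROI set")
        pos = np.array([r.position_mm for r in self.rois])
        edge = self.rois[0].edge_mm
        if np.any(np.diff(pos) <= 0):
            raise RoiError("ROI longitudinal positions must be strictly increasing")
        if not np.allclose(np.diff(pos), edge, atol=1e-6):
            raise RoiError("ROI spacing must equal the edge length")

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def positions(self) -> np.ndarray:
        return np.array([r.position_mm for r in self.rois])

    def label_volume(self) -> Volume:
        """ROIs rendered as a label image (1-based index, 0 = background)."""
        lab = np.zeros(self.grid.shape, dtype=np.int32)
        for roi in self.rois:
            lab[roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]] = roi.index + 1
        return Volume(data=lab, grid=self.grid)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "position_mm", "center_x_mm", "center_y_mm", "center_z_mm", "n_voxels"])
            for r in self.rois:
                w.writerow([r.index, r.position_mm, *map(float, r.center), r.voxels.shape[0]])


@dataclass
class TAC:
    """Per-frame mean activity for one region."""

    mid_times: np.ndarray  # s
    durations: np.ndarray  # s
    values: np.ndarray  # kBq/mL
    source: str = "roi"

    def __post_init__(self) -> None:
        self.mid_times = np.asarray(self.mid_times, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = self.mid_times.size
        if n == 0 or self.durations.size != n or self.values.size != n:
            raise RoiError("TAC arrays must be non-empty and consistent in length")
        if np.any(np.diff(self.mid_times) <= 0):
            raise RoiError("TAC mid-times must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["mid_time_s", "duration_s", "activity"])
            for t, d, v in zip(self.mid_times, self.durations, self.values):
                w.writerow([repr(float(t)), repr(float(d)), repr(float(v))])


def _midwall_tree(masks: AnatomyMasks) -> tuple[cKDTree, np.ndarray]:
    """KD-tree over mid-wall myocardial voxel world positions.

    Mid-wall voxels balance the distance to the blood pools against the
    distance to the outside of the epicardial envelope, keeping ROI anchors
    inside tissue even for thin walls.
    """
    myo = masks.myocardium
    vox = masks.grid.voxel_size
    pools = masks.lv.bool() | masks.rv.bool()
    d_pool = ndimage.distance_transform_edt(~pools, sampling=vox)
    d_out = ndimage.distance_transform_edt(masks.epi.bool(), sampling=vox)
    balance = np.abs(d_pool - d_out)
    tol = max(vox)
    mid = myo & (balance <= tol)
    if not np.any(mid):
        mid = myo
    idx = np.argwhere(mid)
    pts = masks.grid.index_to_world(idx)
    return cKDTree(pts), idx


def subtended_rois(
    centerline: Centerline,
    masks: AnatomyMasks,
    roi_length_mm: float = 4.0,
    clip_to_myocardium: bool = True,
    max_snap_mm: float = 20.0,
) -> VesselROISet:
    """Discretize the myocardium under a centerline into contiguous cubic ROIs.

    One cube of edge ``roi_length_mm`` per arc-length step, base to apex;
    each cube is centered on the mid-wall voxel nearest the centerline sample
    and (by default) clipped to the myocardium mask.  Voxel membership uses
    half-open cube bounds on voxel centers.
    """
    if roi_length_mm <= 0:
        raise RoiError("roi_length_mm must be positive")
    total = centerline.total_length
    n_rois = int(np.floor(total / roi_length_mm))
    if n_rois < 1:
        raise RoiError(
            f"centerline arc length {total:.1f} mm shorter than one ROI ({roi_length_mm} mm)"
        )

    tree, mid_idx = _midwall_tree(masks)
    myo = masks.myocardium
    grid = masks.grid
    half = roi_length_mm / 2.0

    rois: list[VesselROI] = []
    for k in range(n_rois):
        s = (k + 0.5) * roi_length_mm
        target = centerline.point_at(s)
        dist, j = tree.query(target)
        if dist > max_snap_mm:
            raise RoiError(
                f"no myocardium within {max_snap_mm} mm of arc position {s:.1f} mm "
                "(gross misregistration?)"
            )
        center = grid.index_to_world(mid_idx[j]).ravel()

        # candidate voxel index window around the cube
        lo_idx = np.floor(grid.world_to_index(center - half * np.sqrt(3)).ravel()).astype(int)
        hi_idx = np.ceil(grid.world_to_index(center + half * np.sqrt(3)).ravel()).astype(int)
        lo_idx = np.maximum(np.minimum(lo_idx, hi_idx), 0)
        hi_idx = np.minimum(np.maximum(lo_idx, hi_idx), np.asarray(grid.shape) - 1)
        ii, jj, kk = np.meshgrid(
            np.arange(lo_idx[0], hi_idx[0] + 1),
            np.arange(lo_idx[1], hi_idx[1] + 1),
            np.arange(lo_idx[2], hi_idx[2] + 1),
            indexing="ij",
        )
        cand = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        w = grid.index_to_world(cand)
        inside = np.all((w >= center - half) & (w < center + half), axis=1)
        cand = cand[inside]
        if clip_to_myocardium:
            cand = cand[myo[cand[:, 0], cand[:, 1], cand[:, 2]]]
        if cand.shape[0] == 0:
            raise RoiError(f"ROI at arc position {s:.1f} mm contains no myocardial voxels")
        rois.append(
            VesselROI(index=k, position_mm=s, center=center, edge_mm=roi_length_mm, voxels=cand)
        )
    return VesselROISet(rois=rois, vessel=centerline.vessel, grid=grid)


def extract_tac(series: DynamicSeries, voxels: np.ndarray, source: str = "roi") -> TAC:
    """Per-frame unweighted mean over the member voxels."""
    voxels = np.atleast_2d(np.asarray(voxels, dtype=int))
    if voxels.shape[0] == 0:
        raise RoiError("cannot extract a TAC from an empty voxel list")
    shape = np.asarray(series.grid.shape)
    if np.any(voxels < 0) or np.any(voxels >= shape):
        raise RoiError("voxel index outside the series grid")
    vals = series.data[:, voxels[:, 0], voxels[:, 1], voxels[:, 2]].mean(axis=1)
    return TAC(
        mid_times=series.schedule.mid_times,
        durations=series.schedule.durations_arr,
        values=vals,
        source=source,
    )


def arterial_input_tac(
    series: DynamicSeries, masks: AnatomyMasks, erosion_mm: float = 4.0
) -> TAC:
    """Blood input curve from the LV cavity eroded by ``erosion_mm`` to limit spill-in."""
    if erosion_mm < 0:
        raise RoiError("erosion_mm must be >= 0")
    lv = masks.lv.bool()
    if erosion_mm > 0:
        d = ndimage.distance_transform_edt(lv, sampling=masks.grid.voxel_size)
        core = d >= erosion_mm
    else:
        core = lv
    if not np.any(core):
        raise RoiError(
            f"eroding the LV blood pool by {erosion_mm} mm leaves no voxels; "
            "use a smaller erosion"
        )
    return extract_tac(series, np.argwhere(core), source="arterial")
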