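"""Volume / dynamic-series data model, I/O, reorientation, resampling and late-frame summation.

World coordinates are millimetres in a fixed global frame.  A :class:`Grid`
carries the mapping ``world = origin + direction @ (voxel_size * index)`` with
an orthonormal, right-handed ``direction`` matrix; voxel indices are 0-based.
Masks are strict {0, 1} volumes and their containment/disjointness invariants
are checked on construction and on load, never assumed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Grid",
    "Volume",
    "FrameSchedule",
    "DynamicSeries",
    "AnatomyMasks",
    "SCHEDULE_PRESETS",
    "make_schedule",
    "reorient_short_axis",
    "resample",
    "pet_sum",
    "read_volume",
    "write_volume",
    "read_series",
    "write_series",
]

_ORTHO_TOL = 1e-6


class ImagingError(ValueError):
    """Raised for malformed volumes, schedules or masks."""


@dataclass(frozen=True)
class Grid:
    """Regular 3-D sampling grid embedded in world (mm) space."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[tuple[float, ...], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ImagingError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ImagingError(f"voxel_size must be positive on all axes, got {self.voxel_size}")
        d = self.direction_matrix
        if not np.allclose(d.T @ d, np.eye(3), atol=_ORTHO_TOL):
            raise ImagingError("direction matrix is not orthonormal")
        if np.linalg.det(d) < 0:
            raise ImagingError("direction matrix is not right-handed (det < 0)")

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction_matrix * np.asarray(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        m = self.direction_matrix * np.asarray(self.voxel_size)
        return idx @ m.T + np.asarray(self.origin)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        m = self.direction_matrix * np.asarray(self.voxel_size)
        return (pts - np.asarray(self.origin)) @ np.linalg.inv(m).T

    def with_affine_offset(self, rotation: np.ndarray, translation: np.ndarray) -> "Grid":
        """Return the grid whose world coordinates are ``R @ w + t`` of this grid's."""
        r = np.asarray(rotation, dtype=float)
        new_dir = r @ self.direction_matrix
        new_origin = r @ np.asarray(self.origin) + np.asarray(translation, dtype=float)
        return replace(
            self,
            origin=tuple(new_origin),
            direction=tuple(tuple(row) for row in new_dir),
        )

    def same_geometry(self, other: "Grid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction_matrix, other.direction_matrix, atol=atol)
        )


@dataclass
class Volume:
    """Scalar activity or binary label volume on a :class:`Grid`."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ImagingError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ImagingError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.grid.voxel_size

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, grid=self.grid)

    def as_mask(self) -> "Volume":
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ImagingError(f"mask volume contains non-binary values {vals[:10]}")
        return Volume(data=self.data.astype(np.uint8), grid=self.grid)

    def bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping frame timing (seconds)."""

    starts: tuple[float, ...]
    durations: tuple[float, ...]

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if starts.size == 0 or starts.size != durations.size:
            raise ImagingError("schedule must have matching, non-empty starts/durations")
        if np.any(durations <= 0):
            raise ImagingError("frame durations must be positive")
        expected = starts[:-1] + durations[:-1]
        if not np.allclose(starts[1:], expected, atol=1e-9):
            raise ImagingError("frames must be contiguous and non-overlapping")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def starts_arr(self) -> np.ndarray:
        return np.asarray(self.starts, dtype=float)

    @property
    def durations_arr(self) -> np.ndarray:
        return np.asarray(self.durations, dtype=float)

    @property
    def mid_times(self) -> np.ndarray:
        return self.starts_arr + self.durations_arr / 2.0

    @property
    def total(self) -> float:
        return float(self.starts_arr[-1] + self.durations_arr[-1])

    @property
    def end_times(self) -> np.ndarray:
        return self.starts_arr + self.durations_arr


#: Frame binning presets (repeats, frame duration s).
SCHEDULE_PRESETS: dict[str, tuple[tuple[int, float], ...]] = {
    "SNUH": ((12, 10.0), (6, 30.0), (2, 60.0), (1, 180.0)),
    "SMC_CNUH": ((12, 5.0), (6, 10.0), (3, 20.0), (6, 30.0)),
}


def make_schedule(preset: str | Sequence[tuple[float, float]]) -> FrameSchedule:
    """Build a frame schedule from a named preset or an explicit (start, duration) list.

    Preset schedules start at 0 s.  Explicit lists must already be contiguous.
    """
    if isinstance(preset, str):
        try:
            blocks = SCHEDULE_PRESETS[preset]
        except KeyError:
            raise ImagingError(
                f"unknown schedule preset {preset!r}; choose from {sorted(SCHEDULE_PRESETS)}"
            ) from None
        durations: list[float] = []
        for n, dur in blocks:
            durations.extend([dur] * n)
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return FrameSchedule(starts=tuple(starts), durations=tuple(durations))
    pairs = list(preset)
    if not pairs:
        raise ImagingError("explicit schedule is empty")
    return FrameSchedule(
        starts=tuple(float(s) for s, _ in pairs),
        durations=tuple(float(d) for _, d in pairs),
    )


@dataclass
class DynamicSeries:
    """Time-ordered stack of frames sharing one grid.

    ``data`` has shape (n_frames, *grid.shape); ``state`` is 'rest' or 'stress'.
    """

    data: np.ndarray
    grid: Grid
    schedule: FrameSchedule
    state: str = "rest"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ImagingError("dynamic series data must be 4-D (t, x, y, z)")
        if self.data.shape[0] != len(self.schedule):
            raise ImagingError(
                f"frame count {self.data.shape[0]} != schedule length {len(self.schedule)}"
            )
        if tuple(self.data.shape[1:]) != tuple(self.grid.shape):
            raise ImagingError("frame shape does not match grid shape")
        if self.state not in ("rest", "stress"):
            raise ImagingError(f"state must be 'rest' or 'stress', got {self.state!r}")

    def __len__(self) -> int:
        return self.data.shape[0]

    def frame(self, i: int) -> Volume:
        return Volume(data=self.data[i], grid=self.grid)


@dataclass
class AnatomyMasks:
    """LV / RV blood pools and biventricular epicardial envelope on a shared grid."""

    lv: Volume
    rv: Volume
    epi: Volume
    provenance: str = "M"

    def __post_init__(self) -> None:
        self.lv = self.lv.as_mask()
        self.rv = self.rv.as_mask()
        self.epi = self.epi.as_mask()
        if not (
            self.lv.grid.same_geometry(self.rv.grid)
            and self.lv.grid.same_geometry(self.epi.grid)
        ):
            raise ImagingError("anatomy masks must share one grid")
        lv, rv, epi = self.lv.bool(), self.rv.bool(), self.epi.bool()
        if np.any(lv & rv):
            raise ImagingError("LV and RV masks overlap")
        if np.any(lv & ~epi) or np.any(rv & ~epi):
            raise ImagingError("blood pools must lie inside the epicardial envelope")
        if not np.any(epi & ~lv & ~rv):
            raise ImagingError("myocardium (EPI minus blood pools) is empty")

    @property
    def grid(self) -> Grid:
        return self.lv.grid

    @property
    def myocardium(self) -> np.ndarray:
        return self.epi.bool() & ~self.lv.bool() & ~self.rv.bool()

    def with_provenance(self, tag: str) -> "AnatomyMasks":
        return AnatomyMasks(lv=self.lv, rv=self.rv, epi=self.epi, provenance=tag)


# ---------------------------------------------------------------------------
# geometry-preserving reorientation and block resampling
# ---------------------------------------------------------------------------


def _parse_axis_mapping(axis_mapping: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Validate a signed 1-based axis permutation; return (perm, signs)."""
    m = list(axis_mapping)
    if len(m) != 3 or any(not isinstance(v, (int, np.integer)) or v == 0 for v in m):
        raise ImagingError(f"axis mapping must be 3 signed non-zero ints, got {axis_mapping}")
    perm = np.array([abs(v) - 1 for v in m])
    signs = np.array([1 if v > 0 else -1 for v in m])
    if sorted(perm.tolist()) != [0, 1, 2]:
        raise ImagingError(f"axis mapping is not a permutation: {axis_mapping}")
    # signed permutation matrix determinant must be +1 (right-handed)
    p = np.zeros((3, 3))
    for out_ax in range(3):
        p[perm[out_ax], out_ax] = signs[out_ax]
    if np.linalg.det(p) < 0:
        raise ImagingError(f"axis mapping {axis_mapping} is left-handed")
    return perm, signs


def reorient_short_axis(volume: Volume, axis_mapping: Sequence[int]) -> Volume:
    """Reorder/flip voxel axes while keeping every anatomical point at the same world coordinate.

    ``axis_mapping`` gives, per output axis, the signed 1-based source axis:
    (1, 2, 3) is identity, (-2, 1, 3) makes output axis 0 the reversed input
    axis 1.  Only orthogonal (permutation/flip) mappings are supported.
    """
    perm, signs = _parse_axis_mapping(axis_mapping)
    data = np.transpose(volume.data, axes=perm.tolist())
    for out_ax in range(3):
        if signs[out_ax] < 0:
            data = np.flip(data, axis=out_ax)
    data = np.ascontiguousarray(data)

    shape = np.asarray(volume.grid.shape)
    vox = np.asarray(volume.grid.voxel_size)
    d = volume.grid.direction_matrix
    # input index i = P j + b  =>  origin' = origin + D*S*b, column a of D' = sign*D[:, src]
    b = np.zeros(3)
    new_dir = np.zeros((3, 3))
    new_vox = np.zeros(3)
    for out_ax in range(3):
        src = perm[out_ax]
        new_vox[out_ax] = vox[src]
        new_dir[:, out_ax] = signs[out_ax] * d[:, src]
        if signs[out_ax] < 0:
            b[src] = shape[src] - 1
    new_origin = np.asarray(volume.grid.origin) + (d * vox) @ b
    grid = Grid(
        shape=tuple(int(s) for s in data.shape),
        voxel_size=tuple(new_vox),
        origin=tuple(new_origin),
        direction=tuple(tuple(row) for row in new_dir),
    )
    return Volume(data=data, grid=grid)


def resample(volume: Volume, factor: int | Sequence[int], mask: bool = False) -> Volume:
    """Downsample by integer block averaging (intensities) or majority vote (masks).

    The trailing partial block, if any, is zero-padded so the world extent is
    preserved to within one coarse voxel.  New voxel size is ``old * factor``.
    """
    f = np.asarray([factor] * 3 if np.isscalar(factor) else list(factor), dtype=int)
    if f.shape != (3,) or np.any(f < 1):
        raise ImagingError(f"resample factor must be >= 1 per axis, got {factor}")
    shape = np.asarray(volume.grid.shape)
    if np.any(f > shape):
        raise ImagingError(f"resample factor {tuple(f)} exceeds grid extent {tuple(shape)}")
    if np.all(f == 1):
        return Volume(data=volume.data.copy(), grid=volume.grid)

    padded_shape = -(-shape // f) * f  # ceil to a multiple of the factor
    pad = [(0, int(p - s)) for p, s in zip(padded_shape, shape)]
    data = np.pad(volume.data.astype(float), pad, mode="constant")
    new_shape = padded_shape // f
    blocks = data.reshape(
        new_shape[0], f[0], new_shape[1], f[1], new_shape[2], f[2]
    )
    means = blocks.mean(axis=(1, 3, 5))
    if mask:
        out = (means >= 0.5).astype(np.uint8)
    else:
        out = means

    vox = np.asarray(volume.grid.voxel_size)
    d = volume.grid.direction_matrix
    # coarse voxel center 0 sits at the mean of its fine-block centers
    shift = (d * vox) @ ((f - 1) / 2.0)
    grid = Grid(
        shape=tuple(int(s) for s in new_shape),
        voxel_size=tuple(vox * f),
        origin=tuple(np.asarray(volume.grid.origin) + shift),
        direction=volume.grid.direction,
    )
    return Volume(data=out, grid=grid)


def pet_sum(series: DynamicSeries) -> Volume:
    """Duration-weighted sum of the frames from the second half of the acquisition.

    A frame enters the sum iff its start time is at or past half the total
    acquisition time; each contributing frame is weighted by its duration.
    """
    half = series.schedule.total / 2.0
    sel = series.schedule.starts_arr >= half - 1e-9
    if not np.any(sel):
        raise ImagingError("no frame starts in the second half of the acquisition")
    weights = series.schedule.durations_arr[sel]
    data = np.tensordot(weights, series.data[sel], axes=(0, 0))
    return Volume(data=data, grid=series.grid)


# ---------------------------------------------------------------------------
# NIfTI + CSV I/O
# ---------------------------------------------------------------------------


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> Grid:
    m = affine[:3, :3]
    vox = np.linalg.norm(m, axis=0)
    if np.any(vox <= 0):
        raise ImagingError("NIfTI affine has a zero-length column (field: affine)")
    direction = m / vox
    return Grid(
        shape=tuple(int(s) for s in shape),
        voxel_size=tuple(vox),
        origin=tuple(affine[:3, 3]),
        direction=tuple(tuple(row) for row in direction),
    )


def write_volume(volume: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.grid.affine)
    nib.save(img, str(path))


def read_volume(path: str | Path, mask: bool = False) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ImagingError(f"expected 3-D volume in {path}, got ndim={data.ndim} (field: data)")
    vol = Volume(data=data, grid=_grid_from_affine(img.affine, data.shape))
    return vol.as_mask() if mask else vol


def write_series(series: DynamicSeries, image_path: str | Path, schedule_path: str | Path) -> None:
    data4 = np.moveaxis(np.asarray(series.data, dtype=np.float64), 0, -1)  # NIfTI stores t last
    img = nib.Nifti1Image(data4, series.grid.affine)
    nib.save(img, str(image_path))
    with open(schedule_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "duration_s"])
        for s, d in zip(series.schedule.starts, series.schedule.durations):
            writer.writerow([repr(float(s)), repr(float(d))])


def read_schedule_csv(path: str | Path) -> FrameSchedule:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ImagingError(f"empty schedule file {path} (field: start_s)")
    try:
        pairs = [(float(r["start_s"]), float(r["duration_s"])) for r in rows]
    except (KeyError, ValueError) as exc:
        raise ImagingError(f"malformed schedule file {path}: {exc}") from exc
    return make_schedule(pairs)


def read_series(image_path: str | Path, schedule_path: str | Path, state: str = "rest") -> DynamicSeries:
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ImagingError(f"expected 4-D series in {image_path} (field: data)")
    schedule = read_schedule_csv(schedule_path)
    data = np.moveaxis(data, -1, 0)
    if data.shape[0] != len(schedule):
        raise ImagingError(
            f"series has {data.shape[0]} frames but schedule lists {len(schedule)}"
        )
    return DynamicSeries(
        data=data,
        grid=_grid_from_affine(img.affine, data.shape[1:]),
        schedule=schedule,
        state=state,
    )


def read_masks(
    lv_path: str | Path, rv_path: str | Path, epi_path: str | Path, provenance: str = "M"
) -> AnatomyMasks:
    return AnatomyMasks(
        lv=read_volume(lv_path, mask=True),
        rv=read_volume(rv_path, mask=True),
        epi=read_volume(epi_path, mask=True),
        provenance=provenance,
    )


def write_masks(masks: AnatomyMasks, directory: str | Path, prefix: str = "") -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in (("lv", masks.lv), ("rv", masks.rv), ("epi", masks.epi)):
        p = directory / f"{prefix}{name}.nii.gz"
        write_volume(vol, p)
        paths[name] = p
    return paths
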