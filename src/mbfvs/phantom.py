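"""Digital biventricular phantom: anatomy, centerlines, kinetics truth and dynamic PET.

Geometry is generated short-axis aligned on a configurable isotropic grid
(default 96^3 at 2 mm).  The LV blood pool is a base-truncated ellipsoid, the
RV a lateral crescent, and the epicardial envelope the set of points within
one wall thickness of either pool, so the myocardial shell has near-constant
thickness by construction.  The myocardium is split into three vascular
territories (LAD / LCX / rPDA) by azimuthal nearest-seed labeling around the
LV long axis, and each territory carries rest/stress truth flows, optionally
reduced over lesion segments defined along a vessel's arc length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging import AnatomyMasks, DynamicSeries, FrameSchedule, Grid, Volume
from .kinetics import KineticParams, model_tissue_tac, _fine_grid, _sample_input, _frame_average
from .vessel_roi import Centerline, TAC, VESSEL_LABELS

__all__ = [
    "PhantomSpec",
    "PerturbationSpec",
    "InputFunctionParams",
    "Lesion",
    "TruthMaps",
    "generate_anatomy",
    "generate_centerline",
    "simulate_input_function",
    "input_function_curve",
    "simulate_dynamic_pet",
    "perturb_masks",
    "VESSEL_ANGLES_DEG",
]


class PhantomError(ValueError):
    pass


#: Azimuth (degrees, in the short-axis plane around the LV long axis) of each
#: vessel territory seed.  The RV crescent sits at 0 degrees (+x), so the
#: lateral wall (LCX) is opposite it.
VESSEL_ANGLES_DEG: dict[str, float] = {"LAD": 90.0, "LCX": 180.0, "rPDA": 270.0}


@dataclass(frozen=True)
class Lesion:
    """Flow reduction over an arc-length window of one vessel's territory."""

    vessel: str
    start_mm: float
    end_mm: float
    stress_factor: float = 0.5
    rest_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.vessel not in VESSEL_LABELS:
            raise PhantomError(f"unknown vessel {self.vessel!r}")
        if not (0 <= self.start_mm < self.end_mm):
            raise PhantomError("lesion window must satisfy 0 <= start < end")
        if not (0 < self.stress_factor <= 1 and 0 < self.rest_factor <= 1):
            raise PhantomError("lesion factors must be in (0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 2.0
    lv_radius_mm: float = 22.0
    rv_radius_mm: float = 16.0
    wall_thickness_mm: float = 10.0
    apex_extent_mm: float = 60.0
    flow_rest: dict | None = None  # per-territory mL/min/g
    flow_stress: dict | None = None
    k2_per_min: float = 0.3
    k3_per_min: float = 0.12
    v_b: float = 0.3
    lesions: tuple[Lesion, ...] = ()
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wall_thickness_mm <= 0 or self.lv_radius_mm <= 0 or self.rv_radius_mm <= 0:
            raise PhantomError("radii and wall thickness must be positive")
        if self.voxel_size_mm <= 0:
            raise PhantomError("voxel size must be positive")
        if not (0 <= self.v_b < 1):
            raise PhantomError("v_b must be in [0, 1)")
        if self.noise_scale < 0:
            raise PhantomError("noise_scale must be >= 0")
        for d in (self.flow_rest, self.flow_stress):
            if d is not None and any(v <= 0 for v in d.values()):
                raise PhantomError("truth flows must be positive")

    @property
    def rest_flows(self) -> dict[str, float]:
        return dict(self.flow_rest) if self.flow_rest else {v: 0.8 for v in VESSEL_LABELS}

    @property
    def stress_flows(self) -> dict[str, float]:
        return dict(self.flow_stress) if self.flow_stress else {v: 2.4 for v in VESSEL_LABELS}


@dataclass(frozen=True)
class PerturbationSpec:
    """Segmentation-defect model: apex truncation, RV encroachment, border jitter."""

    apex_truncation_slices: int = 0
    rv_dilation_mm: float = 0.0
    boundary_jitter_mm: float = 0.0
    septal_merge: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apex_truncation_slices < 0 or self.rv_dilation_mm < 0 or self.boundary_jitter_mm < 0:
            raise PhantomError("perturbation magnitudes must be >= 0")

    @property
    def is_zero(self) -> bool:
        return (
            self.apex_truncation_slices == 0
            and self.rv_dilation_mm == 0
            and self.boundary_jitter_mm == 0
            and not self.septal_merge
        )


@dataclass(frozen=True)
class InputFunctionParams:
    """Gamma-variate bolus (normalized so the peak value equals ``amplitude``)
    plus an optional saturating recirculation tail."""

    amplitude: float = 100.0  # kBq/mL at peak
    t0_s: float = 10.0
    alpha: float = 3.0
    beta_s: float = 12.0
    recirculation_tail_fraction: float = 0.15
    tail_timescale_s: float = 90.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta_s <= 0:
            raise PhantomError("gamma-variate shape alpha and scale beta must be positive")
        if not (0 <= self.recirculation_tail_fraction < 1):
            raise PhantomError("recirculation tail fraction must be in [0, 1)")


@dataclass
class TruthMaps:
    """Ground-truth companion of the generated anatomy."""

    territory: Volume  # 0 = none, 1..3 = LAD/LCX/rPDA
    flow_rest: Volume  # mL/min/g per myocardial voxel
    flow_stress: Volume
    centerlines: dict[str, Centerline]
    heart_center_mm: np.ndarray
    spec: PhantomSpec

    TERRITORY_CODES = {"LAD": 1, "LCX": 2, "rPDA": 3}

    def flow_volume(self, state: str) -> Volume:
        if state == "rest":
            return self.flow_rest
        if state == "stress":
            return self.flow_stress
        raise PhantomError(f"state must be 'rest' or 'stress', got {state!r}")


def _world_axes(spec: PhantomSpec) -> tuple[Grid, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    shape = tuple(int(n) for n in spec.grid_shape)
    vox = float(spec.voxel_size_mm)
    grid = Grid(shape=shape, voxel_size=(vox, vox, vox))
    ax = [np.arange(n) * vox for n in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    center = np.array([(n - 1) * vox / 2.0 for n in shape])
    return grid, x, y, z, center


def generate_anatomy(spec: PhantomSpec) -> tuple[AnatomyMasks, TruthMaps]:
    """Build the binary anatomy and its truth maps.  Deterministic given the spec."""
    grid, x, y, z, center = _world_axes(spec)
    vox = spec.voxel_size_mm
    extent = np.asarray(spec.grid_shape) * vox

    a = spec.lv_radius_mm
    b = 0.85 * a  # mild in-plane ellipticity: real LVs are not perfectly round
    c = spec.apex_extent_mm
    w = spec.wall_thickness_mm
    needed = 2.0 * (a + spec.rv_radius_mm + 2 * w)
    if needed > extent[0] or needed > extent[1] or 1.4 * c + 2 * w > extent[2]:
        raise PhantomError(
            f"modeled heart (~{needed:.0f} mm wide, {1.4 * c + 2 * w:.0f} mm long) "
            f"does not fit the {tuple(extent)} mm grid"
        )

    cx, cy, cz = center
    z_base = cz + 0.55 * c
    dx, dy, dz = x - cx, y - cy, z - cz

    lv = ((dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0) & (z <= z_base)

    d_lv = ndimage.distance_transform_edt(~lv, sampling=(vox, vox, vox))
    rv_outer = (
        ((dx / (a + w + spec.rv_radius_mm)) ** 2
         + (dy / (b + w + spec.rv_radius_mm)) ** 2
         + (dz / (0.85 * c)) ** 2)
        <= 1.0
    )
    rv = rv_outer & (d_lv >= w) & (dx > 0.15 * a) & (z <= z_base) & (dz >= -0.45 * c)

    pools = lv | rv
    d_pool = ndimage.distance_transform_edt(~pools, sampling=(vox, vox, vox))
    epi = (d_pool <= w) & (z <= z_base)
    epi |= pools  # numerical safety at pool voxels (d_pool = 0 there anyway)

    if not np.any(rv):
        raise PhantomError("RV pool is empty; enlarge the grid or shrink the LV")

    masks = AnatomyMasks(
        lv=Volume(lv.astype(np.uint8), grid),
        rv=Volume(rv.astype(np.uint8), grid),
        epi=Volume(epi.astype(np.uint8), grid),
        provenance="M",
    )

    # azimuthal nearest-seed territory labels over the full myocardium
    myo = masks.myocardium
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    territory = np.zeros(grid.shape, dtype=np.int16)
    seed_angles = np.array([VESSEL_ANGLES_DEG[v] for v in VESSEL_LABELS])
    ang = theta[myo]
    diffs = np.abs(ang[:, None] - seed_angles[None, :])
    diffs = np.minimum(diffs, 360.0 - diffs)
    territory[myo] = np.argmin(diffs, axis=1) + 1

    truth = TruthMaps(
        territory=Volume(territory, grid),
        flow_rest=Volume(np.zeros(grid.shape), grid),
        flow_stress=Volume(np.zeros(grid.shape), grid),
        centerlines={},
        heart_center_mm=center,
        spec=spec,
    )
    for vessel in VESSEL_LABELS:
        truth.centerlines[vessel] = generate_centerline(masks, vessel, n_points=60)

    flow_rest = np.zeros(grid.shape)
    flow_stress = np.zeros(grid.shape)
    rest_flows, stress_flows = spec.rest_flows, spec.stress_flows
    for vessel, code in TruthMaps.TERRITORY_CODES.items():
        sel = territory == code
        flow_rest[sel] = rest_flows[vessel]
        flow_stress[sel] = stress_flows[vessel]

    for lesion in spec.lesions:
        code = TruthMaps.TERRITORY_CODES[lesion.vessel]
        cl = truth.centerlines[lesion.vessel]
        sel = np.argwhere(territory == code)
        pts = grid.index_to_world(sel)
        # arc position of each territory voxel = arc length of nearest path point
        al = cl.arc_length
        d2 = ((pts[:, None, :] - cl.points[None, :, :]) ** 2).sum(axis=2)
        s_vox = al[np.argmin(d2, axis=1)]
        hit = (s_vox >= lesion.start_mm) & (s_vox <= lesion.end_mm)
        ii = sel[hit]
        flow_rest[ii[:, 0], ii[:, 1], ii[:, 2]] *= lesion.rest_factor
        flow_stress[ii[:, 0], ii[:, 1], ii[:, 2]] *= lesion.stress_factor

    truth.flow_rest = Volume(flow_rest, grid)
    truth.flow_stress = Volume(flow_stress, grid)
    return masks, truth


def generate_centerline(anatomy: AnatomyMasks, vessel: str, n_points: int = 60) -> Centerline:
    """Trace an epicardial-surface path for a vessel, base to apex.

    At each short-axis level the path point is the epicardial surface crossing
    along the territory's azimuthal ray, found at sub-voxel precision on the
    blood-pool distance transform.
    """
    if vessel not in VESSEL_ANGLES_DEG:
        raise PhantomError(f"unknown vessel label {vessel!r}; choose from {sorted(VESSEL_ANGLES_DEG)}")
    if n_points < 2:
        raise PhantomError("n_points must be >= 2")

    grid = anatomy.grid
    vox = np.asarray(grid.voxel_size)
    epi = anatomy.epi.bool()
    lv_idx = np.argwhere(anatomy.lv.bool())
    lv_center = grid.index_to_world(lv_idx).mean(axis=0)
    theta = np.radians(VESSEL_ANGLES_DEG[vessel])
    u = np.array([np.cos(theta), np.sin(theta), 0.0])

    zs_epi = np.argwhere(epi)[:, 2]
    z_top = zs_epi.max()
    z_bot = zs_epi.min()
    z_world_top = grid.index_to_world(np.array([0, 0, z_top]))[0][2]
    z_world_bot = grid.index_to_world(np.array([0, 0, z_bot]))[0][2]

    levels = np.linspace(z_world_top - vox[2], z_world_bot + vox[2], n_points)
    r_fine = np.arange(0.0, 0.6 * min(grid.shape[0] * vox[0], grid.shape[1] * vox[1]), vox[0] / 4.0)

    epi_f = ndimage.distance_transform_edt(~epi, sampling=tuple(vox))
    pts = []
    for zw in levels:
        ray = lv_center[None, :] + r_fine[:, None] * u[None, :]
        ray[:, 2] = zw
        ridx = grid.world_to_index(ray)
        d = ndimage.map_coordinates(epi_f, ridx.T, order=1, mode="nearest")
        inside = d <= 1e-6
        if not np.any(inside):
            continue
        r_surf = r_fine[np.max(np.nonzero(inside))]
        pts.append(lv_center + r_surf * u + np.array([0.0, 0.0, zw - lv_center[2]]))
    if len(pts) < 2:
        raise PhantomError(f"could not trace a centerline for {vessel}")
    return Centerline(points=np.asarray(pts), vessel=vessel)


# ---------------------------------------------------------------------------
# input function and dynamic simulation
# ---------------------------------------------------------------------------


def input_function_curve(params: InputFunctionParams):
    """Continuous arterial input Ca(t), t in seconds."""

    def ca(t):
        t = np.asarray(t, dtype=float)
        tau = t - params.t0_s
        out = np.zeros_like(tau)
        pos = tau > 0
        x = tau[pos] / (params.alpha * params.beta_s)
        bolus = params.amplitude * np.power(x, params.alpha) * np.exp(
            params.alpha - tau[pos] / params.beta_s
        )
        tail = (
            params.recirculation_tail_fraction
            * params.amplitude
            * (1.0 - np.exp(-tau[pos] / params.tail_timescale_s))
        )
        out[pos] = bolus + tail
        return out

    return ca


def simulate_input_function(params: InputFunctionParams, times_s: np.ndarray) -> TAC:
    """Sample the arterial input at the given time points (returned as a TAC)."""
    times_s = np.asarray(times_s, dtype=float)
    if times_s.size < 2 or np.any(times_s < 0) or np.any(np.diff(times_s) <= 0):
        raise PhantomError("times must be non-negative and strictly increasing")
    vals = input_function_curve(params)(times_s)
    return TAC(
        mid_times=times_s,
        durations=np.gradient(times_s),
        values=vals,
        source="arterial-truth",
    )


def simulate_dynamic_pet(
    anatomy: AnatomyMasks,
    truth: TruthMaps,
    input_params: InputFunctionParams,
    schedule: FrameSchedule,
    state: str = "rest",
    noise_scale: float | None = None,
    seed: int | None = None,
) -> DynamicSeries:
    """Simulate a dynamic frame series from the voxelwise kinetic truth.

    Myocardial voxels follow the 2-tissue model with territory truth flow as
    K1; blood-pool voxels carry the frame-averaged input curve; voxels outside
    the envelope are zero.  Gaussian noise with variance proportional to
    activity / frame duration is added when ``noise_scale > 0``, seeded.
    """
    spec = truth.spec
    noise_scale = spec.noise_scale if noise_scale is None else noise_scale
    seed = spec.seed if seed is None else seed
    flow = truth.flow_volume(state).data
    myo = anatomy.myocardium
    if not np.any(flow[myo] > 0):
        raise PhantomError(f"truth flow volume for state {state!r} is empty")

    ca = input_function_curve(input_params)
    t_s = _fine_grid(schedule, 0.1)
    ca_fine = _sample_input(ca, t_s)
    ca_frames = _frame_average(t_s, ca_fine, schedule)

    n_frames = len(schedule)
    data = np.zeros((n_frames, *anatomy.grid.shape))
    pools = anatomy.lv.bool() | anatomy.rv.bool()
    data[:, pools] = ca_frames[:, None]

    # one forward model evaluation per distinct truth flow value
    for k1 in np.unique(flow[myo]):
        if k1 <= 0:
            continue
        params = KineticParams(K1=float(k1), k2=spec.k2_per_min, k3=spec.k3_per_min, v_b=spec.v_b)
        tac = model_tissue_tac(params, ca, schedule)
        sel = myo & (flow == k1)
        data[:, sel] = tac.values[:, None]

    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_scale * np.sqrt(
            np.maximum(data, 0.0) / schedule.durations_arr[:, None, None, None]
        )
        data = data + rng.normal(size=data.shape) * sigma

    return DynamicSeries(data=data, grid=anatomy.grid, schedule=schedule, state=state)


# ---------------------------------------------------------------------------
# segmentation-defect perturbations
# ---------------------------------------------------------------------------


def perturb_masks(masks: AnatomyMasks, spec: PerturbationSpec, provenance: str = "FA") -> AnatomyMasks:
    """Apply segmentation-defect perturbations; a zero spec returns bit-identical masks."""
    lv = masks.lv.bool().copy()
    rv = masks.rv.bool().copy()
    epi = masks.epi.bool().copy()
    vox = np.asarray(masks.grid.voxel_size)

    if spec.boundary_jitter_mm > 0:
        # seeded smooth noise field perturbs the signed distance of the
        # envelope; amplitude-scaling one fixed field keeps the flipped voxel
        # set monotone in the jitter magnitude
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(size=epi.shape)
        noise = ndimage.gaussian_filter(noise, sigma=2.0)
        noise /= max(np.abs(noise).max(), 1e-12)
        d_in = ndimage.distance_transform_edt(epi, sampling=tuple(vox))
        d_out = ndimage.distance_transform_edt(~epi, sampling=tuple(vox))
        signed = np.where(epi, -d_in, d_out)  # negative inside
        epi = signed + spec.boundary_jitter_mm * noise <= 0

    if spec.rv_dilation_mm > 0:
        d_rv = ndimage.distance_transform_edt(~rv, sampling=tuple(vox))
        rv = rv | ((d_rv <= spec.rv_dilation_mm) & ~lv)

    if spec.septal_merge:
        # bridge the septal gap: voxels near both pools absorbed into the RV
        d_rv = ndimage.distance_transform_edt(~rv, sampling=tuple(vox))
        d_lv = ndimage.distance_transform_edt(~lv, sampling=tuple(vox))
        bridge = (d_rv <= 1.5 * max(vox)) & (d_lv <= 1.5 * max(vox)) & ~lv
        rv = rv | bridge

    epi = epi | lv | rv  # pools must stay inside the envelope

    if spec.apex_truncation_slices > 0:
        zs = np.nonzero(epi.any(axis=(0, 1)))[0]
        if spec.apex_truncation_slices >= zs.size:
            raise PhantomError(
                f"apex truncation of {spec.apex_truncation_slices} slices exceeds the "
                f"{zs.size}-slice myocardial extent"
            )
        cut = zs[: spec.apex_truncation_slices]  # apex = low-z end
        lv[:, :, cut] = False
        rv[:, :, cut] = False
        epi[:, :, cut] = False

    grid = masks.grid
    return AnatomyMasks(
        lv=Volume(lv.astype(np.uint8), grid),
        rv=Volume(rv.astype(np.uint8), grid),
        epi=Volume(epi.astype(np.uint8), grid),
        provenance=provenance,
    )
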