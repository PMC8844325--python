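"""End-to-end mask-robustness experiment at phantom scale.

For each seeded phantom: simulate dynamic PET, fuse it with the reference
("M") anatomy and with perturbed variants ("FA", "C", optionally "C2"),
extract per-vessel flow profiles, classify them against low-risk ranges, and
score classification agreement with Dice coefficients, pooled globally and per
territory, with Student's t tests between mask modes.  Fully reproducible from
the config seeds.
"""

from __future__ import annotations

import dataclasses
import json
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classification as cls
from . import fusion, kinetics, phantom, vessel_roi
from .imaging import AnatomyMasks, DynamicSeries, Volume, make_schedule, pet_sum
from .phantom import InputFunctionParams, Lesion, PerturbationSpec, PhantomSpec

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_mask_comparison_experiment",
    "analyze_case",
    "default_normal_ranges",
]


@dataclass(frozen=True)
class ExperimentConfig:
    n_phantoms: int = 5
    seed: int = 0
    schedule_preset: str = "SNUH"
    states: tuple[str, ...] = ("stress", "rest")
    vessels: tuple[str, ...] = ("LAD", "LCX", "rPDA")
    roi_length_mm: float = 4.0
    dc_mode: str = "matched-fraction"
    noise_scale: float = 0.5
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 3.0
    fa_spec: PerturbationSpec = PerturbationSpec(apex_truncation_slices=2, rv_dilation_mm=4.0,
                                                boundary_jitter_mm=1.0)
    c_spec: PerturbationSpec = PerturbationSpec(apex_truncation_slices=0, rv_dilation_mm=0.0,
                                               boundary_jitter_mm=0.5)
    c2_spec: PerturbationSpec | None = None
    ct_offset_max_mm: float = 8.0
    ct_offset_max_deg: float = 8.0
    randomize_lesions: bool = True
    lesion_stress_factor: float = 0.5
    rest_lower: float = 0.6
    stress_lower: float = 1.8
    range_upper: float = 10.0
    fit_vb: bool = True
    output_dir: str | None = None

    def to_dict(self) -> dict[str, Any]:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(getattr(v, k)) for k in v.__dataclass_fields__}
            if isinstance(v, tuple):
                return list(v)
            return v

        return {k: enc(getattr(self, k)) for k in self.__dataclass_fields__}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown experiment config keys: {sorted(unknown)}")
        for key in ("fa_spec", "c_spec", "c2_spec"):
            if key in d and isinstance(d[key], dict):
                d[key] = PerturbationSpec(**d[key])
        for key in ("states", "vessels", "grid_shape"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_normal_ranges(config: ExperimentConfig, span_mm: float = 250.0) -> dict[tuple[str, str], cls.NormalRange]:
    """Flat low-risk bands (convention, not a measured cohort): abnormal below
    0.6 / 1.8 mL/min/g at rest / stress."""
    out = {}
    for vessel in config.vessels:
        for state in config.states:
            lower = config.rest_lower if state == "rest" else config.stress_lower
            out[(vessel, state)] = cls.NormalRange(
                vessel=vessel,
                state=state,
                positions=np.array([0.0, span_mm]),
                lower=np.array([lower, lower]),
                upper=np.array([config.range_upper, config.range_upper]),
            )
    return out


def _reframe_masks(masks: AnatomyMasks, offset: fusion.RigidTransform) -> AnatomyMasks:
    """Re-express masks in a CT world frame displaced by ``offset`` (no resampling)."""
    grid = masks.grid.with_affine_offset(offset.matrix, offset.translation_vec)
    return AnatomyMasks(
        lv=Volume(masks.lv.data, grid),
        rv=Volume(masks.rv.data, grid),
        epi=Volume(masks.epi.data, grid),
        provenance=masks.provenance,
    )


def _random_offset(rng: np.random.Generator, max_mm: float, max_deg: float) -> fusion.RigidTransform:
    angles = rng.uniform(-max_deg, max_deg, size=3)
    trans = rng.uniform(-max_mm, max_mm, size=3)
    return fusion.RigidTransform.from_params(angles, trans)


def analyze_case(
    series: DynamicSeries,
    masks_ct: AnatomyMasks,
    centerlines_ct: dict[str, vessel_roi.Centerline],
    vessels: Sequence[str],
    roi_length_mm: float = 4.0,
    fit_vb: bool = True,
    provenance: str | None = None,
) -> tuple[dict[str, kinetics.FlowProfile], fusion.RigidTransform]:
    """Register one anatomy onto one dynamic series and extract all vessel profiles."""
    psum = pet_sum(series)
    lv_pet = fusion.segment_lv_from_pet(psum, threshold_fraction=0.5)
    init = fusion.register_rigid_lv(lv_pet, masks_ct.epi)
    transform = fusion.refine_mutual_information(psum, masks_ct, init)
    fused = fusion.fuse_masks(masks_ct, series.grid, transform)
    ca = vessel_roi.arterial_input_tac(series, fused, erosion_mm=4.0)
    tag = provenance or masks_ct.provenance
    profiles = {}
    for vessel in vessels:
        cl_pet = fusion.transform_centerline(centerlines_ct[vessel], transform)
        rois = vessel_roi.subtended_rois(cl_pet, fused, roi_length_mm=roi_length_mm)
        profiles[vessel] = kinetics.vessel_flow_profile(
            rois, series, ca, provenance=tag, fit_vb=fit_vb
        )
    return profiles, transform


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    records: pd.DataFrame  # per phantom/state/pair/vessel DC rows
    pooled: pd.DataFrame  # Table-2 layout: pooled DC per pair/state/group
    ttests: pd.DataFrame
    seeds: dict[str, Any]
    profiles: list[dict[str, Any]] = field(default_factory=list)  # plotting payloads

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "config": self.config.to_dict(),
            "records": self.records.to_dict(orient="records"),
            "pooled": self.pooled.to_dict(orient="records"),
            "ttests": self.ttests.to_dict(orient="records"),
            "seeds": self.seeds,
        }

    def write(self, out_dir: str | Path, plots: bool = True, overwrite: bool = False) -> Path:
        """Atomically materialize the report (stage to a temp dir, then rename)."""
        out_dir = Path(out_dir)
        if out_dir.exists():
            if not overwrite:
                raise FileExistsError(f"output directory {out_dir} already exists")
        out_dir.parent.mkdir(parents=True, exist_ok=True)
        stage = Path(tempfile.mkdtemp(prefix=out_dir.name + ".tmp-", dir=out_dir.parent))
        try:
            self.config.to_yaml(stage / "config.yaml")
            (stage / "seed_manifest.json").write_text(json.dumps(self.seeds, indent=2))
            self.records.to_csv(stage / "dc_records.csv", index=False)
            self.pooled.to_csv(stage / "dc_pooled.csv", index=False)
            self.ttests.to_csv(stage / "ttests.csv", index=False)
            (stage / "summary.json").write_text(json.dumps(self.to_json_dict(), indent=2))
            if plots and self.profiles:
                self._write_plots(stage / "plots")
            if out_dir.exists():
                shutil.rmtree(out_dir)
            os.replace(stage, out_dir)
        except Exception:
            shutil.rmtree(stage, ignore_errors=True)
            raise
        return out_dir

    def _write_plots(self, plot_dir: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plot_dir.mkdir(parents=True, exist_ok=True)
        colors = {"M": "tab:blue", "FA": "magenta", "C": "green", "C2": "darkorange"}
        for payload in self.profiles:
            fig, ax = plt.subplots(figsize=(6, 4))
            band = payload["range"]
            ax.fill_between(
                band["positions"], band["lower"], band["upper"], color="0.85", label="low-risk range"
            )
            for role, prof in payload["profiles"].items():
                s, v = kinetics.interpolate_profile(prof)
                ax.plot(s, v, color=colors.get(role, "k"), label=role)
                ax.plot(prof.positions, prof.mbf, "*", color=colors.get(role, "k"), ms=5)
            ax.set_xlabel("distance from base (mm)")
            ax.set_ylabel("MBF (mL/min/g)")
            ax.set_ylim(bottom=0)
            ax.set_title(f"phantom {payload['phantom']} {payload['vessel']} {payload['state']}")
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(
                plot_dir
                / f"phantom{payload['phantom']:02d}_{payload['vessel']}_{payload['state']}.png",
                dpi=110,
            )
            plt.close(fig)


def run_mask_comparison_experiment(
    config: ExperimentConfig, keep_profiles: bool = True
) -> ExperimentReport:
    schedule = make_schedule(config.schedule_preset)
    ranges = default_normal_ranges(config)
    input_params = InputFunctionParams()
    master = np.random.default_rng(config.seed)
    phantom_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=config.n_phantoms)]

    roles: dict[str, PerturbationSpec] = {
        "M": PerturbationSpec(),
        "FA": config.fa_spec,
        "C": config.c_spec,
    }
    if config.c2_spec is not None:
        roles["C2"] = config.c2_spec
    pair_defs = [("FA", "M"), ("C", "M")]
    if "C2" in roles:
        pair_defs.append(("C2", "C"))

    rows = []
    profile_payloads = []
    pooled_inputs: dict[tuple[str, str], list] = {}

    for i, pseed in enumerate(phantom_seeds):
        rng = np.random.default_rng(pseed)
        lesions: tuple[Lesion, ...] = ()
        if config.randomize_lesions:
            vessel = str(rng.choice(list(config.vessels)))
            start = float(rng.uniform(20.0, 55.0))
            lesions = (
                Lesion(
                    vessel=vessel,
                    start_mm=start,
                    end_mm=start + 20.0,
                    stress_factor=config.lesion_stress_factor,
                ),
            )
        spec = PhantomSpec(
            grid_shape=config.grid_shape,
            voxel_size_mm=config.voxel_size_mm,
            lv_radius_mm=18.0,
            rv_radius_mm=12.0,
            wall_thickness_mm=9.0,
            apex_extent_mm=50.0,
            lesions=lesions,
            noise_scale=config.noise_scale,
            seed=pseed,
        )
        masks, truth = phantom.generate_anatomy(spec)
        offset = _random_offset(rng, config.ct_offset_max_mm, config.ct_offset_max_deg)
        centerlines_ct = {
            v: vessel_roi.Centerline(points=offset.apply(c.points), vessel=v)
            for v, c in truth.centerlines.items()
        }
        role_masks = {
            role: _reframe_masks(
                phantom.perturb_masks(masks, pspec, provenance=role), offset
            )
            for role, pspec in roles.items()
        }

        for state in config.states:
            series = phantom.simulate_dynamic_pet(
                masks, truth, input_params, schedule, state=state,
                noise_scale=config.noise_scale,
                seed=pseed + (0 if state == "rest" else 1),
            )
            role_profiles: dict[str, dict[str, kinetics.FlowProfile]] = {}
            for role, mct in role_masks.items():
                try:
                    profiles, _ = analyze_case(
                        series, mct, centerlines_ct, config.vessels,
                        roi_length_mm=config.roi_length_mm, fit_vb=config.fit_vb,
                        provenance=role,
                    )
                    role_profiles[role] = profiles
                except (vessel_roi.RoiError, fusion.FusionError) as exc:
                    rows.append(
                        {
                            "phantom": i, "state": state, "pair": f"{role}-failed",
                            "vessel": "all", "dc": np.nan, "n": 0, "error": str(exc),
                        }
                    )

            for test_role, ref_role in pair_defs:
                if test_role not in role_profiles or ref_role not in role_profiles:
                    continue
                pair_key = (f"{test_role}_vs_{ref_role}", state)
                for vessel in config.vessels:
                    ptest = role_profiles[test_role][vessel]
                    pref = role_profiles[ref_role][vessel]
                    band = ranges[(vessel, state)]
                    va = cls.classify(ptest, band)
                    vb = cls.classify(pref, band)
                    res = cls.dice_agreement(va, vb, mode=config.dc_mode, group=vessel)
                    rows.append(
                        {
                            "phantom": i, "state": state,
                            "pair": pair_key[0], "vessel": vessel,
                            "dc": res.dc, "n": res.n, "error": "",
                        }
                    )
                    pooled_inputs.setdefault(pair_key, []).append((va, vb))

            if keep_profiles and role_profiles:
                for vessel in config.vessels:
                    band = ranges[(vessel, state)]
                    profile_payloads.append(
                        {
                            "phantom": i,
                            "vessel": vessel,
                            "state": state,
                            "profiles": {
                                role: profs[vessel] for role, profs in role_profiles.items()
                            },
                            "range": {
                                "positions": band.positions.tolist(),
                                "lower": band.lower.tolist(),
                                "upper": band.upper.tolist(),
                            },
                        }
                    )

    records = pd.DataFrame(rows)

    pooled_frames = []
    for (pair, state), pairs in pooled_inputs.items():
        df = cls.pool_agreement(pairs, mode=config.dc_mode)
        df.insert(0, "state", state)
        df.insert(0, "pair", pair)
        pooled_frames.append(df)
    pooled = pd.concat(pooled_frames, ignore_index=True) if pooled_frames else pd.DataFrame()

    # paired t tests between mask modes over matched per-phantom/vessel DC values
    ttest_rows = []
    ok = records[records["dc"].notna()] if not records.empty else records
    for state in config.states:
        sub = ok[ok["state"] == state] if not ok.empty else ok
        pivots = {}
        for pair in sub["pair"].unique() if not sub.empty else []:
            p = sub[sub["pair"] == pair].set_index(["phantom", "vessel"])["dc"]
            pivots[pair] = p
        names = sorted(pivots)
        for idx_a in range(len(names)):
            for idx_b in range(idx_a + 1, len(names)):
                pa, pb = pivots[names[idx_a]], pivots[names[idx_b]]
                common = pa.index.intersection(pb.index)
                if common.size < 2:
                    continue
                res = cls.compare_dc_groups(
                    pa.loc[common].to_numpy(), pb.loc[common].to_numpy(), paired=True
                )
                ttest_rows.append(
                    {
                        "state": state, "group_a": names[idx_a], "group_b": names[idx_b],
                        "t": res.t, "p": res.p, "n": int(common.size),
                        "paired": True, "degenerate": res.degenerate,
                    }
                )
    ttests = pd.DataFrame(ttest_rows)

    return ExperimentReport(
        config=config,
        records=records,
        pooled=pooled,
        ttests=ttests,
        seeds={"master_seed": config.seed, "phantom_seeds": phantom_seeds},
        profiles=profile_payloads if keep_profiles else [],
    )
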