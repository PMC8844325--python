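import numpy as np
import pytest
from scipy import ndimage
from scipy.integrate import quad, solve_ivp

from mbfvs.imaging import make_schedule
from mbfvs.phantom import (
    InputFunctionParams,
    Lesion,
    PerturbationSpec,
    PhantomError,
    PhantomSpec,
    generate_anatomy,
    generate_centerline,
    input_function_curve,
    perturb_masks,
    simulate_dynamic_pet,
    simulate_input_function,
)


class TestGenerateAnatomy:
    def test_pool_disjointness_and_containment(self, phantom_default):
        _, masks, _ = phantom_default
        lv, rv, epi = masks.lv.bool(), masks.rv.bool(), masks.epi.bool()
        assert not np.any(lv & rv)
        assert np.all(epi[lv]) and np.all(epi[rv])
        assert np.any(epi & ~lv & ~rv)

    def test_wall_thickness_distance_transform_oracle(self, phantom_default):
        # oracle: local thickness at a myocardial voxel ~ distance to the
        # blood pools + distance to the outside of the envelope
        spec, masks, _ = phantom_default
        vox = masks.grid.voxel_size
        pools = masks.lv.bool() | masks.rv.bool()
        d_pool = ndimage.distance_transform_edt(~pools, sampling=vox)
        d_out = ndimage.distance_transform_edt(masks.epi.bool(), sampling=vox)
        myo = masks.myocardium
        # exclude the base cut plane, where the shell is open
        zs = np.nonzero(myo.any(axis=(0, 1)))[0]
        interior = myo.copy()
        interior[:, :, zs[-2:]] = False
        # center-to-center EDT distances overshoot by half a voxel at each of
        # the two interfaces; correct by one voxel total
        thickness = d_pool[interior] + d_out[interior] - max(vox)
        assert abs(thickness.mean() - spec.wall_thickness_mm) <= max(vox)

    def test_every_myocardial_voxel_labeled(self, phantom_default):
        _, masks, truth = phantom_default
        myo = masks.myocardium
        labels = truth.territory.data[myo]
        assert np.all(np.isin(labels, (1, 2, 3)))
        assert np.all(truth.territory.data[~myo] == 0)
        assert np.all(truth.flow_rest.data[myo] > 0)
        assert np.all(truth.flow_stress.data[myo] > 0)

    def test_determinism(self, small_spec):
        m1, t1 = generate_anatomy(small_spec)
        m2, t2 = generate_anatomy(small_spec)
        assert np.array_equal(m1.lv.data, m2.lv.data)
        assert np.array_equal(m1.rv.data, m2.rv.data)
        assert np.array_equal(m1.epi.data, m2.epi.data)
        assert np.array_equal(t1.flow_stress.data, t2.flow_stress.data)

    def test_heart_must_fit_grid(self):
        with pytest.raises(PhantomError, match="does not fit"):
            generate_anatomy(PhantomSpec(grid_shape=(32, 32, 32), voxel_size_mm=2.0))

    def test_lesion_reduces_stress_flow_only_in_window(self, small_spec):
        import dataclasses

        lesioned = dataclasses.replace(
            small_spec, lesions=(Lesion(vessel="LAD", start_mm=40, end_mm=60, stress_factor=0.5),)
        )
        _, t_plain = generate_anatomy(small_spec)
        masks, t_les = generate_anatomy(lesioned)
        changed = t_plain.flow_stress.data != t_les.flow_stress.data
        assert np.any(changed)
        # only LAD-territory voxels change, and rest flow is untouched
        assert np.all(t_les.territory.data[changed] == 1)
        assert np.array_equal(t_plain.flow_rest.data, t_les.flow_rest.data)


class TestCenterline:
    def test_two_point_arc_length(self, phantom_small):
        masks, _ = phantom_small
        cl = generate_centerline(masks, "LAD", n_points=2)
        expected = np.linalg.norm(cl.points[1] - cl.points[0])
        assert np.isclose(cl.total_length, expected)

    def test_points_near_epi_surface(self, phantom_default):
        _, masks, truth = phantom_default
        cl = truth.centerlines["LAD"]
        vox = max(masks.grid.voxel_size)
        epi = masks.epi.bool()
        d_out = ndimage.distance_transform_edt(~epi, sampling=masks.grid.voxel_size)
        d_in = ndimage.distance_transform_edt(epi, sampling=masks.grid.voxel_size)
        surf_dist = np.minimum(d_out, d_in)  # 0 on the surface shell
        idx = masks.grid.world_to_index(cl.points)
        vals = ndimage.map_coordinates(surf_dist, idx.T, order=1)
        assert np.all(vals <= vox)

    def test_reversal_maps_arc_length(self, phantom_small):
        masks, truth = phantom_small
        cl = truth.centerlines["LCX"]
        rev = cl.reversed()
        L = cl.total_length
        assert np.allclose(rev.arc_length, L - cl.arc_length[::-1])

    def test_unknown_vessel(self, phantom_small):
        masks, _ = phantom_small
        with pytest.raises(PhantomError, match="unknown vessel"):
            generate_centerline(masks, "LIMA")


class TestInputFunction:
    def test_zero_at_and_before_t0(self):
        p = InputFunctionParams(t0_s=15.0)
        t = np.array([0.0, 5.0, 14.9, 15.0])
        tac = simulate_input_function(p, t)
        assert np.all(tac.values == 0)

    def test_peak_at_t0_plus_alpha_beta(self):
        # dCa/dt = 0 at tau = alpha * beta for the pure gamma variate
        p = InputFunctionParams(t0_s=10.0, alpha=3.0, beta_s=12.0, recirculation_tail_fraction=0.0)
        ca = input_function_curve(p)
        t_peak = 10.0 + 3.0 * 12.0
        t = np.linspace(0, 200, 20001)
        assert abs(t[np.argmax(ca(t))] - t_peak) < 0.02

    def test_amplitude_linearity(self):
        t = np.linspace(0, 300, 301)
        a = input_function_curve(InputFunctionParams(amplitude=50.0))(t)
        b = input_function_curve(InputFunctionParams(amplitude=100.0))(t)
        assert np.allclose(b, 2 * a)

    def test_nonnegative(self):
        t = np.linspace(0, 600, 6001)
        vals = input_function_curve(InputFunctionParams())(t)
        assert np.all(vals >= 0)

    def test_bad_params(self):
        with pytest.raises(PhantomError):
            InputFunctionParams(alpha=0.0)
        with pytest.raises(PhantomError):
            InputFunctionParams(beta_s=-1.0)
        with pytest.raises(PhantomError):
            InputFunctionParams(recirculation_tail_fraction=1.0)

    def test_times_validation(self):
        with pytest.raises(PhantomError):
            simulate_input_function(InputFunctionParams(), np.array([3.0, 2.0]))


class TestSimulateDynamicPet:
    def test_blood_pool_equals_frame_averaged_ca(self, phantom_small, input_params, series_clean):
        masks, _ = phantom_small
        sched = series_clean.schedule
        ca = input_function_curve(input_params)
        # independent frame-average oracle by adaptive quadrature
        expected = np.array(
            [
                quad(ca, s, s + d, limit=200)[0] / d
                for s, d in zip(sched.starts, sched.durations)
            ]
        )
        iv, jv, kv = np.argwhere(masks.lv.bool())[0]
        got = series_clean.data[:, iv, jv, kv]
        assert np.allclose(got, expected, rtol=1e-4, atol=1e-6)

    def test_myocardial_voxel_matches_ode_oracle(self, phantom_small, input_params, series_clean):
        # independent oracle: integrate the compartment ODEs with solve_ivp
        masks, truth = phantom_small
        spec = truth.spec
        sched = series_clean.schedule
        ca = input_function_curve(input_params)
        myo_idx = np.argwhere(masks.myocardium)
        iv, jv, kv = myo_idx[len(myo_idx) // 2]
        k1 = truth.flow_stress.data[iv, jv, kv]
        k2, k3, vb = spec.k2_per_min, spec.k3_per_min, spec.v_b

        def rhs(t, y):  # t in seconds, rates per minute
            c1, c2 = y
            return [(k1 * ca(t) - (k2 + k3) * c1) / 60.0, k3 * c1 / 60.0]

        sol = solve_ivp(rhs, (0, sched.total), [0.0, 0.0], rtol=1e-9, atol=1e-12, dense_output=True)

        def measured(t):
            c1, c2 = sol.sol(t)
            return (1 - vb) * (c1 + c2) + vb * ca(t)

        expected = np.array(
            [
                quad(measured, s, s + d, limit=400)[0] / d
                for s, d in zip(sched.starts, sched.durations)
            ]
        )
        got = series_clean.data[:, iv, jv, kv]
        assert np.allclose(got, expected, rtol=2e-3, atol=1e-3)

    def test_outside_epi_zero_and_nonnegative(self, phantom_small, series_clean):
        masks, _ = phantom_small
        outside = ~masks.epi.bool()
        assert np.all(series_clean.data[:, outside] == 0)
        assert np.all(series_clean.data >= 0)

    def test_seed_determinism(self, phantom_small, input_params):
        masks, truth = phantom_small
        sched = make_schedule("SMC_CNUH")
        a = simulate_dynamic_pet(masks, truth, input_params, sched, "rest", noise_scale=1.0, seed=7)
        b = simulate_dynamic_pet(masks, truth, input_params, sched, "rest", noise_scale=1.0, seed=7)
        assert np.array_equal(a.data, b.data)
        c = simulate_dynamic_pet(masks, truth, input_params, sched, "rest", noise_scale=1.0, seed=8)
        assert not np.array_equal(a.data, c.data)


class TestPerturbMasks:
    def test_zero_spec_bit_identical(self, phantom_small):
        masks, _ = phantom_small
        out = perturb_masks(masks, PerturbationSpec())
        assert np.array_equal(out.lv.data, masks.lv.data)
        assert np.array_equal(out.rv.data, masks.rv.data)
        assert np.array_equal(out.epi.data, masks.epi.data)

    def test_apex_truncation_slice_count(self, phantom_small):
        masks, _ = phantom_small
        out = perturb_masks(masks, PerturbationSpec(apex_truncation_slices=3))
        n_before = int(masks.epi.bool().any(axis=(0, 1)).sum())
        n_after = int(out.epi.bool().any(axis=(0, 1)).sum())
        assert n_before - n_after == 3

    def test_rv_dilation_strictly_increases_volume(self, phantom_small):
        masks, _ = phantom_small
        out = perturb_masks(masks, PerturbationSpec(rv_dilation_mm=4.0))
        assert out.rv.data.sum() > masks.rv.data.sum()
        assert np.all(out.rv.bool()[masks.rv.bool()])

    def test_truncation_beyond_extent_errors(self, phantom_small):
        masks, _ = phantom_small
        with pytest.raises(PhantomError, match="exceeds"):
            perturb_masks(masks, PerturbationSpec(apex_truncation_slices=1000))

    def test_determinism_with_jitter(self, phantom_small):
        masks, _ = phantom_small
        spec = PerturbationSpec(boundary_jitter_mm=2.0, seed=5)
        a = perturb_masks(masks, spec)
        b = perturb_masks(masks, spec)
        assert np.array_equal(a.epi.data, b.epi.data)

    @pytest.mark.parametrize(
        "family",
        [
            [PerturbationSpec(apex_truncation_slices=n) for n in (0, 1, 3, 5)],
            [PerturbationSpec(rv_dilation_mm=m) for m in (0.0, 3.0, 6.0, 9.0)],
            [PerturbationSpec(boundary_jitter_mm=j, seed=3) for j in (0.0, 1.0, 2.0, 4.0)],
        ],
    )
    def test_nested_specs_monotone_symmetric_difference(self, phantom_small, family):
        masks, _ = phantom_small
        vols = []
        for spec in family:
            out = perturb_masks(masks, spec)
            sym = 0
            for a, b in ((out.lv, masks.lv), (out.rv, masks.rv), (out.epi, masks.epi)):
                sym += int(np.sum(a.bool() ^ b.bool()))
            vols.append(sym)
        assert all(v2 >= v1 for v1, v2 in zip(vols, vols[1:]))
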