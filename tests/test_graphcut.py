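"""Unit tests for VARPRO decomposition and graph-cut field mapping."""

import itertools

import numpy as np
import pytest

from fatfrac import (
    FwsConfig,
    VoxelSignalParams,
    exact_fieldmap_mrf,
    fieldmap_graphcut,
    gre_signal,
    mixed_fit_refine,
    residual_lattice,
    separate,
    simulate_acquisition,
    varpro_decompose,
)
from fatfrac.graphcut import _grid_pairs, _min_cut, _mrf_energy
from fatfrac.phantoms import make_vial_phantom


class TestVarproDecompose:
    def test_exact_recovery_at_true_parameters(self, invivo_model, proto_7t_high):
        p = VoxelSignalParams(0.8, 0.3, 0.4, -0.1, 35.0, 60.0)
        s = gre_signal(p, invivo_model, proto_7t_high)
        w, f, res = varpro_decompose(s, proto_7t_high.te, invivo_model, 7.0, 35.0, 60.0)
        assert res == pytest.approx(0.0, abs=1e-10)
        assert w == pytest.approx(0.8 * np.exp(0.3j), rel=1e-9)
        assert f == pytest.approx(0.4 * np.exp(-0.1j), rel=1e-9)

    def test_all_zero_signal(self, invivo_model, proto_7t_high):
        w, f, res = varpro_decompose(np.zeros(6, complex), proto_7t_high.te,
                                     invivo_model, 7.0, 10.0, 20.0)
        assert (w, f, res) == (0.0, 0.0, 0.0)

    def test_residual_valleys_repeat_at_echo_spacing_alias(self, single_peak,
                                                           proto_7t_high):
        # swap ambiguity: with equidistant echoes, shifting the field by
        # k / dTE leaves the fitted subspace unchanged up to a constant
        # phase, so zero-residual valleys recur at exactly that spacing
        p = VoxelSignalParams.from_pdff(0.5, r2s=50.0, delta_f=0.0)
        s = gre_signal(p, single_peak, proto_7t_high)
        alias = 1.0 / proto_7t_high.dte
        for f in (0.0, -alias, alias):
            res = varpro_decompose(s, proto_7t_high.te, single_peak, 7.0, f, 50.0)[2]
            assert res == pytest.approx(0.0, abs=1e-9)
        # mid-way between valleys the residual is decisively nonzero
        res_mid = varpro_decompose(s, proto_7t_high.te, single_peak, 7.0,
                                   0.5 * alias, 50.0)[2]
        assert res_mid > 1e-2 * np.linalg.norm(s)

    def test_too_few_echoes_rejected(self, invivo_model):
        with pytest.raises(ValueError):
            varpro_decompose(np.ones(2, complex), (1e-3, 2e-3), invivo_model, 7.0, 0.0, 0.0)


class TestResidualLattice:
    def test_consistent_with_pointwise_varpro(self, phantom_model, proto_7t_high):
        ph = make_vial_phantom(grid_size=16)
        series = simulate_acquisition(ph, phantom_model, proto_7t_high, noise_sd=0.02, seed=4)
        cfg = FwsConfig(fat_model=phantom_model,
                        offres_grid=np.linspace(-100, 100, 9),
                        r2s_grid=np.linspace(0, 200, 5))
        res2, r2i = residual_lattice(series, cfg)
        iy, ix = 8, 8
        for l, f in enumerate(cfg.offres_grid):
            best = min(
                varpro_decompose(series.data[:, iy, ix], proto_7t_high.te,
                                 phantom_model, 7.0, f, r)[2] ** 2
                for r in cfg.r2s_grid
            )
            assert res2[l, iy, ix] == pytest.approx(best, rel=1e-8, abs=1e-14)

    def test_finer_r2s_grid_never_increases_minimum(self, phantom_model, proto_7t_high):
        ph = make_vial_phantom(grid_size=16)
        series = simulate_acquisition(ph, phantom_model, proto_7t_high, noise_sd=0.02, seed=4)
        coarse = FwsConfig(fat_model=phantom_model, offres_grid=np.linspace(-100, 100, 9),
                           r2s_grid=np.linspace(0, 200, 5))
        fine = FwsConfig(fat_model=phantom_model, offres_grid=np.linspace(-100, 100, 9),
                         r2s_grid=np.linspace(0, 200, 9))  # superset of the coarse grid
        rc, _ = residual_lattice(series, coarse)
        rf, _ = residual_lattice(series, fine)
        assert np.all(rf <= rc + 1e-12)

    def test_noiseless_minimum_at_truth_within_grid(self, phantom_model, proto_7t_high):
        ph = make_vial_phantom(grid_size=16)
        ph.b0_truth += 42.0 * ph.foreground
        series = simulate_acquisition(ph, phantom_model, proto_7t_high, noise_sd=0.0)
        cfg = FwsConfig(fat_model=phantom_model)
        res2, _ = residual_lattice(series, cfg)
        best = cfg.offres_grid[np.argmin(res2[:, ph.foreground], axis=0)]
        spacing = cfg.offres_grid[1] - cfg.offres_grid[0]
        assert np.all(np.abs(best - 42.0) <= spacing)


class TestMinCut:
    def test_binary_solutions_match_enumeration(self, rng):
        for _ in range(50):
            u0, u1 = rng.uniform(0, 1, 2), rng.uniform(0, 1, 2)
            c = rng.uniform(0, 1)
            best = min(
                ((u1[0] if x0 else u0[0]) + (u1[1] if x1 else u0[1])
                 + (c if (x0 == 0 and x1 == 1) else 0), (x0, x1))
                for x0 in (0, 1) for x1 in (0, 1)
            )[0]
            st = _min_cut(2, u1, u0, np.array([0]), np.array([1]), np.array([c]))
            got = ((u1[0] if st[0] else u0[0]) + (u1[1] if st[1] else u0[1])
                   + (c if (not st[0] and st[1]) else 0))
            assert got == pytest.approx(best, rel=1e-6)


class TestFieldmapGraphcut:
    def test_zero_smoothness_reduces_to_voxelwise_argmin(self, rng):
        unary = rng.uniform(0, 1, (5, 6, 6))
        labels, trace = fieldmap_graphcut(unary, np.arange(5.0), pairwise_weight=0.0)
        np.testing.assert_array_equal(labels, np.argmin(unary, axis=0))

    def test_constant_truth_recovered_exactly(self, rng):
        # unary minimized at label 2 everywhere, noiseless
        unary = np.ones((5, 8, 8))
        unary[2] = 0.0
        for lam in (0.0, 0.1, 5.0):
            labels, _ = fieldmap_graphcut(unary, np.arange(5.0), pairwise_weight=lam)
            assert np.all(labels == 2)

    def test_energy_trace_non_increasing(self, rng):
        unary = rng.uniform(0, 1, (7, 10, 10))
        _, trace = fieldmap_graphcut(unary, np.arange(7.0), pairwise_weight=0.3,
                                     n_iterations=40)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_smoothing_flips_isolated_outlier(self):
        # a single voxel prefers a far label; smoothness must pull it back
        unary = np.full((5, 4, 4), 0.2)
        unary[0, :, :] = 0.0  # everyone else firmly prefers label 0
        unary[:, 2, 2] = [1.0, 1.0, 1.0, 1.0, 0.0]  # outlier prefers label 4
        labels, _ = fieldmap_graphcut(unary, np.arange(5.0) * 10, pairwise_weight=0.5)
        assert np.all(labels == 0)


class TestExactOracle:
    def test_matches_brute_force_enumeration(self, rng):
        # 3x3 lattice, 4 labels: 262144 states enumerated exactly
        L, ny, nx = 4, 3, 3
        pairs = _grid_pairs(np.ones((ny, nx), bool), 4)
        values = np.arange(L, dtype=float)
        for _ in range(3):
            unary = rng.uniform(0, 1, (L, ny, nx))
            lam = rng.uniform(0.05, 0.6)
            u = unary.reshape(L, -1)
            best = min(
                _mrf_energy(u, np.array(combo), values, pairs, lam)
                for combo in itertools.product(range(L), repeat=ny * nx)
            )
            sol = exact_fieldmap_mrf(unary, values, lam)
            got = _mrf_energy(u, sol.ravel(), values, pairs, lam)
            assert got == pytest.approx(best, rel=1e-9)

    def test_jump_moves_reach_exact_optimum_on_signal_instances(self, single_peak,
                                                                proto_7t_high, rng):
        # instances drawn from the solver's problem class: residual lattices
        from fatfrac import DigitalPhantom
        from fatfrac.graphcut import _default_pairwise_weight

        ny = nx = 8
        grid7 = np.linspace(-90, 90, 7)
        pairs = _grid_pairs(np.ones((ny, nx), bool), 4)
        for trial in range(5):
            ph = DigitalPhantom(
                pdff_truth=rng.uniform(0, 1, (ny, nx)), rho_total=np.ones((ny, nx)),
                r2s_truth=rng.uniform(20, 80, (ny, nx)),
                b0_truth=rng.uniform(-60, 60) + rng.uniform(-40, 40, (ny, nx)),
                phi0_truth=np.zeros((ny, nx)), labels=np.ones((ny, nx), int),
                label_names={1: "all"})
            series = simulate_acquisition(ph, single_peak, proto_7t_high,
                                          noise_sd=0.05, seed=trial)
            cfg = FwsConfig(fat_model=single_peak, offres_grid=grid7,
                            r2s_grid=np.linspace(0, 200, 21))
            res2, _ = residual_lattice(series, cfg)
            u = res2.reshape(7, -1)
            lam = _default_pairwise_weight(u, grid7, 1.0)
            labels, _ = fieldmap_graphcut(res2, grid7, pairwise_weight=lam, n_iterations=50)
            sol = exact_fieldmap_mrf(res2, grid7, lam)
            e_gc = _mrf_energy(u, labels.ravel(), grid7, pairs, lam)
            e_ex = _mrf_energy(u, sol.ravel(), grid7, pairs, lam)
            assert e_gc == pytest.approx(e_ex, rel=1e-7)


class TestSeparate:
    def test_noiseless_vial_phantom_recovery(self, phantom_model, proto_7t_high):
        ph = make_vial_phantom(grid_size=40)
        series = simulate_acquisition(ph, phantom_model, proto_7t_high, noise_sd=0.0)
        res = separate(series, FwsConfig(fat_model=phantom_model))
        assert np.all(res.water_mag >= 0) and np.all(res.fat_mag >= 0)
        assert np.all(np.diff(res.energy_trace) <= 1e-12)
        err = np.abs(res.pdff() - ph.pdff_truth)[ph.foreground]
        assert err.max() < 0.005

    def test_field_map_confined_to_search_grid(self, phantom_model, proto_7t_high):
        ph = make_vial_phantom(grid_size=32)
        series = simulate_acquisition(ph, phantom_model, proto_7t_high,
                                      noise_sd=0.05, seed=2)
        cfg = FwsConfig(fat_model=phantom_model)
        res = separate(series, cfg)
        assert res.field_map.min() >= cfg.offres_grid[0]
        assert res.field_map.max() <= cfg.offres_grid[-1]

    def test_masked_background_reports_zeros(self, phantom_model, proto_7t_high):
        ph = make_vial_phantom(grid_size=32)
        series = simulate_acquisition(ph, phantom_model, proto_7t_high,
                                      noise_sd=0.02, seed=2)
        res = separate(series, FwsConfig(fat_model=phantom_model))
        bg = ~res.mask
        assert not np.any(res.water_mag[bg]) and not np.any(res.fat_mag[bg])


class TestMixedFitRefine:
    def test_no_phase_error_is_a_noiseless_no_op(self, invivo_model, proto_7t_high):
        from fatfrac import make_calf_phantom

        ph = make_calf_phantom(grid_size=40)
        series = simulate_acquisition(ph, invivo_model, proto_7t_high, noise_sd=0.0)
        res = separate(series, FwsConfig(fat_model=invivo_model))
        ref = mixed_fit_refine(series, res, fat_model=invivo_model)
        d = np.abs(ref.pdff() - res.pdff())[res.mask]
        assert d.max() < 1e-8

    def test_first_echo_ramp_bias_is_reduced(self, invivo_model, proto_7t_high):
        from fatfrac import apply_eddy_phase, make_calf_phantom

        ph = make_calf_phantom(grid_size=40)
        muscle = ph.mask("ANT") | ph.mask("SOL") | ph.mask("GM")
        series = simulate_acquisition(ph, invivo_model, proto_7t_high, noise_sd=0.02, seed=3)
        series = apply_eddy_phase(series, 0.4, 0.04, mode="first-echo-only")
        res = separate(series, FwsConfig(fat_model=invivo_model))
        ref = mixed_fit_refine(series, res, fat_model=invivo_model)
        bias_gc = np.mean(np.abs(res.pdff() - ph.pdff_truth)[muscle])
        bias_mx = np.mean(np.abs(ref.pdff() - ph.pdff_truth)[muscle])
        assert bias_mx < bias_gc
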