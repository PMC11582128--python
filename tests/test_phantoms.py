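"""Unit tests for digital phantoms and the forward simulator."""

import numpy as np
import pytest

from fatfrac import (
    FwsConfig,
    VoxelSignalParams,
    apply_eddy_phase,
    make_calf_phantom,
    make_field_map,
    make_vial_phantom,
    separate,
    simulate_acquisition,
)


class TestVialPhantom:
    def test_default_vial_means_are_the_published_vffs(self, vial_phantom_small):
        ph = vial_phantom_small
        means = [np.mean(ph.pdff_truth[ph.mask(f"vial-{k}")]) for k in range(1, 7)]
        np.testing.assert_allclose(means, [0.05, 0.10, 0.25, 0.50, 0.75, 1.00], atol=1e-12)

    def test_zero_vff_is_indistinguishable_from_bath(self):
        ph = make_vial_phantom(vff_list=[0.0], grid_size=32)
        assert not np.any(ph.pdff_truth)

    def test_vial_area_matches_disk_area_within_perimeter(self):
        n = 96
        ph = make_vial_phantom(grid_size=n)
        r = 0.11 * n
        expected = np.pi * r**2
        perimeter = 2 * np.pi * r
        for k in range(1, 7):
            count = np.count_nonzero(ph.mask(f"vial-{k}"))
            assert abs(count - expected) <= perimeter

    def test_overlapping_vials_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_vial_phantom(vff_list=[0.1] * 12, grid_size=48, vial_radius_frac=0.11)


class TestCalfPhantom:
    def test_muscle_roi_means_equal_truth(self, calf_phantom_small):
        ph = calf_phantom_small
        for roi in ("ANT", "SOL", "GM"):
            assert np.mean(ph.pdff_truth[ph.mask(roi)]) == pytest.approx(0.03)
        assert np.mean(ph.pdff_truth[ph.mask("subcutaneous_fat")]) == pytest.approx(0.90)

    def test_fat_ring_encloses_muscle(self, calf_phantom_small):
        # morphological check: dilating muscle by one voxel meets only ring/bone,
        # never background
        ph = calf_phantom_small
        muscle = ph.mask("ANT") | ph.mask("SOL") | ph.mask("GM")
        grown = muscle.copy()
        grown[1:, :] |= muscle[:-1, :]
        grown[:-1, :] |= muscle[1:, :]
        grown[:, 1:] |= muscle[:, :-1]
        grown[:, :-1] |= muscle[:, 1:]
        halo = grown & ~muscle
        assert not np.any(ph.labels[halo] == 0)

    def test_bone_is_low_signal(self, calf_phantom_small):
        assert np.all(calf_phantom_small.rho_total[calf_phantom_small.mask("bone")] < 0.1)


class TestFieldMap:
    def test_zero_amplitudes_give_zero_field(self, calf_phantom_small):
        ph = make_field_map(calf_phantom_small, 0.0, 0.0)
        assert not np.any(ph.b0_truth)

    def test_amplitude_bound_over_object(self, calf_phantom_small):
        # amplitudes refer to the imaged object; the polynomial tail outside
        # the foreground carries no signal and is unconstrained
        ph = make_field_map(calf_phantom_small, smooth_amplitude=120.0,
                            local_gradient_amplitude=60.0)
        assert np.max(np.abs(ph.b0_truth[ph.foreground])) <= 180.0 + 1e-9

    def test_smooth_term_has_small_laplacian(self, calf_phantom_small):
        # quadratic polynomial: discrete Laplacian is spatially constant, bounded
        # by 4 * amplitude / (grid/2)^2 (second-derivative bound of the polynomial)
        amp = 100.0
        ph = make_field_map(calf_phantom_small, smooth_amplitude=amp)
        b = ph.b0_truth
        lap = b[2:, 1:-1] + b[:-2, 1:-1] + b[1:-1, 2:] + b[1:-1, :-2] - 4 * b[1:-1, 1:-1]
        n = b.shape[0]
        bound = 8 * amp / (n / 2) ** 2
        assert np.max(np.abs(lap)) <= bound

    def test_susceptibility_step_confined_to_fatty_tissue(self, calf_phantom_small):
        ph = make_field_map(calf_phantom_small, susceptibility_offset=110.0)
        fat = ph.mask("subcutaneous_fat")
        muscle = ph.mask("SOL")
        assert np.all(ph.b0_truth[fat] == 110.0)
        assert np.all(ph.b0_truth[muscle] == 0.0)

    def test_deterministic_given_seed(self, calf_phantom_small):
        a = make_field_map(calf_phantom_small, 50.0, 80.0, seed=3)
        b = make_field_map(calf_phantom_small, 50.0, 80.0, seed=3)
        np.testing.assert_array_equal(a.b0_truth, b.b0_truth)


class TestSimulateAcquisition:
    def test_same_seed_is_bit_identical(self, vial_phantom_small, phantom_model, proto_7t_high):
        a = simulate_acquisition(vial_phantom_small, phantom_model, proto_7t_high,
                                 noise_sd=0.05, seed=9)
        b = simulate_acquisition(vial_phantom_small, phantom_model, proto_7t_high,
                                 noise_sd=0.05, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_background_noise_sd_matches_request(self, phantom_model, proto_7t_high):
        ph = make_vial_phantom(grid_size=160)
        series = simulate_acquisition(ph, phantom_model, proto_7t_high,
                                      noise_sd=0.04, seed=1)
        bg = ~ph.foreground
        assert np.count_nonzero(bg) * proto_7t_high.n_echoes >= 1e4
        measured = np.sqrt(np.mean(np.abs(series.data[:, bg]) ** 2))
        assert measured == pytest.approx(0.04, rel=0.02)

    def test_seeds_give_independent_noise(self, vial_phantom_small, phantom_model, proto_7t_high):
        clean = simulate_acquisition(vial_phantom_small, phantom_model, proto_7t_high,
                                     noise_sd=0.0)
        a = simulate_acquisition(vial_phantom_small, phantom_model, proto_7t_high,
                                 noise_sd=0.05, seed=1)
        b = simulate_acquisition(vial_phantom_small, phantom_model, proto_7t_high,
                                 noise_sd=0.05, seed=2)
        na = (a.data - clean.data).real.ravel()
        nb = (b.data - clean.data).real.ravel()
        assert abs(np.corrcoef(na, nb)[0, 1]) < 0.02

    def test_voxel_signal_matches_voxel_model(self, calf_phantom_small, invivo_model,
                                              proto_7t_high):
        from fatfrac import gre_signal

        ph = make_field_map(calf_phantom_small, smooth_amplitude=40.0)
        series = simulate_acquisition(ph, invivo_model, proto_7t_high, noise_sd=0.0)
        iy, ix = 24, 30
        p = VoxelSignalParams(
            rho_w=ph.rho_total[iy, ix] * (1 - ph.pdff_truth[iy, ix]),
            rho_f=ph.rho_total[iy, ix] * ph.pdff_truth[iy, ix],
            delta_f=ph.b0_truth[iy, ix], r2s=ph.r2s_truth[iy, ix],
        )
        np.testing.assert_allclose(series.data[:, iy, ix],
                                   gre_signal(p, invivo_model, proto_7t_high), rtol=1e-12)


class TestEddyPhase:
    def test_zero_amplitude_is_identity(self, vial_phantom_small, phantom_model, proto_7t_high):
        s = simulate_acquisition(vial_phantom_small, phantom_model, proto_7t_high, noise_sd=0.0)
        out = apply_eddy_phase(s, 0.0, 0.0)
        np.testing.assert_array_equal(out.data, s.data)

    @pytest.mark.parametrize("mode", ["first-echo-only", "all-echoes-linear"])
    def test_apply_then_negate_is_an_involution(self, mode, vial_phantom_small,
                                                phantom_model, proto_7t_high):
        s = simulate_acquisition(vial_phantom_small, phantom_model, proto_7t_high,
                                 noise_sd=0.02, seed=5)
        fwd = apply_eddy_phase(s, 0.4, 0.03, mode=mode)
        back = apply_eddy_phase(fwd, -0.4, -0.03, mode=mode)
        np.testing.assert_allclose(back.data, s.data, rtol=1e-13, atol=1e-18)

    def test_pi_ramp_gives_antipodal_edge_phases(self, proto_7t_high):
        from fatfrac import EchoSeries

        s = EchoSeries(data=np.ones((6, 12, 12), complex), protocol=proto_7t_high)
        n = 12
        gradient = np.pi / (n - 1)  # total phase span of pi across the FOV
        out = apply_eddy_phase(s, 0.0, gradient, mode="first-echo-only")
        dphi = np.angle(out.data[0])
        edge_diff = dphi[:, -1] - dphi[:, 0]
        np.testing.assert_allclose(edge_diff, np.pi, atol=1e-9)

    def test_first_echo_mode_leaves_later_echoes_untouched(self, vial_phantom_small,
                                                           phantom_model, proto_7t_high):
        s = simulate_acquisition(vial_phantom_small, phantom_model, proto_7t_high,
                                 noise_sd=0.02, seed=5)
        out = apply_eddy_phase(s, 0.7, 0.02, mode="first-echo-only")
        np.testing.assert_array_equal(out.data[1:], s.data[1:])
        assert not np.array_equal(out.data[0], s.data[0])


class TestForwardInverseLoop:
    def test_noiseless_separation_recovers_truth_to_grid_resolution(
        self, phantom_model, proto_7t_high
    ):
        ph = make_vial_phantom(grid_size=40)
        series = simulate_acquisition(ph, phantom_model, proto_7t_high, noise_sd=0.0)
        result = separate(series, FwsConfig(fat_model=phantom_model))
        err = np.abs(result.pdff() - ph.pdff_truth)[ph.foreground]
        assert err.max() < 0.005  # bounded by the off-resonance/R2* grid spacing
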