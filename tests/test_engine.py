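import numpy as np
import pytest

from tacs import engine
from tacs.engine import (AlgorithmParams, LevelSetState, RegionFeatures,
                         Segmentation, dirac_delta, double_well_potential,
                         evolve_step, external_energy, external_velocity,
                         has_converged, merge_threshold_from_snr, prune,
                         region_timecourses, regularizer_gradient, segment,
                         signed_distance, try_merge)
from tacs.initialize import CandidateROI, disc_mask, init_level_set
from tacs.io import VideoStack
from tacs.simulate import SyntheticSpec, simulate_video


def _state_from_mask(mask, width=10.0, label=0):
    st = LevelSetState.from_mask(mask, narrowband_width=width, label=label)
    return st


def _two_region_video(shape=(24, 24), t=40, cell_center=(12, 12), cell_radius=4,
                      cell_value=None, bg_value=None, seed=0):
    """Noiseless video: cell pixels share one trace, background another."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(50, 150, t) if cell_value is None else cell_value
    b = rng.uniform(0, 10, t) if bg_value is None else bg_value
    mask = disc_mask(shape, cell_center, cell_radius)
    data = np.empty((t,) + shape)
    data[:, :, :] = b[:, None, None]
    data[:, mask] = u[:, None]
    return VideoStack(data), mask, u, b


class TestAlgorithmParams:
    def test_cfl_defaults_hold(self):
        p = AlgorithmParams(r=5)
        assert p.mu * p.delta_tau == pytest.approx(0.2)

    def test_cfl_violation_raises(self):
        with pytest.raises(ValueError, match="CFL"):
            AlgorithmParams(r=5, mu=0.03, delta_tau=10.0)

    def test_default_size_thresholds(self):
        p = AlgorithmParams(r=5)
        assert p.min_area == 3
        assert p.max_area == pytest.approx(3 * np.pi * 25)

    def test_narrowband_defaults_to_2r(self):
        assert AlgorithmParams(r=7).narrowband_width == 14.0


class TestDiracDelta:
    def test_peak_value_at_zero(self):
        assert dirac_delta(np.zeros(1), 2.0)[0] == pytest.approx(0.5)

    def test_zero_outside_band(self):
        phi = np.array([-5.0, -2.1, 2.1, 9.0])
        np.testing.assert_array_equal(dirac_delta(phi, 2.0), 0.0)

    def test_non_negative(self, rng):
        phi = rng.uniform(-4, 4, size=(20, 20))
        assert dirac_delta(phi, 2.0).min() >= 0.0

    def test_integrates_to_one_across_ramp(self):
        # 1-D linear phi ramp with |grad| = 1 sampled at spacing h
        h = 0.01
        phi = np.arange(-3, 3, h)
        total = dirac_delta(phi, 2.0).sum() * h
        assert total == pytest.approx(1.0, rel=0.02)

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            dirac_delta(np.zeros(3), 0.0)


class TestRegionTimecourses:
    def test_isolated_cell_constant_background(self):
        video, mask, u, b = _two_region_video(bg_value=np.full(40, 4.0))
        seg = Segmentation([_state_from_mask(mask)])
        f = region_timecourses(video, seg, 0)
        np.testing.assert_allclose(f.f_out, 4.0)
        np.testing.assert_allclose(f.f_in, u)

    def test_two_pixel_interior_is_arithmetic_mean(self, rng):
        data = rng.uniform(size=(15, 8, 8))
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = mask[4, 5] = True
        seg = Segmentation([_state_from_mask(mask, width=3.0)])
        f = region_timecourses(VideoStack(data), seg, 0)
        np.testing.assert_allclose(f.f_in, (data[:, 4, 4] + data[:, 4, 5]) / 2)

    def test_overlapping_pair_uses_exclusive_pixels(self, rng):
        data = rng.uniform(size=(20, 16, 16))
        a = disc_mask((16, 16), (8, 6), 3.5)
        b = disc_mask((16, 16), (8, 10), 3.5)
        assert (a & b).any()
        seg = Segmentation([_state_from_mask(a, label=0), _state_from_mask(b, label=1)])
        f = region_timecourses(VideoStack(data), seg, 0)
        oracle = data[:, a & ~b].mean(axis=1)
        np.testing.assert_allclose(f.f_in, oracle)
        out_oracle = data[:, seg.states[0].narrowband & ~a & ~b].mean(axis=1)
        np.testing.assert_allclose(f.f_out, out_oracle)


class TestExternalVelocity:
    """Branch signs of the two-branch velocity, on exact (given) features."""

    def _setup(self, overlap=False):
        shape = (20, 20)
        t = 30
        rng = np.random.default_rng(3)
        f_in_i = rng.uniform(50, 100, t)
        f_in_j = rng.uniform(40, 90, t)
        f_out = rng.uniform(0, 5, t)
        # true cells; contour i starts smaller than its cell so band pixels in
        # the overlap zone are not yet claimed by contour i
        true_a = disc_mask(shape, (10, 7), 4.5)
        true_b = disc_mask(shape, (10, 13), 4.5) if overlap else np.zeros(shape, bool)
        data = np.zeros((t,) + shape) + f_out[:, None, None]
        data[:, true_a] = f_in_i[:, None]
        if overlap:
            data[:, true_b] = f_in_j[:, None]
            data[:, true_a & true_b] = (f_in_i + f_in_j)[:, None]
        video = VideoStack(data)
        a = disc_mask(shape, (10, 7), 4.0) if not overlap else disc_mask(shape, (10, 7), 3.0)
        states = [_state_from_mask(a, label=0)]
        if overlap:
            states.append(_state_from_mask(true_b, label=1))
        seg = Segmentation(states)
        feats = {0: RegionFeatures(f_in=f_in_i, f_out=f_out)}
        if overlap:
            feats[1] = RegionFeatures(f_in=f_in_j, f_out=f_out)
        return video, seg, feats, f_in_i, f_in_j, f_out, true_a, true_b

    def test_pixel_matching_interior_is_attracted(self):
        video, seg, feats, f_in_i, _, f_out, true_a, _ = self._setup()
        v = external_velocity(video, seg, 0, "euclidean", feats)
        band_in = (np.abs(seg.states[0].phi) <= 2) & seg.states[0].interior
        expected = -np.linalg.norm(f_in_i - f_out)
        assert np.all(v[band_in] < 0)
        assert v[band_in].min() == pytest.approx(expected, rel=1e-10)

    def test_pixel_matching_background_is_repelled(self):
        video, seg, feats, f_in_i, _, f_out, true_a, _ = self._setup()
        v = external_velocity(video, seg, 0, "euclidean", feats)
        band_out = (np.abs(seg.states[0].phi) <= 2) & ~true_a
        assert band_out.any()
        expected = +np.linalg.norm(f_out - f_in_i)
        assert np.all(v[band_out] > 0)
        assert v[band_out].max() == pytest.approx(expected, rel=1e-10)

    def test_summed_overlap_pixel_drives_expansion(self):
        # pixel inside neighbour j whose content is the summed signal
        # f_in_i + f_in_j: contour i expands into the shared pixel
        video, seg, feats, f_in_i, f_in_j, _, true_a, true_b = self._setup(overlap=True)
        v = external_velocity(video, seg, 0, "euclidean", feats)
        band = np.abs(seg.states[0].phi) <= 2
        sel = band & true_a & true_b & ~seg.states[0].interior
        assert sel.any()
        expected = -np.linalg.norm(f_in_i)
        assert np.all(v[sel] < 0)
        assert v[sel].min() == pytest.approx(expected, rel=1e-10)

    def test_zero_outside_dirac_band(self):
        video, seg, feats, *_ = self._setup()
        v = external_velocity(video, seg, 0, "euclidean", feats)
        assert np.all(v[np.abs(seg.states[0].phi) > 2] == 0)


class TestRegularizer:
    def test_near_zero_at_signed_distance_well(self):
        phi = signed_distance(disc_mask((40, 40), (20, 20), 8.0))
        g_well = regularizer_gradient(phi, mu=1.0)
        g_off = regularizer_gradient(2.0 * phi, mu=1.0)
        band = np.abs(phi) <= 4
        # at the |grad|=1 well the restoring force is an order of magnitude
        # below that of a doubled slope (discrete staircase kinks excepted)
        assert np.abs(g_well[band]).mean() < 0.1 * np.abs(g_off[band]).mean()
        assert np.quantile(np.abs(g_well[band]), 0.8) < 0.05

    def test_zero_at_constant_well(self):
        g = regularizer_gradient(np.full((20, 20), 3.0), mu=1.0)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_descent_drives_gradient_toward_one(self):
        phi = 2.0 * signed_distance(disc_mask((40, 40), (20, 20), 8.0))
        mu, dt = 0.02, 10.0

        def potential(p):
            gr, gc = np.gradient(p)
            return double_well_potential(np.hypot(gr, gc)).sum()

        energies = [potential(phi)]
        for _ in range(200):
            phi = phi - dt * regularizer_gradient(phi, mu)
            energies.append(potential(phi))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-9)
        assert energies[-1] < 0.5 * energies[0]


class TestExternalEnergy:
    def test_zero_on_perfect_partition(self):
        video, mask, _, _ = _two_region_video(bg_value=np.full(40, 4.0))
        seg = Segmentation([_state_from_mask(mask)])
        assert external_energy(video, seg, "euclidean") == pytest.approx(0.0, abs=1e-9)

    def test_single_cell_reduces_to_two_region_form(self, rng):
        # with M=1 the multi-cell energy equals the direct interior/background sum
        data = rng.uniform(0, 100, size=(25, 18, 18))
        video = VideoStack(data)
        mask = disc_mask((18, 18), (9, 9), 4.0)
        seg = Segmentation([_state_from_mask(mask, width=6.0)])
        nb = seg.states[0].narrowband
        f_in = data[:, mask].mean(axis=1)
        f_out = data[:, nb].mean(axis=1)
        direct = (np.linalg.norm(data[:, mask] - f_in[:, None], axis=0).sum()
                  + np.linalg.norm(data[:, nb] - f_out[:, None], axis=0).sum())
        assert external_energy(video, seg, "euclidean") == pytest.approx(direct, rel=1e-12)

    def test_true_partition_beats_one_pixel_perturbations(self):
        video, mask, _, _ = _two_region_video(shape=(16, 16), cell_center=(8, 8),
                                              cell_radius=3)
        base = external_energy(video, Segmentation([_state_from_mask(mask)]),
                               "euclidean")
        # flip every pixel adjacent to the boundary, one at a time
        from scipy import ndimage
        ring = ndimage.binary_dilation(mask) ^ ndimage.binary_erosion(mask)
        for r, c in np.argwhere(ring):
            perturbed = mask.copy()
            perturbed[r, c] = ~perturbed[r, c]
            if not perturbed.any():
                continue
            e = external_energy(video, Segmentation([_state_from_mask(perturbed)]),
                                "euclidean")
            assert e >= base - 1e-9


class TestEvolveStep:
    def test_zero_velocity_keeps_interior_one_step(self):
        mask = disc_mask((30, 30), (15, 15), 5.0)
        st = _state_from_mask(mask)
        p = AlgorithmParams(r=5, curvature_weight=0.0)
        changed = evolve_step(st, np.zeros((30, 30)), p)
        assert changed == 0
        np.testing.assert_array_equal(st.interior, mask)

    def test_negative_velocity_grows_interior(self):
        mask = disc_mask((30, 30), (15, 15), 5.0)
        st = _state_from_mask(mask)
        p = AlgorithmParams(r=5, curvature_weight=0.0)
        area0 = st.area
        evolve_step(st, np.full((30, 30), -1.0), p)
        assert st.area >= area0

    def test_positive_velocity_shrinks_interior(self):
        mask = disc_mask((30, 30), (15, 15), 5.0)
        st = _state_from_mask(mask)
        p = AlgorithmParams(r=5, curvature_weight=0.0)
        area0 = st.area
        evolve_step(st, np.full((30, 30), 1.0), p)
        assert st.area <= area0

    def test_interior_always_phi_positive(self, rng):
        st = _state_from_mask(disc_mask((30, 30), (15, 15), 5.0))
        p = AlgorithmParams(r=5)
        for _ in range(5):
            evolve_step(st, rng.uniform(-1, 1, (30, 30)), p)
            np.testing.assert_array_equal(st.interior, st.phi > 0)


class TestConvergenceAndPruning:
    def test_counter_thresholds(self):
        st = _state_from_mask(disc_mask((20, 20), (10, 10), 4.0))
        p = AlgorithmParams(r=4)
        st.stable_iters = 39
        assert not has_converged(st, p)
        st.stable_iters = 40
        assert has_converged(st, p)

    def test_nmax_forces_stop(self):
        spec = SyntheticSpec(height=40, width=40, n_frames=40, n_cells=1,
                             cell_radius=5, noise_sd=20.0, seed=1,
                             centers=((20., 20.),))
        video, _ = simulate_video(spec)
        cand = CandidateROI(disc_mask((40, 40), (20, 20), 3.0), "grid")
        p = AlgorithmParams(r=5, n_max=5)
        seg = segment(video, [cand], p)
        assert seg.n_sweeps_run == 5
        assert all(s.n_sweeps <= 5 for s in seg.states)

    @pytest.mark.parametrize("area,r,kept", [
        (2, 5, False),    # below the 3-px floor
        (237, 5, False),  # above 3*pi*25 ~ 235.6
        (50, 5, True),
    ])
    def test_prune_size_thresholds(self, area, r, kept):
        mask = np.zeros((40, 40), bool)
        # build a connected blob of exactly `area` pixels
        coords = [(r0, c0) for r0 in range(40) for c0 in range(40)]
        coords.sort(key=lambda rc: (rc[0] - 20) ** 2 + (rc[1] - 20) ** 2)
        for r0, c0 in coords[:area]:
            mask[r0, c0] = True
        seg = Segmentation([_state_from_mask(mask)])
        prune(seg, AlgorithmParams(r=r))
        assert (seg.states[0].status == "active") == kept


class TestMerging:
    def test_threshold_formula(self):
        assert merge_threshold_from_snr(0.0) == pytest.approx(0.5)
        assert merge_threshold_from_snr(5.0) == pytest.approx(0.7597, abs=1e-4)
        assert merge_threshold_from_snr(100.0) == pytest.approx(1.0, abs=1e-9)
        snrs = np.linspace(-20, 20, 41)
        vals = [merge_threshold_from_snr(s) for s in snrs]
        assert np.all(np.diff(vals) > 0)

    def _pair_video(self, corr_identical, gap):
        rng = np.random.default_rng(5)
        t = 40
        u = rng.uniform(20, 80, t)
        v2 = u if corr_identical else rng.uniform(20, 80, t)
        shape = (30, 40)
        a = disc_mask(shape, (15, 10), 4.0)
        b = disc_mask(shape, (15, 10 + 8 + gap), 4.0)
        data = np.zeros((t,) + shape) + rng.uniform(0, 2, t)[:, None, None]
        data[:, a] = u[:, None]
        data[:, b] = v2[:, None]
        video = VideoStack(data)
        seg = Segmentation([_state_from_mask(a, label=0), _state_from_mask(b, label=1)])
        return video, seg

    def test_adjacent_identical_cells_merge(self):
        video, seg = self._pair_video(corr_identical=True, gap=2)
        try_merge(seg, video, AlgorithmParams(r=5))
        statuses = [s.status for s in seg.states]
        assert statuses[:2] == ["merged", "merged"]
        assert len(seg.states) == 3 and seg.states[2].status == "active"
        np.testing.assert_array_equal(
            seg.states[2].interior,
            disc_mask((30, 40), (15, 10), 4.0) | disc_mask((30, 40), (15, 20), 4.0))

    def test_uncorrelated_cells_do_not_merge(self):
        video, seg = self._pair_video(corr_identical=False, gap=2)
        try_merge(seg, video, AlgorithmParams(r=5))
        assert [s.status for s in seg.states] == ["active", "active"]

    def test_distant_identical_cells_do_not_merge(self):
        video, seg = self._pair_video(corr_identical=True, gap=9)
        try_merge(seg, video, AlgorithmParams(r=5))
        assert [s.status for s in seg.states] == ["active", "active"]


class TestSegmentLoop:
    def test_noiseless_cell_recovered_with_high_jaccard(self):
        spec = SyntheticSpec(height=40, width=40, n_frames=60, n_cells=1,
                             cell_radius=5, noise_sd=0.0, seed=2,
                             centers=((20., 20.),))
        video, gt = simulate_video(spec)
        cand = CandidateROI(disc_mask((40, 40), (20, 20), 3.0), "grid")
        seg = segment(video, [cand], AlgorithmParams(r=5))
        states = seg.surviving_states()
        assert len(states) == 1
        est = states[0].interior
        jac = (est & gt.masks[0]).sum() / (est | gt.masks[0]).sum()
        assert jac >= 0.9

    def test_background_seed_is_pruned(self):
        spec = SyntheticSpec(height=40, width=40, n_frames=80, n_cells=1,
                             cell_radius=5, noise_sd=30.0, seed=3,
                             centers=((10., 10.),))
        video, _ = simulate_video(spec)
        cand = CandidateROI(disc_mask((40, 40), (30, 30), 3.0), "grid")
        seg = segment(video, [cand], AlgorithmParams(r=5))
        assert seg.surviving_states() == []

    def test_overlap_is_permitted_and_recovered(self):
        spec = SyntheticSpec(height=40, width=60, n_frames=120, n_cells=2,
                             cell_radius=6, noise_sd=20.0, seed=4,
                             centers=((20., 24.), (20., 33.)))
        video, gt = simulate_video(spec)
        assert (gt.masks[0] & gt.masks[1]).any()
        cands = [CandidateROI(disc_mask((40, 60), c, 4.0), "user")
                 for c in gt.centers]
        seg = segment(video, cands, AlgorithmParams(r=6, metric="correlation"))
        states = seg.surviving_states()
        assert len(states) == 2
        assert (states[0].interior & states[1].interior).any()

    def test_locality_of_updates(self):
        # perturbing pixels far from a cell's narrowband never changes its update
        spec = SyntheticSpec(height=48, width=48, n_frames=50, n_cells=1,
                             cell_radius=5, noise_sd=25.0, seed=6,
                             centers=((14., 14.),))
        video, _ = simulate_video(spec)
        data2 = video.data.copy()
        data2[:, 40:, 40:] += 500.0  # >= 2r + eps + 1 away from the narrowband
        video2 = VideoStack(data2, frame_rate=video.frame_rate)
        p = AlgorithmParams(r=5, n_max=3)
        cand = CandidateROI(disc_mask((48, 48), (14, 14), 3.0), "grid")
        seg1 = segment(video, [cand], p)
        seg2 = segment(video2, [cand], p)
        np.testing.assert_array_equal(seg1.states[0].interior,
                                      seg2.states[0].interior)

    def test_empty_candidates_raise(self):
        video = VideoStack(np.ones((5, 10, 10)))
        with pytest.raises(ValueError):
            segment(video, [], AlgorithmParams(r=3))
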