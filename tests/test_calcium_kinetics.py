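"""Global transient kinetics, dyssynchrony mapping, and local-site timing."""

import math

import numpy as np
import pytest

from dyadscape.calcium_kinetics import (
    ORPHANED,
    classify_sites,
    dyssynchrony_map,
    global_transient,
    local_ttf50,
)
from dyadscape.image_core import VideoStack
from dyadscape.synthetic_data import (
    CalciumSpec,
    TubuleNetworkSpec,
    generate_calcium_video,
)
from dyadscape.tubule_morphometry import TRANSVERSE, skeletonize_mask


def ramp_video(baseline=100.0, peak=300.0, rise_ms=150.0, dt=1.5, stim=10,
               n=200, shape=(20, 20)):
    times = np.arange(n) * dt
    t_stim = stim * dt
    trace = np.where(
        times < t_stim, baseline,
        np.minimum(baseline + (peak - baseline) * (times - t_stim) / rise_ms, peak))
    frames = np.broadcast_to(trace[:, None, None], (n, *shape)).copy()
    return VideoStack(frames, dt, 0.16)


class TestGlobalTransient:
    def test_linear_ramp_analytic_values(self):
        vid = ramp_video()
        roi = np.ones(vid.frame_shape, bool)
        trace, kin = global_transient(vid, roi, 10)
        assert kin.f50_level == pytest.approx(200.0, abs=1e-6)
        assert kin.tf50_ms == pytest.approx(75.0, abs=0.1)
        assert kin.time_to_peak_ms >= kin.tf50_ms

    def test_step_peaks_immediately(self):
        frames = np.full((30, 20, 20), 100.0)
        frames[10:] = 300.0
        vid = VideoStack(frames, 1.5, 0.16)
        _, kin = global_transient(vid, np.ones((20, 20), bool), 10)
        assert kin.time_to_peak_ms <= 1.5

    def test_flat_trace_flagged_invalid(self):
        vid = VideoStack(np.full((30, 20, 20), 100.0), 1.5, 0.16)
        _, kin = global_transient(vid, np.ones((20, 20), bool), 10)
        assert not kin.valid
        assert math.isnan(kin.tf50_ms)

    def test_generator_rise_within_one_frame_of_analytic(self):
        spec = CalciumSpec(seed=0, site_delay_mean_ms=5.0, site_delay_sd_ms=0.0,
                           noise_sd=0.0)
        vid, truth = generate_calcium_video(spec)
        _, kin = global_transient(vid, truth.footprint, spec.stimulus_frame)
        # uniform delay d: half-max of (1-exp(-u/tr))exp(-u/td) reached at the
        # analytic crossing of half the peak value
        tr, td = spec.rise_tau_ms, spec.decay_tau_ms
        u = np.linspace(0, 200, 20001)
        g = (1 - np.exp(-u / tr)) * np.exp(-u / td)
        u50 = u[np.argmax(g >= g.max() / 2)]
        expected = 5.0 + u50
        assert kin.tf50_ms == pytest.approx(expected, abs=spec.frame_interval_ms)


class TestDyssynchronyMap:
    def test_uniform_video_is_synchronous(self):
        vid = ramp_video()
        dim = dyssynchrony_map(vid, np.ones(vid.frame_shape, bool), 10)
        assert dim.di_ms == pytest.approx(0.0, abs=0.01)

    def test_two_half_cells_sd(self):
        n, dt = 120, 1.0
        times = np.arange(n) * dt
        frames = np.full((n, 24, 24), 100.0)
        rise_left = np.clip((times - 20.0 - 10.0) / 0.5, 0, 1) * 200.0
        rise_right = np.clip((times - 20.0 - 30.0) / 0.5, 0, 1) * 200.0
        frames[:, :, :12] += rise_left[:, None, None]
        frames[:, :, 12:] += rise_right[:, None, None]
        vid = VideoStack(frames, dt, 0.16)
        dim = dyssynchrony_map(vid, np.ones((24, 24), bool), 20, smooth_px=1)
        assert dim.di_ms == pytest.approx(10.0, abs=0.5)

    def test_programmed_delay_sd_recovered(self):
        spec = CalciumSpec(seed=3, site_delay_mean_ms=30.0, site_delay_sd_ms=12.0)
        vid, truth = generate_calcium_video(spec)
        dim = dyssynchrony_map(vid, truth.footprint, spec.stimulus_frame)
        assert dim.di_ms == pytest.approx(12.0, abs=2.0)

    def test_invariance_to_offset_and_scale(self):
        spec = CalciumSpec(seed=1, site_delay_mean_ms=20.0, site_delay_sd_ms=8.0)
        vid, truth = generate_calcium_video(spec)
        roi = truth.footprint
        d0 = dyssynchrony_map(vid, roi, spec.stimulus_frame).di_ms
        shifted = VideoStack(vid.frames + 37.0, vid.frame_interval_ms, vid.pixel_size_um)
        scaled = VideoStack(vid.frames * 2.5, vid.frame_interval_ms, vid.pixel_size_um)
        assert dyssynchrony_map(shifted, roi, spec.stimulus_frame).di_ms \
            == pytest.approx(d0, abs=0.3)
        assert dyssynchrony_map(scaled, roi, spec.stimulus_frame).di_ms \
            == pytest.approx(d0, abs=0.3)

    def test_crossing_times_converge_with_frame_rate(self):
        errors = []
        for dt in (6.0, 3.0, 1.5):
            vid = ramp_video(dt=dt, stim=10, n=int(300 / dt))
            _, kin = global_transient(vid, np.ones(vid.frame_shape, bool), 10)
            errors.append(abs(kin.tf50_ms - 75.0))
        assert errors[2] <= errors[0] + 1e-9


class TestSites:
    @staticmethod
    def _gap_skeleton(ps=0.16):
        # regular vertical lines with one missing -> a ~3.6 um gap
        mask = np.zeros((64, 64), bool)
        cols = [8, 19, 30, 52]  # line at 41 omitted
        for c in cols:
            mask[4:60, c] = True
        return skeletonize_mask(mask, ps), mask

    def test_dense_grid_has_no_orphans(self):
        mask = np.zeros((64, 64), bool)
        for c in range(4, 64, 6):
            mask[4:60, c] = True
        sk = skeletonize_mask(mask, 0.16)
        sites = classify_sites(sk, np.ones((64, 64), bool), categories=(ORPHANED,))
        assert sites == []

    def test_gap_yields_orphan_site_at_centre(self):
        sk, _ = self._gap_skeleton()
        roi = np.ones((64, 64), bool)
        sites = classify_sites(sk, roi, categories=(ORPHANED,))
        assert len(sites) >= 1
        # deepest gap centre lies midway between columns 30 and 52
        r, c = sites[0].centre_rc
        assert abs(c - 41) * 0.16 <= 0.5

    def test_boxes_fully_inside_roi(self):
        sk, _ = self._gap_skeleton()
        roi = np.zeros((64, 64), bool)
        roi[6:58, 6:58] = True
        for site in classify_sites(sk, roi, n_sites=10, seed=1):
            rs, cs = site.slices()
            assert roi[rs, cs].all()


class TestLocalTTF50:
    def test_self_consistency_with_global_trace(self):
        vid = ramp_video(shape=(21, 21))
        roi = np.ones(vid.frame_shape, bool)
        _, kin = global_transient(vid, roi, 10)
        from dyadscape.calcium_kinetics import LocalSite
        site = LocalSite((10, 10), 3, TRANSVERSE)
        ttf50, flag = local_ttf50(vid, site, kin)
        assert flag == "ok"
        assert ttf50 >= 0
        # local trace == global trace: ttf50 = global tf50 - onset offset
        onset_offset = kin.rise_onset_ms - kin.stimulus_frame * vid.frame_interval_ms
        assert ttf50 == pytest.approx(kin.tf50_ms - onset_offset, abs=0.2)

    def test_programmed_delay_recovered(self):
        # two synthetic regions sharing the rise shape, one delayed by d
        d = 12.0
        n, dt = 160, 1.5
        times = np.arange(n) * dt
        frames = np.full((n, 24, 24), 100.0)
        g = lambda u: np.where(u > 0, (1 - np.exp(-u / 10.0)), 0.0) * 200.0
        frames[:, :, :12] += g(times - 30.0)[:, None, None]
        frames[:, :, 12:] += g(times - 30.0 - d)[:, None, None]
        vid = VideoStack(frames, dt, 0.16)
        roi = np.ones((24, 24), bool)
        _, kin = global_transient(vid, roi, 10)
        from dyadscape.calcium_kinetics import LocalSite
        early = local_ttf50(vid, LocalSite((12, 5), 3, TRANSVERSE), kin)[0]
        late = local_ttf50(vid, LocalSite((12, 18), 3, ORPHANED), kin)[0]
        assert late - early == pytest.approx(d, abs=dt)

    def test_orphaned_sites_lag_transverse_sites(self):
        # propagation-limited release: orphan sites must time later than
        # tubule-adjacent sites in every seeded replicate
        wins = 0
        n_seeds = 4
        for seed in range(n_seeds):
            net = TubuleNetworkSpec(
                cell_length_um=11.0, cell_width_um=9.0, pixel_size_um=0.16,
                margin_um=0.8, transverse_occupancy=0.55,
                longitudinal_density_per_um2=0.02, photon_scale=math.inf,
                seed=seed)
            spec = CalciumSpec(network=net, seed=seed, site_delay_mean_ms=8.0,
                               site_delay_sd_ms=2.0,
                               orphan_propagation_speed_um_per_ms=0.1)
            vid, truth = generate_calcium_video(spec)
            roi = truth.footprint
            _, kin = global_transient(vid, roi, spec.stimulus_frame)
            sites = classify_sites(truth.true_skeleton(), roi, n_sites=5, seed=seed)
            med = {}
            for cat in (TRANSVERSE, ORPHANED):
                vals = [local_ttf50(vid, s, kin)[0]
                        for s in sites if s.category == cat]
                vals = [v for v in vals if v is not None]
                if vals:
                    med[cat] = np.median(vals)
            if ORPHANED in med and TRANSVERSE in med and med[ORPHANED] > med[TRANSVERSE]:
                wins += 1
        assert wins == n_seeds
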