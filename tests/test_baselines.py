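import numpy as np
import pytest

import poolloc as pl
from poolloc.baselines import SRPConfig, pairwise_correlations, \
    spherical_interpolation, srp_localize
from poolloc.features import central_slice
from poolloc.geometry import HydrophoneGeometry, HydrophoneRecord


class TestSphericalInterpolation:
    def test_exact_tdoas_recover_p3(self, env):
        p3 = np.array([15.18, -4.91, 0.0])
        tau = pl.expected_tdoas(p3, c=env.sound_speed)
        est = spherical_interpolation(tau, c=env.sound_speed)
        assert np.linalg.norm(est - p3) < 1e-6

    def test_one_sample_jitter_stays_under_a_meter(self, env):
        rng = np.random.default_rng(8)
        fs = env.sampling_rate
        errs = []
        for loc in pl.DEFAULT_SOURCE_LOCATIONS:
            tau = pl.expected_tdoas(loc.position, c=env.sound_speed)
            for _ in range(5):
                jit = tau + rng.integers(-1, 2, tau.size) / fs
                est = spherical_interpolation(jit, c=env.sound_speed)
                errs.append(np.linalg.norm(est - np.asarray(loc.position)))
        assert np.median(errs) < 1.0

    def test_gauge_invariance(self, env):
        """TDOAs built from arrival times are unchanged by a clock offset,
        so the SI estimate is too."""
        src = np.array([12.0, -6.0, -2.0])
        pos = pl.DEFAULT_HYDROPHONES.positions
        toa = np.linalg.norm(pos - src, axis=1) / env.sound_speed
        for offset in (0.0, 1.7):
            t = toa + offset
            tau_ref = t[0] - t[1:]        # tau_1j = t_1 - t_j
            est = spherical_interpolation(tau_ref, c=env.sound_speed)
            assert np.linalg.norm(est - src) < 1e-6

    def test_zero_tdoas_symmetric_array_gives_equidistant_point(self):
        # 16 hydrophones on a 10-m sphere about the origin: zero TDOAs are
        # consistent with the center
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        phi = np.tile([-0.5, -0.2, 0.2, 0.5], 4)
        recs = []
        for k, (a, p) in enumerate(zip(theta, phi)):
            pos = (10 * np.cos(p) * np.cos(a), 10 * np.cos(p) * np.sin(a),
                   10 * np.sin(p))
            recs.append(HydrophoneRecord(k + 1, f"H{k % 4 + 1}",
                                         f"S{k // 4 + 1}", pos))
        geom = HydrophoneGeometry(tuple(recs))
        est = spherical_interpolation(np.zeros(15), geom, c=1500.0)
        assert np.linalg.norm(est) < 1e-6

    def test_collinear_array_rejected(self):
        recs = tuple(
            HydrophoneRecord(k + 1, f"H{k % 4 + 1}", f"S{k // 4 + 1}",
                             (float(k), 0.0, 0.0))
            for k in range(16)
        )
        geom = HydrophoneGeometry(recs)
        with pytest.raises(np.linalg.LinAlgError):
            spherical_interpolation(np.zeros(15), geom, c=1500.0)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            spherical_interpolation(np.zeros(7))


class TestSRP:
    def test_true_corner_beats_distant_corner(self, env, anechoic_p10):
        snip, src = anechoic_p10
        corr = pairwise_correlations(snip)
        near = tuple((src[k] - 0.1, src[k] + 0.1) for k in range(3))
        far_pt = src + np.array([5.0, 2.0, 1.0])
        far = tuple((far_pt[k] - 0.1, far_pt[k] + 0.1) for k in range(3))
        _, near_info = srp_localize(
            snip, env=env, cfg=SRPConfig(0.1, search_bounds=near),
            correlations=corr)
        _, far_info = srp_localize(
            snip, env=env, cfg=SRPConfig(0.1, search_bounds=far),
            correlations=corr)
        assert near_info["score"] >= far_info["score"]

    def test_grid_refinement_non_increasing_error(self, env, anechoic_p10):
        snip, src = anechoic_p10
        corr = pairwise_correlations(snip)
        bounds = tuple((src[k] - 2.0, src[k] + 2.0) for k in range(3))
        errs = []
        for edge in (0.30, 0.15, 0.075):
            pt, _ = srp_localize(
                snip, env=env,
                cfg=SRPConfig(edge, search_bounds=bounds),
                correlations=corr)
            errs.append(np.linalg.norm(pt - src))
        tol = 1e-9
        assert errs[0] >= errs[1] - tol
        assert errs[1] >= errs[2] - tol

    def test_silent_channel_still_returns_a_corner(self, env, anechoic_p10):
        snip, src = anechoic_p10
        data = snip.data.copy()
        data[4] = 0.0
        from poolloc.simulate import MultiChannelRecording
        from poolloc.snippets import Snippet
        crippled = Snippet(MultiChannelRecording(data, snip.fs))
        bounds = tuple((src[k] - 1.0, src[k] + 1.0) for k in range(3))
        pt, info = srp_localize(crippled, env=env,
                                cfg=SRPConfig(0.3, search_bounds=bounds))
        assert pt.shape == (3,)
        assert np.isfinite(info["score"])

    def test_empty_region_rejected(self, env, anechoic_p10):
        snip, _ = anechoic_p10
        bounds = ((100.0, 101.0), (100.0, 101.0), (0.0, 1.0))
        with pytest.raises(ValueError):
            srp_localize(snip, env=env,
                         cfg=SRPConfig(0.3, search_bounds=bounds))

    def test_central_slice_correlations_equivalent(self, env, anechoic_p10):
        """When every looked-up lag is within +-3300 samples, scoring from
        the sliced correlations equals scoring from the full series."""
        snip, src = anechoic_p10
        corr = pairwise_correlations(snip)
        n = corr.shape[1]
        sliced = np.zeros_like(corr)
        width = 6601
        sl = central_slice(corr, width)          # (120, 6601), lag ascending
        half = (width - 1) // 2
        sliced[:, :half + 1] = sl[:, half:]
        sliced[:, n - half:] = sl[:, :half]
        bounds = tuple((src[k] - 1.0, src[k] + 1.0) for k in range(3))
        cfg = SRPConfig(0.15, search_bounds=bounds)
        pt_full, info_full = srp_localize(snip, env=env, cfg=cfg,
                                          correlations=corr)
        pt_sl, info_sl = srp_localize(snip, env=env, cfg=cfg,
                                      correlations=sliced)
        assert np.array_equal(pt_full, pt_sl)
        assert info_full["score"] == pytest.approx(info_sl["score"])

    def test_phat_variant_runs(self, env, anechoic_p10):
        snip, src = anechoic_p10
        bounds = tuple((src[k] - 0.5, src[k] + 0.5) for k in range(3))
        pt, _ = srp_localize(
            snip, env=env,
            cfg=SRPConfig(0.25, use_phat=True, search_bounds=bounds))
        assert pl.in_pool(pt, env)

    def test_lag_window_variant_is_no_worse_nearby(self, env, anechoic_p10):
        """The robust lag-window score tolerates within-cell lag spread,
        so at a coarse grid its error should not exceed the plain
        lookup's by much; both must return in-pool points."""
        snip, src = anechoic_p10
        bounds = tuple((src[k] - 2.0, src[k] + 2.0) for k in range(3))
        errs = {}
        for w in (0, 10):
            pt, _ = srp_localize(
                snip, env=env,
                cfg=SRPConfig(0.30, lag_window=w, search_bounds=bounds))
            errs[w] = np.linalg.norm(pt - src)
            assert pl.in_pool(pt, env)
        assert errs[10] <= errs[0] + 0.30
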