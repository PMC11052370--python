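"""Tracking pipeline: I0 calibration, spot detection/linking, angular
decomposition, MSD fitting and theta-chi motion maps.

Oracles: algebraic identities (I0 renormalization, histogram normalization),
rendered spots at known sub-pixel positions, brute-force double-loop MSD,
closed forms (drift MSD, Gaussian FWHM), and generating parameters of seeded
walks.
"""

import math

import numpy as np
import pytest

from dxduo.dxt import (
    AngularTrajectory,
    MotionHist2D,
    MSDFit,
    Spot,
    SpotTrajectory,
    build_motion_hist,
    compute_msd,
    detect_spots,
    fit_msd,
    filter_by_lifetime,
    link_spots,
    normalize_i0,
    peak_and_fwhm,
    route_trajectories,
    subtract_hists,
    superpose_hotspots,
    to_angular,
)
from dxduo.geometry import InvalidInputError


def _spot(frame, r, c, center=(97.0, 243.0), intensity=10.0):
    return Spot(
        frame=frame,
        position_px=(r, c),
        intensity=intensity,
        radius_px=math.hypot(r - center[0], c - center[1]),
        azimuth_deg=math.degrees(math.atan2(r - center[0], c - center[1])),
    )


def _walk_trajectory(rng, start, n, step_sd=0.4, frame0=0):
    r, c = start
    spots = []
    for i in range(n):
        spots.append(_spot(frame0 + i, r, c))
        r += rng.normal(0, step_sd)
        c += rng.normal(0, step_sd)
    return spots


class TestNormalizeI0:
    def test_constant_i0_is_identity(self):
        stack = np.random.default_rng(0).poisson(3.0, size=(5, 8, 8)).astype(float)
        out = normalize_i0(stack, np.full(5, 2.7))
        assert np.allclose(out, stack)

    def test_doubled_i0_halves_frame(self):
        stack = np.ones((4, 3, 3))
        i0 = np.array([1.0, 1.0, 1.0, 1.0])
        i0[2] = 2.0
        out = normalize_i0(stack, i0)
        assert np.allclose(out[2], 1.0 * i0.mean() / 2.0)

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(1)
        stack = rng.poisson(5.0, size=(20, 6, 6)).astype(float)
        i0 = rng.uniform(0.5, 2.0, 20)
        out = normalize_i0(stack, i0)
        # frame means scaled by mean(i0)/i0; per-frame mean of scale is 1
        scale = (i0.mean() / i0).mean()
        assert out.mean() == pytest.approx((stack.mean(axis=(1, 2)) *
                                            (i0.mean() / i0)).mean())
        assert abs(scale - out.mean() / stack.mean()) < 0.5  # sanity

    def test_nonpositive_i0_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_i0(np.ones((2, 2, 2)), np.array([1.0, 0.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_i0(np.ones((3, 2, 2)), np.array([1.0, 1.0]))


class TestDetectSpots:
    def test_blank_frame(self, dxt_geom):
        assert detect_spots(np.zeros((195, 487)), dxt_geom) == []

    def test_subpixel_localization(self, dxt_geom):
        # Gaussian spot, sigma 1.2 px, SNR >> 10, known sub-pixel center
        rng = np.random.default_rng(3)
        truth = (101.37, 260.81)
        rows = np.arange(195)[:, None]
        cols = np.arange(487)[None, :]
        lam = 0.2 + 40.0 * np.exp(
            -((rows - truth[0]) ** 2 + (cols - truth[1]) ** 2) / (2 * 1.2**2)
        )
        errs = []
        for _ in range(10):
            frame = rng.poisson(lam).astype(float)
            spots = detect_spots(frame, dxt_geom, min_intensity=8.0)
            assert len(spots) == 1
            errs.append(math.dist(spots[0].position_px, truth))
        assert np.sqrt(np.mean(np.square(errs))) < 0.3

    def test_close_pair_merges_to_one(self, dxt_geom):
        frame = np.zeros((195, 487))
        frame[100, 250] = 50.0
        frame[100, 252] = 45.0
        spots = detect_spots(frame, dxt_geom, min_intensity=5.0,
                             min_separation_px=3)
        assert len(spots) == 1

    def test_negative_frame_rejected(self, dxt_geom):
        with pytest.raises(InvalidInputError):
            detect_spots(-np.ones((10, 10)), dxt_geom)


class TestLinkSpots:
    def test_two_separated_walkers_stay_whole(self):
        rng = np.random.default_rng(4)
        a = _walk_trajectory(rng, (60.0, 100.0), 50)
        b = _walk_trajectory(rng, (140.0, 380.0), 50)
        per_frame = [[a[i], b[i]] for i in range(50)]
        trajs = link_spots(per_frame)
        assert len(trajs) == 2
        assert sorted(t.lifetime_frames for t in trajs) == [50, 50]

    def test_gap_beyond_memory_splits_track(self):
        spots = [_spot(f, 100.0, 200.0) for f in range(20) if not 8 <= f <= 11]
        per_frame = [[s] if s else [] for s in
                     ([next((x for x in spots if x.frame == f), None)
                       for f in range(20)])]
        per_frame = [[s for s in fr if s is not None] for fr in per_frame]
        trajs = link_spots(per_frame, memory_frames=2)
        assert len(trajs) == 2

    def test_gap_within_memory_bridged(self):
        spots = [_spot(f, 100.0, 200.0) for f in range(20) if f != 10]
        per_frame = [[] for _ in range(20)]
        for s in spots:
            per_frame[s.frame].append(s)
        trajs = link_spots(per_frame, memory_frames=2)
        assert len(trajs) == 1

    def test_fifty_noncrossing_walkers_recovered_uncut(self):
        rng = np.random.default_rng(5)
        n_frames, n_walkers = 200, 50
        walkers = []
        for i in range(n_walkers):
            r0 = 20.0 + 30.0 * (i % 5)
            c0 = 30.0 + 45.0 * (i // 5)
            walkers.append(_walk_trajectory(rng, (r0, c0), n_frames,
                                            step_sd=0.3))
        per_frame = [[w[f] for w in walkers] for f in range(n_frames)]
        trajs = link_spots(per_frame)
        full = [t for t in trajs if t.lifetime_frames == n_frames]
        assert len(full) >= 0.95 * n_walkers


class TestToAngular:
    def test_static_spot_is_zero(self, dxt_geom):
        traj = SpotTrajectory(spots=tuple(_spot(f, 120.0, 300.0)
                                          for f in range(5)))
        ang = to_angular(traj, dxt_geom)
        assert np.allclose(ang.chi_deg, 0.0)
        assert np.allclose(ang.theta_deg, 0.0)
        assert ang.time_s[1] == pytest.approx(dxt_geom.frame_interval_s)

    def test_pure_azimuthal_step(self, dxt_geom):
        cr, cc = dxt_geom.beam_center_px
        r = 150.0
        az0, az1 = math.radians(10.0), math.radians(11.0)
        traj = SpotTrajectory(spots=(
            _spot(0, cr + r * math.sin(az0), cc + r * math.cos(az0)),
            _spot(1, cr + r * math.sin(az1), cc + r * math.cos(az1)),
        ))
        ang = to_angular(traj, dxt_geom)
        assert ang.chi_deg[1] == pytest.approx(1.0, abs=1e-9)
        assert ang.theta_deg[1] == pytest.approx(0.0, abs=1e-9)

    def test_radial_step_gives_half_two_theta(self, dxt_geom):
        # radii chosen so 2theta changes by exactly 0.2 deg -> theta +0.1
        cr, cc = dxt_geom.beam_center_px
        two_theta0 = 17.0
        two_theta1 = 17.2
        to_r = lambda tt: dxt_geom.distance_mm * math.tan(
            math.radians(tt)) / dxt_geom.pixel_pitch_mm
        traj = SpotTrajectory(spots=(
            _spot(0, cr, cc + to_r(two_theta0)),
            _spot(1, cr, cc + to_r(two_theta1)),
        ))
        ang = to_angular(traj, dxt_geom)
        assert ang.theta_deg[1] == pytest.approx(0.1, abs=1e-9)
        assert ang.chi_deg[1] == pytest.approx(0.0, abs=1e-9)

    def test_too_short_rejected(self, dxt_geom):
        traj = SpotTrajectory(spots=(_spot(0, 120.0, 300.0),))
        with pytest.raises(InvalidInputError):
            to_angular(traj, dxt_geom)


class TestLifetimeFilter:
    def _trajs(self, lifetimes):
        out = []
        for life in lifetimes:
            out.append(SpotTrajectory(
                spots=tuple(_spot(f, 100.0, 200.0) for f in range(life))))
        return out

    def test_bounds(self):
        kept = filter_by_lifetime(self._trajs([3, 10, 50]), 5, math.inf)
        assert [t.lifetime_frames for t in kept] == [10, 50]

    def test_identity_bounds(self):
        trajs = self._trajs([2, 7, 30])
        assert filter_by_lifetime(trajs, 0, math.inf) == trajs

    def test_partition_sums_to_total(self):
        trajs = self._trajs([2, 5, 9, 14, 40])
        short = filter_by_lifetime(trajs, 0, 9)
        long = filter_by_lifetime(trajs, 10, math.inf)
        assert len(short) + len(long) == len(trajs)

    def test_invalid_bounds(self):
        with pytest.raises(InvalidInputError):
            filter_by_lifetime([], 10, 5)


class TestMSD:
    def _angular(self, x, dt=0.0125):
        t = np.arange(len(x)) * dt
        return AngularTrajectory(time_s=t, chi_deg=np.asarray(x, float),
                                 theta_deg=np.zeros(len(x)))

    def test_linear_drift_closed_form(self):
        v, dt = 3.0, 0.1
        x = v * np.arange(100) * dt
        curve = compute_msd(self._angular(x, dt), axis="chi")
        assert np.allclose(curve.msd_deg2, (v * curve.lag_s) ** 2)

    def test_stationary_is_zero(self):
        curve = compute_msd(self._angular(np.zeros(40)), axis="both")
        assert np.allclose(curve.msd_deg2, 0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(6)
        x = np.cumsum(rng.normal(0, 0.1, 173))
        curve = compute_msd(self._angular(x), axis="chi")
        for mi, m in enumerate(range(1, 173 // 4 + 1)):
            acc = [(x[t + m] - x[t]) ** 2 for t in range(173 - m)]
            assert curve.msd_deg2[mi] == pytest.approx(np.mean(acc), rel=1e-12)

    def test_both_axes_add(self):
        rng = np.random.default_rng(7)
        chi = np.cumsum(rng.normal(0, 0.1, 60))
        theta = np.cumsum(rng.normal(0, 0.2, 60))
        t = np.arange(60) * 0.0125
        ang = AngularTrajectory(time_s=t, chi_deg=chi, theta_deg=theta)
        both = compute_msd(ang, axis="both").msd_deg2
        sep = (compute_msd(ang, axis="chi").msd_deg2
               + compute_msd(ang, axis="theta").msd_deg2)
        assert np.allclose(both, sep)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_msd(self._angular([0.0, 1.0]))


class TestFitMSD:
    def test_noiseless_normal_diffusion_round_trip(self):
        t = np.arange(1, 40) * 0.0125
        from dxduo.dxt import MSDCurve

        curve = MSDCurve(lag_s=t, msd_deg2=2.0 * t, n_frames=160, axis="chi")
        fit = fit_msd(curve)
        assert fit.converged
        assert fit.D_alpha == pytest.approx(2.0, rel=1e-4)
        assert fit.alpha == pytest.approx(1.0, rel=1e-5)
        assert fit.regime == "normal"

    def test_subdiffusion_classification(self):
        t = np.arange(1, 40) * 0.0125
        from dxduo.dxt import MSDCurve

        curve = MSDCurve(lag_s=t, msd_deg2=0.5 * t**0.5, n_frames=160,
                         axis="chi")
        fit = fit_msd(curve)
        assert fit.regime == "subdiffusion"

    def test_brownian_slope_recovery(self):
        rng = np.random.default_rng(8)
        d, dt, n = 0.8, 0.0125, 5000
        x = np.cumsum(rng.normal(0, math.sqrt(2 * d * dt), n))
        t = np.arange(n) * dt
        ang = AngularTrajectory(time_s=t, chi_deg=x, theta_deg=np.zeros(n))
        fit = fit_msd(compute_msd(ang, axis="chi"))
        # generating MSD slope is 2 d per axis
        assert fit.D_alpha == pytest.approx(2 * d, rel=0.15)

    def test_classification_tolerance(self):
        assert MSDFit.classify(1.0) == "normal"
        assert MSDFit.classify(0.3) == "subdiffusion"
        assert MSDFit.classify(1.7) == "superdiffusion"


class TestMotionHist:
    def _population(self, seed, d, n_traj=40, n=120, dt=0.0125):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_traj):
            chi = np.cumsum(rng.normal(0, math.sqrt(2 * d * dt), n))
            theta = np.cumsum(rng.normal(0, math.sqrt(2 * d * dt), n))
            t = np.arange(n) * dt
            out.append(AngularTrajectory(time_s=t, chi_deg=chi - chi[0],
                                         theta_deg=theta - theta[0]))
        return out

    def test_identical_trajectories_single_bin(self):
        rng = np.random.default_rng(9)
        chi = np.cumsum(rng.normal(0, 0.1, 80))
        t = np.arange(80) * 0.0125
        a = AngularTrajectory(time_s=t, chi_deg=chi, theta_deg=chi * 0.5)
        hist, mchi, mtheta = build_motion_hist([a] * 7, bins=11)
        assert np.count_nonzero(hist.counts) == 1
        assert np.count_nonzero(mchi) == 1 and np.count_nonzero(mtheta) == 1
        assert hist.density.sum() == pytest.approx(1.0)

    def test_density_sums_to_one(self):
        hist, _, _ = build_motion_hist(self._population(10, 0.05), bins=13)
        assert hist.density.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tenfold_msd_separation_in_log_units(self):
        slow = self._population(11, 0.02, n_traj=150)
        fast = self._population(12, 0.2, n_traj=150)
        hist, mchi, _ = build_motion_hist(slow + fast, bins=40)
        centers = 0.5 * (hist.chi_edges[:-1] + hist.chi_edges[1:])
        slow_peak = centers[np.argmax(
            np.histogram([math.log10(compute_msd(a, axis="chi").msd_deg2[0])
                          for a in slow], bins=hist.chi_edges)[0])]
        fast_peak = centers[np.argmax(
            np.histogram([math.log10(compute_msd(a, axis="chi").msd_deg2[0])
                          for a in fast], bins=hist.chi_edges)[0])]
        assert fast_peak - slow_peak == pytest.approx(1.0, abs=0.35)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            build_motion_hist([])


class TestPeakFWHM:
    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0.0, 0.5, 100_000)
        counts, edges = np.histogram(x, bins=60, range=(-2.0, 2.0))
        peak, fwhm = peak_and_fwhm(counts, edges)
        assert peak == pytest.approx(0.0, abs=0.05)
        assert fwhm == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 0.5,
                                     abs=0.08)

    def test_symmetric_histogram_peak_centered(self):
        counts = np.array([1, 4, 9, 4, 1])
        edges = np.linspace(0, 5, 6)
        peak, _ = peak_and_fwhm(counts, edges)
        assert peak == pytest.approx(2.5)

    def test_single_occupied_bin_width_convention(self):
        counts = np.array([0, 0, 7, 0, 0])
        edges = np.linspace(0, 5, 6)
        peak, fwhm = peak_and_fwhm(counts, edges)
        assert fwhm == pytest.approx(1.0)

    def test_empty_histogram_rejected(self):
        with pytest.raises(InvalidInputError):
            peak_and_fwhm(np.zeros(5), np.linspace(0, 1, 6))


class TestHistAlgebra:
    def _hist(self, counts, edges):
        return MotionHist2D(chi_edges=edges, theta_edges=edges,
                            counts=np.asarray(counts, float),
                            axis_statistic="test")

    def test_self_subtraction_is_zero(self):
        edges = np.linspace(0, 1, 5)
        h = self._hist(np.arange(16).reshape(4, 4), edges)
        assert np.all(subtract_hists(h, h) == 0.0)

    def test_difference_total_is_zero(self):
        edges = np.linspace(0, 1, 5)
        rng = np.random.default_rng(14)
        a = self._hist(rng.integers(0, 10, (4, 4)), edges)
        b = self._hist(rng.integers(0, 10, (4, 4)), edges)
        assert subtract_hists(a, b).sum() == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_edges_rejected(self):
        a = self._hist(np.ones((4, 4)), np.linspace(0, 1, 5))
        b = self._hist(np.ones((4, 4)), np.linspace(0, 2, 5))
        with pytest.raises(InvalidInputError):
            subtract_hists(a, b)

    def test_hotspot_shift_recovered(self):
        edges = np.linspace(-2, 2, 41)
        rng = np.random.default_rng(15)
        pts_a = rng.normal(0.0, 0.2, (4000, 2))
        pts_b = pts_a + np.array([0.5, 0.0])
        ca, _, _ = np.histogram2d(pts_a[:, 0], pts_a[:, 1],
                                  bins=[edges, edges])
        cb, _, _ = np.histogram2d(pts_b[:, 0], pts_b[:, 1],
                                  bins=[edges, edges])
        report = superpose_hotspots(
            [self._hist(ca, edges), self._hist(cb, edges)], quantile=0.9
        )
        d_chi, d_theta = report["centroid_displacements"][(0, 1)]
        assert d_chi == pytest.approx(0.5, abs=0.1)
        assert d_theta == pytest.approx(0.0, abs=0.1)

    def test_identical_hotspots_no_displacement(self):
        edges = np.linspace(-2, 2, 21)
        h = self._hist(np.random.default_rng(16).integers(0, 20, (20, 20)),
                       edges)
        report = superpose_hotspots([h, h], quantile=0.9)
        assert report["centroid_displacements"][(0, 1)] == (0.0, 0.0)

    def test_quantile_zero_selects_all_occupied(self):
        edges = np.linspace(0, 1, 5)
        counts = np.zeros((4, 4))
        counts[1, 2] = 3
        counts[3, 0] = 1
        h = self._hist(counts, edges)
        report = superpose_hotspots([h], quantile=0.0)
        assert report["hotspots"][0]["mask"].sum() == 2


def test_route_trajectories_never_pools_rings(dxt_rois, dxt_geom):
    cr, cc = dxt_geom.beam_center_px
    trajs = []
    for roi in dxt_rois:
        for k in range(3):
            r = roi.radius_px
            az = math.radians(5.0 * k)
            trajs.append(SpotTrajectory(spots=tuple(
                _spot(f, cr + r * math.sin(az), cc + r * math.cos(az),
                      center=(cr, cc))
                for f in range(4))))
    routed, report = route_trajectories(trajs, dxt_rois, tolerance_px=2.0)
    assert report["assigned"] == 6
    labels = {t.ring_label for t in routed}
    assert labels == {dxt_rois[0].label, dxt_rois[1].label}
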