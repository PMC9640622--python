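"""Cluster identification, classification and coarsening-law tests."""

import math

import numpy as np
import pytest

from commswarm import clusters
from commswarm.fixtures import make_fixtures
from commswarm.signaling import ParameterError


def disc_field(M, L, center, radius, value=1.5, background=0.6):
    x = np.arange(M) * L / M
    X, Y = np.meshgrid(x, x, indexing="ij")
    dx = X - center[0] - L * np.round((X - center[0]) / L)
    dy = Y - center[1] - L * np.round((Y - center[1]) / L)
    rho = np.full((M, M), background)
    rho[np.hypot(dx, dy) < radius] = value
    return rho


def ellipse_mask_field(M, L, center, a, b, theta=0.0, value=1.5, background=0.6):
    x = np.arange(M) * L / M
    X, Y = np.meshgrid(x, x, indexing="ij")
    dx = X - center[0] - L * np.round((X - center[0]) / L)
    dy = Y - center[1] - L * np.round((Y - center[1]) / L)
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    rho = np.full((M, M), background)
    rho[(u / a) ** 2 + (v / b) ** 2 < 1] = value
    return rho


class TestBinarizeAndLabel:
    def test_uniform_subthreshold_gives_no_components(self):
        labels, n = clusters.binarize_and_label(np.full((64, 64), 0.6))
        assert n == 0

    def test_single_disc(self):
        rho = disc_field(64, 64.0, (32, 32), 8.0)
        _, n = clusters.binarize_and_label(rho)
        assert n == 1

    def test_disc_across_periodic_edge_is_one_component(self):
        rho = disc_field(64, 64.0, (0.0, 32.0), 8.0)
        labels, n = clusters.binarize_and_label(rho)
        assert n == 1

    def test_corner_disc_is_one_component(self):
        rho = disc_field(64, 64.0, (0.0, 0.0), 6.0)
        _, n = clusters.binarize_and_label(rho)
        assert n == 1

    def test_strictly_above_threshold(self):
        rho = np.full((16, 16), 0.7)
        _, n = clusters.binarize_and_label(rho, 0.7)
        assert n == 0


class TestClusterShape:
    def test_disc_is_round(self):
        rho = disc_field(128, 128.0, (64, 64), 12.0)
        labels, _ = clusters.binarize_and_label(rho)
        rec = clusters.cluster_shape(labels, rho, 128.0)[0]
        assert 1.0 <= rec.shape_factor <= 1.1

    def test_two_to_one_ellipse(self):
        rho = ellipse_mask_field(128, 128.0, (64, 64), 24.0, 12.0)
        labels, _ = clusters.binarize_and_label(rho)
        rec = clusters.cluster_shape(labels, rho, 128.0)[0]
        assert rec.shape_factor == pytest.approx(2.0, rel=0.05)
        ang = min(rec.orientation, math.pi - rec.orientation)
        assert ang < math.radians(2.0)
        # equivalent-ellipse diameters recover the true axes
        assert rec.major_axis == pytest.approx(48.0, rel=0.05)

    def test_shape_invariant_under_90_degree_rotation(self):
        rho = ellipse_mask_field(128, 128.0, (64, 64), 20.0, 9.0, theta=0.3)
        labels, _ = clusters.binarize_and_label(rho)
        rec = clusters.cluster_shape(labels, rho, 128.0)[0]
        rho_rot = np.rot90(rho).copy()
        labels_rot, _ = clusters.binarize_and_label(rho_rot)
        rec_rot = clusters.cluster_shape(labels_rot, rho_rot, 128.0)[0]
        assert rec_rot.shape_factor == pytest.approx(rec.shape_factor, abs=1e-12)

    def test_shape_invariant_under_30_degree_rotation(self):
        recs = {}
        for theta in (0.0, math.radians(30)):
            rho = ellipse_mask_field(192, 192.0, (96, 96), 30.0, 15.0, theta)
            labels, _ = clusters.binarize_and_label(rho)
            recs[theta] = clusters.cluster_shape(labels, rho, 192.0)[0]
        assert recs[math.radians(30)].shape_factor == pytest.approx(
            recs[0.0].shape_factor, rel=0.03
        )
        assert recs[math.radians(30)].orientation == pytest.approx(
            math.radians(30), abs=math.radians(2)
        )

    def test_single_pixel_cluster_shape_factor_one(self):
        rho = np.full((32, 32), 0.6)
        rho[5, 7] = 1.5
        labels, _ = clusters.binarize_and_label(rho)
        rec = clusters.cluster_shape(labels, rho, 32.0)[0]
        assert rec.shape_factor == pytest.approx(1.0)

    def test_mass_is_integrated_density(self):
        rho = disc_field(64, 64.0, (32, 32), 8.0, value=1.5)
        labels, _ = clusters.binarize_and_label(rho)
        rec = clusters.cluster_shape(labels, rho, 64.0)[0]
        npix = (labels == 1).sum()
        assert rec.mass == pytest.approx(1.5 * npix * 1.0)

    def test_third_moments_vanish_for_symmetric_mask(self):
        rho = disc_field(128, 128.0, (64, 64), 12.0)
        labels, _ = clusters.binarize_and_label(rho)
        rec = clusters.cluster_shape(labels, rho, 128.0)[0]
        for v in rec.third_moments.values():
            assert abs(v) < 1.0  # length^3 units; disc is ~symmetric


class TestClusterFlow:
    def _vortex_setup(self, amp=0.5, radius=12.0):
        M, L = 128, 128.0
        rho = disc_field(M, L, (64, 64), radius)
        x = np.arange(M) * L / M
        X, Y = np.meshgrid(x, x, indexing="ij")
        dx, dy = X - 64.0, Y - 64.0
        inside = np.hypot(dx, dy) < radius
        p = np.zeros((M, M, 2))
        p[..., 0] = np.where(inside, -amp * dy / radius, 0.0)
        p[..., 1] = np.where(inside, amp * dx / radius, 0.0)
        return rho, p, L

    def test_uniform_polarity(self):
        rho = disc_field(64, 64.0, (32, 32), 8.0)
        p = np.zeros((64, 64, 2))
        p[..., 0] = 1.0
        labels, _ = clusters.binarize_and_label(rho)
        recs = clusters.cluster_shape(labels, rho, 64.0)
        clusters.cluster_flow(labels, p, 64.0, recs)
        assert np.allclose(recs[0].mean_polarity, [1.0, 0.0], atol=1e-10)
        assert recs[0].mean_vorticity == pytest.approx(0.0, abs=1e-10)

    def test_rigid_vortex_curl(self):
        """Azimuthal p = amp * r/R e_theta: interior curl is 2 amp / R; the
        cluster mean (which includes the smeared boundary circulation sheet)
        is positive, classification-relevant, and matches an independent
        finite-difference curl oracle on the same mask."""
        amp, radius = 0.5, 12.0
        rho, p, L = self._vortex_setup(amp, radius)
        labels, _ = clusters.binarize_and_label(rho)
        recs = clusters.cluster_shape(labels, rho, L)
        clusters.cluster_flow(labels, p, L, recs)
        assert np.linalg.norm(recs[0].mean_polarity) < 0.02
        dx = L / rho.shape[0]
        curl_fd = (
            (np.roll(p[..., 1], -1, 0) - np.roll(p[..., 1], 1, 0))
            - (np.roll(p[..., 0], -1, 1) - np.roll(p[..., 0], 1, 1))
        ) / (2 * dx)
        oracle = curl_fd[labels == 1].mean()
        assert recs[0].mean_vorticity > clusters.VORTICITY_MIN
        assert recs[0].mean_vorticity == pytest.approx(oracle, rel=0.10)
        # well inside the disc the pointwise curl is the rigid-body value
        inner = np.hypot(*np.meshgrid(
            np.arange(rho.shape[0]) * dx - 64.0,
            np.arange(rho.shape[0]) * dx - 64.0, indexing="ij",
        )) < radius / 2
        from commswarm._spectral import spectral_curl

        curl_sp = spectral_curl(p[..., 0], p[..., 1], L)
        assert curl_sp[inner].mean() == pytest.approx(2 * amp / radius, rel=0.05)

    def test_sign_flip(self):
        rho, p, L = self._vortex_setup()
        labels, _ = clusters.binarize_and_label(rho)
        r1 = clusters.cluster_shape(labels, rho, L)
        clusters.cluster_flow(labels, p, L, r1)
        r2 = clusters.cluster_shape(labels, rho, L)
        clusters.cluster_flow(labels, -p, L, r2)
        assert r2[0].mean_vorticity == pytest.approx(-r1[0].mean_vorticity)


class TestClassify:
    def rec(self, shape, orientation=0.0, polarity=(1.0, 0.0), vorticity=0.0):
        return clusters.ClusterRecord(
            label=1, n_pixels=100, mass=100.0, centroid=(0, 0),
            major_axis=10.0, minor_axis=10.0 / shape, orientation=orientation,
            shape_factor=shape, mean_polarity=np.asarray(polarity, float),
            mean_vorticity=vorticity,
        )

    def test_elongated_aligned_is_stream(self):
        assert clusters.classify_cluster(self.rec(2.0, 0.1)) == "stream"

    def test_round_rotating_is_vortex(self):
        r = self.rec(1.0, polarity=(0.0, 0.0), vorticity=0.05)
        assert clusters.classify_cluster(r) == "vortex"

    def test_residual_cases_are_droplets(self):
        assert clusters.classify_cluster(
            self.rec(1.0, vorticity=0.001)
        ) == "droplet"
        r = self.rec(2.0, orientation=0.0, polarity=(0.0, 1.0))  # perpendicular
        assert clusters.classify_cluster(r) == "droplet"

    def test_boundary_equalities_resolve_to_droplet(self):
        assert clusters.classify_cluster(self.rec(1.4, vorticity=1.0)) == "droplet"
        r = self.rec(2.0, orientation=0.0, polarity=(1.0, 1.0))  # exactly pi/4
        assert clusters.classify_cluster(r) == "droplet"
        r = self.rec(1.0, vorticity=0.01)  # exactly at the vorticity bound
        assert clusters.classify_cluster(r) == "droplet"

    def test_angle_folded_for_undirected_axis(self):
        # polarity anti-parallel to the major axis still counts as aligned
        r = self.rec(2.0, orientation=0.0, polarity=(-1.0, 0.0))
        assert clusters.classify_cluster(r) == "stream"


class TestInvariances:
    def test_classification_invariant_under_rotation_and_translation(self):
        f = make_fixtures("planted_vortex", seed=1)
        recs = clusters.analyze_field(f.rho, f.p, f.L)
        # translation by a lattice vector
        rho_t = np.roll(f.rho, (13, 29), axis=(0, 1))
        p_t = np.roll(f.p, (13, 29), axis=(0, 1))
        recs_t = clusters.analyze_field(rho_t, p_t, f.L)
        assert [r.cls for r in recs] == [r.cls for r in recs_t]
        assert recs_t[0].shape_factor == pytest.approx(
            recs[0].shape_factor, abs=1e-9
        )
        # 90-degree CCW rotation: (x, y) -> (-y, x), p -> (-p_y, p_x)
        rho_r = np.rot90(f.rho).copy()
        p_r = np.stack(
            [-np.rot90(f.p[..., 1]), np.rot90(f.p[..., 0])], axis=-1
        )
        recs_r = clusters.analyze_field(rho_r, p_r, f.L)
        assert [r.cls for r in recs_r] == [r.cls for r in recs]
        assert recs_r[0].mean_vorticity == pytest.approx(
            recs[0].mean_vorticity, rel=1e-6
        )


class TestPlantedConfusionMatrix:
    KINDS = ("planted_droplet", "planted_stream", "planted_vortex")

    def test_noise_free_classification_is_perfect(self):
        for kind in self.KINDS:
            f = make_fixtures(kind, seed=0)
            recs = clusters.analyze_field(f.rho, f.p, f.L)
            assert len(recs) == 1
            assert recs[0].cls == f.expected_class

    def test_noisy_classification_90_percent_per_class(self):
        """>= 90% per class at 10% field noise, dominant cluster judged."""
        n_trials = 20
        for kind in self.KINDS:
            hits = 0
            for trial in range(n_trials):
                f = make_fixtures(kind, {"noise": 0.1}, seed=100 + trial)
                recs = clusters.analyze_field(f.rho, f.p, f.L)
                if not recs:
                    continue
                dominant = max(recs, key=lambda r: r.mass)
                hits += dominant.cls == f.expected_class
            assert hits >= 0.9 * n_trials, kind


class TestClusterSeries:
    def make_frame(self, centers, M=64, L=64.0):
        rho = np.full((M, M), 0.6)
        for c in centers:
            rho = np.maximum(rho, disc_field(M, L, c, 4.0))
        return rho

    def test_counts_follow_planted_discs(self):
        L = 64.0
        frames = [
            (0.0, self.make_frame([(10, 10), (30, 30), (50, 50)]), None),
            (1.0, self.make_frame([(10, 10), (30, 30)]), None),
            (2.0, self.make_frame([(10, 10)]), None),
        ]
        out = clusters.cluster_series(frames, L)
        assert list(out["N_c"]) == [3, 2, 1]

    def test_static_series_constant(self):
        rho = self.make_frame([(20, 20), (40, 40)])
        out = clusters.cluster_series([(0.0, rho, None), (1.0, rho, None)], 64.0)
        assert list(out["N_c"]) == [2, 2]

    def test_class_counts_partition_total(self):
        rng = np.random.default_rng(0)
        frames = []
        for i in range(3):
            f = make_fixtures("planted_vortex", {"noise": 0.05}, seed=i)
            frames.append((float(i), f.rho, f.p))
        out = clusters.cluster_series(frames, f.L)
        total = out["droplet"] + out["stream"] + out["vortex"]
        assert np.array_equal(total, out["N_c"])

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            clusters.cluster_series([(0.0, np.zeros((8, 8)), None)], 8.0)


class TestCoalescenceModel:
    def test_gamma_zero_closed_form(self):
        """n(t) = n0 / (1 + D0 n0 t) for size-independent diffusion."""
        t = np.geomspace(0.01, 100.0, 50)
        n, z = clusters.coalescence_model(1.0, 1.0, 0.0, t)
        exact = 1.0 / (1.0 + t - t[0])
        assert np.allclose(n, exact, rtol=1e-6)
        assert z == 1.0

    @pytest.mark.parametrize("gamma,z", [(0.0, 1.0), (0.5, 2.0), (0.25, 4 / 3)])
    def test_exponent_relation(self, gamma, z):
        _, got = clusters.coalescence_model(1.0, 1.0, gamma, np.array([1.0, 2.0]))
        assert got == pytest.approx(z)

    def test_gamma_one_rejected(self):
        with pytest.raises(ParameterError):
            clusters.coalescence_model(1.0, 1.0, 1.0, np.array([1.0, 2.0]))

    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.5])
    def test_late_time_exponent_recovered_by_fit(self, gamma):
        """fit_coarsening(power) recovers z = 1/(1-gamma) within 5% on the
        final time decade."""
        t = np.geomspace(1.0, 1e5, 400)
        n, z = clusters.coalescence_model(1.0, 1.0, gamma, t)
        fit = clusters.fit_coarsening(t, n, "power", window=(1e4, 1e5))
        assert fit.params["eta"] == pytest.approx(z, rel=0.05)


class TestFitCoarsening:
    def test_exact_power_law_recovery(self):
        t = np.geomspace(1, 1e3, 100)
        fit = clusters.fit_coarsening(t, 500.0 / t, "power")
        assert fit.params["eta"] == pytest.approx(1.0, abs=1e-6)
        assert fit.params["A"] == pytest.approx(500.0, rel=1e-6)

    def test_exact_stream_law_recovery(self):
        t = np.linspace(1, 200, 100)
        n = (1000.0 - 0.01 * t**2) / t
        fit = clusters.fit_coarsening(t, n, "stream")
        assert fit.params["N0"] == pytest.approx(1000.0, rel=1e-10)
        assert fit.params["kappa"] == pytest.approx(0.01, rel=1e-10)

    def test_log_law_recovery(self):
        t = np.geomspace(2, 1e4, 100)
        fit = clusters.fit_coarsening(t, 300.0 / np.log(t), "log")
        assert fit.params["A"] == pytest.approx(300.0, rel=1e-10)

    def test_noisy_recovery_within_ten_percent(self):
        t, n = make_fixtures(
            "coarsening_series",
            {"law": "stream", "N0": 1000.0, "kappa": 0.01, "noise": 0.05,
             "t": np.linspace(1, 250, 200)},
            seed=3,
        )
        fit = clusters.fit_coarsening(t, n, "stream")
        assert fit.params["N0"] == pytest.approx(1000.0, rel=0.10)
        assert fit.params["kappa"] == pytest.approx(0.01, rel=0.10)

    def test_window_and_minimum_points(self):
        t = np.geomspace(1, 100, 50)
        with pytest.raises(ValueError):
            clusters.fit_coarsening(t[:4], (10 / t)[:4], "power")

    def test_nonpositive_times_rejected(self):
        t = np.linspace(-1, 10, 20)
        with pytest.raises(ValueError):
            clusters.fit_coarsening(t, np.ones(20), "power")


class TestAggregationTime:
    def test_interpolated_crossing(self):
        times = np.array([40.0, 44.0])
        max_rho = np.array([0.9, 1.1])
        assert clusters.aggregation_time(times, max_rho) == pytest.approx(42.0)

    def test_never_crossed_sentinel(self):
        out = clusters.aggregation_time(
            np.array([0.0, 10.0]), np.array([0.5, 0.8])
        )
        assert out is None

    def test_crossed_at_start(self):
        out = clusters.aggregation_time(np.array([5.0, 10.0]), np.array([1.2, 1.5]))
        assert out == 5.0
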