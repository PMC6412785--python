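"""Circle fitting, height measurement and the half-angle method."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from multinuc import (
    CircleFitError,
    DropletSpec,
    EdgePointSet,
    EmptySilhouetteError,
    aggregate_by_group,
    contact_angle,
    fit_circle,
    generate_droplet_image,
    measure_droplet,
    measure_height,
)
from multinuc.contact_angle import base_radius_from_fit, detect_baseline, _binarize


def geometric_circle_fit(pts):
    """Independent oracle: minimize true geometric distances to the circle."""
    pts = np.asarray(pts, float)

    def resid(p):
        cx, cy, r = p
        return np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r

    c0 = pts.mean(axis=0)
    r0 = np.hypot(*(pts - c0).T).mean()
    sol = least_squares(resid, x0=[c0[0], c0[1], r0])
    return sol.x


class TestFitCircle:
    def test_unit_circle_exact(self):
        fit = fit_circle(np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], float))
        assert fit.A == pytest.approx(0, abs=1e-12)
        assert fit.B == pytest.approx(0, abs=1e-12)
        assert fit.C == pytest.approx(-1, abs=1e-12)
        assert fit.r == pytest.approx(1, abs=1e-12)

    def test_three_points_match_exact_solve(self):
        fit = fit_circle(np.array([[0, 0], [2, 0], [1, 1]], float))
        assert fit.center == pytest.approx((1.0, 0.0), abs=1e-12)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.rms_residual < 1e-12

    @pytest.mark.parametrize("center,r,n", [((50, 40), 25, 10), ((300, -200), 140, 17)])
    def test_exact_circle_points_recovered(self, center, r, n):
        ang = np.linspace(0.3, 2.1, n)
        pts = np.c_[center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)]
        fit = fit_circle(pts)
        assert abs(fit.r - r) < 1e-9 * r
        assert fit.rms_residual < 1e-9

    def test_jittered_circle_close_to_geometric_fit(self):
        rng = np.random.default_rng(0)
        ang = rng.uniform(0, 2 * np.pi, 10)
        pts = np.c_[50 + 25 * np.cos(ang), 40 + 25 * np.sin(ang)]
        pts += rng.uniform(-0.5, 0.5, pts.shape)
        fit = fit_circle(pts)
        cx, cy, r_geo = geometric_circle_fit(pts)
        assert fit.r == pytest.approx(25, abs=0.5)
        assert fit.r == pytest.approx(r_geo, abs=0.1)
        assert fit.center == pytest.approx((cx, cy), abs=0.2)

    def test_collinear_points_raise_degeneracy_error(self):
        pts = np.c_[np.arange(10.0), 2.0 * np.arange(10.0) + 1.0]
        with pytest.raises(CircleFitError):
            fit_circle(pts)

    def test_too_few_points_raise(self):
        with pytest.raises(CircleFitError):
            fit_circle(np.array([[0, 0], [1, 1]], float))


class TestHalfAngle:
    @pytest.mark.parametrize("h,r,expected", [(1.0, 1.0, 90.0), (0.0, 1.0, 0.0)])
    def test_known_values(self, h, r, expected):
        assert contact_angle(h, r) == pytest.approx(expected, abs=1e-12)

    def test_printed_dish_mean_from_inverted_geometry(self):
        # h/a = tan(46.5 deg) corresponds to a 93 deg contact angle
        assert contact_angle(math.tan(math.radians(46.5)), 1.0) == pytest.approx(93.0)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            contact_angle(1.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(1.0, 300.0), st.floats(1.0, 300.0))
    def test_monotone_in_height(self, h, dh):
        r = 100.0
        assert contact_angle(h + dh, r) > contact_angle(h, r)
        assert contact_angle(r, r) == pytest.approx(90.0, abs=1e-12)


class TestHeightAndBaseline:
    def test_half_disk_height(self):
        img, truth = generate_droplet_image(DropletSpec(90.0, 100.0))
        h = measure_height(img, truth.baseline_row)
        assert h == pytest.approx(100, abs=1)

    def test_93_degree_cap_height(self):
        img, truth = generate_droplet_image(DropletSpec(93.0, 100.0))
        h = measure_height(img, truth.baseline_row)
        assert h == pytest.approx(105, abs=1)

    def test_blank_image_raises(self):
        with pytest.raises(EmptySilhouetteError):
            measure_height(np.full((50, 50), 60000, np.uint16), 40)

    def test_baseline_detection_bottom_matches_truth(self):
        img, truth = generate_droplet_image(DropletSpec(120.0, 80.0))
        mask = _binarize(img)
        assert detect_baseline(mask, "bottom") == truth.baseline_row

    def test_baseline_max_width_for_shallow_cap(self):
        img, truth = generate_droplet_image(DropletSpec(60.0, 80.0))
        mask = _binarize(img)
        assert abs(detect_baseline(mask, "max_width") - truth.baseline_row) <= 1


class TestMeasureDroplet:
    def test_exact_edge_points_half_disk(self):
        ang = np.linspace(0.05, np.pi - 0.05, 10)
        baseline = 200.0
        pts = np.c_[300 + 100 * np.cos(ang), baseline - 100 * np.sin(ang)]
        obs = measure_droplet(EdgePointSet(pts, baseline))
        assert obs.theta_deg == pytest.approx(90.0, abs=1e-6)

    @pytest.mark.parametrize("theta", [30, 45, 66, 71, 90, 93, 120, 150])
    def test_roundtrip_noise_free(self, theta):
        img, truth = generate_droplet_image(DropletSpec(float(theta), 100.0))
        obs = measure_droplet(img, baseline_row=truth.baseline_row)
        assert obs.theta_deg == pytest.approx(theta, abs=1.0)

    def test_roundtrip_71_degrees(self):
        # a more hydrophilic glass dish: mean angle 71 degrees
        img, truth = generate_droplet_image(DropletSpec(71.0, 100.0))
        obs = measure_droplet(img, baseline_row=truth.baseline_row)
        assert obs.theta_deg == pytest.approx(71.0, abs=1.0)

    def test_noisy_replicates_unbiased(self):
        thetas = []
        for i in range(20):
            img, truth = generate_droplet_image(
                DropletSpec(66.0, 100.0, noise_sd=2000.0, seed=i))
            obs = measure_droplet(img, baseline_row=truth.baseline_row)
            thetas.append(obs.theta_deg)
        assert np.mean(thetas) == pytest.approx(66.0, abs=2.0)

    def test_base_radius_identity(self):
        img, truth = generate_droplet_image(DropletSpec(66.0, 100.0))
        obs = measure_droplet(img, baseline_row=truth.baseline_row)
        # a = sqrt(h(2r - h)) must reproduce the generated contact radius
        assert obs.base_radius == pytest.approx(truth.base_radius_px, rel=0.02)
        assert base_radius_from_fit(obs.fit, obs.h) == obs.base_radius


class TestAggregate:
    def test_identical_angles_zero_sd(self):
        obs = [_obs(93.0) for _ in range(5)]
        table = aggregate_by_group(obs, ["FPI"] * 5)
        assert table.loc[0, "sd_theta_deg"] == 0.0

    def test_mean_and_sd_arithmetic(self):
        obs = [_obs(a) for a in (92.0, 93.0, 94.0)]
        table = aggregate_by_group(obs, ["g"] * 3)
        assert table.loc[0, "mean_theta_deg"] == pytest.approx(93.0)
        assert table.loc[0, "sd_theta_deg"] == pytest.approx(1.0)

    def test_three_dish_types_recover_printed_means(self):
        obs, labels = [], []
        for name, angle in [("FPI", 93.0), ("Matsunami", 71.0), ("plastic", 66.0)]:
            for _ in range(10):
                img, truth = generate_droplet_image(DropletSpec(angle, 100.0))
                obs.append(measure_droplet(img, baseline_row=truth.baseline_row))
                labels.append(name)
        table = aggregate_by_group(obs, labels).set_index("group")
        assert table.loc["FPI", "mean_theta_deg"] == pytest.approx(93.0, abs=1.0)
        assert table.loc["Matsunami", "mean_theta_deg"] == pytest.approx(71.0, abs=1.0)
        assert table.loc["plastic", "mean_theta_deg"] == pytest.approx(66.0, abs=1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_by_group([], [])


def _obs(theta):
    from multinuc.contact_angle import CircleFit, DropletObservation

    return DropletObservation("", 1.0, CircleFit(0.0, 0.0, -10000.0), 100.0, theta)
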