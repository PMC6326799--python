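"""%DAPI coordinate system: normalization, peaks, crossings, calibration."""

import numpy as np
import pytest

from nucfish.images import ImageStack
from nucfish.profiles import (
    Profile,
    calibrate_border,
    channel_intersection,
    dapi_centroid,
    extract_profile,
    find_focus_plane,
    marker_peak_position,
    normalize_profile,
    percent_dapi,
    spot_profile,
)
from nucfish.synthetic import (
    OpticsParams,
    generate_cell_scene,
    ray_surface_crossing,
    render_image,
)


def make_profile(dapi, arc=None, **extra):
    """Profile with exact (non-robust) normalization pre-applied: on tiny
    hand-built arrays the robust 1st-percentile floor would shift values."""
    dapi = np.asarray(dapi, dtype=float)
    arc = np.arange(len(dapi)) * 0.1 if arc is None else np.asarray(arc)
    p = Profile(arc=arc, raw={"dapi": dapi, **extra})
    for ch in p.raw:
        try:
            normalize_profile(p, ch, robust_min=False)
        except ValueError:
            pass  # constant channels stay unnormalized
    return p


class TestFocusPlane:
    def test_single_varying_plane_wins(self):
        img = np.zeros((1, 12, 8, 8))
        img[0, 7, 2, 2] = 50.0
        stack = ImageStack(img, (0.1, 0.1, 0.1), ["dapi"])
        assert find_focus_plane(stack, "dapi") == 7

    def test_constant_stack_ties_to_lowest_index(self):
        stack = ImageStack(np.ones((1, 5, 4, 4)), (0.1, 0.1, 0.1), ["dapi"])
        assert find_focus_plane(stack, "dapi") == 0

    def test_rendered_nucleus_focuses_mid_stack(self):
        scene = generate_cell_scene({}, seed=0)
        stack = render_image(scene, OpticsParams(noise_model="none"), seed=0)
        plane = find_focus_plane(stack, "dapi")
        # brute-force variance oracle
        img = stack.channel("dapi")
        oracle = int(np.argmax(img.reshape(img.shape[0], -1).var(axis=1)))
        assert plane == oracle
        mid = scene.nucleus_center[0] / stack.voxel_size[0]
        assert abs(plane - mid) <= 2


class TestExtractProfile:
    def test_degenerate_ray_errors(self, ramp_stack):
        with pytest.raises(ValueError, match="degenerate"):
            extract_profile(ramp_stack, (0.1, 0.2, 1.0), (0.1, 0.2, 1.0))

    def test_point_outside_stack_errors(self, ramp_stack):
        with pytest.raises(ValueError, match="outside"):
            extract_profile(ramp_stack, (0, 0, -5.0), (0.1, 0.2, 1.0))

    def test_constant_image_gives_constant_profile(self):
        stack = ImageStack(np.full((1, 4, 10, 10), 7.0), (0.1, 0.1, 0.1), ["dapi"])
        prof = extract_profile(stack, (0.1, 0.1, 0.1), (0.2, 0.8, 0.8))
        np.testing.assert_allclose(prof.raw["dapi"], 7.0)

    def test_rendered_nucleus_profile_unimodal(self):
        scene = generate_cell_scene({}, seed=1)
        stack = render_image(scene, OpticsParams(noise_model="none"), seed=0)
        c = scene.nucleus_center
        start = c.copy()
        start[1] = 0.05
        prof = extract_profile(stack, start, scene.nucleolus_center, channels=["dapi"])
        v = prof.raw["dapi"]
        peak = int(np.argmax(v))
        rises = np.diff(v[: peak + 1])
        falls = np.diff(v[peak:])
        tol = 0.01 * v.max()
        assert np.all(rises > -tol) and np.all(falls < tol)


class TestNormalization:
    def test_affine_invariance(self):
        v = np.array([200.0, 1000, 5000, 3000, 400])
        p1 = make_profile(v)
        p2 = make_profile(3.7 * v + 55)
        n1 = normalize_profile(p1, "dapi", robust_min=False)
        n2 = normalize_profile(p2, "dapi", robust_min=False)
        np.testing.assert_allclose(n1, n2, atol=1e-9)
        assert n1.max() == 100.0 and n1.min() == 0.0

    def test_idempotence(self):
        p = make_profile([0, 30, 100, 60, 10])
        n1 = normalize_profile(p, "dapi", robust_min=False).copy()
        p2 = make_profile(n1)
        n2 = normalize_profile(p2, "dapi", robust_min=False)
        np.testing.assert_allclose(n1, n2)

    def test_linear_ramp_identity(self):
        p = make_profile(np.linspace(0, 100, 101))
        np.testing.assert_allclose(
            normalize_profile(p, "dapi", robust_min=False), np.linspace(0, 100, 101)
        )

    def test_constant_channel_errors(self):
        with pytest.raises(ValueError, match="dynamic range"):
            normalize_profile(make_profile(np.full(10, 3.0)), "dapi")


class TestPercentDapi:
    def test_peak_is_exactly_100(self):
        p = make_profile([0, 50, 100, 80, 20])
        coord = percent_dapi(p, 0.2)
        assert coord.percent == 100.0 and coord.side is None

    def test_linear_ramp_value_and_side(self):
        p = make_profile(np.linspace(0, 100, 101), arc=np.linspace(0, 10, 101))
        coord = percent_dapi(p, 3.3)
        assert coord.percent == pytest.approx(33.0, abs=0.2)
        assert coord.side == "cytoplasmic"

    def test_gaussian_half_maximum_is_50(self):
        arc = np.linspace(0, 10, 2001)
        mu, sigma = 6.0, 1.0
        p = make_profile(np.exp(-((arc - mu) ** 2) / (2 * sigma**2)), arc=arc)
        # cytoplasmic-side half maximum sits at mu - sigma*sqrt(2 ln 2)
        q = mu - sigma * np.sqrt(2 * np.log(2))
        coord = percent_dapi(p, q)
        assert coord.percent == pytest.approx(50.0, abs=0.5)
        assert coord.side == "cytoplasmic"

    def test_query_outside_support_errors(self):
        with pytest.raises(ValueError, match="outside"):
            percent_dapi(make_profile([0, 1, 2]), 99.0)

    def test_unique_peak_strictly_below_100_elsewhere(self):
        rng = np.random.default_rng(0)
        v = rng.random(50)
        v[20] = 2.0  # unique max
        p = make_profile(v)
        for q in p.arc[::7]:
            c = percent_dapi(p, float(q))
            if q != p.arc[20]:
                assert c.percent < 100.0


class TestMarkerPeak:
    def test_marker_at_dapi_peak_reads_100(self):
        dapi = np.array([0.0, 40, 100, 70, 30])
        marker = np.array([0.0, 10, 90, 5, 0])
        p = make_profile(dapi, nup=marker)
        assert marker_peak_position(p, "nup").percent == 100.0

    def test_tie_resolves_toward_profile_start(self):
        dapi = np.array([0.0, 40, 100, 70, 30])
        marker = np.array([0.0, 80, 10, 80, 0])
        p = make_profile(dapi, nup=marker)
        coord = marker_peak_position(p, "nup")
        assert coord.percent == pytest.approx(40.0)
        assert coord.side == "cytoplasmic"

    def test_monotone_marker_warns_and_returns_boundary(self):
        dapi = np.array([0.0, 40, 100, 70, 30])
        marker = np.linspace(5, 0, 5)
        p = make_profile(dapi, nup=marker)
        with pytest.warns(UserWarning, match="boundary"):
            coord = marker_peak_position(p, "nup")
        assert coord.percent == pytest.approx(0.0)


class TestChannelIntersection:
    def test_symmetric_ramps_cross_at_50(self):
        n = 101
        p = make_profile(np.linspace(0, 100, n), cyto=np.linspace(100, 0, n))
        assert channel_intersection(p, "cyto").percent == pytest.approx(50.0, abs=0.1)

    def test_identical_channels_error(self):
        v = np.linspace(0, 100, 11)
        p = make_profile(v, cyto=v.copy())
        with pytest.raises(ValueError, match="crossing"):
            channel_intersection(p, "cyto")

    def test_two_logistic_closed_form(self):
        # rising DAPI logistic and falling marker logistic; the normalized
        # curves cross where L(x; a) = 1 - L(x; b), solvable in closed form:
        # x* = (a + b) / 2 for equal slopes
        arc = np.linspace(0, 10, 4001)
        k, a, b = 2.0, 4.0, 6.0
        dapi = 1 / (1 + np.exp(-k * (arc - a)))
        marker = 1 - 1 / (1 + np.exp(-k * (arc - b)))
        p = make_profile(dapi, arc=arc, cyto=marker)
        x_star = (a + b) / 2
        expected = float(np.interp(
            x_star, arc, (dapi - dapi.min()) / (dapi.max() - dapi.min()) * 100
        ))
        got = channel_intersection(p, "cyto")
        assert got.percent == pytest.approx(expected, abs=0.3)


class TestCalibration:
    def test_identical_profiles_mean_sd(self):
        dapi = np.array([0.0, 30, 60, 100, 80])
        marker = np.array([0.0, 5, 90, 10, 0])
        profiles = [make_profile(dapi, nup=marker) for _ in range(5)]
        cal = calibrate_border(profiles, method="marker_peak")
        assert cal.mean == pytest.approx(60.0)
        assert cal.sd == 0.0 and cal.n == 5

    def test_fraction_below_threshold(self):
        def prof(peak_pos):
            dapi = np.array([0.0, 20, 40, 70, 100, 60])
            marker = np.zeros(6)
            marker[peak_pos] = 1.0
            return make_profile(dapi, nup=marker)

        cal = calibrate_border([prof(1), prof(2)], method="marker_peak")
        # marker peaks at 20% and 40% DAPI -> half the values below 33.3
        assert cal.fraction_below_33 == pytest.approx(0.5)

    def test_zero_accepted_profiles_error(self):
        v = np.linspace(0, 100, 11)
        p = make_profile(v, cyto=v.copy())  # no crossing ever
        with pytest.raises(ValueError, match="no accepted"):
            calibrate_border([p], method="intersection", marker_channel="cyto")


class TestSpotRays:
    def test_recovery_against_analytic_surface_oracle(self):
        """Pore-peak and intersection estimates agree with the %DAPI value
        read off at the analytic ray/ellipsoid crossing, within the local
        slope over one sampling step."""
        scene = generate_cell_scene({}, seed=21)
        stack = render_image(scene, OpticsParams(noise_model="none"), seed=0)
        c = dapi_centroid(stack)
        direction = np.array([0.0, 1.0, 0.0])
        hi = (np.array(stack.shape_zyx) - 1) * np.array(stack.voxel_size)
        start = c.copy()
        start[1] = hi[1] * 0.999
        prof = extract_profile(stack, start, c)
        t = ray_surface_crossing(
            start, (c - start) / np.linalg.norm(c - start),
            scene.nucleus_center, scene.geometry.nucleus_radii,
        )
        oracle = percent_dapi(prof, t)
        est = marker_peak_position(prof, "nup")
        # tolerance: steepest local %DAPI change over one sampling step
        norm = prof.normalized["dapi"]
        slope = np.abs(np.diff(norm)).max()
        assert abs(est.percent - oracle.percent) <= 2 * slope

    def test_spot_profile_locates_spot(self):
        scene = generate_cell_scene({("single_probe", "cytoplasm"): 1}, seed=22)
        stack = render_image(scene, OpticsParams(noise_model="none"), seed=0)
        c = dapi_centroid(stack)
        pos = scene.molecules[0].probe_positions["red"]
        prof, arc = spot_profile(stack, pos, c, channels=["dapi", "red"])
        # the red channel along this ray peaks at the spot's arc position
        peak_arc = prof.arc[int(np.argmax(prof.raw["red"]))]
        assert abs(peak_arc - arc) <= 2 * prof.step

    def test_spot_at_centroid_errors(self, clean_stack):
        c = dapi_centroid(clean_stack)
        with pytest.raises(ValueError, match="ray undefined"):
            spot_profile(clean_stack, c, c)
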