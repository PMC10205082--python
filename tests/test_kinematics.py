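"""Joint-angle decomposition, condylar A-P, cycle normalization and RoM."""

import numpy as np
import pytest

from tkagait import kinematics as kin


def _pose(R=np.eye(3), t=(0.0, 0.0, 0.0)):
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = t
    return T


class TestGroodSuntay:
    def test_identity_gives_zero_angles(self):
        assert kin.decompose_grood_suntay(np.eye(4)) == (0.0, 0.0, 0.0)

    def test_pure_flexion(self):
        R = kin.compose_grood_suntay(30.0, 0.0, 0.0)
        fl, ad, ir = kin.decompose_grood_suntay(R)
        assert fl == pytest.approx(30.0, abs=1e-12)
        assert ad == pytest.approx(0.0, abs=1e-12)
        assert ir == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_exact_over_domain(self):
        """decompose(compose(angles)) == angles to 1e-9 deg over the
        physiological domain (flexion -10..130, ab/ad +-15, rotation +-30)."""
        rng = np.random.default_rng(42)
        n = 2000
        flex = rng.uniform(-10, 130, n)
        add = rng.uniform(-15, 15, n)
        intr = rng.uniform(-30, 30, n)
        worst = 0.0
        for a, b, c in zip(flex, add, intr):
            out = kin.decompose_grood_suntay(kin.compose_grood_suntay(a, b, c))
            worst = max(worst, abs(out[0] - a), abs(out[1] - b), abs(out[2] - c))
        assert worst < 1e-9

    def test_gimbal_proximity_reported(self):
        R = kin.compose_grood_suntay(10.0, 89.7, 5.0)
        with pytest.raises(kin.GimbalLockError):
            kin.decompose_grood_suntay(R)

    def test_non_orthonormal_rejected(self):
        R = np.eye(3)
        R[0, 0] = 1.001
        with pytest.raises(ValueError, match="orthonormal"):
            kin.decompose_grood_suntay(R)


@pytest.fixture
def flat_geometry():
    """Two condyle clouds whose points sit at known heights above the plane."""
    rng = np.random.default_rng(0)
    plane = kin.TibialPlane(
        point=np.zeros(3), normal=np.array([0.0, 1.0, 0.0]), ap_axis=np.array([1.0, 0.0, 0.0])
    )
    med = np.column_stack([rng.uniform(-10, 10, 12), np.full(12, 2.0), rng.uniform(-25, -15, 12)])
    lat = np.column_stack([rng.uniform(-10, 10, 12), np.full(12, 2.0), rng.uniform(15, 25, 12)])
    return kin.CondyleGeometry(medial_points=med, lateral_points=lat, tibial_plane=plane)


class TestCondylarAP:
    def test_equidistant_points_give_plain_mean(self, flat_geometry):
        med, lat = kin.condylar_ap(_pose(), flat_geometry)
        # all points share one height -> equal weights -> mean of 10 nearest;
        # with 12 equidistant points argsort keeps input order, so the mean
        # covers the first 10
        assert med == pytest.approx(flat_geometry.medial_points[:10, 0].mean())
        assert lat == pytest.approx(flat_geometry.lateral_points[:10, 0].mean())

    def test_ap_translation_equivariance(self, flat_geometry):
        m0, l0 = kin.condylar_ap(_pose(), flat_geometry)
        m5, l5 = kin.condylar_ap(_pose(t=(5.0, 0.0, 0.0)), flat_geometry)
        assert m5 - m0 == pytest.approx(5.0, abs=1e-12)
        assert l5 - l0 == pytest.approx(5.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        """Hemispherical condyles at a generic pose against an explicit
        loop-based reimplementation of the nearest-points weighted mean."""
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, 2 * np.pi, 60)
        phi = rng.uniform(np.pi / 2, np.pi, 60)  # lower hemisphere
        sphere = 20.0 * np.column_stack(
            [np.cos(theta) * np.sin(phi), np.cos(phi), np.sin(theta) * np.sin(phi)]
        )
        geom = kin.CondyleGeometry(
            medial_points=sphere + [3.0, 22.0, -21.0],
            lateral_points=sphere + [-2.0, 22.0, 21.0],
            tibial_plane=kin.TibialPlane(
                point=np.array([0.0, 1.0, 0.0]),
                normal=np.array([0.0, 1.0, 0.0]),
                ap_axis=np.array([1.0, 0.0, 0.0]),
            ),
        )
        R = kin.compose_grood_suntay(35.0, 4.0, -9.0)
        pose = _pose(R, t=(6.0, 1.5, -2.0))

        def oracle(points):
            scored = []
            for p in points:
                q = R @ p + np.array([6.0, 1.5, -2.0])
                d = (q - geom.tibial_plane.point) @ geom.tibial_plane.normal
                ap = (q - geom.tibial_plane.point) @ geom.tibial_plane.ap_axis
                scored.append((d, ap))
            scored.sort(key=lambda x: x[0])
            ten = scored[:10]
            weights = [1.0 / (abs(d) + 0.1) for d, _ in ten]
            return sum(w * ap for w, (_, ap) in zip(weights, ten)) / sum(weights)

        med, lat = kin.condylar_ap(pose, geom)
        assert med == pytest.approx(oracle(geom.medial_points), abs=1e-10)
        assert lat == pytest.approx(oracle(geom.lateral_points), abs=1e-10)

    def test_too_few_points_rejected(self, flat_geometry):
        with pytest.raises(ValueError, match="at least 10"):
            kin.CondyleGeometry(
                medial_points=flat_geometry.medial_points[:5],
                lateral_points=flat_geometry.lateral_points,
                tibial_plane=flat_geometry.tibial_plane,
            )


def _series(n=101, to=60):
    frames = np.tile(np.eye(4), (n, 1, 1))
    return kin.PoseSeries(frames=frames, events=kin.GaitEvents(0, to, n - 1))


class TestTimeNormalize:
    def test_101_equispaced_frames_pass_through(self):
        series = _series()
        rng = np.random.default_rng(1)
        tracks = {name: rng.normal(size=101) for name in kin.CYCLE_PARAMETERS}
        cycle = kin.time_normalize_cycle(series, tracks)
        ref = tracks["medial_ap"][0]
        assert np.allclose(cycle.flexion, tracks["flexion"])
        assert np.allclose(cycle.medial_ap, tracks["medial_ap"] - ref)
        assert np.allclose(cycle.lateral_ap, tracks["lateral_ap"] - ref)
        assert cycle.medial_ap[0] == 0.0

    def test_constant_signal_stays_constant(self):
        series = _series(n=37, to=20)
        tracks = {name: np.full(37, 3.5) for name in kin.CYCLE_PARAMETERS}
        cycle = kin.time_normalize_cycle(series, tracks)
        assert np.allclose(cycle.flexion, 3.5)
        rom = kin.rom_summary(cycle)
        assert rom.stance["flexion"] == 0.0

    def test_linear_ramp_resampled_exactly(self):
        """Resampling is exact for signals affine in time."""
        n = 34
        series = _series(n=n, to=20)
        ramp = np.linspace(0.0, 10.0, n)
        tracks = {name: ramp.copy() for name in kin.CYCLE_PARAMETERS}
        cycle = kin.time_normalize_cycle(series, tracks)
        assert cycle.flexion[0] == pytest.approx(0.0)
        assert cycle.flexion[-1] == pytest.approx(10.0)
        assert np.allclose(cycle.flexion, np.linspace(0, 10, 101), atol=1e-12)

    def test_bad_event_order_rejected(self):
        with pytest.raises(ValueError, match="heel_strike_1 < toe_off"):
            kin.GaitEvents(10, 5, 20)


def _cycle_from_tracks(**tracks):
    defaults = {name: np.zeros(101) for name in kin.CYCLE_PARAMETERS}
    defaults.update(tracks)
    return kin.KinematicCycle(toe_off_pct=60.0, **defaults)


class TestRoMSummary:
    def test_constant_tracks_zero_rom(self):
        rom = kin.rom_summary(_cycle_from_tracks())
        assert all(v == 0.0 for v in rom.stance.values())
        assert rom.swing["intercondylar_ap_diff"] == 0.0

    def test_published_intercondylar_diff_example(self):
        """Medial stance RoM 5.4 with lateral 5.1 gives a diff of -0.3 mm."""
        x = np.zeros(101)
        x[10:60] = 1.0
        cycle = _cycle_from_tracks(medial_ap=5.4 * x, lateral_ap=5.1 * x)
        rom = kin.rom_summary(cycle)
        assert rom.stance["medial_ap"] == pytest.approx(5.4)
        assert rom.stance["lateral_ap"] == pytest.approx(5.1)
        assert rom.stance["intercondylar_ap_diff"] == pytest.approx(-0.3)

    def test_sinusoid_rom_is_twice_amplitude(self):
        i = np.arange(101)
        # period 20 samples puts the extremes exactly on the grid
        cycle = _cycle_from_tracks(flexion=3.0 * np.sin(2 * np.pi * i / 20))
        rom = kin.rom_summary(cycle)
        assert rom.stance["flexion"] == pytest.approx(6.0, abs=1e-12)
        assert rom.swing["flexion"] == pytest.approx(6.0, abs=1e-12)

    def test_diff_equals_lateral_minus_medial_rom(self):
        rng = np.random.default_rng(3)
        cycle = _cycle_from_tracks(
            medial_ap=rng.normal(size=101), lateral_ap=rng.normal(size=101)
        )
        rom = kin.rom_summary(cycle)
        for phase in ("stance", "swing"):
            d = getattr(rom, phase)
            assert d["intercondylar_ap_diff"] == d["lateral_ap"] - d["medial_ap"]


class TestHeelStrike:
    def test_step_crossing(self):
        f = np.zeros(100)
        f[40:] = 800.0
        assert kin.detect_heelstrike(f) == 40

    def test_subthreshold_trace_gives_no_event(self):
        assert kin.detect_heelstrike(np.full(200, 20.0)) is None

    def test_trace_starting_above_threshold(self):
        assert kin.detect_heelstrike(np.full(10, 600.0)) == 0
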