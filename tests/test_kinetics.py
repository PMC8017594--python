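"""Transition geometry: angles, blocks, projections, noise floor, velocities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nuctrack as nt
from nuctrack.io import Point2D, TrackSet
from nuctrack.kinetics import (
    AngleBlock,
    PositionState,
    block_frequencies,
    compare_phase_displacements,
    estimate_noise_threshold,
    nc_cc_distance_series,
    transitions,
)

from conftest import make_track


def _angle_oracle(nc_n, nc_n1, cc_n1):
    """Independent arccos(u.v/|u||v|) arithmetic, via numpy."""
    u = np.asarray(nc_n) - np.asarray(nc_n1)
    v = np.asarray(cc_n1) - np.asarray(nc_n1)
    return math.degrees(
        np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    )


class TestAngle:
    @pytest.mark.parametrize(
        "nc_n, nc_n1, cc_n1, expected",
        [
            ((0, 0), (1, 0), (2, 0), 180.0),  # collinear, CC beyond advancing NC
            ((0, 0), (1, 0), (1, 1), 90.0),
            ((0, 0), (2, 0), (3, 1), 135.0),
        ],
    )
    def test_analytic_cases(self, nc_n, nc_n1, cc_n1, expected):
        got = nt.nnc_ncc_angle(Point2D(*nc_n), Point2D(*nc_n1), Point2D(*cc_n1))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(_angle_oracle(nc_n, nc_n1, cc_n1), abs=1e-9)

    def test_degenerate_arms_are_undefined(self):
        p = Point2D(1.0, 1.0)
        assert nt.nnc_ncc_angle(p, p, Point2D(2, 2)) is None
        assert nt.nnc_ncc_angle(Point2D(0, 0), p, p) is None

    def test_rigid_motion_and_scale_invariance(self, rng):
        """The angle is a similarity invariant of the three points."""
        for _ in range(1000):
            pts = rng.normal(size=(3, 2)) * 10
            base = nt.nnc_ncc_angle(*(Point2D(*p) for p in pts))
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            scale = rng.uniform(0.1, 10.0)
            shift = rng.normal(size=2) * 100
            moved = (pts @ rot.T) * scale + shift
            got = nt.nnc_ncc_angle(*(Point2D(*p) for p in moved))
            assert got == pytest.approx(base, abs=1e-6)


class TestBlocks:
    @pytest.mark.parametrize(
        "angle, block",
        [
            (0.0, AngleBlock.LOW),
            (40.0, AngleBlock.LOW),  # boundary included in LOW
            (40.0001, AngleBlock.MID),
            (139.9999, AngleBlock.MID),
            (140.0, AngleBlock.HIGH),  # boundary included in HIGH
            (180.0, AngleBlock.HIGH),
            (90.0, AngleBlock.MID),
            (None, AngleBlock.UNDEF),
        ],
    )
    def test_boundaries(self, angle, block):
        assert nt.classify_block(angle) is block

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nt.classify_block(-1.0)
        with pytest.raises(ValueError):
            nt.classify_block(180.5)

    def test_configurable_bounds(self):
        assert nt.classify_block(135.0, high_min=130.0) is AngleBlock.HIGH


class TestSignedProjection:
    def test_nucleus_ahead(self):
        assert nt.signed_nc_cc(
            Point2D(0, 0), Point2D(1, 0), Point2D(1.5, 0)
        ) == pytest.approx(0.5)

    def test_trailing_component_only(self):
        assert nt.signed_nc_cc(
            Point2D(0, 0), Point2D(1, 0), Point2D(0.5, 2)
        ) == pytest.approx(-0.5)

    def test_no_motion_axis_is_undefined(self):
        assert nt.signed_nc_cc(Point2D(0, 0), Point2D(0, 0), Point2D(1, 1)) is None


class TestNoiseCorrect:
    @pytest.mark.parametrize(
        "value, expected", [(0.05, 0.0), (0.50, 0.50), (-0.30, -0.30), (None, None)]
    )
    def test_threshold_at_default_tau(self, value, expected):
        assert nt.noise_correct(value, 0.12) == expected

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            nt.noise_correct(1.0, -0.1)

    @given(st.floats(-10, 10), st.floats(0, 1))
    @settings(max_examples=200, derandomize=True)
    def test_odd_and_idempotent(self, v, tau):
        c = nt.noise_correct(v, tau)
        assert nt.noise_correct(-v, tau) == -c
        assert nt.noise_correct(c, tau) == c
        assert abs(c) <= abs(v)
        assert c in (0.0, v)


class TestTransitions:
    def test_three_frames_two_records(self):
        t = make_track([[0, 0], [1, 0], [2, 0]], [[0, 0], [1, 0], [2, 0]])
        assert len(transitions(t)) == 2

    def test_stationary_track_all_undefined_neutral(self):
        t = make_track([[1, 1]] * 4, [[2, 2]] * 4)
        recs = transitions(t)
        assert all(r.angle_deg is None for r in recs)
        assert all(r.block is AngleBlock.UNDEF for r in recs)
        assert all(r.pos_state is PositionState.NEUTRAL for r in recs)

    def test_matches_per_frame_oracle(self, rng):
        """Record fields equal a brute-force frame-by-frame recomputation."""
        cc = np.cumsum(rng.normal(size=(30, 2)), axis=0)
        nc = cc + rng.normal(size=(30, 2))
        t = make_track(cc, nc, interval=5.0)
        recs = transitions(t, tau=0.12)
        assert len(recs) == 29
        for i, r in enumerate(recs):
            ang = _angle_oracle(nc[i], nc[i + 1], cc[i + 1])
            assert r.angle_deg == pytest.approx(ang, abs=1e-9)
            step = cc[i + 1] - cc[i]
            raw = (nc[i + 1] - cc[i + 1]) @ step / np.linalg.norm(step)
            assert r.raw_nc_cc_um == pytest.approx(raw, abs=1e-9)
            expected_signed = 0.0 if abs(raw) < 0.12 else raw
            assert r.signed_nc_cc_um == pytest.approx(expected_signed, abs=1e-12)
            assert r.cc_step_um == pytest.approx(np.linalg.norm(step))
            assert r.nc_step_um == pytest.approx(np.linalg.norm(nc[i + 1] - nc[i]))
            assert r.dt_min == pytest.approx(5.0)

    def test_signed_invariant_vs_raw(self, rng):
        cc = np.cumsum(rng.normal(size=(50, 2)) * 0.1, axis=0)
        nc = cc + rng.normal(size=(50, 2)) * 0.1
        for r in transitions(make_track(cc, nc)):
            if r.raw_nc_cc_um is not None:
                assert abs(r.signed_nc_cc_um) <= abs(r.raw_nc_cc_um)
                assert r.signed_nc_cc_um in (0.0, r.raw_nc_cc_um)

    def test_frame_gap_flags_and_elapsed_time(self):
        t = make_track(
            [[0, 0], [1, 0], [3, 0]],
            [[0, 0], [1, 0], [3, 0]],
            frame_index=[0, 1, 4],
            interval=5.0,
        )
        recs = transitions(t)
        assert [r.gap_flag for r in recs] == [False, True]
        assert recs[1].dt_min == pytest.approx(15.0)  # 3-frame gap x 5 min


class TestVelocity:
    def test_constant_steps(self):
        cc = [[i, 0] for i in range(5)]  # 4 steps of 1 um at 5-min interval
        v, acc = nt.track_velocity(make_track(cc, cc, interval=5.0), "CC")
        assert acc == pytest.approx(4.0)
        assert v == pytest.approx(0.2)

    def test_stationary_is_zero(self):
        v, acc = nt.track_velocity(make_track([[1, 1]] * 3, [[1, 1]] * 3))
        assert v == 0.0 and acc == 0.0

    def test_random_track_matches_summation_oracle(self, rng):
        xy = np.cumsum(rng.normal(size=(101, 2)), axis=0)
        t = make_track(xy, xy, interval=2.0)
        v, acc = nt.track_velocity(t, "NC")
        oracle = sum(
            math.hypot(*(xy[i + 1] - xy[i])) for i in range(100)
        )
        assert acc == pytest.approx(oracle)
        assert v == pytest.approx(oracle / 200.0)

    def test_rigid_motion_invariance_and_linear_scaling(self, rng):
        xy = np.cumsum(rng.normal(size=(20, 2)), axis=0)
        v0, _ = nt.track_velocity(make_track(xy, xy))
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = xy @ rot.T + np.array([5.0, -3.0])
        v1, _ = nt.track_velocity(make_track(moved, moved))
        assert v1 == pytest.approx(v0)
        v3, _ = nt.track_velocity(make_track(xy * 3.0, xy * 3.0))
        assert v3 == pytest.approx(3.0 * v0)


class TestSessileAndNoise:
    def test_slow_track_is_sessile(self):
        nc = [[0.1 * i, 0] for i in range(5)]  # 0.1 um / 5 min = 0.02 um/min
        assert nt.is_sessile(make_track(nc, nc, interval=5.0))

    def test_fast_track_is_not(self):
        nc = [[i, 0] for i in range(5)]  # 0.2 um/min
        assert not nt.is_sessile(make_track(nc, nc, interval=5.0))

    def test_mixed_steps_match_median_oracle(self, rng):
        steps = rng.uniform(0, 0.5, size=40)
        x = np.concatenate([[0.0], np.cumsum(steps)])
        nc = np.column_stack([x, np.zeros_like(x)])
        t = make_track(nc, nc, interval=5.0)
        assert nt.is_sessile(t) == (np.median(steps) / 5.0 < 0.05)

    def test_constant_steps_give_constant_median(self):
        x = np.arange(6) * 0.12
        nc = np.column_stack([x, np.zeros(6)])
        ts = TrackSet(tracks=[make_track(nc, nc, interval=15.0)])
        assert estimate_noise_threshold(ts) == pytest.approx(0.12)

    def test_pooling_is_over_concatenated_displacements(self):
        a = np.column_stack([np.arange(4) * 0.1, np.zeros(4)])
        b = np.column_stack([np.arange(4) * 0.3, np.zeros(4)])
        ts = TrackSet(
            tracks=[
                make_track(a, a, "a", interval=15.0),
                make_track(b, b, "b", interval=15.0),
            ]
        )
        pooled = np.concatenate([[0.1] * 3, [0.3] * 3])
        assert estimate_noise_threshold(ts) == pytest.approx(np.median(pooled))

    def test_rayleigh_median_closed_form(self, rng):
        """Per-axis Gaussian step noise sigma -> median step sigma*sqrt(2 ln 2)."""
        sigma = 0.1
        n = 12000
        disp = rng.normal(0, sigma, size=(n, 2))
        nc = np.concatenate([[[0, 0]], np.cumsum(disp, axis=0)])
        ts = TrackSet(tracks=[make_track(nc, nc, interval=15.0)])
        est = estimate_noise_threshold(ts)
        assert est == pytest.approx(sigma * math.sqrt(2 * math.log(2)), rel=0.05)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_noise_threshold(TrackSet(tracks=[]))

    def test_strict_mode_rejects_motile_tracks(self):
        nc = np.column_stack([np.arange(5) * 2.0, np.zeros(5)])
        ts = TrackSet(tracks=[make_track(nc, nc, interval=5.0)])
        with pytest.raises(ValueError, match="sessile"):
            estimate_noise_threshold(ts, strict=True)


class TestBlockFrequenciesAndDistances:
    def test_counting(self):
        t = make_track(np.zeros((5, 2)), np.zeros((5, 2)))
        recs = transitions(t)
        # forge blocks via dataclasses.replace to exercise pure counting
        import dataclasses

        blocks = [AngleBlock.LOW, AngleBlock.LOW, AngleBlock.HIGH, AngleBlock.MID]
        recs = [dataclasses.replace(r, block=b) for r, b in zip(recs, blocks)]
        freqs, undef = block_frequencies(recs)
        assert undef == 0
        assert freqs[AngleBlock.LOW] == 0.5
        assert freqs[AngleBlock.MID] == 0.25
        assert freqs[AngleBlock.HIGH] == 0.25
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_undefined(self):
        recs = transitions(make_track(np.zeros((4, 2)), np.zeros((4, 2))))
        freqs, undef = block_frequencies(recs)
        assert freqs == {} and undef == 3

    def test_frequencies_sum_to_one_on_simulated_track(self):
        lts = nt.simulate(nt.SimParams(mode=nt.Mode.NUC, n_tracks=1, n_frames=60, seed=9))
        freqs, _ = block_frequencies(transitions(lts.tracks.tracks[0]))
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_nc_cc_distance_series(self):
        t = make_track([[0, 0], [0, 0]], [[3, 4], [0, 0]])
        np.testing.assert_allclose(nc_cc_distance_series(t), [5.0, 0.0])

    def test_distance_series_matches_hypot_oracle(self, rng):
        cc = rng.normal(size=(20, 2))
        nc = rng.normal(size=(20, 2))
        expected = [math.hypot(*(nc[i] - cc[i])) for i in range(20)]
        np.testing.assert_allclose(
            nc_cc_distance_series(make_track(cc, nc)), expected
        )


class TestPhaseComparison:
    @staticmethod
    def _phased_track(g1_step, sg2_step, n_each=30):
        steps = [g1_step] * n_each + [sg2_step] * n_each
        x = np.concatenate([[0.0], np.cumsum(steps)])
        nc = np.column_stack([x, np.zeros_like(x)])
        phases = ["g1"] * n_each + ["s_g2"] * n_each + ["unknown"]
        return make_track(nc, nc, phase=phases)

    def test_identical_groups_have_zero_D(self):
        ts = TrackSet(tracks=[self._phased_track(1.0, 1.0)])
        res = compare_phase_displacements(ts)
        assert res["D"] == pytest.approx(0.0)
        assert res["n_G1"] == 30 and res["n_SG2"] == 30

    def test_disjoint_supports_give_D_one(self):
        ts = TrackSet(tracks=[self._phased_track(1.0, 2.0)])
        assert compare_phase_displacements(ts)["D"] == pytest.approx(1.0)

    def test_matches_ecdf_sup_difference_oracle(self, rng):
        g1 = rng.normal(1.0, 0.2, 50)
        sg2 = rng.normal(1.3, 0.2, 60)
        steps = np.abs(np.concatenate([g1, sg2]))
        x = np.concatenate([[0.0], np.cumsum(steps)])
        nc = np.column_stack([x, np.zeros_like(x)])
        phases = ["g1"] * 50 + ["s_g2"] * 60 + ["unknown"]
        ts = TrackSet(tracks=[make_track(nc, nc, phase=phases)])
        res = compare_phase_displacements(ts)
        grid = np.sort(steps)
        ecdf1 = np.searchsorted(np.sort(steps[:50]), grid, side="right") / 50
        ecdf2 = np.searchsorted(np.sort(steps[50:]), grid, side="right") / 60
        assert res["D"] == pytest.approx(np.max(np.abs(ecdf1 - ecdf2)), abs=1e-12)

    def test_empty_group_is_an_error(self):
        t = make_track([[0, 0], [1, 0], [2, 0]], [[0, 0], [1, 0], [2, 0]],
                       phase=["g1", "g1", "g1"])
        with pytest.raises(ValueError, match="S_G2"):
            compare_phase_displacements(TrackSet(tracks=[t]))
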