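"""Arm-swing metrics, the ASA index and synchrony indices."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinegait import (
    SynthConfig,
    angular_metrics,
    arm_swing_params,
    asa,
    asymmetry_indices,
    generate,
    linear_metrics,
    synchrony_indices,
    wrist_relative_series,
)
from kinegait.errors import UndefinedAsymmetryError, UndefinedCorrelationError
from kinegait.preprocess import extract_gap, lowpass_8hz, resample_50hz

from conftest import build_window

# printed worked examples: (P_left, P_right) -> published ASA (%)
PRINTED_ASA_EXAMPLES = [
    # impaired subject with strong right-arm reduction
    (40.34, 18.06, 23.24),  # angular range (deg)
    (2522.04, 1408.56, 17.61),  # total path (mm)
    (295.89, 123.95, 24.78),  # AP sway range (mm)
    # impaired subject with near-symmetric swing
    (55.21, 52.68, 1.52),
    (1551.77, 1575.54, 0.51),
    (411.13, 395.67, 1.25),
    # control subject with visible asymmetry
    (39.48, 20.47, 19.59),
    (1330.83, 618.68, 22.33),
    (279.31, 136.28, 21.14),
    # control subject with symmetric swing
    (43.50, 46.18, 1.92),
    (1455.22, 1465.84, 0.26),
    (333.67, 327.56, 0.61),
]


def _sim_window(cfg):
    seq, truth = generate(cfg)
    rs = lowpass_8hz(resample_50hz(seq))
    return extract_gap(rs, cfg.gap_near_m, cfg.gap_far_m), truth


class TestWristRelativeSeries:
    def test_wrist_on_pelvis_gives_zeros(self):
        t = np.arange(60) / 50.0
        p = np.column_stack([0 * t + 5, 0 * t + 900, 2500 - 100 * t])
        win = build_window(t, PELVIS=p, WRIST_L=p)
        np.testing.assert_allclose(
            wrist_relative_series(win, "left"), 0.0, atol=1e-12
        )

    def test_anterior_sign_convention(self):
        t = np.arange(60) / 50.0
        p = np.column_stack([0 * t, 0 * t + 900, 2500 - 100 * t])
        win = build_window(t, PELVIS=p, WRIST_R=p + np.array([0, 0, -100.0]))
        rel = wrist_relative_series(win, "right")
        np.testing.assert_allclose(rel[:, 0], 100.0, atol=1e-12)

    def test_simulated_ap_amplitude_matches_config(self):
        cfg = SynthConfig(seed=13)
        win, truth = _sim_window(cfg)
        rel = wrist_relative_series(win, "left")
        assert np.ptp(rel[:, 0]) == pytest.approx(
            truth.sway_range_ap_mm["left"], rel=0.05
        )


class TestLinearMetrics:
    def test_sinusoid_extrema_and_degenerate_hull(self):
        t = np.arange(500) / 50.0
        ap = 100.0 * np.sin(2 * np.pi * 0.5 * t)  # grid hits the peaks
        rel = np.column_stack([ap, 0 * t, 0 * t])
        with pytest.warns(UserWarning, match="collinear"):
            m = linear_metrics(rel)
        assert m.sway_ant_ap_mm == pytest.approx(100.0, rel=1e-6)
        assert m.sway_pos_ap_mm == pytest.approx(-100.0, rel=1e-6)
        assert m.sway_range_ap_mm == pytest.approx(200.0, rel=1e-6)
        assert m.sway_area_mm2 == 0.0

    def test_circle_hull_area_matches_closed_form(self):
        phi = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        r = 130.0
        rel = np.column_stack([r * np.cos(phi), r * np.sin(phi), 0 * phi])
        m = linear_metrics(rel)
        assert m.sway_area_mm2 == pytest.approx(math.pi * r**2, rel=0.02)

    def test_peak_ap_speed_matches_analytic_derivative(self):
        t = np.arange(500) / 50.0
        rel = np.column_stack([100.0 * np.sin(2 * np.pi * t), 0 * t, 0 * t])
        m = linear_metrics(rel, dt=0.02)
        assert m.speed_ap_mms == pytest.approx(200.0 * math.pi, rel=0.02)

    def test_path_bounds_range(self):
        rng = np.random.default_rng(5)
        rel = rng.normal(0, 50, (200, 3))
        m = linear_metrics(rel)
        assert m.path_tot_mm >= m.sway_range_ap_mm


class TestAngularMetrics:
    @staticmethod
    def _arm_window(theta_deg):
        """Shoulder fixed; wrist hung at 600 mm under angle theta(t)."""
        n = len(theta_deg)
        t = np.arange(n) / 50.0
        th = np.radians(np.asarray(theta_deg, dtype=float))
        shoulder = np.column_stack(
            [np.full(n, 190.0), np.full(n, 1350.0), np.full(n, 3000.0)]
        )
        wrist = shoulder + np.column_stack(
            [0 * th, -600.0 * np.cos(th), -600.0 * np.sin(th)]
        )
        hip = shoulder + np.array([0.0, -500.0, 0.0])
        return build_window(t, SHOULDER_L=shoulder, WRIST_L=wrist, HIP_L=hip)

    def test_arm_along_trunk_is_zero(self):
        win = self._arm_window(np.zeros(60))
        m = angular_metrics(win, "left")
        assert m.angle_ant_deg == pytest.approx(0.0, abs=1e-9)
        assert m.angle_range_deg == pytest.approx(0.0, abs=1e-9)

    def test_constructed_30_degree_anterior_angle(self):
        win = self._arm_window(np.full(60, 30.0))
        assert angular_metrics(win, "left").angle_ant_deg == pytest.approx(
            30.0, abs=1e-9
        )

    def test_symmetric_sinusoidal_swing_range(self):
        t = np.arange(300) / 50.0
        win = self._arm_window(25.0 * np.sin(2 * np.pi * 0.9 * t))
        m = angular_metrics(win, "left")
        assert m.angle_range_deg == pytest.approx(50.0, abs=0.5)
        assert m.angle_pos_deg == pytest.approx(-25.0, abs=0.3)


class TestAsa:
    @pytest.mark.parametrize("pl, pr, printed", PRINTED_ASA_EXAMPLES)
    def test_printed_worked_examples(self, pl, pr, printed):
        assert asa(pl, pr) == pytest.approx(printed, abs=0.1)

    def test_limits(self):
        assert asa(3.7, 3.7) == 0.0
        assert asa(1.0, 0.0) == 50.0
        assert asa(0.0, 2.0) == 50.0

    def test_errors(self):
        with pytest.raises(ValueError):
            asa(-1.0, 2.0)
        with pytest.raises(UndefinedAsymmetryError):
            asa(0.0, 0.0)

    @settings(max_examples=100, deadline=None)
    @given(
        x=st.floats(1e-6, 1e6),
        y=st.floats(1e-6, 1e6),
        k=st.floats(1e-3, 1e3),
    )
    def test_symmetry_scale_invariance_and_bounds(self, x, y, k):
        v = asa(x, y)
        assert 0.0 <= v <= 50.0
        assert asa(y, x) == v
        assert asa(k * x, k * y) == pytest.approx(v, abs=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(r1=st.floats(1.0, 50.0), r2=st.floats(1.0, 50.0))
    def test_strictly_increasing_in_ratio(self, r1, r2):
        if abs(r1 - r2) > 1e-9:
            lo, hi = sorted([r1, r2])
            assert asa(hi, 1.0) > asa(lo, 1.0)


class TestAsymmetryAndSynchrony:
    def test_identical_sides_give_zero_indices(self):
        cfg = SynthConfig(noise_sd_mm=0.0, timestamp_jitter_sd_s=0.0, seed=0)
        win, _ = _sim_window(cfg)
        left = arm_swing_params(win, "left")
        right = arm_swing_params(win, "right")
        idx = asymmetry_indices(left, right)
        assert idx.asa_angle_pct == pytest.approx(0.0, abs=0.5)
        assert idx.asa_path_pct == pytest.approx(0.0, abs=0.5)
        assert idx.asa_ap_range_pct == pytest.approx(0.0, abs=0.5)

    def test_si_arms_limits_on_copied_and_negated_series(self):
        t = np.arange(100) / 50.0
        ap = 150.0 * np.sin(2 * np.pi * 0.9 * t)
        pelvis = np.column_stack([0 * t, 0 * t + 900, 2500.0 + 0 * t])
        base = dict(
            PELVIS=pelvis,
            SHOULDER_L=pelvis + np.array([190.0, 450.0, 0.0]),
            SHOULDER_R=pelvis + np.array([-190.0, 450.0, 0.0]),
            HIP_L=pelvis + np.array([90.0, -50.0, 0.0]),
            HIP_R=pelvis + np.array([-90.0, -50.0, 0.0]),
            ANKLE_L=pelvis + np.column_stack([0 * t, 0 * t - 820, 100 * np.sin(t)]),
            ANKLE_R=pelvis + np.column_stack([0 * t, 0 * t - 820, -100 * np.sin(t)]),
        )
        wl = pelvis + np.column_stack([190 + 0 * t, -150 + 0 * t, -ap])
        # right wrist copying the left AP series -> r = +1
        win = build_window(t, WRIST_L=wl, WRIST_R=wl, **base)
        assert synchrony_indices(win).si_arms == pytest.approx(1.0)
        # negated -> r = -1
        wr = pelvis + np.column_stack([-190 + 0 * t, -150 + 0 * t, ap])
        win = build_window(t, WRIST_L=wl, WRIST_R=wr, **base)
        assert synchrony_indices(win).si_arms == pytest.approx(-1.0)

    def test_zero_variance_series_raises(self):
        t = np.arange(60) / 50.0
        pelvis = np.column_stack([0 * t, 0 * t + 900, 2500.0 + 0 * t])
        win = build_window(t, PELVIS=pelvis, WRIST_L=pelvis, WRIST_R=pelvis)
        with pytest.raises(UndefinedCorrelationError):
            synchrony_indices(win)

    def test_noise_attenuation_matches_monte_carlo_oracle(self):
        """Anti-phase sinusoids with additive noise: the measured arm-arm
        correlation must sit within 0.05 of a Monte-Carlo estimate of the
        attenuated correlation at the same signal-to-noise ratio."""
        amp, sigma, n = 50.0, 25.0, 200
        t = np.arange(n) / 50.0
        s = amp * np.sin(2 * np.pi * 0.9 * t)

        rng = np.random.default_rng(42)
        mc = [
            np.corrcoef(
                s + rng.normal(0, sigma, n), -s + rng.normal(0, sigma, n)
            )[0, 1]
            for _ in range(500)
        ]
        expected = float(np.mean(mc))

        pelvis = np.column_stack([0 * t, 0 * t + 900, 2500.0 + 0 * t])
        rng2 = np.random.default_rng(7)
        wl = pelvis + np.column_stack(
            [190 + 0 * t, -150 + 0 * t, -(s + rng2.normal(0, sigma, n))]
        )
        wr = pelvis + np.column_stack(
            [-190 + 0 * t, -150 + 0 * t, -(-s + rng2.normal(0, sigma, n))]
        )
        win = build_window(
            t,
            PELVIS=pelvis,
            WRIST_L=wl,
            WRIST_R=wr,
            SHOULDER_L=pelvis + np.array([190.0, 450.0, 0.0]),
            SHOULDER_R=pelvis + np.array([-190.0, 450.0, 0.0]),
            HIP_L=pelvis + np.array([90.0, -50.0, 0.0]),
            HIP_R=pelvis + np.array([-90.0, -50.0, 0.0]),
            ANKLE_L=pelvis + np.column_stack([0 * t, 0 * t - 820, 50 * np.sin(t)]),
            ANKLE_R=pelvis + np.column_stack([0 * t, 0 * t - 820, -50 * np.sin(t)]),
        )
        assert synchrony_indices(win).si_arms == pytest.approx(expected, abs=0.05)

    def test_arm_leg_pairing_sign_is_positive_in_phase(self):
        cfg = SynthConfig(seed=21)
        win, truth = _sim_window(cfg)
        si = synchrony_indices(win)
        assert si.si_arm_leg_left > 0.5
        assert si.si_arm_leg_right > 0.5
        assert si.si_arms < -0.9

    def test_structural_identities_on_params(self):
        cfg = SynthConfig(arm_amplitude_deg=(28.0, 14.0), seed=3)
        win, _ = _sim_window(cfg)
        for side in ("left", "right"):
            p = arm_swing_params(win, side)
            lin = p.linear
            for d in ("ap", "ml", "ud"):
                assert getattr(lin, f"sway_range_{d}_mm") == pytest.approx(
                    getattr(lin, f"sway_ant_{d}_mm")
                    - getattr(lin, f"sway_pos_{d}_mm")
                )
            assert p.angular.angle_range_deg == pytest.approx(
                p.angular.angle_ant_deg - p.angular.angle_pos_deg
            )
            assert lin.path_tot_mm >= lin.sway_range_ap_mm
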