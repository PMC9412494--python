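"""Parametric synthetic-walking simulator with closed-form ground truth.

Emulates the study protocol every metric in this package is built for: a
subject walking at a steady pace along a 10 m walkway toward a depth
camera sampling at a jittery ~30 fps, with all 32 skeleton joints
emitted. Every kinematic feature the pipeline measures is driven by an
explicit configuration parameter, so each pipeline stage has a
parameter-recovery test without any recorded data.

Kinematic model (all smooth and analytic; noise is added last so the
ground truth stays closed-form):

* the pelvis advances toward the camera at ``step_length / step_time``
  with sinusoidal mediolateral sway at stride frequency and vertical
  sway at step frequency (the double bump of human gait);
* the ankles alternate stance (planted, world z frozen) and swing
  (forward transport by one stride). The swing transport profile is a
  cosine-ramped plateau: velocity ramps sinusoidally over the first and
  last 10% of the swing and is constant in between. Zero endpoint
  velocity makes the pelvis-relative AP extrema (the heel-strike /
  toe-off signature) well defined; the exact foot-clearance shape is
  irrelevant to the tested metrics and arbitrary;
* the wrists swing as sagittal pendulums from the shoulders with a
  configurable angular amplitude per side, anti-phase between arms and
  in phase with the contralateral leg;
* shoulders, hips and all non-modelled joints ride rigidly on their
  parent joint;
* timestamps are drawn at the configured mean frame rate with Gaussian
  jitter; isotropic Gaussian positional noise is added to every joint
  coordinate.

The :class:`GroundTruth` returned alongside each trial reports, for
every parameter the pipeline estimates, the value the metric definition
attains on the noise-free kinematics. For event-timing quantities this
includes the closed-form offset between the nominal footfall schedule
and the pelvis-relative AP extremum the detector finds (the extremum
falls where the swinging ankle's speed drops through the pelvis speed,
slightly before touchdown).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .arm_swing import asa
from .com_sway import _max_abs_residual
from .errors import ConfigError
from .preprocess import GAP_FAR_M, GAP_NEAR_M
from .skeleton_io import JOINT_INDEX, JOINT_NAMES, SkeletonSequence, write_trial

SWING_RAMP_FRACTION = 0.1  # fraction of swing spent in each velocity ramp


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth kinematic parameters for one simulated trial."""

    # gait pattern
    step_length_m: float = 0.60
    step_time_s: float = 0.55
    stance_fraction: float = 0.62
    step_width_m: float = 0.14
    # course geometry (metres from the camera)
    start_z_m: float = 5.5
    end_z_m: float = 1.0
    walkway_length_m: float = 10.0
    gap_near_m: float = GAP_NEAR_M
    gap_far_m: float = GAP_FAR_M
    # arm swing: sinusoidal amplitude of the sagittal arm angle per side;
    # anterior_fraction 0.5 = symmetric anterior/posterior split
    arm_amplitude_deg: tuple[float, float] = (25.0, 25.0)  # (left, right)
    arm_anterior_fraction: float = 0.5
    # small quarter-phase mediolateral wrist wander so the (AP, ML) wrist
    # orbit encloses a finite area, as real arm swing does
    arm_ml_amplitude_mm: float = 15.0
    # centre-of-mass sway amplitudes
    com_lateral_amp_mm: float = 45.0
    com_vertical_amp_mm: float = 35.0
    # acquisition model
    frame_rate_fps: float = 30.0
    timestamp_jitter_sd_s: float = 0.004
    noise_sd_mm: float = 2.0
    seed: int = 0
    # body geometry (millimetres)
    pelvis_height_mm: float = 900.0
    hip_halfwidth_mm: float = 90.0
    hip_drop_mm: float = 50.0
    shoulder_halfwidth_mm: float = 190.0
    shoulder_height_mm: float = 450.0
    arm_length_mm: float = 600.0
    ankle_height_mm: float = 80.0
    foot_clearance_mm: float = 50.0
    # cohort metadata
    subject_id: str = "S00"
    group: str = ""

    @property
    def walk_speed_mps(self) -> float:
        return self.step_length_m / self.step_time_s

    @property
    def stride_time_s(self) -> float:
        return 2.0 * self.step_time_s

    def validate(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ConfigError("stance_fraction must lie in (0, 1)")
        if self.step_length_m <= 0 or self.step_time_s <= 0:
            raise ConfigError("step length and time must be positive")
        if min(self.arm_amplitude_deg) < 0 or self.arm_ml_amplitude_mm < 0:
            raise ConfigError("arm amplitudes must be >= 0")
        if self.com_lateral_amp_mm < 0 or self.com_vertical_amp_mm < 0:
            raise ConfigError("sway amplitudes must be >= 0")
        if self.noise_sd_mm < 0 or self.timestamp_jitter_sd_s < 0:
            raise ConfigError("noise levels must be >= 0")
        if not (self.start_z_m > self.gap_far_m > self.gap_near_m > self.end_z_m > 0):
            raise ConfigError(
                "require start_z > gap_far > gap_near > end_z > 0"
            )
        if self.start_z_m > self.walkway_length_m:
            raise ConfigError("start_z cannot exceed the walkway length")
        travel = self.start_z_m - self.end_z_m
        if travel < 2.0 * self.step_length_m:
            raise ConfigError(
                "course too short for one full stride "
                f"({travel:.2f} m < {2 * self.step_length_m:.2f} m)"
            )


@dataclass
class GroundTruth:
    """Exact parameter values implied by a :class:`SynthConfig`."""

    # spatiotemporal (nominal schedule)
    step_length_m: float
    step_time_s: float
    stride_length_m: float
    step_width_m: float
    gait_velocity_mps: float
    cadence_spm: float  # 60 / step_time (nominal rhythm)
    # event-convention quantities (AP-extremum rule on clean kinematics)
    stance_duration_pct: float
    double_support_s: float
    event_time_offset_s: float
    heel_strikes: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]
    gap_entry_time_s: float
    gap_exit_time_s: float
    step_num: int  # heel strikes inside the GAP window, both sides
    stride_num: int
    # COM sway
    ml_sway_mm: float
    v_sway_mm: float
    # arm swing (per side)
    angle_ant_deg: dict[str, float]
    angle_pos_deg: dict[str, float]
    angle_range_deg: dict[str, float]
    sway_range_ap_mm: dict[str, float]
    path_tot_mm: dict[str, float]
    speed_ap_mms: dict[str, float]
    # indices
    asa_angle_pct: float
    asa_path_pct: float
    asa_ap_range_pct: float
    si_arms: float
    si_arm_leg_left: float
    si_arm_leg_right: float

    def scalars(self) -> dict[str, float]:
        """Flat dict of the scalar truths (manifest/CSV friendly)."""
        out: dict[str, float] = {}
        for name in (
            "step_length_m step_time_s stride_length_m step_width_m "
            "gait_velocity_mps cadence_spm stance_duration_pct "
            "double_support_s ml_sway_mm v_sway_mm asa_angle_pct "
            "asa_path_pct asa_ap_range_pct si_arms si_arm_leg_left "
            "si_arm_leg_right"
        ).split():
            out[name] = float(getattr(self, name))
        for name in (
            "angle_range_deg angle_ant_deg sway_range_ap_mm path_tot_mm "
            "speed_ap_mms"
        ).split():
            d = getattr(self, name)
            out[f"{name}_left"] = float(d["left"])
            out[f"{name}_right"] = float(d["right"])
        out["step_num"] = float(self.step_num)
        out["stride_num"] = float(self.stride_num)
        return out


# --- swing transport profile -------------------------------------------------

def _profile_norm(a: float) -> float:
    return 1.0 - 2.0 * a + 4.0 * a / math.pi


def _swing_position(u: np.ndarray, a: float = SWING_RAMP_FRACTION) -> np.ndarray:
    """Normalized forward displacement through the swing, s(0)=0, s(1)=1."""
    u = np.clip(u, 0.0, 1.0)
    c = 2.0 * a / math.pi
    early = c * (1.0 - np.cos(np.pi * u / (2.0 * a)))
    mid = c + (u - a)
    late = c + (1.0 - 2.0 * a) + c * np.cos(np.pi * (1.0 - u) / (2.0 * a))
    out = np.where(u < a, early, np.where(u <= 1.0 - a, mid, late))
    return out / _profile_norm(a)


def event_time_offset(cfg: SynthConfig, a: float = SWING_RAMP_FRACTION) -> float:
    """Closed-form lead of the AP-extremum event before/after the footfall.

    The pelvis-relative forward position of the swinging ankle peaks where
    the ankle's speed falls back through the pelvis speed, i.e. inside the
    final velocity ramp of the swing: with ramp fraction ``a``,
    normalization ``W = 1 - 2a + 4a/pi`` and swing fraction
    ``sw = 1 - stance_fraction``, the crossing sits ``(2a/pi) *
    asin(W * sw)`` swing-normalized units before touchdown. By symmetry
    the minimum (toe-off) trails the nominal lift-off by the same lag.
    """
    sw = 1.0 - cfg.stance_fraction
    w = _profile_norm(a) * sw
    swing_duration = sw * cfg.stride_time_s
    return (2.0 * a / math.pi) * math.asin(w) * swing_duration


# --- analytic kinematics -----------------------------------------------------

def _pelvis_xyz(cfg: SynthConfig, t: np.ndarray) -> np.ndarray:
    T = cfg.stride_time_s
    x = cfg.com_lateral_amp_mm * np.sin(2.0 * np.pi * t / T)
    y = cfg.pelvis_height_mm + cfg.com_vertical_amp_mm * np.sin(
        4.0 * np.pi * t / T
    )
    z = (cfg.start_z_m - cfg.walk_speed_mps * t) * 1000.0
    return np.column_stack([x, y, z])


def _ankle_zy(
    cfg: SynthConfig, t: np.ndarray, side: str
) -> tuple[np.ndarray, np.ndarray]:
    """World z (mm) and y (mm) of one ankle over time."""
    st = cfg.step_time_s
    T = cfg.stride_time_s
    sf = cfg.stance_fraction
    L_mm = cfg.step_length_m * 1000.0
    t0 = 0.0 if side == "left" else st  # first footfall of this side
    rel = t - t0
    k = np.floor(rel / T)
    tau = rel - k * T
    # footfall k of this side is overall step number t0/st + 2k and lands
    # half a step ahead of the pelvis position at that instant
    land_z = (
        cfg.start_z_m * 1000.0 - (t0 / st + 2.0 * k) * L_mm - 0.5 * L_mm
    )
    swing = tau > sf * T
    u = np.where(swing, (tau - sf * T) / ((1.0 - sf) * T), 0.0)
    z = land_z - np.where(swing, 2.0 * L_mm * _swing_position(u), 0.0)
    y = cfg.ankle_height_mm + np.where(
        swing, cfg.foot_clearance_mm * np.sin(np.pi * u), 0.0
    )
    return z, y


def _arm_angle_rad(cfg: SynthConfig, t: np.ndarray, side: str) -> np.ndarray:
    """Sagittal arm angle: positive = anterior. Anti-phase between sides,
    each arm's anterior peak at the contralateral heel strike."""
    amp_l, amp_r = cfg.arm_amplitude_deg
    amp = math.radians(amp_l if side == "left" else amp_r)
    bias = (2.0 * cfg.arm_anterior_fraction - 1.0) * amp
    # first right footfall at t = step_time: the left arm peaks there
    phase = 2.0 * np.pi * (t - cfg.step_time_s) / cfg.stride_time_s
    sign = 1.0 if side == "left" else -1.0
    return bias + sign * amp * np.cos(phase)


def _arm_ml_mm(cfg: SynthConfig, t: np.ndarray) -> np.ndarray:
    """Mediolateral wrist wander, a quarter cycle out of phase with the
    sagittal swing (same for both sides)."""
    return cfg.arm_ml_amplitude_mm * np.sin(
        2.0 * np.pi * (t - cfg.step_time_s) / cfg.stride_time_s
    )


def _skeleton_at(cfg: SynthConfig, t: np.ndarray) -> np.ndarray:
    """Noise-free positions of all 32 joints, shape (n, 32, 3), mm."""
    n = t.size
    pos = np.zeros((n, len(JOINT_NAMES), 3))
    pelvis = _pelvis_xyz(cfg, t)

    def put(name: str, xyz: np.ndarray) -> None:
        pos[:, JOINT_INDEX[name], :] = xyz

    def offset(base: np.ndarray, dx: float, dy: float, dz: float) -> np.ndarray:
        return base + np.array([dx, dy, dz])

    put("PELVIS", pelvis)
    put("SPINE_NAVEL", offset(pelvis, 0, 150, 0))
    put("SPINE_CHEST", offset(pelvis, 0, 300, 0))
    put("NECK", offset(pelvis, 0, 500, 0))
    head = offset(pelvis, 0, 600, 0)
    put("HEAD", head)
    put("NOSE", offset(head, 0, 20, -80))
    put("EYE_L", offset(head, 30, 30, -70))
    put("EYE_R", offset(head, -30, 30, -70))
    put("EAR_L", offset(head, 70, 20, 0))
    put("EAR_R", offset(head, -70, 20, 0))

    for side, sgn in (("left", 1.0), ("right", -1.0)):
        s = "L" if side == "left" else "R"
        hip = offset(pelvis, sgn * cfg.hip_halfwidth_mm, -cfg.hip_drop_mm, 0)
        put(f"HIP_{s}", hip)
        shoulder = offset(
            pelvis, sgn * cfg.shoulder_halfwidth_mm, cfg.shoulder_height_mm, 0
        )
        put(f"SHOULDER_{s}", shoulder)
        put(f"CLAVICLE_{s}", offset(pelvis, sgn * 80, 440, 0))

        theta = _arm_angle_rad(cfg, t, side)
        arm_vec = np.column_stack(
            [
                _arm_ml_mm(cfg, t),
                -cfg.arm_length_mm * np.cos(theta),
                -cfg.arm_length_mm * np.sin(theta),
            ]
        )
        wrist = shoulder + arm_vec
        put(f"WRIST_{s}", wrist)
        put(f"ELBOW_{s}", shoulder + 0.45 * arm_vec)
        put(f"HAND_{s}", offset(wrist, 0, -50, -20))
        put(f"HANDTIP_{s}", offset(wrist, 0, -90, -40))
        put(f"THUMB_{s}", offset(wrist, sgn * -30, -40, -20))

        az, ay = _ankle_zy(cfg, t, side)
        ax = np.full_like(az, sgn * cfg.step_width_m * 500.0)
        ankle = np.column_stack([ax, ay, az])
        put(f"ANKLE_{s}", ankle)
        put(f"KNEE_{s}", 0.5 * (hip + ankle) + np.array([0, 0, -30.0]))
        put(f"FOOT_{s}", offset(ankle, 0, -40, -120))
    return pos


# --- trial generation --------------------------------------------------------

def _timestamps(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    total = (cfg.start_z_m - cfg.end_z_m) / cfg.walk_speed_mps
    mean_dt = 1.0 / cfg.frame_rate_fps
    n_max = int(total / mean_dt * 1.5) + 10
    steps = mean_dt + rng.normal(0.0, cfg.timestamp_jitter_sd_s, n_max)
    steps = np.clip(steps, 0.5 * mean_dt, 2.0 * mean_dt)
    t = np.concatenate([[0.0], np.cumsum(steps)])
    return t[t <= total]


def generate(cfg: SynthConfig) -> tuple[SkeletonSequence, GroundTruth]:
    """Simulate one walking trial and its exact ground truth.

    The same seed always yields a bit-identical trial.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = _timestamps(cfg, rng)
    pos = _skeleton_at(cfg, t)
    if cfg.noise_sd_mm > 0:
        pos = pos + rng.normal(0.0, cfg.noise_sd_mm, pos.shape)
    seq = SkeletonSequence(
        times=t,
        positions=pos,
        subject_id=cfg.subject_id,
        group=cfg.group,
    )
    return seq, ground_truth(cfg)


def ground_truth(cfg: SynthConfig) -> GroundTruth:
    """Exact pipeline-parameter values implied by the configuration."""
    cfg.validate()
    v = cfg.walk_speed_mps
    st = cfg.step_time_s
    T = cfg.stride_time_s
    sf = cfg.stance_fraction
    total = (cfg.start_z_m - cfg.end_z_m) / v
    t_entry = (cfg.start_z_m - cfg.gap_far_m) / v
    t_exit = (cfg.start_z_m - cfg.gap_near_m) / v
    dt_ev = event_time_offset(cfg)

    # event times under the AP-extremum convention, whole trial
    hs: dict[str, np.ndarray] = {}
    to: dict[str, np.ndarray] = {}
    for side, t0 in (("left", 0.0), ("right", st)):
        lands = np.arange(t0, total + T, T)
        hs_t = lands - dt_ev
        hs[side] = hs_t[(hs_t > 0) & (hs_t <= total)]
        to_t = np.arange(t0 - T, total + T, T) + sf * T + dt_ev
        to[side] = to_t[(to_t > 0) & (to_t <= total)]

    in_win = {
        s: hs[s][(hs[s] >= t_entry) & (hs[s] <= t_exit)] for s in ("left", "right")
    }
    step_num = sum(len(x) for x in in_win.values())
    stride_num = sum(max(0, len(x) - 1) for x in in_win.values())

    # dense noise-free window grid for trajectory-derived truths
    tg = np.arange(t_entry, t_exit, 1e-3)
    pelvis = _pelvis_xyz(cfg, tg)
    com = pelvis + np.array([0.0, -cfg.hip_drop_mm, 0.0])  # hip midpoint
    ml_sway = _max_abs_residual(com[:, 2], com[:, 0])
    v_sway = _max_abs_residual(com[:, 2], com[:, 1])

    angle_ant: dict[str, float] = {}
    angle_pos: dict[str, float] = {}
    angle_range: dict[str, float] = {}
    ap_range: dict[str, float] = {}
    path_tot: dict[str, float] = {}
    speed_ap: dict[str, float] = {}
    ap_series: dict[str, np.ndarray] = {}
    arm_ext: dict[str, np.ndarray] = {}
    leg_ext: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        theta = _arm_angle_rad(cfg, tg, side)
        deg = np.degrees(theta)
        angle_ant[side] = float(deg.max())
        angle_pos[side] = float(deg.min())
        angle_range[side] = float(deg.max() - deg.min())
        ap = cfg.arm_length_mm * np.sin(theta)
        ud = -cfg.arm_length_mm * np.cos(theta)
        ml = _arm_ml_mm(cfg, tg)
        ap_series[side] = ap
        ap_range[side] = float(ap.max() - ap.min())
        rel = np.column_stack([ap, ml, ud])
        path_tot[side] = float(
            np.sum(np.linalg.norm(np.diff(rel, axis=0), axis=1))
        )
        speed_ap[side] = float(np.max(np.abs(np.gradient(ap, tg))))
        arm_ext[side] = -ap  # wrist_z - shoulder_z
        hz, _ = _ankle_zy(cfg, tg, side)
        leg_ext[side] = hz - pelvis[:, 2]  # ankle_z - hip_z (hip rides pelvis)

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.corrcoef(a, b)[0, 1])

    return GroundTruth(
        step_length_m=cfg.step_length_m,
        step_time_s=st,
        stride_length_m=2.0 * cfg.step_length_m,
        step_width_m=cfg.step_width_m,
        gait_velocity_mps=v,
        cadence_spm=60.0 / st,
        stance_duration_pct=100.0 * (sf * T + 2.0 * dt_ev) / T,
        double_support_s=(sf - 0.5) * T + 2.0 * dt_ev,
        event_time_offset_s=dt_ev,
        heel_strikes=hs,
        toe_offs=to,
        gap_entry_time_s=t_entry,
        gap_exit_time_s=t_exit,
        step_num=step_num,
        stride_num=stride_num,
        ml_sway_mm=ml_sway,
        v_sway_mm=v_sway,
        angle_ant_deg=angle_ant,
        angle_pos_deg=angle_pos,
        angle_range_deg=angle_range,
        sway_range_ap_mm=ap_range,
        path_tot_mm=path_tot,
        speed_ap_mms=speed_ap,
        asa_angle_pct=asa(angle_range["left"], angle_range["right"]),
        asa_path_pct=asa(path_tot["left"], path_tot["right"]),
        asa_ap_range_pct=asa(ap_range["left"], ap_range["right"]),
        si_arms=_corr(ap_series["left"], ap_series["right"]),
        si_arm_leg_left=_corr(arm_ext["left"], leg_ext["right"]),
        si_arm_leg_right=_corr(arm_ext["right"], leg_ext["left"]),
    )


def study_cohort_configs(base_seed: int = 0) -> "list[SynthConfig]":
    """Default two-group study design: 16 impaired-like + 13 control-like
    subjects (two trials each under :func:`cohort` gives 32 + 26 trials).

    Impaired-like subjects walk slower with shorter steps, longer stance,
    reduced and asymmetric arm swing, and larger lateral sway; control-like
    subjects walk faster with near-symmetric arms. Per-subject parameters
    are drawn once, deterministically, from ``base_seed``.
    """
    rng = np.random.default_rng(base_seed)
    configs: list[SynthConfig] = []

    def draw(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    for i in range(16):
        base_amp = draw(8.0, 18.0)
        ratio = draw(1.1, 1.8)
        more, less = base_amp * ratio, base_amp
        left_first = rng.random() < 0.5
        amps = (more, less) if left_first else (less, more)
        configs.append(
            SynthConfig(
                subject_id=f"imp{i + 1:02d}",
                group="impaired",
                step_length_m=draw(0.50, 0.62),
                step_time_s=draw(0.55, 0.64),
                stance_fraction=draw(0.61, 0.66),
                arm_amplitude_deg=amps,
                com_lateral_amp_mm=draw(45.0, 80.0),
                com_vertical_amp_mm=draw(25.0, 45.0),
                seed=int(rng.integers(2**31)),
            )
        )
    for i in range(13):
        base_amp = draw(17.0, 23.0)
        ratio = draw(1.0, 1.15)
        more, less = base_amp * ratio, base_amp
        left_first = rng.random() < 0.5
        amps = (more, less) if left_first else (less, more)
        configs.append(
            SynthConfig(
                subject_id=f"ctl{i + 1:02d}",
                group="control",
                step_length_m=draw(0.60, 0.70),
                step_time_s=draw(0.52, 0.58),
                stance_fraction=draw(0.58, 0.61),
                arm_amplitude_deg=amps,
                com_lateral_amp_mm=draw(40.0, 60.0),
                com_vertical_amp_mm=draw(28.0, 42.0),
                seed=int(rng.integers(2**31)),
            )
        )
    return configs


def cohort(
    configs: "list[SynthConfig]",
    n_trials: int,
    out_dir,
) -> "pd.DataFrame":
    """Write a reproducible trial set plus a ground-truth manifest.

    Each subject (one config) contributes ``n_trials`` trials whose seeds
    are derived deterministically from the config seed. Returns the
    manifest as a DataFrame; it is also written to ``manifest.csv`` in
    ``out_dir`` with one row per trial (config parameters and all scalar
    ground truths).
    """
    import pandas as pd

    if not configs:
        raise ConfigError("cohort needs at least one configuration")
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cfg in configs:
        for j in range(1, n_trials + 1):
            trial_cfg = replace(cfg, seed=(cfg.seed * 1009 + j) % 2**31)
            seq, truth = generate(trial_cfg)
            seq.trial_id = j
            fname = f"{cfg.subject_id}_trial{j}.json"
            write_trial(seq, out / fname)
            row = {
                "subject_id": cfg.subject_id,
                "trial_id": j,
                "group": cfg.group,
                "path": fname,
                "seed": trial_cfg.seed,
                "step_length_m_cfg": cfg.step_length_m,
                "step_time_s_cfg": cfg.step_time_s,
                "stance_fraction_cfg": cfg.stance_fraction,
                "arm_amplitude_deg_left": cfg.arm_amplitude_deg[0],
                "arm_amplitude_deg_right": cfg.arm_amplitude_deg[1],
                "com_lateral_amp_mm_cfg": cfg.com_lateral_amp_mm,
                "noise_sd_mm": cfg.noise_sd_mm,
            }
            row.update(truth.scalars())
            rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
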