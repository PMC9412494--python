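"""Arm-swing amplitude, asymmetry and synchrony metrics.

Linear measures are displacements of each wrist relative to the pelvis,
decomposed into anteroposterior (AP = pelvis_z − wrist_z, positive when
the wrist is ahead of the body, toward the camera), mediolateral
(ML = wrist_x − pelvis_x) and up–down (UD = wrist_y − pelvis_y)
components. From these come the per-direction anterior/posterior maxima
and peak-to-peak ranges, the total 3D path travelled inside the GAP, the
convex-hull area of the (AP, ML) wrist motion, and the peak AP speed.

Angular measures are the signed sagittal-plane angle between the arm
segment (shoulder→wrist) and the same-side trunk segment (shoulder→hip),
positive when the arm is anterior of the trunk line. Signed anterior /
posterior decomposition requires a planar angle, hence the sagittal
(AP–UD) projection.

Asymmetry is quantified with the absolute symmetry angle

    ASA = |(45° − arctan(P_MORE / P_LESS)) / 90°| × 100  (%)

where P_MORE and P_LESS are the larger and smaller of the left/right
values of a parameter. ASA is 0 for perfect symmetry, 50 in the limit of
one-sided motion, and scale-invariant in its inputs. It is reported for
the angular range (ASA_ANGLE), the path travelled (ASA_PATH) and the AP
sway range (ASA_AP_RANGE).

Synchrony is the Pearson correlation of anteroposterior limb signals:
between the two wrists' AP series (SI_ARMS, expected strongly negative —
healthy arms move in opposition) and between each arm segment's
z-extension and the opposite leg segment's z-extension (SI_ARM_LEG,
expected positive — opposite arm and leg advance together).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import pearsonr

from .errors import (
    DegenerateGeometryWarning,
    InsufficientDataError,
    UndefinedAsymmetryError,
    UndefinedCorrelationError,
)
from .preprocess import GaitWindow

MIN_PROJECTED_NORM_MM = 10.0
DIRECTIONS = ("ap", "ml", "ud")


@dataclass
class LinearArmMetrics:
    sway_ant_ap_mm: float
    sway_ant_ml_mm: float
    sway_ant_ud_mm: float
    sway_pos_ap_mm: float
    sway_pos_ml_mm: float
    sway_pos_ud_mm: float
    sway_range_ap_mm: float
    sway_range_ml_mm: float
    sway_range_ud_mm: float
    path_tot_mm: float
    sway_area_mm2: float
    speed_ap_mms: float


@dataclass
class AngularArmMetrics:
    angle_ant_deg: float
    angle_pos_deg: float
    angle_range_deg: float


@dataclass
class ArmSwingParams:
    """All per-arm metrics for one side."""

    linear: LinearArmMetrics
    angular: AngularArmMetrics

    @property
    def angle_range_deg(self) -> float:
        return self.angular.angle_range_deg

    @property
    def path_tot_mm(self) -> float:
        return self.linear.path_tot_mm

    @property
    def sway_range_ap_mm(self) -> float:
        return self.linear.sway_range_ap_mm


@dataclass
class AsymmetryIndices:
    asa_angle_pct: float  # over left/right ANGLE_RANGE
    asa_path_pct: float  # over left/right PATH_TOT
    asa_ap_range_pct: float  # over left/right SWAY_RANGE_AP


@dataclass
class SynchronyIndices:
    si_arms: float
    si_arm_leg_left: float  # left arm vs right leg
    si_arm_leg_right: float  # right arm vs left leg

    @property
    def si_arm_leg_mean(self) -> float:
        return 0.5 * (self.si_arm_leg_left + self.si_arm_leg_right)


def _joints(side: str) -> tuple[str, str, str, str]:
    s = "L" if side == "left" else "R"
    return f"WRIST_{s}", f"SHOULDER_{s}", f"HIP_{s}", f"ANKLE_{s}"


def wrist_relative_series(win: GaitWindow, side: str) -> np.ndarray:
    """Wrist displacement relative to the pelvis, shape ``(n, 3)`` mm.

    Columns are (AP, ML, UD); AP is positive when the wrist is anterior
    of the pelvis (closer to the camera).
    """
    wrist_name, _, _, _ = _joints(side)
    wrist = win.joint(wrist_name)
    pelvis = win.joint("PELVIS")
    ap = pelvis[:, 2] - wrist[:, 2]
    ml = wrist[:, 0] - pelvis[:, 0]
    ud = wrist[:, 1] - pelvis[:, 1]
    return np.column_stack([ap, ml, ud])


def linear_metrics(rel: np.ndarray, dt: float = 0.02) -> LinearArmMetrics:
    """Linear arm-swing metrics from a pelvis-relative wrist series.

    Extrema are per-component maxima/minima; the path is the summed 3D
    chord length; the area is the 2D convex hull of the (AP, ML) cloud
    (zero, with a warning, when the points are collinear); the peak AP
    speed uses central differences on the uniform grid.
    """
    rel = np.asarray(rel, dtype=float)
    if rel.ndim != 2 or rel.shape[1] != 3:
        raise ValueError("rel must be an (n, 3) (AP, ML, UD) array")
    if rel.shape[0] < 10:
        raise InsufficientDataError("linear metrics need >= 10 samples")

    maxima = rel.max(axis=0)
    minima = rel.min(axis=0)
    path = float(np.sum(np.linalg.norm(np.diff(rel, axis=0), axis=1)))
    try:
        area = float(ConvexHull(rel[:, :2]).volume)  # 2-D hull: volume == area
    except QhullError:
        warnings.warn(
            "wrist (AP, ML) points are (near-)collinear; sway area set to 0",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
        area = 0.0
    speed = float(np.max(np.abs(np.gradient(rel[:, 0], dt))))
    return LinearArmMetrics(
        sway_ant_ap_mm=float(maxima[0]),
        sway_ant_ml_mm=float(maxima[1]),
        sway_ant_ud_mm=float(maxima[2]),
        sway_pos_ap_mm=float(minima[0]),
        sway_pos_ml_mm=float(minima[1]),
        sway_pos_ud_mm=float(minima[2]),
        sway_range_ap_mm=float(maxima[0] - minima[0]),
        sway_range_ml_mm=float(maxima[1] - minima[1]),
        sway_range_ud_mm=float(maxima[2] - minima[2]),
        path_tot_mm=path,
        sway_area_mm2=area,
        speed_ap_mms=speed,
    )


def sagittal_arm_angle(win: GaitWindow, side: str) -> np.ndarray:
    """Signed sagittal angle (deg) between arm and trunk segments.

    Both the arm vector (wrist − shoulder) and the trunk vector
    (hip − shoulder) are projected onto the sagittal (z, y) plane; the
    returned angle is positive when the arm points anterior (toward the
    camera) of the trunk line. Samples where either projection is shorter
    than 10 mm are NaN; a warning is emitted if more than 5% of samples
    are excluded.
    """
    wrist_name, shoulder_name, hip_name, _ = _joints(side)
    shoulder = win.joint(shoulder_name)
    arm = win.joint(wrist_name) - shoulder
    trunk = win.joint(hip_name) - shoulder
    # sagittal projection: keep (z, y)
    az, ay = arm[:, 2], arm[:, 1]
    bz, by = trunk[:, 2], trunk[:, 1]
    norm_a = np.hypot(az, ay)
    norm_b = np.hypot(bz, by)
    ok = (norm_a >= MIN_PROJECTED_NORM_MM) & (norm_b >= MIN_PROJECTED_NORM_MM)
    # positive cross product <=> arm anterior (toward -z) of trunk
    cross = az * by - ay * bz
    dot = az * bz + ay * by
    angle = np.degrees(np.arctan2(cross, dot))
    angle[~ok] = np.nan
    n_bad = int(np.count_nonzero(~ok))
    if n_bad > 0.05 * angle.size:
        warnings.warn(
            f"{n_bad}/{angle.size} samples excluded from the sagittal angle "
            "(projected segment below 10 mm)",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
    return angle


def angular_metrics(win: GaitWindow, side: str) -> AngularArmMetrics:
    """Anterior/posterior extrema and range of the sagittal arm angle."""
    angle = sagittal_arm_angle(win, side)
    if np.all(np.isnan(angle)):
        raise InsufficientDataError("no valid samples for the arm angle")
    ant = float(np.nanmax(angle))
    pos = float(np.nanmin(angle))
    return AngularArmMetrics(
        angle_ant_deg=ant, angle_pos_deg=pos, angle_range_deg=ant - pos
    )


def arm_swing_params(win: GaitWindow, side: str) -> ArmSwingParams:
    """All linear and angular arm-swing metrics for one side."""
    rel = wrist_relative_series(win, side)
    return ArmSwingParams(
        linear=linear_metrics(rel, dt=win.dt),
        angular=angular_metrics(win, side),
    )


def asa(p_left: float, p_right: float) -> float:
    """Absolute symmetry angle (%) of a left/right parameter pair.

    ``asa(x, x) == 0`` for any ``x > 0``; the supremum 50 is returned
    exactly when the smaller value is 0. Symmetric and scale-invariant in
    its arguments.

    Raises
    ------
    ValueError
        If either input is negative.
    UndefinedAsymmetryError
        If both inputs are 0 (no motion on either side).
    """
    if p_left < 0 or p_right < 0:
        raise ValueError("asa inputs must be non-negative magnitudes")
    p_more, p_less = max(p_left, p_right), min(p_left, p_right)
    if p_more == 0:
        raise UndefinedAsymmetryError("both sides are zero; asymmetry undefined")
    if p_less == 0:
        return 50.0
    return abs((45.0 - math.degrees(math.atan(p_more / p_less))) / 90.0) * 100.0


def asymmetry_indices(
    left: ArmSwingParams, right: ArmSwingParams
) -> AsymmetryIndices:
    """ASA indices over angular range, total path and AP sway range.

    Note: ASA_ANGLE is computed from the left/right ANGLE_RANGE values —
    the peak-to-peak angular amplitude is the quantity whose asymmetry
    the index tracks.
    """
    return AsymmetryIndices(
        asa_angle_pct=asa(left.angle_range_deg, right.angle_range_deg),
        asa_path_pct=asa(left.path_tot_mm, right.path_tot_mm),
        asa_ap_range_pct=asa(left.sway_range_ap_mm, right.sway_range_ap_mm),
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero-variance series")
    return float(pearsonr(a, b).statistic)


def synchrony_indices(win: GaitWindow) -> SynchronyIndices:
    """Arm–arm and arm–opposite-leg Pearson synchrony indices.

    SI_ARMS correlates the two wrists' pelvis-relative AP series.
    SI_ARM_LEG(side) correlates the z-extension of that side's arm
    segment (wrist_z − shoulder_z) with the z-extension of the opposite
    leg segment (ankle_z − hip_z); the sign convention makes in-phase
    forward motion of opposite limbs positive.
    """
    if win.n_samples < 25:
        raise InsufficientDataError("synchrony needs >= 25 window samples")
    ap = {s: wrist_relative_series(win, s)[:, 0] for s in ("left", "right")}
    si_arms = _pearson(ap["left"], ap["right"])

    def arm_ext(side: str) -> np.ndarray:
        wrist_name, shoulder_name, _, _ = _joints(side)
        return win.joint(wrist_name)[:, 2] - win.joint(shoulder_name)[:, 2]

    def leg_ext(side: str) -> np.ndarray:
        _, _, hip_name, ankle_name = _joints(side)
        return win.joint(ankle_name)[:, 2] - win.joint(hip_name)[:, 2]

    return SynchronyIndices(
        si_arms=si_arms,
        si_arm_leg_left=_pearson(arm_ext("left"), leg_ext("right")),
        si_arm_leg_right=_pearson(arm_ext("right"), leg_ext("left")),
    )
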