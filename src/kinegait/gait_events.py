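"""Gait event detection and spatiotemporal parameters.

Events are estimated from the anteroposterior (z) component of the ankle
trajectories only. To remove the forward drift of overground walking, each
ankle is expressed relative to the pelvis:

    f_side(t) = pelvis_z(t) - ankle_z(t)

which is largest when the ankle is furthest ahead of the body. During
stance the planted ankle is overtaken by the advancing pelvis (f falls);
during swing the ankle outruns the pelvis (f rises). Heel strike is
therefore the local maximum of f and toe-off the local minimum — the
standard pelvis-relative extremum rule for walkway (non-treadmill) gait.
Peaks must clear a prominence of 10 mm and be separated by at least
0.3 s; both thresholds are arguments.

From the events, the full spatiotemporal parameter set is computed per
side (step length/width/velocity/time, stride length, double support,
stance duration) and overall (gait velocity, cadence, step and stride
counts), with all spatial quantities taken from the same filtered 50 Hz
window the events were detected in.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import NoEventsError, SegmentationWarning
from .preprocess import GaitWindow

EVENT_PROMINENCE_MM = 10.0
EVENT_MIN_SEPARATION_S = 0.3

SIDES = ("left", "right")


@dataclass
class GaitEvents:
    """Per-side heel-strike and toe-off times (seconds, ordered)."""

    heel_strikes: dict[str, np.ndarray]  # side -> strictly increasing times
    toe_offs: dict[str, np.ndarray]

    def heel_strike_count(self) -> int:
        return sum(len(self.heel_strikes[s]) for s in SIDES)

    def all_heel_strikes(self) -> list[tuple[float, str]]:
        """Merged (time, side) heel strikes in chronological order."""
        merged = [
            (float(t), side) for side in SIDES for t in self.heel_strikes[side]
        ]
        merged.sort()
        return merged


@dataclass
class SideParams:
    """Spatiotemporal parameters of one side; NaN where inestimable."""

    step_len_m: float = math.nan
    step_width_m: float = math.nan
    step_vel_mps: float = math.nan
    step_time_s: float = math.nan
    stride_len_m: float = math.nan
    double_supp_s: float = math.nan
    stance_dur_pct: float = math.nan


@dataclass
class SpatiotemporalParams:
    left: SideParams
    right: SideParams
    gait_vel_mps: float
    cadence_spm: float
    step_num: int
    stride_num: int
    #: sides whose stride metrics could not be estimated (< 2 heel strikes)
    missing_sides: list[str] = field(default_factory=list)

    def side(self, side: str) -> SideParams:
        return self.left if side == "left" else self.right


def _relative_forward(win: GaitWindow, side: str) -> np.ndarray:
    ankle = win.joint("ANKLE_L" if side == "left" else "ANKLE_R")
    return win.joint("PELVIS")[:, 2] - ankle[:, 2]


def detect_events(
    win: GaitWindow,
    prominence_mm: float = EVENT_PROMINENCE_MM,
    min_separation_s: float = EVENT_MIN_SEPARATION_S,
) -> GaitEvents:
    """Detect heel strikes and toe-offs from pelvis-relative ankle AP.

    Raises :class:`NoEventsError` when no qualifying peak exists on
    either side (e.g. the subject stands still). Emits a
    :class:`SegmentationWarning` naming the offending times when heel
    strikes of the two sides fail to alternate.
    """
    distance = max(1, int(round(min_separation_s / win.dt)))
    hs: dict[str, np.ndarray] = {}
    to: dict[str, np.ndarray] = {}
    for side in SIDES:
        f = _relative_forward(win, side)
        pk_hs, _ = find_peaks(f, prominence=prominence_mm, distance=distance)
        pk_to, _ = find_peaks(-f, prominence=prominence_mm, distance=distance)
        hs[side] = win.times[pk_hs]
        to[side] = win.times[pk_to]

    events = GaitEvents(heel_strikes=hs, toe_offs=to)
    if events.heel_strike_count() == 0:
        raise NoEventsError(
            "no heel strikes found: relative ankle excursion below "
            f"{prominence_mm} mm prominence (standing or empty window?)"
        )

    merged = events.all_heel_strikes()
    bad = [
        t2
        for (t1, s1), (t2, s2) in zip(merged, merged[1:])
        if s1 == s2
    ]
    if bad:
        warnings.warn(
            "heel strikes do not alternate between sides at "
            f"t = {[round(t, 3) for t in bad]} s",
            SegmentationWarning,
            stacklevel=2,
        )
    return events


def _value_at(win: GaitWindow, series: np.ndarray, t: float) -> float:
    return float(np.interp(t, win.times, series))


def spatiotemporal(win: GaitWindow, ev: GaitEvents) -> SpatiotemporalParams:
    """Compute the spatiotemporal parameter set from detected events.

    Per-side definitions (averages over the events of that side inside
    the window):

    * step length: |ankle_z separation| at that side's heel strikes;
    * step width: |ankle_x separation| at that side's heel strikes;
    * step time: interval from the preceding contralateral heel strike;
    * step velocity: per-event step length / step time, then averaged;
    * stride length: |Δ ankle_z| between consecutive same-side strikes;
    * double support: contralateral toe-off minus this side's strike;
    * stance duration: (toe-off − heel strike) / stride time × 100.

    Overall: gait velocity = GAP length / traversal time; cadence =
    60 × step count / traversal time; step/stride counts summed over
    sides. A side with < 2 heel strikes has its stride metrics reported
    as NaN and is listed in ``missing_sides``.
    """
    if ev.heel_strike_count() < 2:
        raise NoEventsError("need >= 2 heel strikes to compute parameters")

    ankle_z = {
        "left": win.joint("ANKLE_L")[:, 2],
        "right": win.joint("ANKLE_R")[:, 2],
    }
    ankle_x = {
        "left": win.joint("ANKLE_L")[:, 0],
        "right": win.joint("ANKLE_R")[:, 0],
    }

    sides: dict[str, SideParams] = {}
    missing: list[str] = []
    for side in SIDES:
        other = "right" if side == "left" else "left"
        hs = ev.heel_strikes[side]
        hs_o = ev.heel_strikes[other]
        to_s = ev.toe_offs[side]
        to_o = ev.toe_offs[other]
        p = SideParams()

        if len(hs) > 0:
            seps = [
                abs(
                    _value_at(win, ankle_z[side], t)
                    - _value_at(win, ankle_z[other], t)
                )
                / 1000.0
                for t in hs
            ]
            p.step_len_m = float(np.mean(seps))
            widths = [
                abs(
                    _value_at(win, ankle_x["left"], t)
                    - _value_at(win, ankle_x["right"], t)
                )
                / 1000.0
                for t in hs
            ]
            p.step_width_m = float(np.mean(widths))

            times, vels = [], []
            for t, sep in zip(hs, seps):
                prev = hs_o[hs_o < t]
                if len(prev) > 0:
                    dt_step = float(t - prev[-1])
                    times.append(dt_step)
                    vels.append(sep / dt_step)
            if times:
                p.step_time_s = float(np.mean(times))
                p.step_vel_mps = float(np.mean(vels))

            ds = []
            for t in hs:
                nxt_to = to_o[to_o > t]
                nxt_hs = hs_o[hs_o > t]
                if len(nxt_to) > 0 and (
                    len(nxt_hs) == 0 or nxt_to[0] < nxt_hs[0]
                ):
                    ds.append(float(nxt_to[0] - t))
            if ds:
                p.double_supp_s = float(np.mean(ds))

        if len(hs) >= 2:
            strides = [
                abs(
                    _value_at(win, ankle_z[side], t2)
                    - _value_at(win, ankle_z[side], t1)
                )
                / 1000.0
                for t1, t2 in zip(hs, hs[1:])
            ]
            p.stride_len_m = float(np.mean(strides))

            stance = []
            for t1, t2 in zip(hs, hs[1:]):
                tos = to_s[(to_s > t1) & (to_s < t2)]
                if len(tos) > 0:
                    stance.append(100.0 * float(tos[0] - t1) / float(t2 - t1))
            if stance:
                p.stance_dur_pct = float(np.mean(stance))
        else:
            missing.append(side)
        sides[side] = p

    traversal = win.traversal_time
    step_num = ev.heel_strike_count()
    stride_num = sum(max(0, len(ev.heel_strikes[s]) - 1) for s in SIDES)
    return SpatiotemporalParams(
        left=sides["left"],
        right=sides["right"],
        gait_vel_mps=win.gap_length / traversal,
        cadence_spm=60.0 * step_num / traversal,
        step_num=step_num,
        stride_num=stride_num,
        missing_sides=missing,
    )
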