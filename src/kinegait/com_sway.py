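"""Centre-of-mass sway during walking.

The body centre of mass is proxied by the midpoint of the two hip joints
(COM_HIP). Sway is the maximum absolute deviation of that midpoint from
the subject's straight walking line toward the camera: a least-squares
line of the lateral (x) and vertical (y) coordinates against forward
progress (z) defines the reference path, and the sway parameters are the
largest absolute residuals, in millimetres. Fitting a line rather than
assuming the camera axis makes both parameters invariant to the subject
walking at a small constant angle to the sensor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InsufficientProgressError
from .preprocess import GaitWindow

MIN_PROGRESS_M = 0.2


@dataclass
class ComSwayParams:
    ml_sway_mm: float  # max |lateral residual|
    v_sway_mm: float  # max |vertical residual|
    trajectory: np.ndarray  # (n, 3) COM_HIP path, mm (for plotting/QA)


def com_trajectory(win: GaitWindow) -> np.ndarray:
    """Pointwise midpoint of the two hip joints, shape ``(n, 3)`` mm."""
    return 0.5 * (win.joint("HIP_L") + win.joint("HIP_R"))


def _max_abs_residual(ref: np.ndarray, val: np.ndarray) -> float:
    coeff = np.polyfit(ref, val, 1)
    return float(np.max(np.abs(val - np.polyval(coeff, ref))))


def sway_params(com: np.ndarray) -> ComSwayParams:
    """Maximum lateral and vertical oscillation about the walking line.

    Raises :class:`InsufficientProgressError` if the forward travel is
    below 0.2 m (no meaningful walking direction to detrend against).
    """
    com = np.asarray(com, dtype=float)
    if com.ndim != 2 or com.shape[1] != 3:
        raise ValueError("com must be an (n, 3) array")
    if com.shape[0] < 10:
        raise InsufficientDataError("sway needs >= 10 samples")
    z = com[:, 2]
    if np.ptp(z) < MIN_PROGRESS_M * 1000.0:
        raise InsufficientProgressError(
            f"forward travel {np.ptp(z) / 1000.0:.3f} m < {MIN_PROGRESS_M} m"
        )
    return ComSwayParams(
        ml_sway_mm=_max_abs_residual(z, com[:, 0]),
        v_sway_mm=_max_abs_residual(z, com[:, 1]),
        trajectory=com,
    )


def com_sway(win: GaitWindow) -> ComSwayParams:
    """Convenience composition: COM trajectory then sway parameters."""
    return sway_params(com_trajectory(win))
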