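"""Shared fixtures: simulated trials and hand-built windows."""
from __future__ import annotations

import numpy as np
import pytest

from kinegait import SkeletonSequence, SynthConfig, generate
from kinegait.preprocess import GaitWindow, ResampledSequence
from kinegait.skeleton_io import JOINT_INDEX, JOINT_NAMES


@pytest.fixture(scope="session")
def default_cfg() -> SynthConfig:
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def sim_trial(default_cfg):
    """One default simulated walking trial with its ground truth."""
    return generate(default_cfg)


@pytest.fixture(scope="session")
def wide_gap_trial():
    """A trial analysed over a wide GAP so both sides collect >= 3 strides."""
    cfg = SynthConfig(seed=11, gap_near_m=1.2, gap_far_m=4.8)
    return cfg, *generate(cfg)


def build_sequence(times, **joints) -> SkeletonSequence:
    """A SkeletonSequence with the named joints set and the rest at a
    constant offset (so validation passes and lookups stay finite)."""
    times = np.asarray(times, dtype=float)
    n = times.size
    pos = np.zeros((n, len(JOINT_NAMES), 3))
    for name, xyz in joints.items():
        pos[:, JOINT_INDEX[name], :] = np.asarray(xyz, dtype=float)
    return SkeletonSequence(times=times, positions=pos)


def build_resampled(times, rate: float = 50.0, **joints) -> ResampledSequence:
    times = np.asarray(times, dtype=float)
    n = times.size
    pos = np.zeros((n, len(JOINT_NAMES), 3))
    for name, xyz in joints.items():
        pos[:, JOINT_INDEX[name], :] = np.asarray(xyz, dtype=float)
    return ResampledSequence(times=times, positions=pos, rate=rate)


def build_window(times, rate: float = 50.0, gap=(1.5, 3.5), **joints) -> GaitWindow:
    """A GaitWindow wrapping hand-built uniform samples (no GAP slicing)."""
    samples = build_resampled(times, rate=rate, **joints)
    return GaitWindow(
        samples=samples,
        gap_near=gap[0],
        gap_far=gap[1],
        entry_time=float(samples.times[0]),
        exit_time=float(samples.times[-1]),
    )
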