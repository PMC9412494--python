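"""Per-trial batch analysis and two-group statistical reporting.

`analyze_trial` composes the whole pipeline — read, resample to 50 Hz,
8 Hz zero-phase low-pass, GAP windowing, event detection, spatiotemporal
/ COM-sway / arm-swing metrics, asymmetry and synchrony indices — into
one flat parameter row per trial, with the preprocessing configuration
recorded for provenance. `compare_groups` reproduces the classic
two-group report layout: per-parameter medians with first/third
quartiles, the Mann–Whitney rank-sum test (with the parametric t-test
alongside), Shapiro–Wilk normality checks and significance stars.
`correlation_matrix` computes the Spearman (and Pearson) coefficients
between the arm-swing parameters and the spatiotemporal/COM parameters
with per-cell significance tiers.

Parameters estimated separately per side carry ``_L``/``_R`` suffixes;
group tests pool the two sides as independent observations (so a cohort
of 32 + 26 trials yields 64 and 52 side-wise samples). This replicates
the sample accounting of field practice but ignores the within-subject
correlation of the two sides — a documented caveat, not a bug.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .arm_swing import arm_swing_params, asymmetry_indices, synchrony_indices
from .com_sway import com_sway
from .errors import KinegaitError, PipelineStageError
from .gait_events import detect_events, spatiotemporal
from .preprocess import (
    FILTER_CUTOFF_HZ,
    FILTER_ORDER,
    GAP_FAR_M,
    GAP_NEAR_M,
    RESAMPLE_RATE_HZ,
    extract_gap,
    lowpass_8hz,
    resample_50hz,
)
from .skeleton_io import SkeletonSequence, read_trial

#: Parameter columns estimated separately per side (suffix _L/_R).
SIDED_PARAMS = (
    "STEP_LEN", "STEP_WIDTH", "STEP_VEL", "STEP_TIME", "STRIDE_LEN",
    "DOUBLE_SUPP", "STANCE_DUR",
    "SWAY_ANT_AP", "SWAY_ANT_ML", "SWAY_ANT_UD",
    "SWAY_POS_AP", "SWAY_POS_ML", "SWAY_POS_UD",
    "SWAY_RANGE_AP", "SWAY_RANGE_ML", "SWAY_RANGE_UD",
    "PATH_TOT", "SWAY_AREA", "SPEED_AP",
    "ANGLE_ANT", "ANGLE_POS", "ANGLE_RANGE",
    "SI_ARM_LEG",
)
#: Whole-gait parameter columns (one observation per trial).
OVERALL_PARAMS = (
    "GAIT_VEL", "CADENCE", "STEP_NUM", "STRIDE_NUM",
    "ML_SWAY", "V_SWAY",
    "ASA_ANGLE", "ASA_PATH", "ASA_AP_RANGE", "SI_ARMS",
)

ARM_SWING_PARAMS = (
    "SWAY_ANT_AP", "SWAY_ANT_ML", "SWAY_ANT_UD",
    "SWAY_POS_AP", "SWAY_POS_ML", "SWAY_POS_UD",
    "SWAY_RANGE_AP", "SWAY_RANGE_ML", "SWAY_RANGE_UD",
    "PATH_TOT", "SWAY_AREA", "SPEED_AP",
    "ANGLE_ANT", "ANGLE_POS", "ANGLE_RANGE",
    "ASA_ANGLE", "ASA_PATH", "ASA_AP_RANGE",
    "SI_ARM_LEG", "SI_ARMS",
)
SPATIOTEMPORAL_PARAMS = (
    "STEP_LEN", "STEP_WIDTH", "STEP_VEL", "STEP_TIME", "STRIDE_LEN",
    "DOUBLE_SUPP", "STANCE_DUR", "GAIT_VEL", "CADENCE",
    "STEP_NUM", "STRIDE_NUM",
)
COM_PARAMS = ("ML_SWAY", "V_SWAY")


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _check_identities(row: dict) -> None:
    """Structural identities every analyzed trial must satisfy."""
    for s in ("L", "R"):
        for d in ("AP", "ML", "UD"):
            rng = row[f"SWAY_RANGE_{d}_{s}"]
            assert math.isclose(
                rng, row[f"SWAY_ANT_{d}_{s}"] - row[f"SWAY_POS_{d}_{s}"]
            ), f"SWAY_RANGE_{d}_{s} identity violated"
        assert math.isclose(
            row[f"ANGLE_RANGE_{s}"],
            row[f"ANGLE_ANT_{s}"] - row[f"ANGLE_POS_{s}"],
        ), f"ANGLE_RANGE_{s} identity violated"
        assert row[f"PATH_TOT_{s}"] >= row[f"SWAY_RANGE_AP_{s}"] - 1e-9
    for key in ("ASA_ANGLE", "ASA_PATH", "ASA_AP_RANGE"):
        assert 0.0 <= row[key] <= 50.0, f"{key} outside [0, 50]"
    for key in ("SI_ARMS", "SI_ARM_LEG_L", "SI_ARM_LEG_R"):
        assert abs(row[key]) <= 1.0 + 1e-12, f"|{key}| > 1"


def analyze_trial(
    trial: "SkeletonSequence | str",
    gap_near: float = GAP_NEAR_M,
    gap_far: float = GAP_FAR_M,
    on_error: str = "raise",
) -> dict:
    """Run the full pipeline on one trial and return a flat parameter row.

    ``trial`` may be a file path or an in-memory sequence. Any stage
    failure is re-raised as :class:`PipelineStageError` naming the stage
    and trial; with ``on_error="flag"`` a stub row carrying the error
    description is returned instead.
    """
    stage = "read"
    trial_name = str(trial) if not isinstance(trial, SkeletonSequence) else (
        f"{trial.subject_id}/{trial.trial_id}"
    )
    try:
        seq = trial if isinstance(trial, SkeletonSequence) else read_trial(trial)
        trial_name = f"{seq.subject_id}/{seq.trial_id}"
        stage = "resample"
        rs = resample_50hz(seq)
        stage = "lowpass"
        rs = lowpass_8hz(rs)
        stage = "extract_gap"
        win = extract_gap(rs, gap_near, gap_far)
        stage = "detect_events"
        events = detect_events(win)
        stage = "spatiotemporal"
        spt = spatiotemporal(win, events)
        stage = "com_sway"
        com = com_sway(win)
        stage = "arm_swing"
        arms = {side: arm_swing_params(win, side) for side in ("left", "right")}
        asym = asymmetry_indices(arms["left"], arms["right"])
        sync = synchrony_indices(win)
    except (KinegaitError, ValueError) as e:
        err = PipelineStageError(stage, trial_name, e)
        if on_error == "flag":
            return {
                "subject_id": getattr(e, "subject_id", trial_name),
                "trial_id": "",
                "group": "",
                "error": f"{stage}: {e}",
            }
        raise err from e

    row: dict = {
        "subject_id": seq.subject_id,
        "trial_id": seq.trial_id,
        "group": seq.group,
        "error": "",
    }
    for side, s in (("left", "L"), ("right", "R")):
        sp = spt.side(side)
        row[f"STEP_LEN_{s}"] = sp.step_len_m
        row[f"STEP_WIDTH_{s}"] = sp.step_width_m
        row[f"STEP_VEL_{s}"] = sp.step_vel_mps
        row[f"STEP_TIME_{s}"] = sp.step_time_s
        row[f"STRIDE_LEN_{s}"] = sp.stride_len_m
        row[f"DOUBLE_SUPP_{s}"] = sp.double_supp_s
        row[f"STANCE_DUR_{s}"] = sp.stance_dur_pct
        lin = arms[side].linear
        ang = arms[side].angular
        for d in ("AP", "ML", "UD"):
            row[f"SWAY_ANT_{d}_{s}"] = getattr(lin, f"sway_ant_{d.lower()}_mm")
            row[f"SWAY_POS_{d}_{s}"] = getattr(lin, f"sway_pos_{d.lower()}_mm")
            row[f"SWAY_RANGE_{d}_{s}"] = getattr(
                lin, f"sway_range_{d.lower()}_mm"
            )
        row[f"PATH_TOT_{s}"] = lin.path_tot_mm
        row[f"SWAY_AREA_{s}"] = lin.sway_area_mm2
        row[f"SPEED_AP_{s}"] = lin.speed_ap_mms
        row[f"ANGLE_ANT_{s}"] = ang.angle_ant_deg
        row[f"ANGLE_POS_{s}"] = ang.angle_pos_deg
        row[f"ANGLE_RANGE_{s}"] = ang.angle_range_deg
    row["SI_ARM_LEG_L"] = sync.si_arm_leg_left
    row["SI_ARM_LEG_R"] = sync.si_arm_leg_right
    row["GAIT_VEL"] = spt.gait_vel_mps
    row["CADENCE"] = spt.cadence_spm
    row["STEP_NUM"] = spt.step_num
    row["STRIDE_NUM"] = spt.stride_num
    row["ML_SWAY"] = com.ml_sway_mm
    row["V_SWAY"] = com.v_sway_mm
    row["ASA_ANGLE"] = asym.asa_angle_pct
    row["ASA_PATH"] = asym.asa_path_pct
    row["ASA_AP_RANGE"] = asym.asa_ap_range_pct
    row["SI_ARMS"] = sync.si_arms
    # provenance
    row["gap_near_m"] = gap_near
    row["gap_far_m"] = gap_far
    row["resample_rate_hz"] = RESAMPLE_RATE_HZ
    row["filter_cutoff_hz"] = FILTER_CUTOFF_HZ
    row["filter_order"] = FILTER_ORDER
    row["software_version"] = __version__
    _check_identities(row)
    return row


def analyze_directory(
    trial_dir,
    gap_near: float = GAP_NEAR_M,
    gap_far: float = GAP_FAR_M,
    on_error: str = "flag",
) -> pd.DataFrame:
    """Analyze every ``*.json`` trial in a directory into a DataFrame."""
    from pathlib import Path

    paths = sorted(Path(trial_dir).glob("*.json"))
    rows = [
        analyze_trial(str(p), gap_near, gap_far, on_error=on_error)
        for p in paths
    ]
    return pd.DataFrame(rows)


def pool_observations(rows: pd.DataFrame, param: str) -> np.ndarray:
    """Observations for one parameter, pooling _L/_R when side-wise."""
    if param in SIDED_PARAMS:
        vals = np.concatenate(
            [rows[f"{param}_L"].to_numpy(), rows[f"{param}_R"].to_numpy()]
        )
    else:
        vals = rows[param].to_numpy()
    return vals[np.isfinite(vals.astype(float))]


@dataclass
class GroupComparison:
    """Per-parameter two-group comparison table."""

    table: pd.DataFrame
    label_a: str = "A"
    label_b: str = "B"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=True)

    def formatted(self) -> pd.DataFrame:
        """Classic report layout: ``median (Q1, Q3)`` per group, then the
        rank-sum statistic, p-value and significance stars."""
        out = pd.DataFrame(index=self.table.index)
        for label in (self.label_a, self.label_b):
            out[label] = self.table.apply(
                lambda r: (
                    f"{r[f'median_{label}']:.2f}"
                    f"({r[f'q1_{label}']:.2f}, {r[f'q3_{label}']:.2f})"
                    if pd.notna(r.get(f"median_{label}"))
                    else ""
                ),
                axis=1,
            )
        out["statistic"] = self.table.get("rank_sum_W")
        out["p"] = self.table.get("mw_p")
        out["stars"] = self.table.get("stars")
        return out


def compare_groups(
    rows_a: pd.DataFrame,
    rows_b: pd.DataFrame,
    label_a: str = "A",
    label_b: str = "B",
    params: "tuple[str, ...] | None" = None,
) -> GroupComparison:
    """Two-group comparison of every parameter.

    Per parameter: median and quartiles per group, Mann–Whitney rank-sum
    statistic W (the reported statistic; U = W − n1(n1+1)/2) with
    exact-or-asymptotic p (SciPy's policy: exact for small tie-free
    samples, normal approximation with tie correction otherwise),
    Student's t statistic and p, Shapiro–Wilk normality p per group, and
    significance stars (* < 0.05, ** < 0.01, *** < 0.001). No
    multiple-testing correction is applied (raw per-parameter p-values);
    parameters with all-identical pooled observations are reported with a
    note and NaN statistics.
    """
    if params is None:
        params = SIDED_PARAMS + OVERALL_PARAMS
    out = []
    for param in params:
        a = pool_observations(rows_a, param)
        b = pool_observations(rows_b, param)
        rec: dict = {"parameter": param, "note": ""}
        if len(a) < 3 or len(b) < 3:
            rec["note"] = "insufficient observations"
            out.append(rec)
            continue
        for label, x in ((label_a, a), (label_b, b)):
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            rec[f"median_{label}"] = med
            rec[f"q1_{label}"] = q1
            rec[f"q3_{label}"] = q3
            rec[f"n_{label}"] = len(x)
            rec[f"shapiro_p_{label}"] = (
                float(stats.shapiro(x).pvalue) if np.ptp(x) > 0 else math.nan
            )
        if np.ptp(np.concatenate([a, b])) == 0:
            rec["note"] = "all observations identical; tests skipped"
            rec["rank_sum_W"] = math.nan
            rec["mw_p"] = math.nan
            rec["t_stat"] = math.nan
            rec["t_p"] = math.nan
            rec["stars"] = ""
            out.append(rec)
            continue
        mw = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        n1 = len(a)
        rec["rank_sum_W"] = float(mw.statistic) + n1 * (n1 + 1) / 2.0
        rec["mw_U"] = float(mw.statistic)
        rec["mw_p"] = float(mw.pvalue)
        tt = stats.ttest_ind(a, b)
        rec["t_stat"] = float(tt.statistic)
        rec["t_p"] = float(tt.pvalue)
        rec["stars"] = significance_stars(rec["mw_p"])
        out.append(rec)
    return GroupComparison(
        table=pd.DataFrame(out).set_index("parameter"),
        label_a=label_a,
        label_b=label_b,
    )


@dataclass
class CorrelationMatrix:
    """Arm-swing × (spatiotemporal ∪ COM) correlation matrices."""

    r: pd.DataFrame  # coefficients
    p: pd.DataFrame  # p-values (NaN where undefined)
    tier: pd.DataFrame  # "", "*", "**", "***" per cell
    method: str

    def to_csv(self, path) -> None:
        self.r.to_csv(path)


def correlation_matrix(
    rows: pd.DataFrame,
    method: str = "spearman",
    row_params: "tuple[str, ...]" = ARM_SWING_PARAMS,
    col_params: "tuple[str, ...]" = SPATIOTEMPORAL_PARAMS + COM_PARAMS,
) -> CorrelationMatrix:
    """Correlation of arm-swing parameters against gait/COM parameters.

    Side-wise parameters are pooled (left and right observations
    concatenated in the same order on both axes, so per-side pairs stay
    aligned). Cells with a constant column are NaN (undefined).
    """
    if len(rows) < 5:
        raise ValueError("correlation needs >= 5 trials")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")

    def obs(param: str) -> np.ndarray:
        if param in SIDED_PARAMS:
            return np.concatenate(
                [
                    rows[f"{param}_L"].to_numpy(dtype=float),
                    rows[f"{param}_R"].to_numpy(dtype=float),
                ]
            )
        # whole-gait parameters repeat for both side observations
        v = rows[param].to_numpy(dtype=float)
        return np.concatenate([v, v])

    r = pd.DataFrame(index=row_params, columns=col_params, dtype=float)
    p = pd.DataFrame(index=row_params, columns=col_params, dtype=float)
    for rp in row_params:
        x = obs(rp)
        for cp in col_params:
            y = obs(cp)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 5 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue  # undefined cell stays NaN
            if method == "spearman":
                res = stats.spearmanr(x[ok], y[ok])
                r.loc[rp, cp], p.loc[rp, cp] = res.statistic, res.pvalue
            else:
                res = stats.pearsonr(x[ok], y[ok])
                r.loc[rp, cp], p.loc[rp, cp] = res.statistic, res.pvalue
    tier = p.map(lambda v: significance_stars(v) if pd.notna(v) else "")
    return CorrelationMatrix(r=r, p=p, tier=tier, method=method)
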