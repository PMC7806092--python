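"""Evaluation metrics, cycle-level detection and the sensitivity harness.

Reporting follows robust-statistics practice for motion-tracking studies:
medians with 5th/95th percentiles, both time-based (over all samples) and
cycle-based (over per-cycle means/medians), separately per method.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import RunConfig
from .detect import MotionCycle, UnclassifiableCycleError, classify_cycle
from .heading import GeometryConfig
from .quat import heading_angle, quat_conj, quat_multiply, wrap_angle

__all__ = [
    "time_metrics",
    "cycle_shoulder_errors",
    "true_heading_offset",
    "heading_errors_deg",
    "detect_cycles",
    "confusion_table",
    "sensitivity_sweep",
]


def _percentiles(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return {"median": np.nan, "p5": np.nan, "p95": np.nan, "n": 0}
    return {
        "median": float(np.median(x)),
        "p5": float(np.percentile(x, 5)),
        "p95": float(np.percentile(x, 95)),
        "n": int(x.size),
    }


def time_metrics(
    pose: pd.DataFrame,
    truth,
    planar: bool = False,
    t_min: float | None = None,
) -> pd.DataFrame:
    """Time-based error statistics per method against the ground truth.

    Shoulder error is the Euclidean distance between estimated and true
    shoulder positions (restricted to the horizontal plane with
    ``planar=True``); the elbow error is the absolute angle difference in
    degrees.  Only valid samples at or after ``t_min`` enter.
    """
    rows = []
    for method, grp in pose.groupby("method"):
        grp = grp[grp["valid"].astype(bool)]
        if t_min is not None:
            grp = grp[grp["t"] >= t_min - 1e-9]
        idx = np.searchsorted(truth.t, grp["t"].to_numpy())
        idx = np.clip(idx, 0, len(truth.t) - 1)
        d = grp[["psx", "psy", "psz"]].to_numpy() - truth.p_s[idx]
        if planar:
            d = d[:, :2]
        sh_err = np.linalg.norm(d, axis=-1)
        el_err = np.abs(grp["elbow_deg"].to_numpy() - truth.elbow_angle_deg[idx])
        for quantity, err in (("shoulder_m", sh_err), ("elbow_deg", el_err)):
            rows.append({"method": method, "quantity": quantity, **_percentiles(err)})
    return pd.DataFrame(rows)


def cycle_shoulder_errors(
    pose: pd.DataFrame,
    truth,
    boundaries: np.ndarray,
    method: str = "hybrid",
    t_min: float | None = None,
    planar: bool = False,
) -> pd.DataFrame:
    """Mean shoulder tracking error per completed motion cycle.

    Cycles containing invalid samples or starting before ``t_min`` are
    dropped (they have no defined estimate yet).  Returns one row per kept
    cycle with its mean and median error in meters.
    """
    grp = pose[pose["method"] == method]
    t = grp["t"].to_numpy()
    est = grp[["psx", "psy", "psz"]].to_numpy()
    valid = grp["valid"].to_numpy().astype(bool)
    idx = np.clip(np.searchsorted(truth.t, t), 0, len(truth.t) - 1)
    d = est - truth.p_s[idx]
    if planar:
        d = d[:, :2]
    err = np.linalg.norm(d, axis=-1)
    rows = []
    boundaries = np.asarray(boundaries, dtype=float)
    for i, (t0, t1) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        if t_min is not None and t0 < t_min - 1e-9:
            continue
        sel = (t >= t0 - 1e-9) & (t < t1 - 1e-9)
        if not np.any(sel) or not np.all(valid[sel]):
            continue
        rows.append(
            {
                "cycle": i,
                "t_start": t0,
                "t_end": t1,
                "mean_err_m": float(np.mean(err[sel])),
                "median_err_m": float(np.median(err[sel])),
            }
        )
    return pd.DataFrame(rows, columns=["cycle", "t_start", "t_end", "mean_err_m", "median_err_m"])


def true_heading_offset(q_ra_true: np.ndarray, q_ia_est: np.ndarray) -> np.ndarray:
    """Reference heading offset δ(t) implied by the truth and the filter.

    δ is defined as the heading of ``q_RA_true ⊗ q_IA_est*`` — the rotation
    that maps the filter's inertial frame onto the robot frame.  It depends
    on the filter's (arbitrary, drifting) reference frame, which is why it
    is computed at evaluation time rather than generated.
    """
    rel = quat_multiply(np.asarray(q_ra_true, dtype=float), quat_conj(q_ia_est))
    return np.mod(heading_angle(rel), 2.0 * np.pi)


def heading_errors_deg(heading_log: pd.DataFrame, delta_true: np.ndarray,
                       t_truth: np.ndarray) -> pd.DataFrame:
    """Wrapped heading-estimate errors (deg) at each defined update time."""
    rows = []
    for _, r in heading_log.dropna(subset=["delta_hat_deg"]).iterrows():
        i = int(np.clip(np.searchsorted(t_truth, r["t"]), 0, len(t_truth) - 1))
        err = np.rad2deg(
            abs(wrap_angle(np.deg2rad(r["delta_hat_deg"]) - delta_true[i]))
        )
        rows.append({"t": r["t"], "abs_err_deg": err, "converged": bool(r["converged"])})
    return pd.DataFrame(rows, columns=["t", "abs_err_deg", "converged"])


def detect_cycles(
    pose: pd.DataFrame,
    boundaries: np.ndarray,
    p_s_nom: np.ndarray,
    cfg: RunConfig | None = None,
    method: str = "hybrid",
) -> pd.DataFrame:
    """Classify every completed cycle from estimated shoulder positions.

    Cycles whose poses are not all valid (heading not yet estimated) are
    labelled ``unclassifiable`` rather than guessed.
    """
    cfg = cfg or RunConfig()
    grp = pose[pose["method"] == method]
    t = grp["t"].to_numpy()
    p_s = grp[["psx", "psy", "psz"]].to_numpy()
    valid = grp["valid"].to_numpy().astype(bool)
    if "converged" in grp.columns:
        # a defined but unconverged heading estimate is still provisional:
        # cycles touched by it are reported, not classified
        valid = valid & grp["converged"].to_numpy().astype(bool)
    rows = []
    boundaries = np.asarray(boundaries, dtype=float)
    for i, (t0, t1) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
        if not np.any(sel):
            rows.append({"cycle": i, "t_start": t0, "t_end": t1,
                         "fraction_out": np.nan, "label": "unclassifiable"})
            continue
        cyc = MotionCycle(
            t_start=t0, t_end=t1, t=t[sel], p_s=p_s[sel],
            p_s_nom=np.asarray(p_s_nom, dtype=float), valid=valid[sel],
        )
        try:
            res = classify_cycle(
                cyc,
                threshold_m=cfg.detector_threshold_m,
                fraction_limit=cfg.detector_fraction,
                planar=cfg.planar_detection,
            )
            rows.append({"cycle": i, "t_start": t0, "t_end": t1,
                         "fraction_out": res.out_of_range_fraction, "label": res.label})
        except UnclassifiableCycleError:
            rows.append({"cycle": i, "t_start": t0, "t_end": t1,
                         "fraction_out": np.nan, "label": "unclassifiable"})
    return pd.DataFrame(rows, columns=["cycle", "t_start", "t_end", "fraction_out", "label"])


def confusion_table(predicted: list[str], actual: list[str]) -> pd.DataFrame:
    """2×2 confusion table (plus an unclassifiable row when present)."""
    labels_pred = sorted(set(predicted) | {"proper", "compensatory"})
    labels_act = sorted(set(actual) | {"proper", "compensatory"})
    table = pd.DataFrame(0, index=labels_act, columns=labels_pred)
    for p, a in zip(predicted, actual):
        table.loc[a, p] += 1
    table.index.name = "actual"
    table.columns.name = "predicted"
    return table


def sensitivity_sweep(
    trial,
    cfg: RunConfig | None = None,
    imu_offset_shifts_m: tuple[float, ...] = (-0.075, 0.075),
    l_a_shifts_m: tuple[float, ...] = (-0.025, 0.025),
    gyro_cutoff_shifts_hz: tuple[float, ...] = (-1.0, 1.0),
    t_min: float | None = None,
) -> pd.DataFrame:
    """Perturb assumed parameters and report metric changes vs. baseline.

    Emulates a mismatch between assumed and actual values of the
    IMU-to-joint distance (±7.5 cm along the segment), the segment length
    (±2.5 cm) and the gyro-filter cutoff (±1 Hz): the *measurements* stay
    fixed, only the tracker's assumptions change.
    """
    from .pipeline import track_trial

    cfg = cfg or RunConfig()

    def run(run_cfg: RunConfig, geom_kw: dict) -> pd.DataFrame:
        trial_cfg = trial.config
        base_geom = GeometryConfig(
            p_imu_to_joint=np.asarray(trial_cfg.p_imu_to_joint, dtype=float),
            l_a=trial_cfg.l_a,
            l_p=trial_cfg.l_p,
        )
        geom = replace(base_geom, **geom_kw) if geom_kw else base_geom
        from .pipeline import track_streams

        res = track_streams(
            trial.imu.t, trial.imu.gyro, trial.imu.acc,
            trial.robot.t, trial.robot.p_e, geom, trial.p_s_nom,
            cfg=run_cfg, p_w_cuff=trial.robot.p_w, p_p_cuff=trial.robot.p_p,
            method="hybrid",
        )
        tm = t_min if t_min is not None else res.converged_t
        return time_metrics(res.pose, trial.truth, t_min=tm)

    baseline = run(cfg, {})
    rows = []

    def record(name: str, value: float, metrics: pd.DataFrame) -> None:
        for _, r in metrics.iterrows():
            base = baseline[
                (baseline["method"] == r["method"])
                & (baseline["quantity"] == r["quantity"])
            ]["median"].iloc[0]
            rows.append(
                {
                    "parameter": name,
                    "shift": value,
                    "quantity": r["quantity"],
                    "median": r["median"],
                    "baseline_median": base,
                    "delta_median": r["median"] - base,
                }
            )

    record("baseline", 0.0, baseline)
    ape = np.asarray(trial.config.p_imu_to_joint, dtype=float)
    for s in imu_offset_shifts_m:
        shifted = ape + np.array([s, 0.0, 0.0])
        record("p_imu_to_joint_x", s, run(cfg, {"p_imu_to_joint": shifted}))
    for s in l_a_shifts_m:
        record("l_a", s, run(cfg, {"l_a": trial.config.l_a + s}))
    for s in gyro_cutoff_shifts_hz:
        record("lp_cutoff_gyro", s,
               run(replace(cfg, lp_cutoff_gyro=cfg.lp_cutoff_gyro + s), {}))
    return pd.DataFrame(rows)
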