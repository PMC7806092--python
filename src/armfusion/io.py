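"""CSV stream formats.

All streams are plain CSV with a header row and leading ``#`` comment lines
carrying units and provenance.  Timestamps are seconds and monotone
increasing; all quantities are SI (m, rad/s, m/s²).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import ImuStream, RobotStream, Truth

__all__ = [
    "write_csv",
    "read_csv",
    "imu_to_frame",
    "imu_from_frame",
    "robot_to_frame",
    "robot_from_frame",
    "truth_to_frame",
    "truth_from_frame",
]

IMU_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az"]
ROBOT_COLUMNS = ["t", "pex", "pey", "pez",
                 "pwx", "pwy", "pwz", "ppx", "ppy", "ppz"]


def write_csv(path, frame: pd.DataFrame, comments: list[str] | None = None) -> None:
    """Write a stream CSV with ``#``-prefixed unit/provenance comments."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path, allow_missing: bool = False) -> pd.DataFrame:
    """Read a stream CSV, skipping comment lines; validates the time base.

    Measurement streams must be gap-free; pose files may carry NaN cells
    (poses before the first heading estimate, quaternions of the
    fixed-shoulder baseline), read with ``allow_missing=True``.
    """
    frame = pd.read_csv(path, comment="#")
    if "t" not in frame.columns:
        raise ValueError(f"{path}: missing required column 't'")
    if not allow_missing and frame.isna().any().any():
        raise ValueError(f"{path}: stream contains missing cells")
    groups = frame.groupby("method") if "method" in frame.columns else [(None, frame)]
    for _, grp in groups:
        if np.any(np.diff(grp["t"].to_numpy()) <= 0):
            raise ValueError(f"{path}: timestamps not strictly increasing")
    return frame


def imu_to_frame(imu: ImuStream) -> pd.DataFrame:
    return pd.DataFrame(
        np.column_stack([imu.t, imu.gyro, imu.acc]), columns=IMU_COLUMNS
    )


def imu_from_frame(frame: pd.DataFrame) -> ImuStream:
    missing = set(IMU_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"IMU stream missing columns: {sorted(missing)}")
    return ImuStream(
        t=frame["t"].to_numpy(),
        gyro=frame[["gx", "gy", "gz"]].to_numpy(),
        acc=frame[["ax", "ay", "az"]].to_numpy(),
    )


def robot_to_frame(robot: RobotStream) -> pd.DataFrame:
    cols = {"t": robot.t,
            "pex": robot.p_e[:, 0], "pey": robot.p_e[:, 1], "pez": robot.p_e[:, 2]}
    if robot.p_w is not None:
        cols.update({"pwx": robot.p_w[:, 0], "pwy": robot.p_w[:, 1], "pwz": robot.p_w[:, 2]})
    if robot.p_p is not None:
        cols.update({"ppx": robot.p_p[:, 0], "ppy": robot.p_p[:, 1], "ppz": robot.p_p[:, 2]})
    return pd.DataFrame(cols)


def robot_from_frame(frame: pd.DataFrame) -> RobotStream:
    has_cuffs = {"pwx", "ppx"}.issubset(frame.columns)
    has_elbow = "pex" in frame.columns
    if not has_elbow and not has_cuffs:
        raise ValueError("robot stream needs elbow columns (pex..) or cuff columns (pwx.., ppx..)")
    return RobotStream(
        t=frame["t"].to_numpy(),
        p_e=frame[["pex", "pey", "pez"]].to_numpy() if has_elbow else None,
        p_w=frame[["pwx", "pwy", "pwz"]].to_numpy() if has_cuffs else None,
        p_p=frame[["ppx", "ppy", "ppz"]].to_numpy() if has_cuffs else None,
    )


def truth_to_frame(truth: Truth) -> pd.DataFrame:
    return pd.DataFrame(
        np.column_stack(
            [truth.t, truth.p_s, truth.p_e, truth.p_w, truth.q_ra,
             truth.x_c, truth.elbow_angle_deg]
        ),
        columns=[
            "t", "psx", "psy", "psz", "pex", "pey", "pez",
            "pwx", "pwy", "pwz", "qw", "qx", "qy", "qz",
            "xcx", "xcy", "xcz", "elbow_deg",
        ],
    )


def truth_from_frame(frame: pd.DataFrame) -> Truth:
    return Truth(
        t=frame["t"].to_numpy(),
        p_s=frame[["psx", "psy", "psz"]].to_numpy(),
        p_e=frame[["pex", "pey", "pez"]].to_numpy(),
        p_w=frame[["pwx", "pwy", "pwz"]].to_numpy(),
        q_ra=frame[["qw", "qx", "qy", "qz"]].to_numpy(),
        x_c=frame[["xcx", "xcy", "xcz"]].to_numpy(),
        elbow_angle_deg=frame["elbow_deg"].to_numpy(),
    )
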