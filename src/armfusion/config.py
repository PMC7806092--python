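"""Tracker configuration: every method constant with its published default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """All tunable constants of the tracking and detection method.

    Defaults are the method's reference parametrization: heading updates
    every 5 s over a 20 s window split into five 4 s sub-windows, a 10 cm
    motion sphere with a 3-of-5 gate, a 5° coarse grid with ±5°/1°
    refinement, convergence after five consecutive estimates within 5°,
    causal 5th-order Butterworth low-passes at 0.5 Hz (accelerations) and
    2.5 Hz (gyro, before differentiation), and the ±10 cm / 20% detection
    rule.
    """

    update_period: float = 5.0        # s between heading updates
    window: float = 20.0              # s of data per update
    n_subwindows: int = 5             # motion-gate sub-windows
    motion_sphere: float = 0.10       # m, sphere diameter of "no motion"
    min_moving_subwindows: int = 3    # gate opens at this many moving sub-windows
    coarse_step_deg: float = 5.0      # coarse heading grid spacing
    refine_halfwidth_deg: float = 5.0 # refinement half-width
    refine_step_deg: float = 1.0      # refinement spacing (sets the accuracy floor)
    convergence_len: int = 5          # estimates in the convergence streak
    convergence_tol_deg: float = 5.0  # max change between consecutive estimates
    lp_cutoff_accel: float = 0.5      # Hz, shared disagreement low-pass
    lp_cutoff_gyro: float = 2.5       # Hz, low-pass before gyro differentiation
    butterworth_order: int = 5
    gravity: float = 9.81             # m/s²
    orientation_gain: float = 0.2     # 1/s, inclination-correction gain
    detector_threshold_m: float = 0.10
    detector_fraction: float = 0.20
    planar_detection: bool = False    # restrict displacement to the horizontal plane

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v <= 0:
                if f.name not in ("planar_detection",):
                    raise ValueError(f"RunConfig.{f.name} must be positive, got {v}")
        if self.window < self.n_subwindows * 1e-3:
            raise ValueError("window too short for the requested sub-windows")


def load_config(path: str) -> dict:
    """Load a ``key: value`` (YAML) config file into a dict of sections.

    Recognized sections: ``trial`` (simulator conditions, see
    :class:`armfusion.simulate.TrialConfig`) and ``tracker``
    (:class:`RunConfig`).  Unknown keys raise, catching typos early.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    from .simulate import TrialConfig

    out: dict = {}
    trial_keys = {f.name for f in fields(TrialConfig)}
    tracker_keys = {f.name for f in fields(RunConfig)}
    trial_raw = dict(raw.get("trial", {}))
    tracker_raw = dict(raw.get("tracker", {}))
    for name, d, allowed in (("trial", trial_raw, trial_keys),
                             ("tracker", tracker_raw, tracker_keys)):
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown keys in [{name}] section: {sorted(unknown)}")
    # lists from YAML become tuples where the dataclasses expect them
    for key in ("rect_center", "p_imu_to_joint", "p_s_nom", "gyro_bias_deg_s"):
        if key in trial_raw and isinstance(trial_raw[key], list):
            trial_raw[key] = tuple(trial_raw[key])
    out["trial"] = TrialConfig(**trial_raw)
    out["tracker"] = RunConfig(**tracker_raw)
    return out


def save_config(path: str, trial=None, tracker: RunConfig | None = None) -> None:
    """Write a config file with the given (or default) sections."""
    from .simulate import TrialConfig

    doc = {
        "trial": asdict(trial if trial is not None else TrialConfig()),
        "tracker": asdict(tracker if tracker is not None else RunConfig()),
    }
    # tuples serialize more readably as lists
    for k, v in doc["trial"].items():
        if isinstance(v, tuple):
            doc["trial"][k] = list(v)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
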