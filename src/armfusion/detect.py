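"""Rule-based detection of compensatory shoulder motion and biofeedback.

In upper-limb rehabilitation, patients often substitute trunk or
shoulder-girdle motion for impaired shoulder/elbow joint motion.  Healthy
("proper") executions of a cyclic reaching task show shoulder displacements
around 4 cm, while compensatory executions reach around 14 cm.  A completed
motion cycle is classified as *compensatory* when the estimated shoulder
leaves a radial tolerance of 0.10 m around the nominal (therapeutically
desired) shoulder position for more than 20% of the cycle duration; brief
excursions up to 20% are tolerated.

A three-state per-sample biofeedback signal accompanies the per-cycle rule:
green while the shoulder is inside the tolerance, blue immediately after
leaving it, and orange when it stays outside longer than a maximum tolerated
duration (by default a fraction of the cycle duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotionCycle",
    "DetectionResult",
    "UnclassifiableCycleError",
    "shoulder_displacement",
    "classify_cycle",
    "biofeedback_state",
    "biofeedback_stream",
]

#: Radial shoulder-displacement tolerance in meters ("±10 cm").
DEFAULT_THRESHOLD_M = 0.10
#: Tolerated fraction of a cycle spent outside the tolerance ("up to 20%").
DEFAULT_FRACTION_LIMIT = 0.20


class UnclassifiableCycleError(ValueError):
    """Raised when a cycle contains invalid poses (heading not yet estimated)."""


@dataclass
class MotionCycle:
    """One completed iteration of the rehabilitation motion.

    ``t`` and ``p_s`` are the time stamps (s) and estimated shoulder
    positions (m) of the samples within [t_start, t_end]; ``valid`` flags
    per-sample pose availability (all True when omitted).
    """

    t_start: float
    t_end: float
    t: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_s: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    p_s_nom: np.ndarray = field(default_factory=lambda: np.zeros(3))
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p_s = np.asarray(self.p_s, dtype=float)
        self.p_s_nom = np.asarray(self.p_s_nom, dtype=float)
        if self.t_end <= self.t_start:
            raise ValueError("cycle must have t_end > t_start")
        if self.t.size == 0:
            raise ValueError("cycle contains no samples")
        if self.t.min() < self.t_start - 1e-9 or self.t.max() > self.t_end + 1e-9:
            raise ValueError("cycle samples outside [t_start, t_end]")


@dataclass
class DetectionResult:
    """Outcome of the per-cycle classification rule."""

    label: str  # "proper" | "compensatory"
    out_of_range_fraction: float
    threshold_m: float
    fraction_limit: float


def shoulder_displacement(
    p_s: np.ndarray, p_s_nom: np.ndarray, planar: bool = False
) -> np.ndarray:
    """Euclidean distance of the shoulder from its nominal position, meters.

    ``planar=True`` restricts the distance to the horizontal (x, y) plane,
    matching a camera-from-above reference measurement.
    """
    d = np.asarray(p_s, dtype=float) - np.asarray(p_s_nom, dtype=float)
    if planar:
        d = d[..., :2]
    return np.linalg.norm(d, axis=-1)


def classify_cycle(
    cycle: MotionCycle,
    threshold_m: float = DEFAULT_THRESHOLD_M,
    fraction_limit: float = DEFAULT_FRACTION_LIMIT,
    planar: bool = False,
) -> DetectionResult:
    """Classify one completed cycle as proper or compensatory.

    The out-of-range fraction is the *time-weighted* share of the cycle the
    shoulder displacement exceeds ``threshold_m``; the cycle is compensatory
    iff that fraction is strictly greater than ``fraction_limit``
    (excursions for *up to* the limit are tolerated).  Cycles containing
    invalid poses raise :class:`UnclassifiableCycleError` rather than
    guessing a label.
    """
    if cycle.valid is not None and not np.all(cycle.valid):
        raise UnclassifiableCycleError(
            f"cycle [{cycle.t_start:.1f}, {cycle.t_end:.1f}] s contains poses "
            "with undefined heading"
        )
    disp = shoulder_displacement(cycle.p_s, cycle.p_s_nom, planar=planar)
    over = disp > threshold_m
    if cycle.t.size == 1:
        fraction = float(over[0])
    else:
        weights = np.gradient(cycle.t)  # per-sample time weights
        fraction = float(np.sum(weights[over]) / np.sum(weights))
    label = "compensatory" if fraction > fraction_limit + 1e-12 else "proper"
    return DetectionResult(
        label=label,
        out_of_range_fraction=fraction,
        threshold_m=float(threshold_m),
        fraction_limit=float(fraction_limit),
    )


def biofeedback_state(
    displacement: float,
    over_limit_duration: float,
    max_tolerated: float,
    threshold_m: float = DEFAULT_THRESHOLD_M,
) -> str:
    """Three-state visual biofeedback signal.

    ``green`` while the shoulder displacement is within the tolerance,
    ``blue`` right after leaving it, and ``orange`` once it has been outside
    for longer than ``max_tolerated`` seconds.
    """
    if displacement <= threshold_m:
        return "green"
    if over_limit_duration <= max_tolerated:
        return "blue"
    return "orange"


def biofeedback_stream(
    t: np.ndarray,
    displacement: np.ndarray,
    max_tolerated: float,
    threshold_m: float = DEFAULT_THRESHOLD_M,
) -> list[str]:
    """Per-sample biofeedback states for a displacement time series.

    The over-limit stopwatch starts when the displacement first exceeds the
    tolerance and resets as soon as it returns inside.
    """
    t = np.asarray(t, dtype=float)
    displacement = np.asarray(displacement, dtype=float)
    states: list[str] = []
    t_exceeded: float | None = None
    for ti, di in zip(t, displacement):
        if di <= threshold_m:
            t_exceeded = None
        elif t_exceeded is None:
            t_exceeded = ti
        over = 0.0 if t_exceeded is None else ti - t_exceeded
        states.append(biofeedback_state(di, over, max_tolerated, threshold_m))
    return states
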