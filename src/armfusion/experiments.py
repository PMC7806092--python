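"""Reference evaluation experiments on synthetic trials.

The classification experiment reproduces, at desk scale on simulation, the
study design of the validation: one long trial of proper cyclic reaching
(shoulder-displacement amplitude 4 cm, 4.6 s cycles) and one of compensatory
reaching (14 cm, 5.4 s cycles), both with a 0.34 deg/s gyroscope bias and
the default sensor-noise model.  The full hybrid pipeline runs end to end on
each trial; completed cycles after heading convergence are classified by the
±10 cm / 20% rule and compared with the generator's ground-truth labels, and
the shoulder tracking error is summarized per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import RunConfig
from .metrics import cycle_shoulder_errors, detect_cycles
from .pipeline import track_trial
from .simulate import TrialConfig, simulate_trial

__all__ = ["ClassificationResult", "classification_experiment"]

#: Cycles to budget for heading convergence (first estimate needs 20 s of
#: data; convergence needs five gated updates) plus safety margin.
_WARMUP_CYCLES = 12


@dataclass
class ClassificationResult:
    """Outcome of the two-trial classification experiment."""

    accuracy_pct: float
    n_cycles: int
    n_correct: int
    cycle_errors_m: pd.DataFrame  # per post-convergence cycle: mean shoulder error
    median_cycle_error_cm: float
    detections: pd.DataFrame      # per-cycle labels, both trials
    converged_t: dict             # per trial type


def _one_trial(label: str, cfg: TrialConfig, run_cfg: RunConfig, n_keep: int):
    trial = simulate_trial(cfg)
    res = track_trial(trial, cfg=run_cfg, method="hybrid")
    det = detect_cycles(res.pose, trial.cycle_boundaries, trial.p_s_nom, cfg=run_cfg)
    det["actual"] = trial.true_cycle_labels(
        run_cfg.detector_threshold_m, run_cfg.detector_fraction
    )
    det["trial"] = label
    if res.converged_t is None:
        raise RuntimeError(f"heading never converged in the {label} trial")
    keep = det[
        (det["t_start"] >= res.converged_t - 1e-9) & (det["label"] != "unclassifiable")
    ].head(n_keep)
    errs = cycle_shoulder_errors(
        res.pose, trial.truth, trial.cycle_boundaries, t_min=res.converged_t
    )
    errs = errs[errs["cycle"].isin(keep["cycle"])].assign(trial=label)
    return keep, errs, res.converged_t


def classification_experiment(
    seed: int = 0,
    n_per_class: int = 40,
    run_cfg: RunConfig | None = None,
) -> ClassificationResult:
    """Run the end-to-end detection experiment on two simulated trials.

    Uses ``n_per_class`` post-convergence cycles of each movement type
    (≥ 80 cycles total by default).  Returns the classification accuracy in
    percent and the median over cycles of the mean per-cycle shoulder
    tracking error in centimeters.
    """
    run_cfg = run_cfg or RunConfig()
    cfg_p = TrialConfig.proper(
        duration=(n_per_class + _WARMUP_CYCLES) * 4.6, seed=int(seed) % 2**31
    )
    cfg_c = TrialConfig.compensatory(
        duration=(n_per_class + _WARMUP_CYCLES) * 5.4,
        seed=(int(seed) + 1000003) % 2**31,
    )
    keep_p, errs_p, conv_p = _one_trial("proper", cfg_p, run_cfg, n_per_class)
    keep_c, errs_c, conv_c = _one_trial("compensatory", cfg_c, run_cfg, n_per_class)
    det = pd.concat([keep_p, keep_c], ignore_index=True)
    errs = pd.concat([errs_p, errs_c], ignore_index=True)
    n_correct = int((det["label"] == det["actual"]).sum())
    n_cycles = int(len(det))
    return ClassificationResult(
        accuracy_pct=100.0 * n_correct / n_cycles,
        n_cycles=n_cycles,
        n_correct=n_correct,
        cycle_errors_m=errs,
        median_cycle_error_cm=100.0 * float(errs["mean_err_m"].median()),
        detections=det,
        converged_t={"proper": conv_p, "compensatory": conv_c},
    )
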