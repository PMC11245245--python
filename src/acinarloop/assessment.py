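"""Qualitative endpoints derived from simulated trajectories.

The injury mechanism modeled here is hyperstimulation: when synthesis
outstrips the Golgi packaging capacity ``S_max``, unpackaged enzyme
accumulates, osmotic balance is disturbed and pancreatitis follows.  The
classification is therefore operationalized as *sustained* packaging
overflow; the duration threshold, rest tolerance and serum-proxy gain
are explicit and configurable, and every result reports the raw
quantities alongside the call.

The serum-marker proxy stands in for circulating amylase/lipase: the
basolateral leak ``F*S`` gives a small non-zero baseline under normal
stimulation, and packaging overflow adds a sharp elevation during
hyperstimulation.  It is an appearance-rate proxy — no clearance
kinetics are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ConfigurationError, Trajectory, detect_rest_state

__all__ = [
    "AssessmentThresholds",
    "AssessmentResult",
    "OverflowSummary",
    "TrajectorySummary",
    "packaging_overflow",
    "classify_pancreatitis",
    "serum_marker_proxy",
    "summarize",
    "CLASSIFICATIONS",
]

CLASSIFICATIONS = ("none", "hyperstimulation")


@dataclass(frozen=True)
class AssessmentThresholds:
    """Explicit cutoffs behind every pancreatitis call.

    overflow_duration_min
        Minutes of sustained positive packaging overflow required for a
        "hyperstimulation" classification.
    rest_tol
        Relative threshold used for rest-state detection.
    serum_gain
        Proportionality constant mapping interstitial enzyme appearance
        to the serum proxy.
    """

    overflow_duration_min: float = 30.0
    rest_tol: float = 1e-6
    serum_gain: float = 1.0

    def __post_init__(self) -> None:
        if not self.overflow_duration_min > 0:
            raise ConfigurationError("overflow_duration_min must be > 0")
        if not 0 < self.rest_tol < 1:
            raise ConfigurationError("rest_tol must lie in (0, 1)")
        if not self.serum_gain > 0:
            raise ConfigurationError("serum_gain must be > 0")


@dataclass(frozen=True)
class OverflowSummary:
    series: np.ndarray
    peak: float
    duration: float


@dataclass
class AssessmentResult:
    classification: str
    peak_overflow_rate: float
    overflow_duration: float
    peak_N_fraction: float
    rest_time: float | None
    serum_proxy_baseline: float
    serum_proxy_peak: float
    thresholds: AssessmentThresholds = AssessmentThresholds()

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "peak_overflow_rate": self.peak_overflow_rate,
            "overflow_duration": self.overflow_duration,
            "peak_N_fraction": self.peak_N_fraction,
            "rest_time": self.rest_time,
            "serum_proxy_baseline": self.serum_proxy_baseline,
            "serum_proxy_peak": self.serum_proxy_peak,
            "thresholds": {
                "overflow_duration_min": self.thresholds.overflow_duration_min,
                "rest_tol": self.thresholds.rest_tol,
                "serum_gain": self.thresholds.serum_gain,
            },
        }


@dataclass(frozen=True)
class TrajectorySummary:
    peak_N_fraction: float
    total_duct_enzyme: float
    t_peak_S: float
    rest_time: float | None


def packaging_overflow(traj: Trajectory, S_max: float | None = None) -> OverflowSummary:
    """Golgi packaging overflow: overflow(t) = max(S(t) - S_max, 0).

    Duration is measured on the output grid as the total length of
    intervals whose left endpoint has positive overflow.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if S_max is None:
        S_max = traj.params.S_max
    if not S_max > 0:
        raise ConfigurationError("S_max must be > 0")
    series = np.maximum(traj.S - S_max, 0.0)
    t = traj.t
    if len(t) > 1:
        dt = np.diff(t)
        duration = float(dt[series[:-1] > 0].sum())
    else:
        duration = 0.0
    return OverflowSummary(series=series, peak=float(series.max()), duration=duration)


def serum_marker_proxy(
    traj: Trajectory,
    thresholds: AssessmentThresholds = AssessmentThresholds(),
) -> np.ndarray:
    """Serum amylase/lipase appearance proxy.

    proxy(t) = serum_gain * (F*S(t) + overflow(t)): the physiological
    basolateral leak plus any packaging overflow.  Strictly positive
    whenever synthesis is active, sharply elevated under overflow.
    """
    overflow = packaging_overflow(traj).series
    leak = traj.params.F * traj.S
    return thresholds.serum_gain * (leak + overflow)


def classify_pancreatitis(
    traj: Trajectory,
    thresholds: AssessmentThresholds = AssessmentThresholds(),
    S_max: float | None = None,
) -> AssessmentResult:
    """Classify a trajectory as "none" or "hyperstimulation".

    The call is "hyperstimulation" iff positive packaging overflow is
    sustained for at least ``thresholds.overflow_duration_min`` minutes.
    """
    ovf = packaging_overflow(traj, S_max)
    proxy = serum_marker_proxy(traj, thresholds)
    classification = (
        "hyperstimulation" if ovf.duration >= thresholds.overflow_duration_min else "none"
    )
    # baseline: last proxy value before the first intervention, or the
    # terminal value in an unperturbed run
    t = traj.t
    if traj.interventions:
        t_first = min(iv.time for iv in traj.interventions)
        pre = proxy[t < t_first]
        baseline = float(pre[-1]) if len(pre) else 0.0
    else:
        baseline = float(proxy[-1])
    return AssessmentResult(
        classification=classification,
        peak_overflow_rate=ovf.peak,
        overflow_duration=ovf.duration,
        peak_N_fraction=float(traj.N.max() / traj.params.N_max),
        rest_time=detect_rest_state(traj, tol=thresholds.rest_tol),
        serum_proxy_baseline=baseline,
        serum_proxy_peak=float(proxy.max()),
        thresholds=thresholds,
    )


def summarize(traj: Trajectory) -> TrajectorySummary:
    """Peak occupancy fraction, total duct-delivered enzyme (trapezoidal),
    time of peak synthesis and rest time."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    t = traj.t
    duct = traj.frame["duct_export_rate"].to_numpy()
    total = float(np.trapezoid(duct, t)) if len(t) > 1 else 0.0
    return TrajectorySummary(
        peak_N_fraction=float(traj.N.max() / traj.params.N_max),
        total_duct_enzyme=total,
        t_peak_S=float(t[int(np.argmax(traj.S))]),
        rest_time=detect_rest_state(traj),
    )
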