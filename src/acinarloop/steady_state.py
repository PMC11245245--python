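"""Closed-loop transfer-function algebra and fixed-point analysis.

Under constant vagal drive the loop admits an analytic fixed point.  The
static (non-integrating) transfer function of the feedback block diagram
is ``output/input = G / (1 + G*H)`` with feedback gain ``H = (F/J) * k_cat``.
The integrating dynamics of the full model instead pin hydrolysis to the
input exactly, giving the G-free fixed point ``S* = r_in / H`` with
occupancy ``N* = S*/G`` and BCHE mass ``B* = F*S*/J``.  The two agree in
the high-loop-gain regime: their relative discrepancy is exactly
``1/(1 + G*H)``, negligible whenever the loop gain is much greater
than 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .model import ConfigurationError, EffectiveParameters, ModelParameters

__all__ = [
    "OpenLoopError",
    "LoopSignals",
    "SteadyStateResult",
    "feedback_gain",
    "static_transfer",
    "steady_state_output",
    "steady_state_full",
    "g_independence_report",
]

Params = ModelParameters | EffectiveParameters


class OpenLoopError(ValueError):
    """Raised when H = 0: with no feedback the transfer-function
    denominator of the fixed point goes to zero and no finite
    steady state exists under sustained drive."""


@dataclass(frozen=True)
class LoopSignals:
    """Signals around the summing junction of the feedback diagram.

    ``X`` is the input as modified by the negative feedback
    (X = input - H*output); the forward path gives output = G*X.
    Implied units: input and X in ACh-units/min, output in
    enzyme-units/min, H in (ACh-units/min) per (enzyme-units/min).
    """

    input: float
    X: float
    output: float
    H: float


@dataclass(frozen=True)
class SteadyStateResult:
    """Analytic fixed point and loop-gain diagnostics."""

    S_star: float
    N_star: float
    B_star: float
    H: float
    loop_gain: float
    saturated: bool
    approx_error: float

    def to_dict(self) -> dict:
        return {
            "S_star": self.S_star,
            "N_star": self.N_star,
            "B_star": self.B_star,
            "H": self.H,
            "loop_gain": self.loop_gain,
            "saturated": self.saturated,
            "approx_error": self.approx_error,
        }


def feedback_gain(params: Params) -> float:
    """H = (F/J) * k_cat."""
    if params.J <= 0:
        raise ConfigurationError("J must be > 0")
    return (params.F / params.J) * params.k_cat


def static_transfer(G: float, H: float, input: float) -> LoopSignals:
    """Evaluate the static closed-loop transfer function.

    output = input * G / (1 + G*H);  X = input - H*output, so that
    output = G*X holds exactly.
    """
    denom = 1.0 + G * H
    if denom == 0.0:
        raise ZeroDivisionError("singular loop: 1 + G*H = 0")
    X = input / denom  # summing junction first: keeps output = G*X exact
    output = G * X
    return LoopSignals(input=input, X=X, output=output, H=H)


def steady_state_output(params: Params, r_in: float) -> float:
    """Fixed-point synthesis rate S* = r_in / H (G-free).

    Raises
    ------
    OpenLoopError
        If H = 0 (e.g. F = 0 or k_cat = 0): the open loop has no finite
        fixed point under sustained drive — the fixed-point denominator
        goes to zero and occupancy runs away to the receptor cap instead.
    """
    H = feedback_gain(params)
    if H == 0.0:
        raise OpenLoopError(
            "feedback gain H = (F/J)*k_cat is zero: the fixed-point "
            "denominator goes to zero, so no finite steady state exists; "
            "occupancy is bounded only by the finite receptor count"
        )
    if r_in < 0:
        raise ValueError("r_in must be >= 0")
    return r_in / H


def steady_state_full(params: Params, r_in: float) -> SteadyStateResult:
    """Full analytic fixed point: S*, N* = S*/G, B* = F*S*/J, with the
    loop-gain diagnostic and the static-vs-integrating approximation error.
    """
    H = feedback_gain(params)
    S_star = steady_state_output(params, r_in)
    if params.G <= 0:
        raise ConfigurationError("G must be > 0 for a finite occupancy fixed point")
    N_star = S_star / params.G
    B_star = params.F * S_star / params.J
    loop_gain = params.G * H
    static_out = static_transfer(params.G, H, r_in).output
    if S_star > 0:
        approx_error = abs(static_out - S_star) / S_star
    else:
        approx_error = 1.0 / (1.0 + loop_gain)
    return SteadyStateResult(
        S_star=S_star,
        N_star=N_star,
        B_star=B_star,
        H=H,
        loop_gain=loop_gain,
        saturated=N_star >= params.N_max,
        approx_error=approx_error,
    )


def g_independence_report(
    params: ModelParameters,
    r_in: float,
    g_multipliers: Sequence[float],
) -> pd.DataFrame:
    """Fixed points across a sweep of acinar-sensitivity multipliers.

    The synthesis rate S* is identical in every row (the G's cancel in the
    fixed point) while the required occupancy N* scales as 1/G; rows where
    N* exceeds the receptor count are flagged saturated — the regime in
    which the loop can no longer compensate.

    Returns a DataFrame with columns ``G``, ``S_star``, ``N_star``,
    ``saturated``.
    """
    for m in g_multipliers:
        if not (m > 0 and math.isfinite(m)):
            raise ConfigurationError("g_multipliers must be positive and finite")
    rows = []
    for m in g_multipliers:
        p = params.replace(G=params.G * m)
        res = steady_state_full(p, r_in)
        rows.append(
            {"G": p.G, "S_star": res.S_star, "N_star": res.N_star, "saturated": res.saturated}
        )
    return pd.DataFrame(rows, columns=["G", "S_star", "N_star", "saturated"])
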