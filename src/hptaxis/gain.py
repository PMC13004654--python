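"""Loop-gain and ultrasensitivity analytics.

The feedback loop TH -> (TSH, TRH) -> TSH -> TH amplifies percentage
changes.  Each Hill step contributes a local logarithmic slope bounded by
its Hill coefficient n; far from saturation the slope approaches n.  TH
inhibits TSH both directly (coefficient n3) and indirectly through TRH
(n5 then n7), and the two parallel feedback pathways add, so the maximal
loop gain composes as (n5*n7 + n3)*n1.  Both built-in designs reach 8:
Design A as (2*2 + 4)*1, Design B as (1*1 + 1)*4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import HormoneState, ModelParameters

__all__ = [
    "GainReport",
    "local_step_gains",
    "maximal_loop_gain",
    "local_loop_gain",
    "gain_report",
    "log2_gain",
    "hill_dynamic_range",
    "exponential_feedback_gain",
]

#: Step labels for the four regulatory edges of the loop.
STEPS = ("TSH->TH", "TH-|TSH", "TH-|TRH", "TRH->TSH")


@dataclass(frozen=True)
class GainReport:
    """Local step gains, their loop composition, and the structural maximum."""

    step_gains: dict[str, float]
    local_loop_gain: float
    maximal_loop_gain: float

    def __post_init__(self) -> None:
        if abs(self.local_loop_gain) > self.maximal_loop_gain * (1 + 1e-12):
            raise ValueError("local loop gain cannot exceed the structural maximum")

    def as_dict(self) -> dict:
        return {
            "step_gains": dict(self.step_gains),
            "local_loop_gain": self.local_loop_gain,
            "maximal_loop_gain": self.maximal_loop_gain,
        }


def local_step_gains(params: ModelParameters, state: HormoneState) -> dict[str, float]:
    """Signed local logarithmic slope of each regulatory step at ``state``.

    Stimulatory steps give n*(1-f) > 0, inhibitory steps -n*(1-h) < 0,
    where f (h) is the step's fractional activity at the state; saturation
    drives a step's gain to zero.
    """
    if min(state.trh, state.tsh, state.th) <= 0:
        raise ValueError("step gains require a strictly positive state")
    return {
        "TSH->TH": params.hill_tsh_to_th.log_slope(state.tsh),
        "TH-|TSH": params.hill_th_on_tsh.log_slope(state.th),
        "TH-|TRH": params.hill_th_on_trh.log_slope(state.th),
        "TRH->TSH": params.hill_trh_to_tsh.log_slope(state.trh),
    }


def maximal_loop_gain(params: ModelParameters) -> float:
    """Structural maximum of the loop gain: (n5*n7 + n3)*n1.

    The indirect feedback path (TH inhibits TRH, TRH stimulates TSH)
    multiplies along the cascade; it adds to the direct TH-on-TSH path,
    and the sum is carried through the thyroid step.  Attained only in the
    zero-saturation limit of all four Hill steps.
    """
    return (params.n5 * params.n7 + params.n3) * params.n1


def local_loop_gain(params: ModelParameters, state: HormoneState) -> float:
    """Magnitude of the loop gain from the local step slopes at ``state``.

    |TSH->TH| * (|TH-|TSH| + |TH-|TRH| * |TRH->TSH|): the two feedback
    pathways add before passing through the thyroid step.
    """
    g = local_step_gains(params, state)
    return abs(g["TSH->TH"]) * (abs(g["TH-|TSH"]) + abs(g["TH-|TRH"]) * abs(g["TRH->TSH"]))


def gain_report(params: ModelParameters, state: HormoneState) -> GainReport:
    """Bundle step gains, local loop gain and the structural maximum."""
    return GainReport(
        step_gains=local_step_gains(params, state),
        local_loop_gain=local_loop_gain(params, state),
        maximal_loop_gain=maximal_loop_gain(params),
    )


def log2_gain(fold_output: float, fold_input: float = 2.0) -> float:
    """Logarithmic gain from fold changes: log(fold_output)/log(fold_input).

    For a doubling of the input (fold_input=2) this is log2 of the output
    fold change: a 64-fold output response per input doubling is a gain
    of 6.
    """
    if fold_output <= 0 or fold_input <= 0:
        raise ValueError("fold changes must be positive")
    if fold_input == 1.0:
        raise ValueError("fold_input must differ from 1")
    return math.log(fold_output) / math.log(fold_input)


def hill_dynamic_range(n: float, f_lo: float = 0.1, f_hi: float = 0.9) -> float:
    """Input fold change moving a stimulatory Hill response from f_lo to f_hi.

    Equals ((f_hi/(1-f_hi)) / (f_lo/(1-f_lo)))^(1/n); at the 10%-90%
    defaults this is 81^(1/n): a Michaelis-Menten step (n=1) needs an
    81-fold dose change, a steep n=4 step only 3-fold.
    """
    if n <= 0:
        raise ValueError("Hill coefficient must be > 0")
    if not (0.0 < f_lo < f_hi < 1.0):
        raise ValueError("need 0 < f_lo < f_hi < 1")
    odds_ratio = (f_hi / (1.0 - f_hi)) / (f_lo / (1.0 - f_lo))
    return odds_ratio ** (1.0 / n)


def exponential_feedback_gain(phi: float, th: float) -> float:
    """Logarithmic gain of an exponential feedback law TSH ~ exp(-phi*TH).

    d ln(TSH)/d ln(TH) = -phi*TH: unlike a Hill step the gain is not a
    constant but grows linearly with the hormone level, and amplification
    (|gain| > 1) requires phi*TH > 1.
    """
    if th < 0:
        raise ValueError("TH concentration must be >= 0")
    return -phi * th
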