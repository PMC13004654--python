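"""Parameter calibration and the two built-in amplifier-placement presets.

A full 14-constant parameter set is derived from four pieces of information:

* the basal steady state to reproduce — (TRH, TSH, TH) = (1, 1, 15) by
  default (arbitrary units);
* the basal activity of every Hill step — 10% by default, i.e. each
  regulatory function evaluates to 0.1 at the basal state, leaving ample
  dynamic range in both directions;
* hormone half-lives, which fix the clearance constants: TRH 6 min,
  TSH 1 h, TH 6 days (half-life spread of ~3 orders of magnitude keeps the
  high-gain loop stable);
* the four Hill coefficients, which place the signal amplification.

Two presets ship with the package.  "design_A" puts the amplification in
the brain (n1=1, n3=4, n5=2, n7=2: steep feedback of TH onto TSH and TRH,
steep TRH->TSH step, Michaelis-type thyroid step).  "design_B" puts it in
the thyroid (n1=4, n3=n5=n7=1).  Both compose to the same maximal loop
gain of 8.  The "_printed" variants carry the rounded constants as usually
quoted (k2=0.0048, Kd3=8.66, ...) instead of the unrounded calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import HillTerm, HormoneState, ModelParameters

__all__ = [
    "CalibrationSpec",
    "clearance_from_half_life",
    "kd_for_basal_activity",
    "vmax_for_steady_state",
    "build_design",
    "get_preset",
    "preset_names",
    "DESIGN_A_HILL_COEFFICIENTS",
    "DESIGN_B_HILL_COEFFICIENTS",
]

#: (n1, n3, n5, n7) — brain-side amplification.
DESIGN_A_HILL_COEFFICIENTS = (1.0, 4.0, 2.0, 2.0)
#: (n1, n3, n5, n7) — thyroid-side amplification.
DESIGN_B_HILL_COEFFICIENTS = (4.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class CalibrationSpec:
    """Constraints sufficient to derive a full ModelParameters.

    half_lives are (TRH, TSH, TH) in hours; hill_coefficients are
    (n1, n3, n5, n7).  saturation_fraction is the value every Hill step
    takes at the basal state.
    """

    target_state: HormoneState = field(default_factory=lambda: HormoneState(1.0, 1.0, 15.0))
    saturation_fraction: float = 0.1
    half_lives: tuple[float, float, float] = (0.1, 1.0, 144.0)
    hill_coefficients: tuple[float, float, float, float] = DESIGN_A_HILL_COEFFICIENTS

    def __post_init__(self) -> None:
        f = self.saturation_fraction
        if not (0.0 < f < 1.0):
            raise ValueError(f"saturation fraction must be in (0, 1), got {f!r}")
        if any(t <= 0 or not math.isfinite(t) for t in self.half_lives):
            raise ValueError(f"half-lives must be positive, got {self.half_lives!r}")
        if any(n <= 0 or not math.isfinite(n) for n in self.hill_coefficients):
            raise ValueError(f"Hill coefficients must be positive, got {self.hill_coefficients!r}")
        s = self.target_state
        if min(s.trh, s.tsh, s.th) <= 0:
            raise ValueError("target steady state must be strictly positive")


def clearance_from_half_life(t_half: float) -> float:
    """First-order clearance constant ln(2)/t_half, in 1/h for t_half in hours."""
    if not (math.isfinite(t_half) and t_half > 0):
        raise ValueError(f"half-life must be positive, got {t_half!r}")
    return math.log(2.0) / t_half


def kd_for_basal_activity(mode: str, x_basal: float, n: float, f: float) -> float:
    """Affinity constant making a Hill step's value equal f at input x_basal.

    For a stimulatory step Kd = x * ((1-f)/f)^(1/n); for an inhibitory step
    Kd = x * (f/(1-f))^(1/n).  Note that an inhibitory step at value f is
    (1-f)-occupied: "10% activity" for the feedback arms means 90% receptor
    occupancy at the basal state.
    """
    if not (0.0 < f < 1.0):
        raise ValueError(f"basal activity fraction must be in (0, 1), got {f!r}")
    if x_basal <= 0 or n <= 0:
        raise ValueError("basal concentration and Hill coefficient must be > 0")
    if mode == "stimulatory":
        return x_basal * ((1.0 - f) / f) ** (1.0 / n)
    if mode == "inhibitory":
        return x_basal * (f / (1.0 - f)) ** (1.0 / n)
    raise ValueError(f"mode must be stimulatory or inhibitory, got {mode!r}")


def vmax_for_steady_state(clearance_k: float, y_ss: float, activity_product: float) -> float:
    """Maximal production rate balancing clearance at the target steady state.

    At steady state production = clearance: vmax * activity = k * y_ss, so
    vmax = k * y_ss / activity, where activity is the product of the Hill
    terms multiplying the production term (one term for TRH and TH, two for
    TSH).
    """
    if clearance_k <= 0 or y_ss <= 0:
        raise ValueError("clearance constant and steady-state level must be > 0")
    if not (0.0 < activity_product <= 1.0):
        raise ValueError(
            f"activity product must be in (0, 1], got {activity_product!r} "
            "(a zero product makes the calibration degenerate)"
        )
    return clearance_k * y_ss / activity_product


def build_design(spec: CalibrationSpec) -> ModelParameters:
    """Derive the full 14-constant parameter set from a calibration spec."""
    trh0, tsh0, th0 = spec.target_state.trh, spec.target_state.tsh, spec.target_state.th
    f = spec.saturation_fraction
    n1, n3, n5, n7 = spec.hill_coefficients
    t_trh, t_tsh, t_th = spec.half_lives

    k6 = clearance_from_half_life(t_trh)
    k4 = clearance_from_half_life(t_tsh)
    k2 = clearance_from_half_life(t_th)

    kd1 = kd_for_basal_activity("stimulatory", tsh0, n1, f)
    kd3 = kd_for_basal_activity("inhibitory", th0, n3, f)
    kd5 = kd_for_basal_activity("inhibitory", th0, n5, f)
    kd7 = kd_for_basal_activity("stimulatory", trh0, n7, f)

    # Every step sits at value f at the basal state by construction.
    k5 = vmax_for_steady_state(k6, trh0, f)
    k3 = vmax_for_steady_state(k4, tsh0, f * f)
    k1 = vmax_for_steady_state(k2, th0, f)

    return ModelParameters(
        k1=k1, k2=k2, k3=k3, k4=k4, k5=k5, k6=k6,
        hill_tsh_to_th=HillTerm(kd1, n1, "stimulatory"),
        hill_th_on_tsh=HillTerm(kd3, n3, "inhibitory"),
        hill_th_on_trh=HillTerm(kd5, n5, "inhibitory"),
        hill_trh_to_tsh=HillTerm(kd7, n7, "stimulatory"),
    )


def _printed(Kd1, Kd3, Kd5, Kd7, n1, n3, n5, n7) -> ModelParameters:
    return ModelParameters.from_constants(
        k1=0.722, k2=0.0048, k3=69.3, k4=0.693, k5=69.3, k6=6.93,
        Kd1=Kd1, Kd3=Kd3, Kd5=Kd5, Kd7=Kd7, n1=n1, n3=n3, n5=n5, n7=n7,
    )


def _build_presets() -> dict[str, ModelParameters]:
    return {
        "design_A": build_design(CalibrationSpec(hill_coefficients=DESIGN_A_HILL_COEFFICIENTS)),
        "design_B": build_design(CalibrationSpec(hill_coefficients=DESIGN_B_HILL_COEFFICIENTS)),
        # Rounded constants as conventionally quoted; their steady state
        # deviates from (1, 1, 15) by <0.5% due to rounding.
        "design_A_printed": _printed(9.0, 8.66, 5.0, 3.0, 1.0, 4.0, 2.0, 2.0),
        "design_B_printed": _printed(1.7321, 1.6667, 1.6667, 9.0, 4.0, 1.0, 1.0, 1.0),
    }


_PRESETS: dict[str, ModelParameters] = _build_presets()


def preset_names() -> tuple[str, ...]:
    return tuple(_PRESETS)


def get_preset(name: str) -> ModelParameters:
    """Look up a named preset ('design_A', 'design_B', or '_printed' variants).

    'A' and 'B' are accepted as shorthands for the calibrated presets.
    """
    shorthand = {"A": "design_A", "B": "design_B", "a": "design_A", "b": "design_B"}
    key = shorthand.get(name, name)
    try:
        return _PRESETS[key]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(_PRESETS)}"
        ) from None
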