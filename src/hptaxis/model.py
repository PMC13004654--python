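"""Core model of the hypothalamic-pituitary-thyroid (HPT) feedback loop.

The axis is reduced to three state variables — TRH (hypothalamus), TSH
(anterior pituitary) and TH (thyroid hormone, primarily T4) — coupled by
four Hill-type regulatory steps:

* TRH stimulates TSH production,
* TSH stimulates TH production,
* TH inhibits both TSH and TRH production (the two feedback arms).

Each hormone is cleared by first-order kinetics, giving the rate equations

    dTRH/dt = k5 * Kd5^n5 / (Kd5^n5 + TH^n5)                       - k6*TRH
    dTSH/dt = k3 * Kd3^n3 / (Kd3^n3 + TH^n3)
                 * TRH^n7 / (Kd7^n7 + TRH^n7)                      - k4*TSH
    dTH/dt  = k1 * TSH^n1 / (Kd1^n1 + TSH^n1)                      - k2*TH

Concentrations are in arbitrary units, time is in hours throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

__all__ = [
    "HormoneState",
    "HillTerm",
    "ModelParameters",
    "PARAMETER_NAMES",
    "hill_activation",
    "hill_inhibition",
    "dstate_dt",
]

#: Canonical ordering of the 14 model constants.
PARAMETER_NAMES = (
    "k1", "k2", "k3", "k4", "k5", "k6",
    "Kd1", "Kd3", "Kd5", "Kd7",
    "n1", "n3", "n5", "n7",
)


def _require_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


def hill_activation(x: float, kd: float, n: float) -> float:
    """Stimulatory Hill response x^n / (Kd^n + x^n), a fraction in [0, 1].

    Evaluated through the ratio (Kd/x)^n in log space so that large Hill
    coefficients or extreme concentrations cannot overflow.

    Parameters
    ----------
    x : input concentration, >= 0.
    kd : half-saturation (affinity) constant, > 0.
    n : Hill coefficient, > 0.
    """
    _require_positive("Kd", kd)
    _require_positive("n", n)
    if x < 0 or not math.isfinite(x):
        raise ValueError(f"concentration must be finite and >= 0, got {x!r}")
    if x == 0.0:
        return 0.0
    # x^n/(Kd^n + x^n) == 1/(1 + exp(n*(ln Kd - ln x)))
    t = n * (math.log(kd) - math.log(x))
    if t > 700.0:
        return 0.0
    if t < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(t))


def hill_inhibition(x: float, kd: float, n: float) -> float:
    """Inhibitory Hill response Kd^n / (Kd^n + x^n) = 1 - hill_activation."""
    _require_positive("Kd", kd)
    _require_positive("n", n)
    if x < 0 or not math.isfinite(x):
        raise ValueError(f"concentration must be finite and >= 0, got {x!r}")
    if x == 0.0:
        return 1.0
    t = n * (math.log(x) - math.log(kd))
    if t > 700.0:
        return 0.0
    if t < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(t))


@dataclass(frozen=True)
class HormoneState:
    """Concentrations of the three axis hormones (arbitrary units)."""

    trh: float
    tsh: float
    th: float

    def __post_init__(self) -> None:
        for name, value in (("TRH", self.trh), ("TSH", self.tsh), ("TH", self.th)):
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(
                    f"{name} concentration must be finite and >= 0, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.trh, self.tsh, self.th], dtype=float)

    @classmethod
    def from_array(cls, values) -> "HormoneState":
        trh, tsh, th = (float(v) for v in values)
        return cls(trh, tsh, th)

    def __iter__(self) -> Iterator[float]:
        return iter((self.trh, self.tsh, self.th))


@dataclass(frozen=True)
class HillTerm:
    """One regulatory step: a stimulatory or inhibitory Hill function."""

    kd: float
    n: float
    mode: str  # "stimulatory" | "inhibitory"

    def __post_init__(self) -> None:
        _require_positive("Kd", self.kd)
        _require_positive("n", self.n)
        if self.mode not in ("stimulatory", "inhibitory"):
            raise ValueError(f"mode must be stimulatory or inhibitory, got {self.mode!r}")

    def response(self, x: float) -> float:
        """Fractional activity in [0, 1] at input concentration x."""
        if self.mode == "stimulatory":
            return hill_activation(x, self.kd, self.n)
        return hill_inhibition(x, self.kd, self.n)

    def log_slope(self, x: float) -> float:
        """Local logarithmic slope d ln(response)/d ln(x) at x > 0.

        Equals n*(1 - response) for a stimulatory step and -n*(1 - response)
        for an inhibitory one; this is the step's percentage gain.
        """
        _require_positive("x", x)
        r = self.response(x)
        if self.mode == "stimulatory":
            return self.n * (1.0 - r)
        return -self.n * (1.0 - r)


@dataclass(frozen=True)
class ModelParameters:
    """The 14 constants of the three rate equations.

    k1, k3, k5 are maximal production rates (conc/h) of TH, TSH and TRH;
    k2, k4, k6 the first-order clearance constants (1/h) of TH, TSH and TRH.
    The four Hill terms carry (Kd1, n1), (Kd3, n3), (Kd5, n5), (Kd7, n7).
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    hill_tsh_to_th: HillTerm    # Kd1, n1: TSH stimulates TH
    hill_th_on_tsh: HillTerm    # Kd3, n3: TH inhibits TSH
    hill_th_on_trh: HillTerm    # Kd5, n5: TH inhibits TRH
    hill_trh_to_tsh: HillTerm   # Kd7, n7: TRH stimulates TSH

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "k6"):
            _require_positive(name, getattr(self, name))
        if self.hill_tsh_to_th.mode != "stimulatory":
            raise ValueError("TSH->TH step must be stimulatory")
        if self.hill_th_on_tsh.mode != "inhibitory":
            raise ValueError("TH-|TSH step must be inhibitory")
        if self.hill_th_on_trh.mode != "inhibitory":
            raise ValueError("TH-|TRH step must be inhibitory")
        if self.hill_trh_to_tsh.mode != "stimulatory":
            raise ValueError("TRH->TSH step must be stimulatory")

    # -- flat access to the Hill constants in the field's naming ------------
    @property
    def Kd1(self) -> float:
        return self.hill_tsh_to_th.kd

    @property
    def Kd3(self) -> float:
        return self.hill_th_on_tsh.kd

    @property
    def Kd5(self) -> float:
        return self.hill_th_on_trh.kd

    @property
    def Kd7(self) -> float:
        return self.hill_trh_to_tsh.kd

    @property
    def n1(self) -> float:
        return self.hill_tsh_to_th.n

    @property
    def n3(self) -> float:
        return self.hill_th_on_tsh.n

    @property
    def n5(self) -> float:
        return self.hill_th_on_trh.n

    @property
    def n7(self) -> float:
        return self.hill_trh_to_tsh.n

    @classmethod
    def from_constants(
        cls,
        k1: float, k2: float, k3: float, k4: float, k5: float, k6: float,
        Kd1: float, Kd3: float, Kd5: float, Kd7: float,
        n1: float, n3: float, n5: float, n7: float,
    ) -> "ModelParameters":
        return cls(
            k1=k1, k2=k2, k3=k3, k4=k4, k5=k5, k6=k6,
            hill_tsh_to_th=HillTerm(Kd1, n1, "stimulatory"),
            hill_th_on_tsh=HillTerm(Kd3, n3, "inhibitory"),
            hill_th_on_trh=HillTerm(Kd5, n5, "inhibitory"),
            hill_trh_to_tsh=HillTerm(Kd7, n7, "stimulatory"),
        )

    def as_dict(self) -> dict[str, float]:
        """The 14 constants keyed by their conventional names."""
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def with_value(self, name: str, value: float) -> "ModelParameters":
        """A copy with one named constant replaced (used for perturbations)."""
        if name not in PARAMETER_NAMES:
            raise KeyError(f"unknown parameter {name!r}; expected one of {PARAMETER_NAMES}")
        if name in ("k1", "k2", "k3", "k4", "k5", "k6"):
            return replace(self, **{name: value})
        field_by_suffix = {
            "1": "hill_tsh_to_th",
            "3": "hill_th_on_tsh",
            "5": "hill_th_on_trh",
            "7": "hill_trh_to_tsh",
        }
        field = field_by_suffix[name[-1]]
        term: HillTerm = getattr(self, field)
        attr = "kd" if name.startswith("Kd") else "n"
        return replace(self, **{field: replace(term, **{attr: value})})


def dstate_dt(state: HormoneState | np.ndarray, params: ModelParameters) -> np.ndarray:
    """Right-hand side of the three rate equations, in conc/h.

    Order of the returned components: (dTRH/dt, dTSH/dt, dTH/dt).
    """
    if isinstance(state, HormoneState):
        trh, tsh, th = state.trh, state.tsh, state.th
    else:
        trh, tsh, th = (float(v) for v in state)
    p = params
    d_trh = p.k5 * p.hill_th_on_trh.response(th) - p.k6 * trh
    d_tsh = (
        p.k3 * p.hill_th_on_tsh.response(th) * p.hill_trh_to_tsh.response(trh)
        - p.k4 * tsh
    )
    d_th = p.k1 * p.hill_tsh_to_th.response(tsh) - p.k2 * th
    return np.array([d_trh, d_tsh, d_th], dtype=float)
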