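"""Local parameter sensitivity of the steady state.

Two independent routes are provided:

* ``finite_difference_sensitivity`` — the simulation protocol: perturb one
  constant at a time by +/-10%, re-solve the steady state, and report the
  relative change of each hormone divided by the relative change of the
  parameter.

* ``analytic_sensitivity`` — the log-linearized oracle: differentiate the
  three steady-state balance equations in log space.  Each Hill step
  contributes its local logarithmic slope (n*(1-f) for a stimulatory step
  at value f, -n*(1-h) for an inhibitory step at value h), which yields a
  3x3 linear system for the infinitesimal relative sensitivities.

The two agree in the small-perturbation limit and serve as mutual checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import SteadyStateError, steady_state
from .model import HormoneState, ModelParameters, PARAMETER_NAMES

__all__ = [
    "SensitivityTable",
    "finite_difference_sensitivity",
    "analytic_sensitivity",
    "classify_sensitivities",
]

OUTPUTS = ("TRH", "TSH", "TH")
DIRECTIONS = ("up", "down", "symmetric")


@dataclass(frozen=True)
class SensitivityTable:
    """Relative sensitivity coefficients, one row per (parameter, direction, output).

    ``frame`` columns: parameter, direction ('up' = +delta, 'down' = -delta,
    'symmetric' = mean of the two), output, coefficient, converged.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"parameter", "direction", "output", "coefficient", "converged"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sensitivity table missing columns: {sorted(missing)}")

    def coefficient(self, parameter: str, output: str, direction: str = "symmetric") -> float:
        f = self.frame
        row = f[
            (f["parameter"] == parameter)
            & (f["output"] == output)
            & (f["direction"] == direction)
        ]
        if row.empty:
            raise KeyError(f"no entry for ({parameter}, {output}, {direction})")
        return float(row["coefficient"].iloc[0])

    def symmetric_matrix(self) -> pd.DataFrame:
        """14 x 3 matrix of symmetric coefficients (parameters x outputs)."""
        sym = self.frame[self.frame["direction"] == "symmetric"]
        mat = sym.pivot(index="parameter", columns="output", values="coefficient")
        return mat.reindex(index=list(PARAMETER_NAMES), columns=list(OUTPUTS))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def finite_difference_sensitivity(
    params: ModelParameters,
    delta: float = 0.1,
    base_state: HormoneState | None = None,
) -> SensitivityTable:
    """Perturb each of the 14 constants by +/-delta and re-solve the steady state.

    For parameter p and output y the coefficient is
    ((y(p*(1+-delta)) - y0)/y0) / (+-delta); the 'symmetric' direction is the
    mean of the two one-sided coefficients.  Perturbed solves start from the
    unperturbed steady state.  A perturbed system that fails to converge is
    kept in the table with coefficient NaN and converged=False.
    """
    if not (0.0 < delta < 0.5):
        raise ValueError(f"delta must be in (0, 0.5), got {delta!r}")
    if base_state is None:
        base_state = steady_state(params)
    y0 = base_state.as_array()
    if np.any(y0 <= 0):
        raise ValueError("base steady state must be strictly positive")

    rows = []
    for name in PARAMETER_NAMES:
        base_value = getattr(params, name)
        one_sided: dict[str, np.ndarray | None] = {}
        for direction, sign in (("up", +1.0), ("down", -1.0)):
            perturbed = params.with_value(name, base_value * (1.0 + sign * delta))
            try:
                y = steady_state(perturbed, init_guess=base_state).as_array()
                coeff = ((y - y0) / y0) / (sign * delta)
                one_sided[direction] = coeff
            except SteadyStateError:
                one_sided[direction] = None
            for output, c in zip(
                OUTPUTS,
                one_sided[direction] if one_sided[direction] is not None else [np.nan] * 3,
            ):
                rows.append(
                    {
                        "parameter": name,
                        "direction": direction,
                        "output": output,
                        "coefficient": float(c),
                        "converged": one_sided[direction] is not None,
                    }
                )
        up, down = one_sided["up"], one_sided["down"]
        if up is not None and down is not None:
            sym = (up + down) / 2.0
            ok = True
        else:
            sym = np.full(3, np.nan)
            ok = False
        for output, c in zip(OUTPUTS, sym):
            rows.append(
                {
                    "parameter": name,
                    "direction": "symmetric",
                    "output": output,
                    "coefficient": float(c),
                    "converged": ok,
                }
            )
    return SensitivityTable(pd.DataFrame(rows))


def _log_linear_system(params: ModelParameters, state: HormoneState):
    """The 3x3 log-space balance matrix and the per-parameter forcing vectors."""
    p = params
    trh, tsh, th = state.trh, state.tsh, state.th

    f1 = p.hill_tsh_to_th.response(tsh)
    h3 = p.hill_th_on_tsh.response(th)
    h5 = p.hill_th_on_trh.response(th)
    f7 = p.hill_trh_to_tsh.response(trh)

    e1 = p.n1 * (1.0 - f1)    # d ln A1 / d ln TSH
    e3 = -p.n3 * (1.0 - h3)   # d ln I3 / d ln TH
    e5 = -p.n5 * (1.0 - h5)   # d ln I5 / d ln TH
    e7 = p.n7 * (1.0 - f7)    # d ln A7 / d ln TRH

    # Balance equations in logs; unknowns (d ln TRH, d ln TSH, d ln TH).
    matrix = np.array(
        [
            [-1.0, 0.0, e5],
            [e7, -1.0, e3],
            [0.0, e1, -1.0],
        ]
    )

    # Elasticity of each balance equation to ln(parameter).
    forcing = {
        "k5": np.array([1.0, 0.0, 0.0]),
        "k6": np.array([-1.0, 0.0, 0.0]),
        "k3": np.array([0.0, 1.0, 0.0]),
        "k4": np.array([0.0, -1.0, 0.0]),
        "k1": np.array([0.0, 0.0, 1.0]),
        "k2": np.array([0.0, 0.0, -1.0]),
        "Kd5": np.array([p.n5 * (1.0 - h5), 0.0, 0.0]),
        "Kd3": np.array([0.0, p.n3 * (1.0 - h3), 0.0]),
        "Kd7": np.array([0.0, -p.n7 * (1.0 - f7), 0.0]),
        "Kd1": np.array([0.0, 0.0, -p.n1 * (1.0 - f1)]),
        "n5": np.array([-p.n5 * (1.0 - h5) * math.log(th / p.Kd5), 0.0, 0.0]),
        "n3": np.array([0.0, -p.n3 * (1.0 - h3) * math.log(th / p.Kd3), 0.0]),
        "n7": np.array([0.0, p.n7 * (1.0 - f7) * math.log(trh / p.Kd7), 0.0]),
        "n1": np.array([0.0, 0.0, p.n1 * (1.0 - f1) * math.log(tsh / p.Kd1)]),
    }
    return matrix, forcing


def analytic_sensitivity(
    params: ModelParameters,
    base_state: HormoneState | None = None,
) -> SensitivityTable:
    """Infinitesimal relative sensitivities from the log-linearized balance.

    Solves M * s = -b for each parameter, where M collects the local
    logarithmic slopes of the four Hill steps (and -1 for each clearance)
    and b is the parameter's direct elasticity in its balance equation.
    Coefficients are reported under direction 'symmetric' (the delta -> 0
    limit has no one-sided variants).
    """
    if base_state is None:
        base_state = steady_state(params)
    if min(base_state.trh, base_state.tsh, base_state.th) <= 0:
        raise ValueError("analytic sensitivity requires a strictly positive steady state")

    matrix, forcing = _log_linear_system(params, base_state)
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ArithmeticError(
            "singular log-linearization: the loop gain exactly cancels the "
            "clearance terms; sensitivities are unbounded"
        )

    rows = []
    for name in PARAMETER_NAMES:
        s = np.linalg.solve(matrix, -forcing[name])
        for output, c in zip(OUTPUTS, s):
            rows.append(
                {
                    "parameter": name,
                    "direction": "symmetric",
                    "output": output,
                    "coefficient": float(c),
                    "converged": True,
                }
            )
    return SensitivityTable(pd.DataFrame(rows))


def classify_sensitivities(
    table: SensitivityTable,
    threshold: float = 0.3,
) -> dict[str, dict[str, tuple[str, ...]]]:
    """Partition the 14 parameters into sensitive/insensitive per output.

    A parameter is sensitive for an output when |symmetric coefficient| >=
    threshold.  Returns {output: {'sensitive': (...), 'insensitive': (...)}}.
    """
    mat = table.symmetric_matrix()
    result: dict[str, dict[str, tuple[str, ...]]] = {}
    for output in OUTPUTS:
        col = mat[output].abs()
        sensitive = tuple(p for p in PARAMETER_NAMES if col[p] >= threshold)
        insensitive = tuple(p for p in PARAMETER_NAMES if not col[p] >= threshold)
        result[output] = {"sensitive": sensitive, "insensitive": insensitive}
    return result
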