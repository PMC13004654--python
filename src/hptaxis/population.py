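"""Virtual populations: where interindividual variability originates decides
the sign of the TSH-TH relationship.

Each individual is a copy of a base parameter set with selected constants
drawn log-normally (median at the base value), solved to its own steady
state.  When the variability sits on the thyroid/clearance side (k1, k2),
the feedback loop answers every TH excursion with an amplified opposite
TSH excursion, producing the inverse log-linear TSH-TH relationship seen
clinically; variability on the brain side (k3, Kd3, k5, ...) drives TSH
and TH in the same direction instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .dynamics import SteadyStateError, steady_state
from .model import ModelParameters, PARAMETER_NAMES

__all__ = [
    "PopulationSpec",
    "PopulationSample",
    "sample_population",
    "fit_log_linear",
    "gain_from_population",
]


@dataclass(frozen=True)
class PopulationSpec:
    """What to vary, by how much, over how many individuals.

    ``varied`` maps parameter names to coefficients of variation; draws are
    independent log-normal with median equal to the base value and
    log-space SD sqrt(ln(1+CV^2)).
    """

    base: ModelParameters
    varied: tuple[tuple[str, float], ...]
    n_individuals: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name, cv in self.varied:
            if name not in PARAMETER_NAMES:
                raise KeyError(f"unknown parameter {name!r}")
            if cv < 0:
                raise ValueError(f"CV must be >= 0, got {cv!r} for {name}")


@dataclass(frozen=True)
class PopulationSample:
    """Per-individual parameter draws and steady states.

    ``records`` columns: individual, one column per varied parameter, and
    TRH, TSH, TH.  ``n_failed`` counts individuals excluded for steady-state
    non-convergence.
    """

    spec: PopulationSpec
    records: pd.DataFrame
    n_failed: int = 0

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def sample_population(spec: PopulationSpec, max_failure_fraction: float = 0.05) -> PopulationSample:
    """Draw and solve a virtual population; reproducible for a given seed.

    Individuals whose steady state cannot be located are excluded and
    counted; more than ``max_failure_fraction`` failures aborts (the
    parameter regime is unsuitable for the requested variability).
    """
    rng = np.random.default_rng(spec.seed)
    varied_names = [name for name, _ in spec.varied]
    sigmas = {name: math.sqrt(math.log1p(cv * cv)) for name, cv in spec.varied}

    # Draw the full parameter matrix up front so the stream of random
    # numbers, and hence the sample, is independent of solver behaviour.
    draws = {
        name: getattr(spec.base, name)
        * np.exp(rng.normal(0.0, sigmas[name], size=spec.n_individuals))
        for name in varied_names
    }

    base_ss = steady_state(spec.base)
    rows, n_failed = [], 0
    for i in range(spec.n_individuals):
        params = spec.base
        for name in varied_names:
            params = params.with_value(name, float(draws[name][i]))
        try:
            ss = steady_state(params, init_guess=base_ss)
        except SteadyStateError:
            n_failed += 1
            continue
        row = {"individual": i}
        row.update({name: float(draws[name][i]) for name in varied_names})
        row.update({"TRH": ss.trh, "TSH": ss.tsh, "TH": ss.th})
        rows.append(row)

    if n_failed > max_failure_fraction * spec.n_individuals:
        raise SteadyStateError(
            f"{n_failed}/{spec.n_individuals} individuals failed to converge; "
            "the varied-parameter regime is unsuitable"
        )
    records = pd.DataFrame(rows)
    return PopulationSample(spec=spec, records=records, n_failed=n_failed)


def fit_log_linear(sample: PopulationSample) -> tuple[float, float, float]:
    """OLS fit of ln(TSH) against TH (the clinical logTSH-fT4 convention).

    Returns (slope per TH unit, intercept, Pearson r).  A negative slope
    with r close to -1 is the inverse log-linear signature of
    thyroid-origin variability.
    """
    rec = sample.records
    if len(rec) < 3:
        raise ValueError("need at least 3 individuals to fit")
    th = rec["TH"].to_numpy()
    if np.ptp(th) <= 0 or np.std(th) == 0:
        raise ValueError("degenerate TH spread: nothing to regress on")
    fit = linregress(th, np.log(rec["TSH"].to_numpy()))
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def gain_from_population(sample: PopulationSample) -> float:
    """Population estimate of the feedback logarithmic gain.

    Negated OLS slope of ln(TSH) on ln(TH): for a population whose
    variability enters at the thyroid, this approaches the local
    TH -> TSH loop-arm gain as the variability shrinks.
    """
    rec = sample.records
    if len(rec) < 3:
        raise ValueError("need at least 3 individuals to fit")
    ln_th = np.log(rec["TH"].to_numpy())
    if np.std(ln_th) == 0:
        raise ValueError("degenerate TH spread: nothing to regress on")
    fit = linregress(ln_th, np.log(rec["TSH"].to_numpy()))
    if fit.slope >= 0:
        raise ValueError(
            "population shows no inverse TSH-TH relationship; the gain "
            "estimate is only meaningful for thyroid-origin variability"
        )
    return float(-fit.slope)
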