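"""Replicate statistics and Arrhenius decomposition of barriers.

Activation free energies computed at several temperatures decompose into
enthalpic and entropic parts through the linear relation

    dG_act(T) / T = dH_act * (1/T) - dS_act

so an ordinary least-squares fit of ``dG_act/T`` against ``1/T`` gives
``dH_act`` as the slope and ``-dS_act`` as the intercept.  Replicate
scatter is summarized with the sample standard deviation (n-1) and the
standard error of the mean SD/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TemperatureSeries",
    "ArrheniusResult",
    "arrhenius_fit",
    "t_delta_s",
    "replicate_summary",
]


@dataclass(frozen=True)
class TemperatureSeries:
    """Activation free energies (kcal/mol) at a set of temperatures (K)."""

    temperatures: np.ndarray
    dg_act: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        g = np.asarray(self.dg_act, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "dg_act", g)
        if t.shape != g.shape or t.ndim != 1 or len(t) < 2:
            raise ValueError("need matching 1D arrays with >= 2 points")
        if np.any(t <= 0):
            raise ValueError("temperatures must be positive")
        if len(np.unique(t)) != len(t):
            raise ValueError("temperatures must be distinct")


@dataclass(frozen=True)
class ArrheniusResult:
    """Activation enthalpy (kcal/mol), entropy (kcal/mol/K) and fit R^2."""

    dh_act: float
    ds_act: float
    r_squared: float

    def t_delta_s(self, temperature: float) -> float:
        return t_delta_s(self.ds_act, temperature)


def arrhenius_fit(series: TemperatureSeries) -> ArrheniusResult:
    """OLS of dG_act/T on 1/T: slope = dH_act, intercept = -dS_act,
    R^2 = squared Pearson correlation of the fitted pair."""
    x = 1.0 / series.temperatures
    y = series.dg_act / series.temperatures
    if np.ptp(x) == 0:
        raise ValueError("zero variance in 1/T")
    fit = stats.linregress(x, y)
    return ArrheniusResult(dh_act=float(fit.slope),
                           ds_act=float(-fit.intercept),
                           r_squared=float(fit.rvalue**2))


def t_delta_s(ds_act: float, temperature: float) -> float:
    """Entropic contribution T * dS_act (kcal/mol) at a temperature."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return temperature * ds_act


def replicate_summary(values) -> tuple:
    """(mean, SD, SEM) over independent replicate values.

    SD uses the sample (n-1) convention and SEM = SD/sqrt(n); needs
    n >= 2.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need at least 2 replicate values")
    sd = float(np.std(values, ddof=1))
    return float(np.mean(values)), sd, sd / np.sqrt(len(values))
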