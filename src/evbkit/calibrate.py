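"""Calibration of the coupling element and gas-phase shift.

The two phase-independent EVB parameters — the constant coupling
``A`` (= H12) and the gas-phase shift ``delta_alpha`` — are fixed so the
analyzed free-energy profile reproduces reference activation and
reaction free energies for the calibration reaction.  Because neither
parameter alters the mapping forces for stored constant-coupling runs
(``delta_alpha`` only shifts each window's potential by a constant),
calibration is pure reanalysis of stored trajectories: no resampling.

Sensitivities are well conditioned near a solution: raising
``delta_alpha`` raises the reaction free energy essentially one-for-one,
and raising ``A`` lowers the barrier by deepening the avoided crossing.
The solver is a damped finite-difference Newton iteration on the
two-component residual, with negative-``A`` excursions clamped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgWarning, solve

from .core import EVBParameters
from .fep import LambdaSchedule, NoBarrierError, extract_barriers, gap_profile

__all__ = [
    "CalibrationTargets",
    "CalibrationResult",
    "CalibrationError",
    "evaluate_targets",
    "calibrate",
]


class CalibrationError(RuntimeError):
    """Non-convergence; carries the best parameters and residuals seen."""

    def __init__(self, message: str, best_params=None, residuals=None):
        super().__init__(message)
        self.best_params = best_params
        self.residuals = residuals


@dataclass(frozen=True)
class CalibrationTargets:
    """Reference free energies the profile must reproduce (kcal/mol)."""

    dg_act_ref: float
    dg_rxn_ref: float
    temperature: float = 300.0
    tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.dg_act_ref < self.dg_rxn_ref:
            warnings.warn(
                "reference barrier below reference reaction free energy; "
                "profile would have no transition state above the product")


@dataclass
class CalibrationResult:
    """Outcome of a calibration: fitted parameters plus diagnostics."""

    params: EVBParameters
    dg_act: float
    dg_rxn: float
    residuals: tuple
    iterations: int
    converged: bool

    def to_json(self, path=None) -> str:
        rec = {
            "A": self.params.A, "mu": self.params.mu, "eta": self.params.eta,
            "r0": self.params.r0, "delta_alpha": self.params.delta_alpha,
            "dg_act": self.dg_act, "dg_rxn": self.dg_rxn,
            "residuals": list(self.residuals), "iterations": self.iterations,
            "converged": self.converged,
        }
        text = json.dumps(rec, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def evaluate_targets(windows, params: EVBParameters, schedule: LambdaSchedule,
                     temperature: float, bins: int = 50,
                     min_count: int = 30) -> tuple:
    """Run the full gap-profile analysis and return (dG_act, dG_rxn).

    Deterministic for fixed inputs; binning is recomputed from the
    observed gap range at the given ``params`` (the gap coordinate moves
    with ``delta_alpha``, so fixed edges would leak frames).
    """
    profile = gap_profile(windows, params, schedule, temperature,
                          bins=bins, min_count=min_count)
    summary = extract_barriers(profile)
    return summary.dg_act, summary.dg_rxn


def calibrate(windows, targets: CalibrationTargets, schedule: LambdaSchedule,
              initial_guess: tuple = (15.0, 0.0), bins: int = 50,
              min_count: int = 30, max_iter: int = 50,
              fd_step: float = 0.5) -> CalibrationResult:
    """Solve for constant-coupling (A, delta_alpha) reproducing the targets.

    Damped Newton iteration on the residual vector
    ``(dG_act - dg_act_ref, dG_rxn - dg_rxn_ref)`` with a forward-difference
    Jacobian (step ``fd_step`` kcal/mol in each parameter).  The step is
    halved (up to 8 times) whenever the residual norm fails to decrease,
    and negative-A trial points are clamped to zero with a warning.
    Every success is re-audited by an independent ``evaluate_targets``
    call before returning.

    Raises :class:`CalibrationError` carrying the best-so-far parameters
    when ``max_iter`` is exhausted.
    """

    def residual(a, dalpha):
        p = EVBParameters(A=a, delta_alpha=dalpha)
        act, rxn = evaluate_targets(windows, p, schedule, targets.temperature,
                                    bins=bins, min_count=min_count)
        return np.array([act - targets.dg_act_ref, rxn - targets.dg_rxn_ref])

    def try_residual(a, dalpha):
        try:
            return residual(a, dalpha)
        except NoBarrierError:
            return None

    a, dalpha = float(initial_guess[0]), float(initial_guess[1])
    if a < 0:
        warnings.warn("negative initial coupling clamped to 0")
        a = 0.0
    res = try_residual(a, dalpha)
    for _ in range(20):
        # an over-strong coupling washes out the barrier entirely; back A
        # off until the profile has a transition state to calibrate on
        if res is not None:
            break
        warnings.warn(f"no barrier at A = {a:.3f}; halving the coupling")
        a *= 0.5
        res = try_residual(a, dalpha)
    if res is None:
        raise CalibrationError("no barrier at any probed coupling",
                               EVBParameters(A=a, delta_alpha=dalpha), None)
    best = (a, dalpha, res)
    tol = targets.tolerance

    for it in range(1, max_iter + 1):
        if np.abs(res).max() <= tol:
            audit_act, audit_rxn = evaluate_targets(
                windows, EVBParameters(A=a, delta_alpha=dalpha), schedule,
                targets.temperature, bins=bins, min_count=min_count)
            audit = np.array([audit_act - targets.dg_act_ref,
                              audit_rxn - targets.dg_rxn_ref])
            if np.abs(audit).max() > tol:  # pragma: no cover - audit guard
                raise CalibrationError(
                    "post-condition audit failed", EVBParameters(
                        A=a, delta_alpha=dalpha), tuple(audit))
            return CalibrationResult(
                params=EVBParameters(A=a, delta_alpha=dalpha),
                dg_act=audit_act, dg_rxn=audit_rxn, residuals=tuple(audit),
                iterations=it - 1, converged=True)

        def fd_column(probe_fwd, probe_bwd):
            """forward difference, falling back to backward when the
            forward probe lands in a barrier-free region"""
            r_fwd = try_residual(*probe_fwd)
            if r_fwd is not None:
                return (r_fwd - res) / fd_step
            r_bwd = try_residual(*probe_bwd)
            if r_bwd is not None:
                return (res - r_bwd) / fd_step
            return np.zeros(2)

        jac = np.empty((2, 2))
        jac[:, 0] = fd_column((a + fd_step, dalpha),
                              (max(a - fd_step, 0.0), dalpha))
        jac[:, 1] = fd_column((a, dalpha + fd_step), (a, dalpha - fd_step))
        with warnings.catch_warnings():
            warnings.simplefilter("error", LinAlgWarning)
            try:
                step = solve(jac, -res)
            except Exception as err:
                raise CalibrationError(
                    f"singular Jacobian at iteration {it}: {err}",
                    EVBParameters(A=best[0], delta_alpha=best[1]),
                    tuple(best[2])) from err

        damping = 1.0
        a_new, d_new, res_new = a, dalpha, res
        for _ in range(8):
            a_try = a + damping * step[0]
            d_try = dalpha + damping * step[1]
            if a_try < 0:
                warnings.warn("negative-A excursion clamped to 0")
                a_try = 0.0
            res_try = try_residual(a_try, d_try)
            if res_try is not None:
                a_new, d_new, res_new = a_try, d_try, res_try
                if np.linalg.norm(res_try) < np.linalg.norm(res):
                    break
            damping *= 0.5
        a, dalpha, res = a_new, d_new, res_new
        if np.linalg.norm(res) < np.linalg.norm(best[2]):
            best = (a, dalpha, res)

    raise CalibrationError(
        f"no convergence within {max_iter} iterations "
        f"(best residuals {tuple(np.round(best[2], 4))})",
        EVBParameters(A=best[0], delta_alpha=best[1]), tuple(best[2]))
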