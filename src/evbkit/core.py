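"""Two-state EVB energy algebra.

The empirical valence bond (EVB) model represents an elementary reaction
step by a 2x2 Hamiltonian whose diagonal elements are the classical
force-field energies of the reactant (``eps1``) and product (``eps2``)
valence states, the product diabat carrying a constant gas-phase shift
``delta_alpha``.  The off-diagonal coupling ``H12`` mixes the two states
and the reacting system moves on the lowest eigenvalue (the adiabatic
ground state).  Everything in this module is pure, unit-consistent
scalar/array algebra in kcal/mol; kJ/mol appears only at file-format
boundaries (see :mod:`evbkit.xvg` and :mod:`evbkit.topology`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EVBParameters",
    "FrameEnergies",
    "MorseParams",
    "SoftRepulsionParams",
    "ground_state_energy",
    "coupling_value",
    "mapping_potential",
    "morse_energy",
    "soft_repulsion_energy",
    "diagonal_energies",
    "KCAL_PER_KJ",
    "KJ_PER_KCAL",
    "BOLTZMANN_KCAL",
]

#: Boltzmann constant, kcal mol^-1 K^-1.
BOLTZMANN_KCAL = 0.0019872041

KJ_PER_KCAL = 4.184
KCAL_PER_KJ = 1.0 / KJ_PER_KCAL


@dataclass(frozen=True)
class EVBParameters:
    """Coupling-element parameters and gas-phase shift.

    The coupling takes the form ``A * exp(-mu*(r-r0) - eta*(r-r0)**2)``
    over a caller-chosen coordinate ``r`` (an interatomic distance or the
    energy gap).  With ``mu = eta = 0`` the coupling is the flat constant
    ``A``, which is the form used for calibrated models here.

    Parameters
    ----------
    A : float
        Coupling amplitude, kcal/mol.  Must be >= 0.
    mu : float
        Linear decay coefficient (per coordinate unit).
    eta : float
        Gaussian decay coefficient (per squared coordinate unit). >= 0.
    r0 : float
        Reference coordinate value.
    delta_alpha : float
        Gas-phase shift added to the product diabat, kcal/mol.
    """

    A: float = 0.0
    mu: float = 0.0
    eta: float = 0.0
    r0: float = 0.0
    delta_alpha: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.A, self.mu, self.eta, self.r0, self.delta_alpha]).all():
            raise ValueError("EVBParameters fields must be finite")
        if self.A < 0:
            raise ValueError(f"coupling amplitude A must be >= 0, got {self.A}")
        if self.eta < 0:
            raise ValueError(f"Gaussian decay eta must be >= 0, got {self.eta}")

    @property
    def is_constant_coupling(self) -> bool:
        return self.mu == 0.0 and self.eta == 0.0

    def replace(self, **kwargs) -> "EVBParameters":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass(frozen=True)
class FrameEnergies:
    """Per-frame diabatic energies (kcal/mol).

    ``eps2`` is the raw product-state force-field energy *before* the
    gas-phase shift; ``H22 = eps2 + delta_alpha`` is formed on demand so
    stored trajectories remain valid under recalibration.  ``r`` is an
    optional coupling coordinate (distance or gap) recorded alongside.
    """

    eps1: float
    eps2: float
    r: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eps1) and np.isfinite(self.eps2)):
            raise ValueError("frame energies must be finite")


@dataclass(frozen=True)
class MorseParams:
    """Morse bond parameters: well depth D (kcal/mol), stiffness a
    (1/distance), equilibrium distance r_eq."""

    D: float
    a: float
    r_eq: float

    def __post_init__(self) -> None:
        if not (self.D > 0 and self.a > 0 and self.r_eq > 0):
            raise ValueError("MorseParams require D > 0, a > 0, r_eq > 0")


@dataclass(frozen=True)
class SoftRepulsionParams:
    """Soft exponential repulsion ``C * exp(-beta_rep * r)`` replacing the
    6-12 van der Waals term between atoms whose bonding changes."""

    C: float = 1.0
    beta_rep: float = 1.0

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.beta_rep > 0):
            raise ValueError("SoftRepulsionParams require C > 0, beta_rep > 0")


def ground_state_energy(h11, h22, h12):
    """Lowest eigenvalue of the two-state secular equation.

    ``Eg = (h11 + h22)/2 - sqrt((h11 - h22)^2 + 4 h12^2)/2``

    Accepts scalars or broadcastable arrays.  ``Eg <= min(h11, h22)``
    always, with equality iff ``h12 == 0``.
    """
    h11 = np.asarray(h11, dtype=float)
    h22 = np.asarray(h22, dtype=float)
    h12 = np.asarray(h12, dtype=float)
    if not (np.isfinite(h11).all() and np.isfinite(h22).all() and np.isfinite(h12).all()):
        raise ValueError("ground_state_energy requires finite inputs")
    eg = 0.5 * (h11 + h22) - 0.5 * np.hypot(h11 - h22, 2.0 * h12)
    return eg if eg.ndim else float(eg)


def coupling_value(r, params: EVBParameters):
    """Coupling element ``A exp(-mu (r-r0) - eta (r-r0)^2)`` at coordinate r.

    With ``mu = eta = 0`` this is the flat constant A for every r.
    """
    r = np.asarray(r, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("coupling coordinate must be finite")
    dr = r - params.r0
    out = params.A * np.exp(-params.mu * dr - params.eta * dr * dr)
    return out if out.ndim else float(out)


def mapping_potential(frame, lam: float, delta_alpha: float = 0.0):
    """Mapping potential ``V(lam) = (1-lam) eps1 + lam (eps2 + delta_alpha)``.

    ``frame`` may be a :class:`FrameEnergies` or a ``(eps1, eps2)`` pair of
    scalars/arrays.  ``lam`` must lie in [0, 1]: lam=0 is the pure reactant
    state and lam=1 the pure (shifted) product state.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if isinstance(frame, FrameEnergies):
        eps1, eps2 = frame.eps1, frame.eps2
    else:
        eps1, eps2 = frame
    eps1 = np.asarray(eps1, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    v = (1.0 - lam) * eps1 + lam * (eps2 + delta_alpha)
    return v if v.ndim else float(v)


def morse_energy(r, p: MorseParams):
    """Morse potential ``D (1 - exp(-a (r - r_eq)))^2``.

    Zero at ``r = r_eq``; tends to the dissociation plateau D as r grows.
    Requires r > 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Morse potential requires r > 0")
    u = 1.0 - np.exp(-p.a * (r - p.r_eq))
    out = p.D * u * u
    return out if out.ndim else float(out)


def soft_repulsion_energy(r, p: SoftRepulsionParams):
    """Soft repulsion ``C exp(-beta_rep r)``: strictly positive and strictly
    decreasing in r.  Requires r >= 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("soft repulsion requires r >= 0")
    out = p.C * np.exp(-p.beta_rep * r)
    return out if out.ndim else float(out)


def diagonal_energies(frame, params: EVBParameters):
    """Diagonal Hamiltonian elements ``(H11, H22) = (eps1, eps2 + delta_alpha)``."""
    if isinstance(frame, FrameEnergies):
        eps1, eps2 = frame.eps1, frame.eps2
    else:
        eps1, eps2 = frame
    return eps1, eps2 + params.delta_alpha
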