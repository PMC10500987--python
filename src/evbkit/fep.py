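"""Free-energy profiles on the energy-gap coordinate.

Windowed (eps1, eps2) trajectories sampled on mapping potentials
``V(lam) = (1-lam) eps1 + lam (eps2 + delta_alpha)`` are turned into a
ground-state free-energy profile in three steps:

1. :func:`mapping_free_energies` — Zwanzig exponential averaging between
   adjacent lambda windows, averaged over the forward and backward
   directions to cancel hysteresis, giving the cumulative free energy
   ``dG(lam_m)`` on the mapping potential.
2. :func:`umbrella_profile` — per-window, per-bin umbrella correction
   ``dG(lam_m) - kT ln < 1_s exp(-beta (Eg - V_m)) >_m`` projecting from
   the mapping potential onto the adiabatic ground state ``Eg``.
3. :func:`combine_bins` — count-weighted average over windows per bin,
   normalized so the reactant-side minimum is zero.

The reaction coordinate is the generalized energy gap
``Xs = eps1 - (eps2 + delta_alpha)``: the reactant basin (sampled at
lam = 0, where eps1 is low and eps2 high) sits at negative Xs and the
product basin at positive Xs.  The per-frame FEP perturbation uses the
opposite-sign gap ``d_eps = (eps2 + delta_alpha) - eps1 = -Xs``, because
``V_{n+1} - V_n = d_eps * d_lam`` for the linear mapping potential.

All exponential averages go through scipy's log-sum-exp, so finite
input can never produce non-finite output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import BOLTZMANN_KCAL, EVBParameters, coupling_value, ground_state_energy

__all__ = [
    "LambdaSchedule",
    "FreeEnergyProfile",
    "ReactionSummary",
    "BinAssignment",
    "AnalysisError",
    "NoBarrierError",
    "mapping_free_energies",
    "bin_frames",
    "umbrella_profile",
    "combine_bins",
    "extract_barriers",
    "gap_profile",
]

DEFAULT_BINS = 50
DEFAULT_MIN_COUNT = 30


class AnalysisError(ValueError):
    """Raised for invalid analysis inputs (empty windows, bad schedule...)."""


class NoBarrierError(AnalysisError):
    """Raised when a profile has no interior maximum to call a barrier."""


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered lambda values defining the FEP path from reactants (0) to
    products (1); strictly increasing."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or len(vals) < 2:
            raise AnalysisError("lambda schedule needs at least two values")
        if vals[0] != 0.0 or vals[-1] != 1.0:
            raise AnalysisError("lambda schedule must start at 0 and end at 1")
        if np.any(np.diff(vals) <= 0):
            raise AnalysisError("lambda schedule must be strictly increasing")

    @classmethod
    def uniform(cls, n_windows: int = 51) -> "LambdaSchedule":
        """Uniform schedule with ``n_windows`` points, 0 to 1 inclusive.
        The 51-window schedule is the conventional default."""
        if n_windows < 2:
            raise AnalysisError("need at least 2 windows")
        return cls(np.linspace(0.0, 1.0, n_windows))

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


@dataclass
class FreeEnergyProfile:
    """Binned ground-state free energy vs the gap coordinate Xs.

    ``valid`` flags bins meeting the minimum-count cutoff; low-count bins
    are kept (flagged, not dropped) so callers can inspect them.
    ``delta_g`` is normalized so the reactant-side minimum is zero when
    ``normalization == "reactant-min-zero"``.
    """

    bin_centers: np.ndarray
    delta_g: np.ndarray
    counts: np.ndarray
    valid: np.ndarray
    normalization: str = "reactant-min-zero"

    def __post_init__(self) -> None:
        n = len(self.bin_centers)
        if not (len(self.delta_g) == len(self.counts) == len(self.valid) == n):
            raise AnalysisError("profile arrays must share one length")


@dataclass(frozen=True)
class ReactionSummary:
    """Activation and reaction free energies read off a profile."""

    dg_act: float       # barrier, TS max minus reactant minimum (kcal/mol)
    dg_rxn: float       # product minimum minus reactant minimum (kcal/mol)
    ts_bin: float       # gap value at the maximum
    rs_bin: float       # gap value at the reactant-side minimum
    ps_bin: float       # gap value at the product-side minimum


@dataclass
class BinAssignment:
    """Uniform binning of every frame's gap value.

    ``indices[m]`` holds the bin index of each frame of window m;
    ``counts[m, s]`` the number of window-m frames in bin s.
    """

    edges: np.ndarray
    centers: np.ndarray
    indices: list = field(repr=False, default_factory=list)
    counts: np.ndarray = None

    @property
    def n_bins(self) -> int:
        return len(self.centers)


def _window_arrays(window):
    """Return (lam, eps1, eps2) arrays for a window record (duck-typed:
    WindowTrajectory or anything with .lam/.eps1/.eps2)."""
    eps1 = np.asarray(window.eps1, dtype=float)
    eps2 = np.asarray(window.eps2, dtype=float)
    return float(window.lam), eps1, eps2


def gap_values(window, delta_alpha: float) -> np.ndarray:
    """Generalized reaction coordinate ``Xs = eps1 - (eps2 + delta_alpha)``
    for every frame of the window."""
    _, eps1, eps2 = _window_arrays(window)
    return eps1 - (eps2 + delta_alpha)


def _exp_average_free_energy(a: np.ndarray, beta: float) -> float:
    """-kT ln < exp(a) > evaluated through log-sum-exp."""
    return -(logsumexp(a) - np.log(len(a))) / beta


def mapping_free_energies(windows, schedule: LambdaSchedule, delta_alpha: float,
                          temperature: float) -> np.ndarray:
    """Cumulative free energy dG(lam_m) along the mapping potential.

    For each adjacent pair (n, n+1) the forward estimate is the
    exponential average of ``-beta (V_{n+1} - V_n)`` over window n and
    the backward estimate the negated exponential average of
    ``-beta (V_n - V_{n+1})`` over window n+1; the per-step free energy
    is their arithmetic mean.  ``V_{n+1} - V_n = d_eps * d_lam`` frame
    by frame, with ``d_eps = (eps2 + delta_alpha) - eps1``.

    Returns an array of the same length as the schedule, anchored at
    ``dG(lam=0) = 0``.
    """
    if temperature <= 0:
        raise AnalysisError("temperature must be positive")
    if len(windows) != len(schedule):
        raise AnalysisError(
            f"{len(windows)} windows for a {len(schedule)}-point schedule")
    if len(windows) < 2:
        raise AnalysisError("need at least 2 windows")
    beta = 1.0 / (BOLTZMANN_KCAL * temperature)

    d_eps = []
    for m, w in enumerate(windows):
        _, eps1, eps2 = _window_arrays(w)
        if eps1.size == 0:
            raise AnalysisError(f"window {m} has no frames")
        d_eps.append((eps2 + delta_alpha) - eps1)

    lams = schedule.values
    dg = np.zeros(len(lams))
    for n in range(len(lams) - 1):
        dlam = lams[n + 1] - lams[n]
        fwd = _exp_average_free_energy(-beta * dlam * d_eps[n], beta)
        bwd = -_exp_average_free_energy(beta * dlam * d_eps[n + 1], beta)
        dg[n + 1] = dg[n] + 0.5 * (fwd + bwd)
    return dg


def bin_frames(windows, delta_alpha: float, bins: int = DEFAULT_BINS,
               edges: np.ndarray | None = None) -> BinAssignment:
    """Assign every frame its gap value and a uniform bin index.

    Bins span the observed gap range unless explicit ``edges`` are given
    (used to analyze several replicas on a common grid).  A degenerate
    range (all gaps identical) falls back to a single bin with a warning.
    Frames outside explicit edges are dropped from the counts.
    """
    gaps = [gap_values(w, delta_alpha) for w in windows]
    if sum(g.size for g in gaps) == 0:
        raise AnalysisError("no frames to bin")

    if edges is None:
        lo = min(g.min() for g in gaps)
        hi = max(g.max() for g in gaps)
        if lo == hi:
            warnings.warn("all gap values identical; using a single bin")
            edges = np.array([lo - 0.5, lo + 0.5])
        else:
            edges = np.linspace(lo, hi, bins + 1)
    else:
        edges = np.asarray(edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)

    asn = BinAssignment(edges=edges, centers=centers)
    counts = np.zeros((len(windows), n_bins), dtype=int)
    for m, g in enumerate(gaps):
        idx = np.digitize(g, edges) - 1
        idx[g == edges[-1]] = n_bins - 1  # right edge inclusive
        idx[(idx < 0) | (idx >= n_bins)] = -1
        asn.indices.append(idx)
        inside = idx >= 0
        counts[m] = np.bincount(idx[inside], minlength=n_bins)
    asn.counts = counts
    return asn


def umbrella_profile(windows, params: EVBParameters, schedule: LambdaSchedule,
                     temperature: float, binning: BinAssignment,
                     dg_map: np.ndarray | None = None) -> np.ndarray:
    """Per-(window, bin) free-energy contributions.

    For window m and bin s, the contribution is

        ``dG(lam_m) - kT ln < 1_s exp(-beta (Eg - V_m)) >_m``

    i.e. the exponential term summed over window-m frames falling in bin
    s but normalized by the window's *total* frame count (``1_s`` is the
    bin indicator), with ``Eg`` from the two-state secular equation
    (H11 = eps1, H22 = eps2 + delta_alpha, H12 from the coupling element)
    and V_m the window's mapping potential.  The whole-window
    normalization makes every window's contribution an estimate of the
    same quantity, ``-kT ln`` (ground-state Boltzmann mass of bin s)
    up to one global constant, so the count-weighted combination across
    windows is consistent with the quadrature oracle.  A conditional
    (per-bin-count) normalization would instead carry a window-dependent
    ``kT ln P_m(s)`` term that does not fully cancel.  Entries for
    (window, bin) pairs with no frames are NaN (absent, not zero).
    """
    if dg_map is None:
        dg_map = mapping_free_energies(windows, schedule, params.delta_alpha,
                                       temperature)
    beta = 1.0 / (BOLTZMANN_KCAL * temperature)
    n_bins = binning.n_bins
    contrib = np.full((len(windows), n_bins), np.nan)

    for m, w in enumerate(windows):
        lam, eps1, eps2 = _window_arrays(w)
        h22 = eps2 + params.delta_alpha
        if params.is_constant_coupling:
            h12 = params.A
        else:
            r = getattr(w, "r", None)
            coord = np.asarray(r, dtype=float) if r is not None else eps1 - h22
            h12 = coupling_value(coord, params)
        eg = ground_state_energy(eps1, h22, h12)
        vm = (1.0 - lam) * eps1 + lam * h22
        a = -beta * (eg - vm)
        idx = binning.indices[m]
        log_n_m = np.log(len(idx))
        for s in np.unique(idx[idx >= 0]):
            sel = idx == s
            contrib[m, s] = dg_map[m] - (logsumexp(a[sel]) - log_n_m) / beta
    return contrib


def _reactant_side_minimum(centers, dg, valid):
    """Index of the reactant-side minimum: the lowest point left of the
    global maximum of the valid profile; falls back to the global minimum
    when there is no interior maximum."""
    vi = np.flatnonzero(valid)
    imax = vi[np.argmax(dg[vi])]
    left = vi[vi < imax]
    if left.size == 0:
        return vi[np.argmin(dg[vi])]
    return left[np.argmin(dg[left])]


def combine_bins(contributions: np.ndarray, counts: np.ndarray,
                 centers: np.ndarray, min_count: int = DEFAULT_MIN_COUNT,
                 normalize: bool = True) -> FreeEnergyProfile:
    """Count-weighted combination of per-window bin contributions.

    Per bin s, ``dG(Xs) = sum_m p_m dG_m(Xs)`` with
    ``p_m = count(m, s) / sum_m' count(m', s)`` over contributing
    windows.  Bins whose total count falls below ``min_count`` are
    flagged invalid; bins with no contributing window are excluded with
    a warning.  The profile is then shifted so the reactant-side minimum
    of the valid bins is zero.
    """
    if contributions.shape != counts.shape:
        raise AnalysisError("contributions and counts must share a shape")
    n_bins = contributions.shape[1]
    dg = np.full(n_bins, np.nan)
    total = counts.sum(axis=0)
    for s in range(n_bins):
        have = (~np.isnan(contributions[:, s])) & (counts[:, s] > 0)
        if not have.any():
            continue
        p = counts[have, s] / counts[have, s].sum()
        dg[s] = p @ contributions[have, s]
    empty = (total > 0) & np.isnan(dg)
    if empty.any():
        warnings.warn(f"{empty.sum()} bins had counts but no contributions; excluded")
    valid = (total >= min_count) & ~np.isnan(dg)
    if not valid.any():
        raise AnalysisError("no bin meets the minimum-count cutoff")
    if normalize:
        rs = _reactant_side_minimum(centers, np.where(np.isnan(dg), np.inf, dg), valid)
        dg = dg - dg[rs]
    return FreeEnergyProfile(bin_centers=np.asarray(centers, float), delta_g=dg,
                             counts=total, valid=valid)


def extract_barriers(profile: FreeEnergyProfile) -> ReactionSummary:
    """Locate reactant minimum, transition-state maximum and product
    minimum on the valid bins and return dG_act / dG_rxn.

    The transition state is the global maximum of the valid profile; the
    reactant-side minimum is the lowest valid bin at smaller gap and the
    product-side minimum the lowest at larger gap.  Ties break toward the
    smaller ``|gap|`` bin.  A profile whose maximum sits at either end has
    no barrier and raises :class:`NoBarrierError`.
    """
    vi = np.flatnonzero(profile.valid)
    if len(vi) < 3:
        raise AnalysisError("need at least 3 valid bins")
    dg = profile.delta_g
    x = profile.bin_centers

    def _pick(cands, values, best):
        """indices in cands where values == best, tie-broken to min |x|."""
        hit = cands[values == best]
        return hit[np.argmin(np.abs(x[hit]))]

    imax = _pick(vi, dg[vi], dg[vi].max())
    left, right = vi[vi < imax], vi[vi > imax]
    if left.size == 0 or right.size == 0:
        raise NoBarrierError("profile is monotone: no interior maximum")
    irs = _pick(left, dg[left], dg[left].min())
    ips = _pick(right, dg[right], dg[right].min())
    return ReactionSummary(dg_act=float(dg[imax] - dg[irs]),
                           dg_rxn=float(dg[ips] - dg[irs]),
                           ts_bin=float(x[imax]), rs_bin=float(x[irs]),
                           ps_bin=float(x[ips]))


def gap_profile(windows, params: EVBParameters, schedule: LambdaSchedule,
                temperature: float, bins: int = DEFAULT_BINS,
                min_count: int = DEFAULT_MIN_COUNT,
                edges: np.ndarray | None = None) -> FreeEnergyProfile:
    """Full pipeline: mapping FEP, binning, umbrella correction, weighted
    combination.  Convenience wrapper used by calibration and the CLI."""
    binning = bin_frames(windows, params.delta_alpha, bins=bins, edges=edges)
    contrib = umbrella_profile(windows, params, schedule, temperature, binning)
    return combine_bins(contrib, binning.counts, binning.centers,
                        min_count=min_count)
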