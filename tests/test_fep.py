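"""Tests for mapping FEP, umbrella projection and bin combination."""

import numpy as np
import pytest

from evbkit.core import BOLTZMANN_KCAL, EVBParameters, ground_state_energy
from evbkit.fep import (
    AnalysisError,
    FreeEnergyProfile,
    LambdaSchedule,
    NoBarrierError,
    bin_frames,
    combine_bins,
    extract_barriers,
    gap_profile,
    mapping_free_energies,
    umbrella_profile,
)
from evbkit.toy import WindowTrajectory

TEMP = 300.0
BETA = 1.0 / (BOLTZMANN_KCAL * TEMP)


def _constant_gap_windows(schedule, gap, n=50, eps1=0.0):
    """Windows whose every frame has eps2 - eps1 = gap."""
    return [WindowTrajectory(lam=float(l), eps1=np.full(n, eps1),
                             eps2=np.full(n, eps1 + gap))
            for l in schedule]


class TestLambdaSchedule:
    def test_uniform_endpoints(self):
        s = LambdaSchedule.uniform(51)
        assert len(s) == 51 and s.values[0] == 0.0 and s.values[-1] == 1.0

    @pytest.mark.parametrize("vals", [[0.0, 0.5], [0.5, 1.0],
                                      [0.0, 0.6, 0.5, 1.0], [0.0]])
    def test_invalid_schedules_rejected(self, vals):
        with pytest.raises(AnalysisError):
            LambdaSchedule(np.array(vals))


class TestMappingFreeEnergies:
    def test_zero_variance_identity(self):
        # constant gap c: the exponential average collapses and the
        # cumulative free energy at lambda=1 equals c exactly
        sched = LambdaSchedule.uniform(11)
        c = 7.3
        dg = mapping_free_energies(_constant_gap_windows(sched, c), sched,
                                   0.0, TEMP)
        assert dg[0] == 0.0
        assert dg[-1] == pytest.approx(c, abs=1e-10)

    def test_gaussian_step_closed_form(self):
        # gap ~ N(mu, s^2): forward step estimate -> dlam*mu - beta*dlam^2*s^2/2
        rng = np.random.default_rng(8)
        mu, s, dlam = 10.0, 4.0, 0.1
        n = 400_000
        sched = LambdaSchedule(np.array([0.0, dlam, 1.0]))
        gaps = rng.normal(mu, s, size=n)
        w0 = WindowTrajectory(0.0, np.zeros(n), gaps)
        # zero-variance middle window: its backward estimate is exactly
        # dlam*g1, so the forward estimate can be extracted from the mean
        g1 = 3.0
        w1 = WindowTrajectory(dlam, np.zeros(4), np.full(4, g1))
        w2 = WindowTrajectory(1.0, np.zeros(2), np.full(2, mu))
        dg = mapping_free_energies([w0, w1, w2], sched, 0.0, TEMP)
        fwd = 2.0 * dg[1] - dlam * g1
        expected = dlam * mu - BETA * dlam**2 * s**2 / 2.0
        assert fwd == pytest.approx(expected, abs=0.02)

    def test_symmetric_hysteresis_cancels(self):
        # identical gap distributions in adjacent windows: the mean of the
        # forward and backward estimates collapses to dlam * mean(gap)
        rng = np.random.default_rng(8)
        mu, s, dlam = 10.0, 4.0, 0.1
        gaps = rng.normal(mu, s, size=400_000)
        sched = LambdaSchedule(np.array([0.0, dlam, 1.0]))
        w0 = WindowTrajectory(0.0, np.zeros(gaps.size), gaps)
        w1 = WindowTrajectory(dlam, np.zeros(gaps.size), gaps)
        w2 = WindowTrajectory(1.0, np.zeros(2), np.full(2, mu))
        dg = mapping_free_energies([w0, w1, w2], sched, 0.0, TEMP)
        # the Gaussian variance terms cancel between the directions; the
        # residual is the higher-order sampling asymmetry
        assert dg[1] == pytest.approx(dlam * mu, abs=0.01)

    def test_gas_shift_adds_exactly_delta(self):
        rng = np.random.default_rng(3)
        sched = LambdaSchedule.uniform(6)
        wins = [WindowTrajectory(float(l), rng.normal(0, 2, 100),
                                 rng.normal(5, 2, 100)) for l in sched]
        base = mapping_free_energies(wins, sched, 0.0, TEMP)
        shifted = mapping_free_energies(wins, sched, 12.5, TEMP)
        assert shifted[-1] - base[-1] == pytest.approx(12.5, abs=1e-10)
        # hysteresis pattern (differences between steps) is unchanged
        assert np.allclose(np.diff(shifted) - np.diff(base),
                           12.5 * np.diff(sched.values), atol=1e-10)

    def test_reversed_frames_negate_total(self):
        rng = np.random.default_rng(4)
        sched = LambdaSchedule.uniform(6)
        wins = [WindowTrajectory(float(l), rng.normal(0, 1, 200),
                                 rng.normal(3, 1, 200)) for l in sched]
        fwd = mapping_free_energies(wins, sched, 0.0, TEMP)[-1]
        # reverse the path: relabel window m as 1-lambda and swap states
        rev = [WindowTrajectory(1.0 - w.lam, w.eps2, w.eps1)
               for w in reversed(wins)]
        bwd = mapping_free_energies(rev, sched, 0.0, TEMP)[-1]
        assert bwd == pytest.approx(-fwd, abs=1e-10)

    def test_empty_window_named_in_error(self):
        sched = LambdaSchedule.uniform(3)
        wins = _constant_gap_windows(sched, 1.0)
        with pytest.raises(ValueError):
            WindowTrajectory(0.5, np.array([]), np.array([]))
        with pytest.raises(AnalysisError, match="schedule"):
            mapping_free_energies(wins[:2], sched, 0.0, TEMP)


class TestBinning:
    def test_three_gaps_three_bins(self):
        w = WindowTrajectory(0.0, np.array([0.0, 0.0, 0.0]),
                             np.array([1.0, 0.0, -1.0]))
        asn = bin_frames([w], 0.0, bins=3)
        assert np.array_equal(asn.counts, [[1, 1, 1]])

    def test_degenerate_range_single_bin(self):
        w = WindowTrajectory(0.0, np.zeros(5), np.ones(5))
        with pytest.warns(UserWarning, match="single bin"):
            asn = bin_frames([w], 0.0)
        assert asn.n_bins == 1 and asn.counts.sum() == 5

    def test_counts_conserved(self, windows_one_replica):
        asn = bin_frames(windows_one_replica, 0.0)
        total = sum(w.n_frames for w in windows_one_replica)
        assert asn.counts.sum() == total


class TestUmbrella:
    def test_logsumexp_matches_direct_average(self):
        # the stabilized evaluation must agree with the naive ratio
        # sum(exp(-beta Eg)) / sum(exp(-beta Vm)) ... identity to 1e-10
        rng = np.random.default_rng(12)
        sched = LambdaSchedule.uniform(3)
        params = EVBParameters(A=2.0, delta_alpha=1.0)
        wins = [WindowTrajectory(float(l), rng.normal(0, 1, 300),
                                 rng.normal(2, 1, 300)) for l in sched]
        binning = bin_frames(wins, params.delta_alpha, bins=5)
        dg_map = mapping_free_energies(wins, sched, params.delta_alpha, TEMP)
        contrib = umbrella_profile(wins, params, sched, TEMP, binning, dg_map)
        m = 1
        w = wins[m]
        h22 = w.eps2 + params.delta_alpha
        eg = ground_state_energy(w.eps1, h22, params.A)
        vm = (1 - w.lam) * w.eps1 + w.lam * h22
        idx = binning.indices[m]
        for s in np.unique(idx):
            sel = idx == s
            direct = dg_map[m] - np.log(
                np.sum(np.exp(-BETA * (eg[sel] - vm[sel]))) / len(idx)) / BETA
            assert contrib[m, s] == pytest.approx(direct, rel=1e-10)

    def test_absent_bins_are_nan(self):
        sched = LambdaSchedule.uniform(2)
        w0 = WindowTrajectory(0.0, np.zeros(10), np.full(10, -5.0))
        w1 = WindowTrajectory(1.0, np.zeros(10), np.full(10, 5.0))
        binning = bin_frames([w0, w1], 0.0, bins=4)
        contrib = umbrella_profile([w0, w1], EVBParameters(A=1.0), sched,
                                   TEMP, binning)
        assert np.isnan(contrib[0, binning.indices[1][0]])


class TestCombine:
    def test_single_window_passthrough_and_equal_count_mean(self):
        centers = np.array([-1.0, 0.0, 1.0])
        contrib = np.array([[0.0, 5.0, np.nan],
                            [np.nan, 7.0, 2.0]])
        counts = np.array([[10, 10, 0],
                           [0, 10, 10]])
        prof = combine_bins(contrib, counts, centers, min_count=1,
                            normalize=False)
        assert prof.delta_g[0] == pytest.approx(0.0)    # one window only
        assert prof.delta_g[1] == pytest.approx(6.0)    # equal-count mean
        assert prof.delta_g[2] == pytest.approx(2.0)

    def test_weights_are_count_ratios(self):
        centers = np.array([0.0])
        contrib = np.array([[4.0], [8.0]])
        counts = np.array([[30], [10]])
        prof = combine_bins(contrib, counts, centers, min_count=1,
                            normalize=False)
        assert prof.delta_g[0] == pytest.approx(0.75 * 4.0 + 0.25 * 8.0)

    def test_low_count_bins_flagged(self):
        centers = np.array([-1.0, 0.0, 1.0])
        contrib = np.array([[0.0, 5.0, 2.0]])
        counts = np.array([[100, 3, 100]])
        prof = combine_bins(contrib, counts, centers, min_count=30)
        assert list(prof.valid) == [True, False, True]


class TestExtractBarriers:
    def _profile(self, dg, valid=None):
        dg = np.asarray(dg, dtype=float)
        n = len(dg)
        return FreeEnergyProfile(np.linspace(-1, 1, n), dg,
                                 np.full(n, 100.0),
                                 np.ones(n, bool) if valid is None else valid)

    def test_simple_barrier(self):
        s = extract_barriers(self._profile([0.0, 5.0, 2.0]))
        assert (s.dg_act, s.dg_rxn) == (5.0, 2.0)

    def test_symmetric_profile_zero_reaction(self):
        s = extract_barriers(self._profile([0.0, 5.0, 0.0]))
        assert s.dg_rxn == 0.0 and s.dg_act == 5.0

    def test_monotone_profile_has_no_barrier(self):
        with pytest.raises(NoBarrierError):
            extract_barriers(self._profile([0.0, 1.0, 2.0, 3.0]))

    def test_invalid_bins_ignored(self):
        s = extract_barriers(self._profile(
            [9.0, 0.0, 5.0, 2.0, 9.0],
            valid=np.array([False, True, True, True, False])))
        assert (s.dg_act, s.dg_rxn) == (5.0, 2.0)


class TestProfileInvariances:
    def test_uniform_energy_shift_leaves_profile_summary(self, windows_one_replica,
                                                         schedule51, toy_model):
        params = toy_model.coupling
        base = extract_barriers(gap_profile(windows_one_replica, params,
                                            schedule51, TEMP))
        shifted_windows = [WindowTrajectory(w.lam, w.eps1 + 50.0,
                                            w.eps2 + 50.0, w.r)
                           for w in windows_one_replica]
        shifted = extract_barriers(gap_profile(shifted_windows, params,
                                               schedule51, TEMP))
        assert shifted.dg_act == pytest.approx(base.dg_act, abs=1e-8)
        assert shifted.dg_rxn == pytest.approx(base.dg_rxn, abs=1e-8)

    def test_reanalysis_without_resampling(self, windows_one_replica,
                                           schedule51):
        # two different (A, delta_alpha) values, same stored frames
        for a, da in [(10.0, 2.0), (18.0, -3.0)]:
            prof = gap_profile(windows_one_replica,
                               EVBParameters(A=a, delta_alpha=da),
                               schedule51, TEMP)
            s = extract_barriers(prof)
            assert np.isfinite(s.dg_act) and np.isfinite(s.dg_rxn)
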