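"""Tests for the toy two-diabat model, Metropolis sampler and oracle."""

import numpy as np
import pytest

from evbkit.core import BOLTZMANN_KCAL, EVBParameters, MorseParams
from evbkit.fep import LambdaSchedule, extract_barriers
from evbkit.toy import (
    DiabatSpec,
    SamplerConfig,
    SamplerError,
    ToyEVBModel,
    default_model,
    diabatic_energies,
    exact_gap_profile,
    run_fep_schedule,
    sample_window,
)


def _harmonic_model(k=1.0, off2=0.0):
    return ToyEVBModel(DiabatSpec("harmonic", k=k, x0=0.0),
                       DiabatSpec("harmonic", k=k, x0=1.0, offset=off2),
                       EVBParameters(A=0.0), (-3.0, 4.0))


class TestDiabaticEnergies:
    def test_harmonic_values(self):
        m = _harmonic_model(k=1.0)
        f = diabatic_energies(0.0, m)
        assert (f.eps1, f.eps2, f.r) == (0.0, pytest.approx(0.5), 0.0)

    def test_minimum_returns_offset(self):
        m = ToyEVBModel(DiabatSpec("harmonic", k=7.0, x0=0.3, offset=2.5),
                        DiabatSpec("harmonic", k=7.0, x0=1.0),
                        EVBParameters(), (-1.0, 2.0))
        assert diabatic_energies(0.3, m).eps1 == pytest.approx(2.5)

    def test_morse_matches_closed_form_on_grid(self):
        p = MorseParams(D=90.0, a=1.8, r_eq=1.1)
        m = ToyEVBModel(DiabatSpec("morse", morse=p),
                        DiabatSpec("harmonic", k=10.0, x0=2.0),
                        EVBParameters(), (0.2, 3.0))
        for x in np.linspace(0.3, 2.9, 25):
            expected = 90.0 * (1 - np.exp(-1.8 * (x - 1.1))) ** 2
            assert diabatic_energies(x, m).eps1 == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diabatic_energies(10.0, _harmonic_model())


class TestSampler:
    def test_harmonic_variance_matches_boltzmann(self):
        # equal-k diabats make V(lam) harmonic with the same k at any lam
        k, temp = 50.0, 300.0
        m = _harmonic_model(k=k)
        cfg = SamplerConfig(n_steps=200_000, step_size=0.3, temperature=temp,
                            seed=11)
        traj = sample_window(m, 0.5, 0.0, cfg)
        var = np.var(traj.r)
        expected = BOLTZMANN_KCAL * temp / k
        # 3 standard errors of a sample variance, inflated for correlation
        se = expected * np.sqrt(2.0 / (traj.n_frames / 10))
        assert abs(var - expected) < 3 * se

    def test_seed_determinism(self):
        m = default_model()
        cfg = SamplerConfig(n_steps=5_000, seed=123)
        a = sample_window(m, 0.3, 1.0, cfg)
        b = sample_window(m, 0.3, 1.0, cfg)
        assert np.array_equal(a.eps1, b.eps1)
        assert np.array_equal(a.eps2, b.eps2)
        assert np.array_equal(a.r, b.r)

    def test_low_temperature_concentrates_at_minimum(self):
        m = _harmonic_model(k=100.0)
        cfg = SamplerConfig(n_steps=50_000, temperature=1.0, step_size=0.02,
                            seed=3)
        traj = sample_window(m, 0.0, 0.0, cfg)
        assert np.std(traj.r) < 0.02
        assert abs(np.mean(traj.r)) < 0.02

    def test_single_window_distribution_matches_boltzmann(self):
        # chi-square check of the empirical x histogram against exp(-beta V)
        m = default_model()
        temp = 300.0
        cfg = SamplerConfig(n_steps=200_000, seed=5, temperature=temp)
        traj = sample_window(m, 0.0, 0.0, cfg)
        beta = 1.0 / (BOLTZMANN_KCAL * temp)
        edges = np.linspace(np.min(traj.r), np.max(traj.r), 21)
        obs, _ = np.histogram(traj.r, bins=edges)
        x = np.linspace(edges[0], edges[-1], 4001)
        w = np.exp(-beta * ((1 - 0.0) * m.diabat1.energy(x)))
        p = np.histogram(x, bins=edges, weights=w)[0]
        p /= p.sum()
        keep = p * traj.n_frames >= 5
        chi2 = np.sum((obs[keep] - traj.n_frames * p[keep]) ** 2
                      / (traj.n_frames * p[keep]))
        # generous: autocorrelated samples inflate chi-square
        assert chi2 / keep.sum() < 25


class TestSchedule:
    def test_fifty_one_windows(self, toy_model, schedule51):
        cfg = SamplerConfig(n_steps=2_000, seed=9)
        trajs = run_fep_schedule(toy_model, schedule51, 0.0, cfg)
        assert len(trajs) == 51
        assert [t.lam for t in trajs] == [pytest.approx(l) for l in schedule51]

    def test_full_run_determinism(self, toy_model):
        sched = LambdaSchedule.uniform(5)
        cfg = SamplerConfig(n_steps=2_000, seed=21)
        a = run_fep_schedule(toy_model, sched, 0.0, cfg)
        b = run_fep_schedule(toy_model, sched, 0.0, cfg)
        for wa, wb in zip(a, b):
            assert np.array_equal(wa.eps1, wb.eps1)
            assert np.array_equal(wa.r, wb.r)

    def test_zero_acceptance_is_an_error(self):
        m = _harmonic_model(k=1.0)
        cfg = SamplerConfig(n_steps=100, step_size=1e9, temperature=1e-3,
                            seed=1, burn_in=0)
        with pytest.raises(SamplerError):
            run_fep_schedule(m, LambdaSchedule.uniform(2), 0.0, cfg)


class TestOracle:
    def test_symmetric_model_gives_symmetric_profile(self):
        # mirror-image diabats with delta_alpha = 0: dG0 must vanish and
        # the profile must be symmetric about zero gap
        m = ToyEVBModel(DiabatSpec("harmonic", k=220.0, x0=0.0),
                        DiabatSpec("harmonic", k=220.0, x0=1.0),
                        EVBParameters(A=15.0), (-1.0, 2.0))
        prof = exact_gap_profile(m, 0.0, m.coupling, 300.0, grid=40001)
        s = extract_barriers(prof)
        assert s.dg_rxn == pytest.approx(0.0, abs=1e-6)
        v = prof.valid
        flipped = np.interp(-prof.bin_centers[v], prof.bin_centers[v],
                            prof.delta_g[v])
        assert np.allclose(prof.delta_g[v], flipped, atol=5e-3)

    def test_zero_coupling_barrier_is_diabatic_crossing(self, toy_model):
        # without coupling the ground state is the lower-diabat envelope,
        # whose cusp at the seam sets the barrier; binning smooths the
        # cusp, so the barrier approaches the seam height from below as
        # the bins refine
        x = np.linspace(0.0, 1.0, 200001)
        envelope = np.minimum(toy_model.diabat1.energy(x),
                              toy_model.diabat2.energy(x))
        seam = envelope.max() - toy_model.diabat1.energy(0.0)
        barriers = [
            extract_barriers(exact_gap_profile(
                toy_model, 0.0, EVBParameters(A=0.0), 300.0, grid=160001,
                bins=bins, min_count=1)).dg_act
            for bins in (200, 800, 3200)
        ]
        assert np.all(np.diff(barriers) > 0)
        assert np.all(np.array(barriers) < seam)
        assert barriers[-1] == pytest.approx(seam, abs=0.05)

    def test_grid_convergence(self, toy_model):
        a = extract_barriers(exact_gap_profile(toy_model, 0.0,
                                               toy_model.coupling, 300.0,
                                               grid=20001))
        b = extract_barriers(exact_gap_profile(toy_model, 0.0,
                                               toy_model.coupling, 300.0,
                                               grid=40001))
        assert abs(a.dg_act - b.dg_act) < 1e-3
        assert abs(a.dg_rxn - b.dg_rxn) < 1e-3
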