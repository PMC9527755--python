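import numpy as np
import pytest

from biqens import (
    GroundTruth,
    fit_fickian,
    fit_internal_dynamics,
    fit_qwise_average,
    make_mixture_spectra,
)
from biqens.constants import HBAR_UEV_NS
from biqens.fitting import compare_models, profile_interval, robustness_scan
from biqens.pipeline import composition_for
from biqens.spectral_models import EISFParams, JumpDiffusionParams, eisf_model, jump_width


@pytest.fixture(scope="module")
def mono_sample_small(instrument_small, calibration_small):
    """Monodisperse (pure BSA) measurement with D = 4 Å²/ns."""
    comp = composition_for(0.15, 1.0)
    truth = GroundTruth(D_BSA=4.0, D_Ig=1.0)   # D_Ig carries zero weight
    spec = make_mixture_spectra(instrument_small, comp, truth,
                                calibration_small["resolution"],
                                calibration_small["solvent"], seed=55)
    return spec


class TestQwiseAverage:
    def test_monodisperse_widths_follow_fickian_law(self, mono_sample_small,
                                                    calibration_small):
        qw = fit_qwise_average(mono_sample_small, calibration_small["resolution"],
                               calibration_small["solvent"].scaled(1 - 0.15))
        good = qw.converged_q & (qw.gamma_glob_err > 0)
        assert good.sum() >= 6
        expected = HBAR_UEV_NS * 4.0 * qw.q**2
        pulls = (qw.gamma_glob - expected)[good] / qw.gamma_glob_err[good]
        # individual widths consistent with ħDq² (generous per-point window)
        assert np.all(np.abs(pulls) < 5.0)
        assert qw.fickian["r2_weighted"] > 0.99
        assert qw.D_av == pytest.approx(4.0, rel=0.05)

    def test_bidisperse_width_lies_between_component_widths(
            self, bidisperse_sample_small, calibration_small):
        qw = fit_qwise_average(bidisperse_sample_small["spectra"],
                               calibration_small["resolution"],
                               bidisperse_sample_small["solvent_scaled"])
        good = qw.converged_q & (qw.gamma_glob_err > 0)
        lo = HBAR_UEV_NS * 1.5 * qw.q**2
        hi = HBAR_UEV_NS * 4.5 * qw.q**2
        g = qw.gamma_glob
        e = qw.gamma_glob_err
        assert np.all(g[good] > lo[good] - 3 * e[good])
        assert np.all(g[good] < hi[good] + 3 * e[good])

    def test_zero_protein_flagged_degenerate(self, instrument_small,
                                             calibration_small):
        comp = composition_for(0.15, 0.5)
        truth = GroundTruth(beta_q=np.zeros(8))
        spec = make_mixture_spectra(instrument_small, comp, truth,
                                    calibration_small["resolution"],
                                    calibration_small["solvent"], seed=66)
        qw = fit_qwise_average(spec, calibration_small["resolution"],
                               calibration_small["solvent"].scaled(1 - 0.15))
        assert not qw.converged_q.any()
        assert qw.fickian is None and np.isnan(qw.D_av)


class TestFitFickian:
    def test_exact_input_machine_precision(self):
        q = np.linspace(0.2, 1.9, 10)
        gamma = HBAR_UEV_NS * 3.3 * q**2
        out = fit_fickian(gamma, np.full(10, 0.01), q)
        assert out["D_av"] == pytest.approx(3.3, rel=1e-12)
        assert out["r2_weighted"] == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 usable"):
            fit_fickian([1.0, 2.0], [0.1, 0.1], [0.5, 1.0])

    def test_heteroscedastic_noise_unbiased(self):
        """Weighted slope through the origin recovers D within 3σ of its
        standard error, over 100 noise realizations."""
        rng = np.random.default_rng(8)
        q = np.linspace(0.2, 1.9, 16)
        D = 2.7
        truth = HBAR_UEV_NS * D * q**2
        sigma = 0.05 + 0.3 * q**2        # grows with q
        pulls = []
        for _ in range(100):
            gamma = truth + rng.normal(0.0, sigma)
            out = fit_fickian(gamma, sigma, q)
            pulls.append((out["D_av"] - D) / out["D_av_err"])
        pulls = np.asarray(pulls)
        assert abs(pulls.mean()) < 3.0 / np.sqrt(100)
        assert pulls.std() == pytest.approx(1.0, abs=0.3)


class TestGlobalFits:
    def test_mono_global_lies_between_component_values(self, mono_fit_small):
        assert 1.5 < mono_fit_small.D_av < 4.5
        assert mono_fit_small.n_free == 1 + 3 * 8

    def test_bidisperse_recovery_and_constraints(self, bi_fit_small):
        assert bi_fit_small.D_Ig < bi_fit_small.D_BSA
        assert bi_fit_small.D_BSA == pytest.approx(4.5, rel=0.15)
        assert bi_fit_small.D_Ig == pytest.approx(1.5, rel=0.15)
        assert 0.85 < bi_fit_small.chi2nu < 1.15
        # EISF monotone non-increasing by construction
        assert np.all(np.diff(bi_fit_small.A0) <= 1e-12)
        assert np.all((bi_fit_small.A0 >= 0) & (bi_fit_small.A0 <= 1))

    def test_exactly_one_extra_parameter(self, mono_fit_small, bi_fit_small):
        cmp = compare_models(mono_fit_small, bi_fit_small)
        assert cmp["extra_parameters"] == 1

    def test_bidisperse_fits_no_worse_than_average(self, mono_fit_small,
                                                   bi_fit_small):
        cmp = compare_models(mono_fit_small, bi_fit_small)
        assert cmp["deviance_bi"] <= cmp["deviance_mono"] + 1e-6

    def test_objective_trace_monotone(self, mono_fit_small, bi_fit_small):
        for fit in (mono_fit_small, bi_fit_small):
            assert fit.trace is not None and len(fit.trace) > 1
            assert np.all(np.diff(fit.trace) <= 1e-9)

    def test_compare_requires_global_mode(self, bi_fit_small, mono_sample_small,
                                          calibration_small):
        qw = fit_qwise_average(mono_sample_small, calibration_small["resolution"],
                               calibration_small["solvent"].scaled(1 - 0.15))
        with pytest.raises(ValueError, match="global"):
            compare_models(qw, bi_fit_small)


class TestRobustnessScan:
    def test_minimum_at_fitted_value_and_convex(self, bi_fit_small):
        err = max(bi_fit_small.D_Ig_err, 0.02)
        grid = bi_fit_small.D_Ig + np.linspace(-3, 3, 7) * err
        scan = robustness_scan(bi_fit_small, "D_Ig", grid)
        chi2 = scan["chi2nu"]
        # profile minimum within a grid step of the fitted value
        assert np.min(chi2) >= scan["chi2nu_min"] - 1e-9
        assert abs(np.argmin(chi2) - 3) <= 1
        # convex near the optimum
        center = chi2[1:6]
        assert np.all(np.diff(center, 2) > -1e-9)

    def test_grid_clipping_warns(self, bi_fit_small):
        with pytest.warns(UserWarning, match="clipped"):
            robustness_scan(bi_fit_small, "D_Ig", np.array([-1.0, bi_fit_small.D_Ig]))

    def test_profile_interval_consistent_with_wald(self, bi_fit_small):
        lo, hi = profile_interval(bi_fit_small, "D_Ig")
        width_profile = hi - lo
        width_wald = 2 * bi_fit_small.D_Ig_err
        assert width_profile == pytest.approx(width_wald, rel=0.3)


class TestInternalDynamics:
    def test_recovery_within_3_sigma(self):
        rng = np.random.default_rng(17)
        q = np.linspace(0.2, 1.9, 16)
        truth_eisf = EISFParams(p=0.4, phi_mobile=0.3, R=10.0)
        truth_jump = JumpDiffusionParams(D_int=100.0, tau=0.1)
        a0 = eisf_model(truth_eisf, q)
        g = jump_width(truth_jump, q)
        a0_err = np.full(16, 0.01)
        g_err = 0.05 * g
        out = fit_internal_dynamics(q, a0 + rng.normal(0, a0_err), a0_err,
                                    g + rng.normal(0, g_err), g_err)
        for name, truth in (("p", 0.4), ("phi_mobile", 0.3), ("R", 10.0)):
            err = out["eisf_err"][name]
            assert np.isfinite(err) and abs(getattr(out["eisf"], name) - truth) < 3 * err
        for name, truth in (("D_int", 100.0), ("tau", 0.1)):
            err = out["jump_err"][name]
            assert np.isfinite(err) and abs(getattr(out["jump"], name) - truth) < 3 * err

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="4 q points"):
            fit_internal_dynamics([0.5, 1.0, 1.5], [1, 1, 1], [0.1] * 3,
                                  [1, 1, 1], [0.1] * 3)
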