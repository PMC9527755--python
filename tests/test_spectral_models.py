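import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from biqens.constants import HBAR_UEV_NS
from biqens.spectral_models import (
    EISFParams,
    JumpDiffusionParams,
    ResolutionModel,
    SolventModel,
    bidisperse_model,
    convolve_with_resolution,
    eisf_model,
    gaussian,
    jump_width,
    lorentzian,
    mono_model,
    numeric_voigt_fft,
    voigt,
    voigt_and_dgamma,
)

OMEGA = np.linspace(-30.0, 30.0, 1201)


@pytest.fixture(scope="module")
def resolution():
    q = np.array([0.5, 1.0])
    return ResolutionModel(q=q, amplitudes=np.tile([0.7, 0.3], (2, 1)),
                           sigmas=np.tile([0.35, 1.0], (2, 1)))


@pytest.fixture(scope="module")
def solvent():
    return SolventModel(q=np.array([0.5, 1.0]), amplitude=np.array([50.0, 40.0]),
                        gamma=np.array([20.0, 30.0]))


class TestLorentzian:
    def test_closed_forms(self):
        g = 2.5
        prof = lorentzian(OMEGA, g)
        assert prof[600] == pytest.approx(1.0 / (np.pi * g))        # ω = 0
        # half height at ω = γ
        assert lorentzian(np.array([g]), g)[0] == pytest.approx(0.5 / (np.pi * g))

    def test_normalization(self):
        val, _ = quad(lambda w: lorentzian(np.array([w]), 1.3)[0], -np.inf, np.inf)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            lorentzian(OMEGA, 0.0)


class TestVoigt:
    def test_delta_limits(self):
        x = np.linspace(-5, 5, 101)
        assert np.allclose(voigt(x, 0.4, 0.0), gaussian(x, 0.4), rtol=1e-12)
        # tiny Gaussian width: Voigt -> Lorentzian
        assert np.allclose(voigt(x, 1e-4, 1.0), lorentzian(x, 1.0), rtol=1e-4)

    def test_matches_fft_convolution(self):
        x = np.linspace(-8, 8, 41)
        for sigma, gam in [(0.35, 1.0), (1.0, 0.3), (0.5, 5.0)]:
            ana = voigt(x, sigma, gam)
            num = numeric_voigt_fft(x, sigma, gam)
            # limited by the FFT grid discretization; the adaptive-quadrature
            # comparison in the acceptance suite is the tighter check
            assert np.max(np.abs(ana - num)) / ana.max() < 2e-6

    def test_gamma_derivative_against_finite_difference(self):
        x = np.linspace(-6, 6, 31)
        v, dv = voigt_and_dgamma(x, 0.4, 1.2)
        h = 1e-6
        num = (voigt(x, 0.4, 1.2 + h) - voigt(x, 0.4, 1.2 - h)) / (2 * h)
        assert np.allclose(dv, num, atol=1e-8)


class TestConvolveWithResolution:
    def test_zero_width_recovers_resolution_shape(self, resolution):
        out = convolve_with_resolution([(1.0, 0.0)], resolution, 0.5, OMEGA)
        assert np.allclose(out, resolution.kernel(OMEGA, 0), rtol=1e-12)

    def test_component_permutation_invariance(self, resolution):
        comps = [(0.6, 2.0), (0.3, 0.7), (0.1, 8.0)]
        a = convolve_with_resolution(comps, resolution, 1.0, OMEGA)
        b = convolve_with_resolution(comps[::-1], resolution, 1.0, OMEGA)
        assert np.allclose(a, b, rtol=1e-14)

    def test_missing_q_raises(self, resolution):
        with pytest.raises(KeyError):
            convolve_with_resolution([(1.0, 1.0)], resolution, 0.77, OMEGA)


class TestMonoModel:
    def test_a0_one_is_single_lorentzian(self, resolution, solvent):
        full = mono_model(OMEGA, 1.0, beta=100.0, gamma_glob=2.0, gamma_int=5.0,
                          A0=1.0, solvent=solvent, resolution=resolution)
        manual = convolve_with_resolution(
            [(100.0, 2.0), (solvent.amplitude[1], solvent.gamma[1])],
            resolution, 1.0, OMEGA)
        assert np.allclose(full, manual, rtol=1e-12)

    def test_beta_zero_is_solvent_only(self, resolution, solvent):
        out = mono_model(OMEGA, 0.5, beta=0.0, gamma_glob=2.0, gamma_int=5.0,
                         A0=0.7, solvent=solvent, resolution=resolution)
        manual = convolve_with_resolution(
            [(solvent.amplitude[0], solvent.gamma[0])], resolution, 0.5, OMEGA)
        assert np.allclose(out, manual, rtol=1e-12)

    def test_invalid_a0(self, resolution, solvent):
        with pytest.raises(ValueError, match="A0"):
            mono_model(OMEGA, 0.5, 1.0, 2.0, 5.0, 1.2, solvent, resolution)


class TestBidisperseModel:
    def test_degenerate_weight_equals_mono(self, resolution, solvent):
        bi = bidisperse_model(OMEGA, 1.0, D_BSA=4.5, D_Ig=1.5, weights=(1.0, 0.0),
                              beta=50.0, A0=0.8, gamma_int=6.0,
                              solvent=solvent, resolution=resolution)
        mono = mono_model(OMEGA, 1.0, beta=50.0,
                          gamma_glob=HBAR_UEV_NS * 4.5, gamma_int=6.0, A0=0.8,
                          solvent=solvent, resolution=resolution)
        assert np.allclose(bi, mono, rtol=1e-12)

    def test_coalescence(self, resolution, solvent):
        bi = bidisperse_model(OMEGA, 1.0, D_BSA=3.0, D_Ig=3.0, weights=(0.6, 0.4),
                              beta=50.0, A0=0.8, gamma_int=6.0,
                              solvent=solvent, resolution=resolution)
        mono = mono_model(OMEGA, 1.0, beta=50.0, gamma_glob=HBAR_UEV_NS * 3.0,
                          gamma_int=6.0, A0=0.8, solvent=solvent,
                          resolution=resolution)
        assert np.allclose(bi, mono, rtol=1e-12)

    def test_term_by_term_oracle(self, resolution, solvent):
        # weights (0.6, 0.4), D = (4.5, 1.5) at q = 1: hand-built Voigt sum
        q, beta, A0, g_int = 1.0, 80.0, 0.75, 6.0
        g_b, g_i = HBAR_UEV_NS * 4.5, HBAR_UEV_NS * 1.5
        out = bidisperse_model(OMEGA, q, 4.5, 1.5, (0.6, 0.4), beta, A0, g_int,
                               solvent, resolution)
        expected = np.zeros_like(OMEGA)
        for w, g in [(beta * A0 * 0.6, g_b), (beta * A0 * 0.4, g_i),
                     (beta * (1 - A0), g_b + g_int),
                     (solvent.amplitude[1], solvent.gamma[1])]:
            expected += w * (0.7 * voigt(OMEGA, 0.35, g) + 0.3 * voigt(OMEGA, 1.0, g))
        assert np.allclose(out, expected, rtol=1e-12)

    def test_ordering_violation_raises(self, resolution, solvent):
        with pytest.raises(ValueError, match="D_Ig"):
            bidisperse_model(OMEGA, 1.0, D_BSA=1.0, D_Ig=2.0, weights=(0.5, 0.5),
                             beta=1.0, A0=0.5, gamma_int=5.0,
                             solvent=solvent, resolution=resolution)

    @settings(max_examples=25, deadline=None)
    @given(d_ig=st.floats(0.2, 3.0), delta=st.floats(0.01, 5.0),
           a0=st.floats(0.0, 1.0), beta=st.floats(0.0, 1e4))
    def test_nonnegative_everywhere(self, resolution, solvent, d_ig, delta, a0, beta):
        out = bidisperse_model(OMEGA, 0.5, d_ig + delta, d_ig, (0.5, 0.5),
                               beta, a0, 5.0, solvent, resolution)
        assert np.all(out >= 0)

    def test_area_conservation(self, resolution):
        # unit-area components: total area = beta + solvent amplitude;
        # checked on a wide grid with narrow lines so the tails are captured
        wide = np.linspace(-3000, 3000, 200001)
        solv = SolventModel(q=np.array([0.5, 1.0]), amplitude=np.array([5.0, 5.0]),
                            gamma=np.array([3.0, 3.0]))
        out = bidisperse_model(wide, 1.0, 4.5, 1.5, (0.5, 0.5), beta=10.0,
                               A0=0.8, gamma_int=4.0, solvent=solv,
                               resolution=resolution)
        area = np.trapezoid(out, wide)
        assert area == pytest.approx(15.0, rel=5e-3)


class TestEisfModel:
    def test_normalization_at_q0(self):
        params = EISFParams(p=0.3, phi_mobile=0.4, R=10.0)
        assert eisf_model(params, np.array([0.0]))[0] == pytest.approx(1.0)

    def test_fully_immobile(self):
        params = EISFParams(p=1.0, phi_mobile=0.4, R=10.0)
        q = np.linspace(0.0, 2.0, 20)
        assert np.allclose(eisf_model(params, q), 1.0)

    def test_large_q_asymptote(self):
        # with R large both sphere and sinc terms vanish: A0 -> p + (1−p)φ/3
        params = EISFParams(p=0.4, phi_mobile=0.3, R=500.0)
        limit = 0.4 + 0.6 * 0.3 / 3.0
        assert eisf_model(params, np.array([200.0]))[0] == pytest.approx(limit, abs=2e-3)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            EISFParams(p=1.2, phi_mobile=0.3, R=10.0)


class TestJumpWidth:
    def test_reference_value(self):
        # D_int = 100 Å²/ns, τ = 0.1 ns, q = 1: γ = ħ·100/11
        params = JumpDiffusionParams(D_int=100.0, tau=0.1)
        assert jump_width(params, np.array([1.0]))[0] == pytest.approx(
            5.983745062727272, rel=1e-12)

    def test_fickian_limit(self):
        params = JumpDiffusionParams(D_int=100.0, tau=0.1)
        q = 1e-3
        assert jump_width(params, np.array([q]))[0] == pytest.approx(
            HBAR_UEV_NS * 100.0 * q**2, rel=1e-4)

    def test_plateau(self):
        params = JumpDiffusionParams(D_int=100.0, tau=0.1)
        assert jump_width(params, np.array([1e3]))[0] == pytest.approx(
            HBAR_UEV_NS / 0.1, rel=1e-4)


def test_resolution_width_error_names_q_index():
    with pytest.raises(ValueError, match="q index 1"):
        ResolutionModel(q=np.array([0.5, 1.0]),
                        amplitudes=np.tile([0.7, 0.3], (2, 1)),
                        sigmas=np.array([[0.35, 1.0], [0.35, -1.0]]))
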