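import numpy as np
import pytest

from biqens.colloid_theory import (
    DEFAULT_COEFFICIENTS,
    HardSphereMixture,
    PureSolutionCurve,
    apparent_diffusion,
    average_theory_diffusion,
    d2o_viscosity,
    pure_curve_from_theory,
    relative_deviation,
    renormalize_to_experiment,
    stokes_einstein_limits,
    theory_for_sample,
    wang_brady_short_time,
)
from biqens.colloid_theory import rotational_weights, _composite_hwhm
from biqens.composition import BSA, IG, ProteinSpecies
from biqens.constants import HBAR_UEV_NS
from biqens.pipeline import composition_for

Q_GRID = np.linspace(0.2, 1.9, 8)


@pytest.fixture(scope="module")
def theory_curves():
    visc = d2o_viscosity(295.0)
    return visc, tuple(pure_curve_from_theory(sp, 295.0, visc, Q_GRID)
                       for sp in (BSA, IG))


class TestStokesEinstein:
    SP36 = ProteinSpecies("X", M_w=66.4, sigma_inc=1.0, nu=0.735, R_H=36.0)

    def test_hand_values(self):
        # independent evaluation of k_B·T/(6πηR) and k_B·T/(8πηR³) at
        # R = 36 Å, T = 295 K, η = 1.1 mPa·s
        D_t, D_r = stokes_einstein_limits(self.SP36, 295.0, 1.1)
        assert D_t == pytest.approx(5.456435045651537, rel=1e-12)
        assert D_r == pytest.approx(0.0031576591699372324, rel=1e-12)

    def test_radius_scaling(self):
        half = ProteinSpecies("Y", M_w=66.4, sigma_inc=1.0, nu=0.735, R_H=72.0)
        D_t1, D_r1 = stokes_einstein_limits(self.SP36, 295.0, 1.1)
        D_t2, D_r2 = stokes_einstein_limits(half, 295.0, 1.1)
        assert D_t2 == pytest.approx(D_t1 / 2.0, rel=1e-12)
        assert D_r2 == pytest.approx(D_r1 / 8.0, rel=1e-12)

    def test_inverse_relation(self):
        import math
        D_t, _ = stokes_einstein_limits(self.SP36, 295.0, 1.1)
        kT = 1.380649e-23 * 295.0
        assert D_t * 6 * math.pi * 1.1e-3 * 36e-10 / (kT * 1e11) == pytest.approx(1.0)


class TestWangBrady:
    def test_dilute_limit(self):
        mix = HardSphereMixture(30.0, 40.0, 0.0, 0.0)
        out = wang_brady_short_time(mix)
        assert out["a"] == (1.0, 1.0) and out["b"] == (1.0, 1.0)

    def test_equal_radii_reduce_to_monodisperse(self):
        mix = HardSphereMixture(30.0, 30.0, 0.12, 0.08)
        mono = HardSphereMixture(30.0, 30.0, 0.20, 0.0)
        out = wang_brady_short_time(mix)
        ref = wang_brady_short_time(mono)
        assert out["a"] == pytest.approx(ref["a"], rel=1e-14)
        assert out["b"] == pytest.approx(out["a"], rel=1e-14)

    def test_monodisperse_dilute_coefficients(self):
        # first-order slopes: d_t = 1 − 1.8315·φ, d_r = 1 − 0.631·φ
        mix = HardSphereMixture(30.0, 30.0, 0.10, 0.0)
        dt, dr = wang_brady_short_time(mix)["a"]
        assert dt == pytest.approx(1.0 - 0.18315, rel=1e-12)
        assert dr == pytest.approx(1.0 - 0.0631, rel=1e-12)

    def test_size_ratio_two_ordering(self):
        # smaller sphere diffuses faster, larger slower, than monodisperse
        mix = HardSphereMixture(20.0, 40.0, 0.10, 0.10)
        mono_small = wang_brady_short_time(HardSphereMixture(20.0, 20.0, 0.2, 0.0))["a"]
        mono_large = wang_brady_short_time(HardSphereMixture(40.0, 40.0, 0.2, 0.0))["a"]
        out = wang_brady_short_time(mix)
        assert out["a"][0] > mono_small[0]
        assert out["b"][0] < mono_large[0]

    def test_ratios_bounded_and_monotone(self):
        phis = np.linspace(0.0, 0.4, 9)
        prev = (1.1, 1.1)
        for phi in phis:
            mix = HardSphereMixture(30.0, 40.0, 0.5 * phi, 0.5 * phi)
            dt, dr = wang_brady_short_time(mix)["a"]
            assert dt <= 1.0 + 1e-12 and dr <= 1.0 + 1e-12
            assert dt <= prev[0] and dr <= prev[1]
            prev = (dt, dr)

    def test_out_of_range_raises(self):
        mix = HardSphereMixture(30.0, 40.0, 0.3, 0.3)
        with pytest.raises(ValueError, match="outside"):
            wang_brady_short_time(mix)


class TestApparentDiffusion:
    def test_pure_translation_is_exact(self):
        D, D_q = apparent_diffusion(3.7, 0.0, 30.0, Q_GRID)
        assert D == 3.7
        assert np.all(D_q == 3.7)

    def test_small_particle_limit(self):
        D, _ = apparent_diffusion(3.0, 0.005, 1.0, np.array([0.2]))
        assert D == pytest.approx(3.0, rel=1e-3)

    def test_rotational_weights_sum_to_one(self):
        for qr in (0.5, 3.0, 20.0, 60.0):
            B = rotational_weights(qr)
            assert B.sum() == pytest.approx(1.0, abs=2e-6)
            assert np.all(B >= -1e-12)

    def test_reference_triple_matches_bruteforce(self):
        # (D_t, D_r, R) = (4.0 Å²/ns, 0.003 1/ns, 30 Å): HWHM from a densely
        # sampled composite profile vs the root-finding implementation
        q = 1.0
        B = rotational_weights(q * 30.0)
        ls = np.arange(B.size)
        gammas = HBAR_UEV_NS * (4.0 * q**2 + ls * (ls + 1) * 0.003)
        om = np.linspace(0.0, 5 * gammas.max(), 2_000_001)
        prof = np.sum(B[:, None] * gammas[:, None]
                      / (om[None, :] ** 2 + gammas[:, None] ** 2), axis=0)
        half = prof[0] / 2.0
        idx = np.searchsorted(-prof, -half)
        frac = (prof[idx - 1] - half) / (prof[idx - 1] - prof[idx])
        hwhm_brute = om[idx - 1] + frac * (om[idx] - om[idx - 1])
        hwhm = _composite_hwhm(gammas, B)
        assert hwhm == pytest.approx(hwhm_brute, rel=1e-5)
        _, D_q = apparent_diffusion(4.0, 0.003, 30.0, np.array([q]))
        assert D_q[0] == pytest.approx(hwhm_brute / HBAR_UEV_NS, rel=1e-4)

    def test_rotation_increases_apparent_width(self):
        D, _ = apparent_diffusion(4.0, 0.003, 30.0, Q_GRID)
        assert D > 4.0


class TestRenormalization:
    def test_ratio_arithmetic(self):
        curve = PureSolutionCurve(coefficients=[3.0, -1.0])
        assert renormalize_to_experiment(0.9, 1.0, curve, 0.0) == pytest.approx(2.7)

    def test_pure_limits_exact(self, theory_curves):
        """At y = 0 and y = 1 the renormalized theory value equals the pure
        curve exactly (machine precision)."""
        visc, curves = theory_curves
        for y, key in ((1.0, "D_theo_BSA"), (0.0, "D_theo_Ig")):
            comp = composition_for(0.2, y)
            tc = theory_for_sample(comp, (BSA, IG), curves, visc, Q_GRID)
            idx = 0 if y == 1.0 else 1
            assert getattr(tc, key) == pytest.approx(curves[idx](tc.phi), rel=1e-12)

    def test_full_chain_compositional_oracle(self, theory_curves):
        """theory_for_sample equals a step-by-step hand composition of the
        three factors (mixture ratio, monodisperse ratio, pure curve)."""
        visc, curves = theory_curves
        comp = composition_for(0.15, 0.4)
        tc = theory_for_sample(comp, (BSA, IG), curves, visc, Q_GRID)
        # hand chain for BSA
        from biqens.colloid_theory import _partial_phi_theo
        phi_b, phi_i = _partial_phi_theo(comp, (BSA, IG))
        D_t0, D_r0 = stokes_einstein_limits(BSA, 295.0, visc)
        mix = HardSphereMixture(BSA.R_H, IG.R_H, phi_b, phi_i, 295.0, visc)
        dt, dr = wang_brady_short_time(mix)["a"]
        D_mix, _ = apparent_diffusion(D_t0 * dt, D_r0 * dr, BSA.R_H, Q_GRID)
        mono = HardSphereMixture(BSA.R_H, BSA.R_H, phi_b + phi_i, 0.0, 295.0, visc)
        dt_m, dr_m = wang_brady_short_time(mono)["a"]
        D_mono, _ = apparent_diffusion(D_t0 * dt_m, D_r0 * dr_m, BSA.R_H, Q_GRID)
        expected = D_mix / D_mono * curves[0](0.15)
        assert tc.D_theo_BSA == pytest.approx(expected, rel=1e-12)

    def test_curve_validity_range(self):
        curve = PureSolutionCurve(coefficients=[3.0, -1.0], phi_max=0.3)
        with pytest.raises(ValueError, match="validity"):
            curve(0.4)
        with pytest.raises(ValueError, match="non-increasing"):
            PureSolutionCurve(coefficients=[3.0, +1.0])


class TestAverageTheoryDiffusion:
    def test_degenerate_cases(self):
        assert average_theory_diffusion(4.5, 1.5, (1.0, 0.0)) == 4.5
        assert average_theory_diffusion(4.5, 1.5, (0.0, 1.0)) == 1.5
        assert average_theory_diffusion(3.0, 3.0, (0.4, 0.6)) == 3.0

    def test_between_components(self):
        D = average_theory_diffusion(4.5, 1.5, (0.55, 0.45), Q_GRID)
        assert 1.5 < D < 4.5

    def test_bruteforce_single_lorentzian_fit(self):
        # grid-search least squares over the single-Lorentzian width at q = 1
        q = 1.0
        s = (0.55, 0.45)
        om = np.linspace(0.0, 30.0, 600)
        g_b, g_i = HBAR_UEV_NS * 4.5 * q**2, HBAR_UEV_NS * 1.5 * q**2
        target = (s[0] * g_b / (om**2 + g_b**2) + s[1] * g_i / (om**2 + g_i**2)) / np.pi
        best = None
        for g in np.linspace(g_i, g_b, 40001):
            L = g / (np.pi * (om**2 + g**2))
            amp = target @ L / (L @ L)
            sse = np.sum((target - amp * L) ** 2)
            if best is None or sse < best[1]:
                best = (g, sse)
        D = average_theory_diffusion(4.5, 1.5, s, np.array([q]))
        assert D == pytest.approx(best[0] / (HBAR_UEV_NS * q**2), rel=1e-3)


class TestRelativeDeviation:
    def test_zero_and_plus_ten_percent(self):
        curve = PureSolutionCurve(coefficients=[3.0, -1.0])
        assert relative_deviation(curve(0.1), curve, 0.1) == 0.0
        assert relative_deviation(1.1 * curve(0.1), curve, 0.1) == pytest.approx(10.0)

    def test_mixture_signs(self, theory_curves):
        visc, curves = theory_curves
        tc = theory_for_sample(composition_for(0.2, 0.5), (BSA, IG), curves,
                               visc, Q_GRID)
        assert tc.delta_BSA_percent > 0
        assert tc.delta_Ig_percent < 0


def test_d2o_viscosity_scale():
    # heavy water near room temperature: ~1.0–1.3 mPa·s
    assert 1.0 < d2o_viscosity(295.0) < 1.3
    with pytest.raises(ValueError):
        d2o_viscosity(100.0)


def test_mixture_validation():
    with pytest.raises(ValueError, match="close packing"):
        HardSphereMixture(30.0, 40.0, 0.4, 0.3)
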