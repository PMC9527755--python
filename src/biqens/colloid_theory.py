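"""Bidisperse hard-sphere short-time diffusion theory chain.

For each sample the chain runs:

1. dilute-limit (Stokes–Einstein) translational and rotational anchors
   D_t0 = k_B·T/(6πηR_H) and D_r0 = k_B·T/(8πηR_H³);
2. normalized short-time self-diffusivities of both species in the binary
   hard-sphere mixture at the effective hydrodynamic volume fractions,
   via a pairwise-additive expansion d_i = 1 + Σ_j I(λ_ij)·φ_j whose
   size-ratio dependence follows the leading far-field two-body
   (method-of-reflections) integrals, calibrated to the exact dilute-limit
   monodisperse coefficients (−1.8315·φ translational, −0.631·φ rotational);
   the coefficient table is config-overridable;
3. the apparent center-of-mass diffusion coefficient D(D_t, D_r): the
   quasi-elastic line of a rigid sphere with uniformly distributed
   scatterers is a superposition Σ_l B_l(qR)·L(ħ(D_t·q² + l(l+1)·D_r));
   D(q) is its half-width at half-maximum divided by ħq², averaged over the
   instrument q grid;
4. renormalization to experimental conditions: the mixture/monodisperse
   ratio at the same effective hard-sphere volume fraction multiplies the
   experimentally parametrized pure-solution curve D_i(φ), so the pure
   limits are recovered exactly at mixing ratios y = 0 and y = 1;
5. relative deviations Δ_i = (D_i − D_i,pure(φ))/D_i,pure(φ) in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import fixed_quad
from scipy.optimize import brentq, minimize_scalar
from scipy.special import spherical_jn

from .composition import ProteinSpecies, SampleComposition, incoherent_weights, theory_volume_fraction, volume_fractions
from .constants import HBAR_UEV_NS, KB_J_PER_K, M2_PER_S_TO_A2_PER_NS, N_AVOGADRO

__all__ = [
    "HardSphereMixture",
    "MixtureCoefficients",
    "PureSolutionCurve",
    "TheoryCurve",
    "stokes_einstein_limits",
    "d2o_viscosity",
    "wang_brady_short_time",
    "apparent_diffusion",
    "renormalize_to_experiment",
    "average_theory_diffusion",
    "relative_deviation",
    "theory_for_sample",
    "pure_curve_from_theory",
]


def d2o_viscosity(T: float) -> float:
    """Heavy-water viscosity in mPa·s from a Vogel-type correlation.

    The light-water Vogel correlation η = 2.414e-2·10^(247.8/(T−140)) mPa·s
    scaled by the D₂O/H₂O ratio 1.23 at 298 K.  Adequate over 278–330 K.
    """
    if not (270.0 < T < 350.0):
        raise ValueError(f"viscosity correlation not valid at T = {T} K")
    return 1.23 * 2.414e-2 * 10.0 ** (247.8 / (T - 140.0))


def stokes_einstein_limits(species: ProteinSpecies, T: float,
                           viscosity: float) -> tuple[float, float]:
    """Dilute-limit diffusion anchors for one species.

    Returns (D_t0 in Å²/ns, D_r0 in 1/ns) with viscosity in mPa·s and the
    hydrodynamic radius of the species in Å.
    """
    if T <= 0 or viscosity <= 0:
        raise ValueError("T and viscosity must be > 0")
    kT = KB_J_PER_K * T
    eta = viscosity * 1e-3          # Pa·s
    R = species.R_H * 1e-10         # m
    D_t = kT / (6.0 * math.pi * eta * R) * M2_PER_S_TO_A2_PER_NS
    D_r = kT / (8.0 * math.pi * eta * R**3) * 1e-9   # 1/s -> 1/ns
    return D_t, D_r


@dataclass(frozen=True)
class MixtureCoefficients:
    """Coefficient table of the pairwise-additive short-time expansion.

    The normalized self-diffusivity of species i is
    d_i = 1 + Σ_j I(λ_ij)·φ_j with λ_ij = R_j/R_i.  The default size-ratio
    dependence is the leading far-field two-body integral — I_t ∝ 1/(1+λ)
    for translation (the r⁻⁴ mobility reflection) and I_r ∝ 1/(1+λ)³ for
    rotation (r⁻⁶) — normalized so that λ = 1 reproduces the exact
    monodisperse dilute-limit coefficients k_t and k_r.
    """

    k_t: float = -1.8315
    k_r: float = -0.631
    phi_max: float = 0.45

    def I_t(self, lam: float) -> float:
        return self.k_t * 2.0 / (1.0 + lam)

    def I_r(self, lam: float) -> float:
        return self.k_r * 8.0 / (1.0 + lam) ** 3

    def to_dict(self) -> dict:
        return {"k_t": self.k_t, "k_r": self.k_r, "phi_max": self.phi_max}

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureCoefficients":
        return cls(**d)


DEFAULT_COEFFICIENTS = MixtureCoefficients()


@dataclass(frozen=True)
class HardSphereMixture:
    """A binary hard-sphere suspension on the hydrodynamic scale.

    radii in Å; phi are the partial volume fractions of species a and b
    (hydrodynamic/effective scale); T in K; viscosity in mPa·s.
    """

    radius_a: float
    radius_b: float
    phi_a: float
    phi_b: float
    T: float = 295.0
    viscosity: float = field(default_factory=lambda: d2o_viscosity(295.0))

    def __post_init__(self) -> None:
        if self.radius_a <= 0 or self.radius_b <= 0:
            raise ValueError("radii must be > 0")
        if self.phi_a < 0 or self.phi_b < 0:
            raise ValueError("partial volume fractions must be >= 0")
        if self.phi_a + self.phi_b >= 0.64:
            raise ValueError("total volume fraction above random close packing")

    @property
    def phi_total(self) -> float:
        return self.phi_a + self.phi_b


def wang_brady_short_time(mixture: HardSphereMixture,
                          coefficients: MixtureCoefficients = DEFAULT_COEFFICIENTS
                          ) -> dict:
    """Normalized short-time self-diffusivities (D_t/D_t0, D_r/D_r0) of both
    species in the binary mixture.

    Raises if the total volume fraction exceeds the validity range of the
    coefficient table (no extrapolation).
    """
    phi = mixture.phi_total
    if phi > coefficients.phi_max:
        raise ValueError(
            f"phi_total = {phi:.3f} outside the coefficient table's fitted "
            f"range (phi <= {coefficients.phi_max})")
    out = {}
    pairs = (("a", mixture.radius_a), ("b", mixture.radius_b))
    phis = {"a": mixture.phi_a, "b": mixture.phi_b}
    for label_i, R_i in pairs:
        dt = 1.0
        dr = 1.0
        for label_j, R_j in pairs:
            lam = R_j / R_i
            dt += coefficients.I_t(lam) * phis[label_j]
            dr += coefficients.I_r(lam) * phis[label_j]
        out[label_i] = (dt, dr)
    return out


# ---------------------------------------------------------------------------
# apparent diffusion coefficient D(D_t, D_r)
# ---------------------------------------------------------------------------

def rotational_weights(qR: float, tol: float = 1e-6, lmax: int = 256) -> np.ndarray:
    """Spectral weights B_l(qR) of a rigid sphere with uniformly distributed
    incoherent scatterers: B_l = 3(2l+1)·∫₀¹ j_l(qR·u)²·u²·du, Σ_l B_l = 1.

    The series is truncated once the residual weight drops below ``tol``;
    exceeding ``lmax`` raises (the caller should not silently truncate).
    """
    weights = []
    total = 0.0
    for ell in range(lmax + 1):
        val, _ = fixed_quad(
            lambda u, l=ell: 3.0 * (2 * l + 1) * spherical_jn(l, qR * u) ** 2 * u**2,
            0.0, 1.0, n=80)
        weights.append(val)
        total += val
        if 1.0 - total < tol:
            return np.asarray(weights)
    raise RuntimeError(
        f"rotational weight series not converged at qR = {qR:.1f} within "
        f"l <= {lmax} (residual {1.0 - total:.2e})")


def _composite_hwhm(gammas: np.ndarray, weights: np.ndarray) -> float:
    """HWHM of Σ w_l·L(γ_l) (unit-area Lorentzians) by root finding."""
    s0 = np.sum(weights / gammas) / math.pi

    def f(om):
        return np.sum(weights * gammas / (om**2 + gammas**2)) / math.pi - 0.5 * s0

    hi = gammas.max()
    while f(hi) > 0:
        hi *= 2.0
    return brentq(f, 1e-12 * gammas.min(), hi, xtol=1e-14, rtol=1e-13)


def apparent_diffusion(D_t: float, D_r: float, R: float, q_grid,
                       tol: float = 1e-6, lmax: int = 256):
    """Apparent diffusion coefficient D from (D_t, D_r, R).

    For each q the composite quasi-elastic line Σ_l B_l(qR)·L(γ_l) with
    γ_l = ħ·(D_t·q² + l(l+1)·D_r) is built and its HWHM converted back via
    D(q) = HWHM/(ħ·q²).  Returns (mean over the q grid, per-q array).
    D_r = 0 reduces exactly to D_t.
    """
    if D_t <= 0 or R <= 0 or D_r < 0:
        raise ValueError("require D_t > 0, R > 0, D_r >= 0")
    q_grid = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if D_r == 0.0:
        return D_t, np.full(q_grid.size, D_t)
    D_q = np.empty(q_grid.size)
    for i, q in enumerate(q_grid):
        B = rotational_weights(q * R, tol=tol, lmax=lmax)
        ls = np.arange(B.size)
        gammas = HBAR_UEV_NS * (D_t * q**2 + ls * (ls + 1) * D_r)
        D_q[i] = _composite_hwhm(gammas, B) / (HBAR_UEV_NS * q**2)
    return float(D_q.mean()), D_q


# ---------------------------------------------------------------------------
# pure-solution curves and renormalization
# ---------------------------------------------------------------------------

@dataclass
class PureSolutionCurve:
    """Parametrized φ dependence of the apparent short-time D of one pure
    protein solution: D(φ) = Σ_k c_k·φ^k (c_0 = D at infinite dilution),
    valid on [phi_min, phi_max]."""

    coefficients: np.ndarray
    phi_min: float = 0.0
    phi_max: float = 0.45

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients[0] <= 0:
            raise ValueError("D(0) must be > 0")
        grid = np.linspace(self.phi_min, self.phi_max, 64)
        vals = np.polynomial.polynomial.polyval(grid, self.coefficients)
        if np.any(np.diff(vals) > 1e-12):
            raise ValueError("pure-solution curve must be non-increasing in φ")

    def __call__(self, phi: float) -> float:
        if not (self.phi_min - 1e-12 <= phi <= self.phi_max + 1e-12):
            raise ValueError(
                f"φ = {phi:.3f} outside the curve's validity range "
                f"[{self.phi_min}, {self.phi_max}]")
        return float(np.polynomial.polynomial.polyval(phi, self.coefficients))


def pure_curve_from_theory(species: ProteinSpecies, T: float, viscosity: float,
                           q_grid, coefficients: MixtureCoefficients = DEFAULT_COEFFICIENTS,
                           phi_max: float = 0.45, n_phi: int = 12,
                           degree: int = 3) -> PureSolutionCurve:
    """Self-consistent pure-solution curve built from the theory chain itself.

    Evaluates the monodisperse apparent D(φ_theo) on a φ grid and fits a
    polynomial; useful for synthetic round trips where no experimental
    parametrization exists.  The φ axis here is the effective hard-sphere
    volume fraction.
    """
    D_t0, D_r0 = stokes_einstein_limits(species, T, viscosity)
    phis = np.linspace(0.0, phi_max, n_phi)
    Ds = np.empty(n_phi)
    for i, phi in enumerate(phis):
        mix = HardSphereMixture(species.R_H, species.R_H, phi, 0.0, T, viscosity)
        ratios = wang_brady_short_time(mix, coefficients)
        dt, dr = ratios["a"]
        Ds[i], _ = apparent_diffusion(D_t0 * dt, D_r0 * dr, species.R_H, q_grid)
    coeffs = np.polynomial.polynomial.polyfit(phis, Ds, degree)
    return PureSolutionCurve(coefficients=coeffs, phi_min=0.0, phi_max=phi_max)


def renormalize_to_experiment(D_theo_mixture: float, D_theo_monodisperse: float,
                              pure_curve: PureSolutionCurve,
                              phi_experimental: float) -> float:
    """D_theo(φ) = [D_mixture/D_monodisperse at the same effective volume
    fraction] × D_pure(φ_experimental)."""
    if D_theo_monodisperse <= 0:
        raise ValueError("monodisperse reference must be > 0")
    return D_theo_mixture / D_theo_monodisperse * pure_curve(phi_experimental)


def average_theory_diffusion(D_BSA: float, D_Ig: float, weights,
                             q_grid=None, window: float = 30.0) -> float:
    """Best single-Lorentzian diffusion coefficient for the weighted sum of
    the two species' Lorentzians.

    At each q the s-weighted two-Lorentzian sum (widths ħ·D_i·q²) is
    approximated by one Lorentzian by least squares on the line shape over
    the instrument energy window (amplitude profiled analytically); the
    fitted widths are converted back to D and averaged over the q grid.
    """
    s_b, s_i = weights
    if abs(s_b + s_i - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if s_b == 1.0 or D_BSA == D_Ig:
        return D_BSA if s_b == 1.0 else (D_BSA if D_BSA == D_Ig else D_Ig)
    if s_i == 1.0:
        return D_Ig
    if q_grid is None:
        q_grid = np.linspace(0.2, 1.9, 16)
    omega = np.linspace(0.0, window, 600)   # even profiles: half axis suffices

    def lor(g):
        return g / (np.pi * (omega**2 + g**2))

    D_fit = np.empty(len(q_grid))
    for i, q in enumerate(np.atleast_1d(q_grid)):
        g_b = HBAR_UEV_NS * D_BSA * q**2
        g_i = HBAR_UEV_NS * D_Ig * q**2
        target = s_b * lor(g_b) + s_i * lor(g_i)

        def sse(g):
            L = lor(g)
            amp = float(np.dot(target, L) / np.dot(L, L))
            return float(np.sum((target - amp * L) ** 2))

        res = minimize_scalar(sse, bounds=(min(g_i, g_b), max(g_i, g_b)),
                              method="bounded",
                              options={"xatol": 1e-10})
        D_fit[i] = res.x / (HBAR_UEV_NS * q**2)
    return float(D_fit.mean())


def relative_deviation(D: float, pure_curve: PureSolutionCurve,
                       phi: float) -> float:
    """Δ = (D − D_pure(φ))/D_pure(φ) in percent."""
    ref = pure_curve(phi)
    return 100.0 * (D - ref) / ref


# ---------------------------------------------------------------------------
# full per-sample chain
# ---------------------------------------------------------------------------

@dataclass
class TheoryCurve:
    """Theory-chain outputs for one sample condition."""

    phi: float
    y: float
    phi_theo: float
    D_theo_BSA: float
    D_theo_Ig: float
    D_theo_av: float
    delta_BSA_percent: float
    delta_Ig_percent: float
    D_mixture_raw: tuple[float, float]
    D_monodisperse_raw: tuple[float, float]


def _partial_phi_theo(composition: SampleComposition, species) -> tuple[float, float]:
    out = []
    for c, sp in ((composition.c_BSA, species[0]), (composition.c_Ig, species[1])):
        n_per_a3 = c / (sp.M_w * 1e6) * N_AVOGADRO / 1e24
        out.append(n_per_a3 * (4.0 / 3.0) * math.pi * sp.R_H**3)
    return tuple(out)


def theory_for_sample(composition: SampleComposition, species,
                      pure_curves: tuple[PureSolutionCurve, PureSolutionCurve],
                      viscosity: float,
                      q_grid=None,
                      coefficients: MixtureCoefficients = DEFAULT_COEFFICIENTS
                      ) -> TheoryCurve:
    """Run the full theory chain for one sample composition.

    ``pure_curves`` are the (BSA, Ig) experimental pure-solution
    parametrizations evaluated at the experimental φ of the sample;
    ``viscosity`` (mPa·s) enters the dilute-limit anchors.
    """
    if q_grid is None:
        q_grid = np.linspace(0.2, 1.9, 16)
    phi_b_exp, phi_i_exp, phi_exp, y = volume_fractions(composition, species)
    phi_theo_b, phi_theo_i = _partial_phi_theo(composition, species)
    phi_theo = phi_theo_b + phi_theo_i
    T = composition.T

    mix = HardSphereMixture(species[0].R_H, species[1].R_H,
                            phi_theo_b, phi_theo_i, T, viscosity)
    ratios_mix = wang_brady_short_time(mix, coefficients)

    D_renorm = {}
    D_mix_raw = {}
    D_mono_raw = {}
    for key, sp, curve, phi_part in (("a", species[0], pure_curves[0], phi_theo_b),
                                     ("b", species[1], pure_curves[1], phi_theo_i)):
        D_t0, D_r0 = stokes_einstein_limits(sp, T, viscosity)
        dt, dr = ratios_mix[key]
        D_mix, _ = apparent_diffusion(D_t0 * dt, D_r0 * dr, sp.R_H, q_grid)
        # monodisperse reference: same species alone at the same total phi_theo
        mono = HardSphereMixture(sp.R_H, sp.R_H, phi_theo, 0.0, T, viscosity)
        dt_m, dr_m = wang_brady_short_time(mono, coefficients)["a"]
        D_mono, _ = apparent_diffusion(D_t0 * dt_m, D_r0 * dr_m, sp.R_H, q_grid)
        D_renorm[key] = renormalize_to_experiment(D_mix, D_mono, curve, phi_exp)
        D_mix_raw[key] = D_mix
        D_mono_raw[key] = D_mono

    weights = incoherent_weights(composition, species) \
        if (composition.c_BSA > 0 or composition.c_Ig > 0) else (1.0, 0.0)
    if composition.c_BSA == 0:
        D_av = D_renorm["b"]
    elif composition.c_Ig == 0:
        D_av = D_renorm["a"]
    else:
        D_av = average_theory_diffusion(D_renorm["a"], D_renorm["b"], weights, q_grid)

    return TheoryCurve(
        phi=phi_exp, y=y, phi_theo=phi_theo,
        D_theo_BSA=D_renorm["a"], D_theo_Ig=D_renorm["b"], D_theo_av=D_av,
        delta_BSA_percent=relative_deviation(D_renorm["a"], pure_curves[0], phi_exp),
        delta_Ig_percent=relative_deviation(D_renorm["b"], pure_curves[1], phi_exp),
        D_mixture_raw=(D_mix_raw["a"], D_mix_raw["b"]),
        D_monodisperse_raw=(D_mono_raw["a"], D_mono_raw["b"]),
    )
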