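"""Analytic spectral model components.

The measured QENS signal is modeled as the instrument resolution (a per-q sum
of two Gaussians fitted to vanadium) convolved with a sum of Lorentzian
quasi-elastic lines: one or two center-of-mass lines with Fickian widths
γ = ħ·D·q², one internal-dynamics line, and a fixed broad solvent line.  Each
Gaussian ⊗ Lorentzian term is a Voigt profile evaluated analytically through
the complex error function (scipy's ``wofz``), which also yields the exact
derivative with respect to the Lorentzian width used by the gradient-based
Poisson fits.  A brute-force FFT convolution is provided as an independent
numerical oracle.

Also here: the elastic incoherent structure factor (EISF) model — immobile
fraction plus methyl three-site jumps plus diffusion in a sphere — and the
jump-diffusion width law for the internal line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import spherical_jn, wofz

from .constants import HBAR_UEV_NS

__all__ = [
    "ResolutionModel",
    "SolventModel",
    "EISFParams",
    "JumpDiffusionParams",
    "lorentzian",
    "gaussian",
    "voigt",
    "voigt_and_dgamma",
    "numeric_voigt_fft",
    "convolve_with_resolution",
    "mono_model",
    "bidisperse_model",
    "eisf_model",
    "jump_width",
]

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# elementary profiles
# ---------------------------------------------------------------------------

def lorentzian(omega, gamma):
    """Unit-area Lorentzian with HWHM ``gamma`` (μeV)."""
    gamma = float(gamma)
    if gamma <= 0:
        raise ValueError(f"Lorentzian HWHM must be > 0, got {gamma}")
    omega = np.asarray(omega, dtype=float)
    return gamma / (np.pi * (omega**2 + gamma**2))


def gaussian(omega, sigma, center=0.0):
    """Unit-area Gaussian with standard deviation ``sigma`` (μeV)."""
    if sigma <= 0:
        raise ValueError(f"Gaussian sigma must be > 0, got {sigma}")
    omega = np.asarray(omega, dtype=float)
    return np.exp(-0.5 * ((omega - center) / sigma) ** 2) / (sigma * _SQRT2PI)


def voigt(omega, sigma, gamma):
    """Unit-area Voigt profile: Gaussian(sigma) ⊗ Lorentzian(gamma).

    ``gamma = 0`` reduces to the pure Gaussian; broadcasting over array
    arguments is supported.
    """
    omega = np.asarray(omega, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    z = (omega + 1j * gamma) / (sigma * _SQRT2)
    return wofz(z).real / (sigma * _SQRT2PI)


def voigt_and_dgamma(omega, sigma, gamma):
    """Voigt profile and its exact partial derivative w.r.t. ``gamma``.

    Uses w'(z) = −2 z w(z) + 2i/√π, so the derivative costs no extra
    special-function evaluation.
    """
    omega = np.asarray(omega, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    z = (omega + 1j * gamma) / (sigma * _SQRT2)
    w = wofz(z)
    value = w.real / (sigma * _SQRT2PI)
    wprime = -2.0 * z * w + 2j / np.sqrt(np.pi)
    dvalue = (1j * wprime).real / (sigma**2 * 2.0 * np.sqrt(np.pi))
    return value, dvalue


def numeric_voigt_fft(omega, sigma, gamma, oversample=64, pad_halfwidths=400.0):
    """Brute-force numerical Gaussian ⊗ Lorentzian on a fine padded grid.

    Independent oracle for the analytic Voigt evaluation: both profiles are
    sampled on a uniform grid extending ``pad_halfwidths``·(σ+γ) beyond the
    requested points with ``oversample``× finer spacing, convolved by FFT,
    and interpolated back onto ``omega``.
    """
    from scipy.signal import fftconvolve

    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    width = sigma + gamma
    half = max(np.max(np.abs(omega)), 1.0) + pad_halfwidths * width
    dx = min(sigma, gamma if gamma > 0 else sigma) / oversample
    n = int(np.ceil(2 * half / dx)) | 1
    grid = np.linspace(-half, half, n)
    dx = grid[1] - grid[0]
    g = gaussian(grid, sigma)
    lo = lorentzian(grid, gamma) if gamma > 0 else None
    if lo is None:
        conv = g
    else:
        conv = fftconvolve(g, lo, mode="same") * dx
    return np.interp(omega, grid, conv)


# ---------------------------------------------------------------------------
# resolution and solvent models
# ---------------------------------------------------------------------------

@dataclass
class ResolutionModel:
    """Per-q two-Gaussian parametrization of the instrument resolution.

    ``amplitudes`` are area fractions (normalized to sum to 1 at each q),
    ``centers`` are elastic-line offsets (0 by default), ``sigmas`` are the
    Gaussian standard deviations in μeV.  Shapes are (nq, 2).
    """

    q: np.ndarray
    amplitudes: np.ndarray
    sigmas: np.ndarray
    centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        if self.centers is None:
            self.centers = np.zeros_like(self.amplitudes)
        else:
            self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        nq = self.q.size
        for name in ("amplitudes", "sigmas", "centers"):
            arr = getattr(self, name)
            if arr.shape[0] != nq:
                raise ValueError(f"{name} first dimension must match q grid")
        if np.any(self.amplitudes < 0):
            raise ValueError("resolution amplitudes must be >= 0")
        bad = np.where(np.any(self.sigmas <= 0, axis=1))[0]
        if bad.size:
            raise ValueError(f"non-positive resolution width at q index {bad[0]}")
        # normalize to unit area per q
        norm = self.amplitudes.sum(axis=1, keepdims=True)
        if np.any(norm <= 0):
            raise ValueError("resolution amplitudes sum to zero at some q")
        self.amplitudes = self.amplitudes / norm

    @property
    def nq(self) -> int:
        return self.q.size

    def q_index(self, q: float) -> int:
        idx = np.where(np.isclose(self.q, q, rtol=1e-10, atol=1e-8))[0]
        if idx.size == 0:
            raise KeyError(f"q = {q} not present in resolution model")
        return int(idx[0])

    def kernel(self, omega, iq: int):
        """Unit-area resolution line shape at q index ``iq``."""
        out = np.zeros_like(np.asarray(omega, dtype=float))
        for a, c, s in zip(self.amplitudes[iq], self.centers[iq], self.sigmas[iq]):
            if a > 0:
                out = out + a * gaussian(omega, s, c)
        return out

    def convolved_lorentzian(self, omega, gamma_q, with_grad=False):
        """Resolution ⊗ Lorentzian(γ(q)) for all q at once.

        ``gamma_q`` has shape (nq,); returns (nq, nw), plus ∂/∂γ if requested.
        γ = 0 entries reduce to the resolution shape itself (elastic term).
        """
        omega = np.asarray(omega, dtype=float)
        gamma_q = np.asarray(gamma_q, dtype=float)
        om = omega[None, None, :] - self.centers[:, :, None]
        sig = self.sigmas[:, :, None]
        gam = gamma_q[:, None, None]
        amp = self.amplitudes[:, :, None]
        if with_grad:
            v, dv = voigt_and_dgamma(om, sig, gam)
            return (amp * v).sum(axis=1), (amp * dv).sum(axis=1)
        return (amp * voigt(om, sig, gam)).sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "q": self.q.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "sigmas": self.sigmas.tolist(),
            "centers": self.centers.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResolutionModel":
        return cls(
            q=np.asarray(d["q"]),
            amplitudes=np.asarray(d["amplitudes"]),
            sigmas=np.asarray(d["sigmas"]),
            centers=np.asarray(d.get("centers")) if d.get("centers") is not None else None,
        )


@dataclass
class SolventModel:
    """Per-q D₂O contribution: one broad Lorentzian with fixed parameters.

    ``amplitude`` is the integrated solvent intensity per q (counts units of
    the spectra it was fitted to), ``gamma`` the Lorentzian HWHM in μeV.
    Amplitudes scale linearly with solvent volume, i.e. by (1 − φ) in a
    protein solution of total volume fraction φ.
    """

    q: np.ndarray
    amplitude: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.amplitude = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if self.amplitude.shape != self.q.shape or self.gamma.shape != self.q.shape:
            raise ValueError("amplitude and gamma must match the q grid")
        if np.any(self.amplitude < 0):
            raise ValueError("solvent amplitude must be >= 0")
        if np.any(self.gamma <= 0):
            raise ValueError("solvent width must be > 0")

    def q_index(self, q: float) -> int:
        idx = np.where(np.isclose(self.q, q, rtol=1e-10, atol=1e-8))[0]
        if idx.size == 0:
            raise KeyError(f"q = {q} not present in solvent model")
        return int(idx[0])

    def require_q(self, q_grid) -> None:
        missing = [float(q) for q in np.atleast_1d(q_grid)
                   if not np.any(np.isclose(self.q, q, rtol=1e-10, atol=1e-8))]
        if missing:
            raise ValueError(f"solvent model missing q values: {missing}")

    def scaled(self, factor: float) -> "SolventModel":
        return SolventModel(self.q.copy(), self.amplitude * factor, self.gamma.copy())

    def to_dict(self) -> dict:
        return {"q": self.q.tolist(), "amplitude": self.amplitude.tolist(),
                "gamma": self.gamma.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SolventModel":
        return cls(np.asarray(d["q"]), np.asarray(d["amplitude"]), np.asarray(d["gamma"]))


# ---------------------------------------------------------------------------
# internal-dynamics models
# ---------------------------------------------------------------------------

@dataclass
class EISFParams:
    """Elastic incoherent structure factor parameters.

    p: immobile hydrogen fraction; phi_mobile: fraction of the mobile
    hydrogens undergoing methyl-like three-site jumps (the rest diffuse in a
    sphere of radius R); a: mean methyl H–H distance in Å (fixed by geometry).
    """

    p: float
    phi_mobile: float
    R: float
    a: float = 1.715

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if not (0.0 <= self.phi_mobile <= 1.0):
            raise ValueError(f"phi_mobile must be in [0, 1], got {self.phi_mobile}")
        if self.R <= 0 or self.a <= 0:
            raise ValueError("R and a must be > 0")


@dataclass
class JumpDiffusionParams:
    """Jump-diffusion law for the internal line width: D_int (Å²/ns), tau (ns)."""

    D_int: float
    tau: float

    def __post_init__(self) -> None:
        if self.D_int <= 0 or self.tau <= 0:
            raise ValueError("D_int and tau must be > 0")


def eisf_model(params: EISFParams, q):
    """A0(q) = p + (1−p)·[φ_m·E_methyl(q; a) + (1−φ_m)·E_sphere(q; R)].

    E_methyl is the powder-averaged three-site jump EISF
    (1/3)(1 + 2·sin(qa)/(qa)); E_sphere is the diffusion-in-a-sphere EISF
    (3 j₁(qR)/(qR))².  A0(0) = 1 by construction.
    """
    q = np.asarray(q, dtype=float)
    qa = q * params.a
    e_methyl = np.where(qa > 0, (1.0 + 2.0 * np.sinc(qa / np.pi)) / 3.0, 1.0)
    qr = q * params.R
    with np.errstate(invalid="ignore", divide="ignore"):
        e_sphere = np.where(qr > 0, (3.0 * spherical_jn(1, qr) / np.where(qr > 0, qr, 1.0)) ** 2, 1.0)
    mobile = params.phi_mobile * e_methyl + (1.0 - params.phi_mobile) * e_sphere
    return params.p + (1.0 - params.p) * mobile


def jump_width(params: JumpDiffusionParams, q):
    """Internal-line HWHM γ(q) = ħ·D_int·q² / (1 + D_int·q²·τ) in μeV."""
    q = np.asarray(q, dtype=float)
    dq2 = params.D_int * q**2
    return HBAR_UEV_NS * dq2 / (1.0 + dq2 * params.tau)


# ---------------------------------------------------------------------------
# composite spectrum models (per q)
# ---------------------------------------------------------------------------

def convolve_with_resolution(components, resolution: ResolutionModel, q: float, omega=None):
    """Resolution ⊗ (sum of weighted Lorentzian / elastic terms) at one q.

    ``components`` is a sequence of (weight, gamma) pairs; gamma = 0 denotes
    an elastic delta term which becomes the resolution shape itself.
    """
    iq = resolution.q_index(q)
    omega = np.asarray(omega, dtype=float)
    out = np.zeros_like(omega)
    for weight, gamma in components:
        if gamma < 0:
            raise ValueError(f"negative Lorentzian width {gamma}")
        for a, c, s in zip(resolution.amplitudes[iq], resolution.centers[iq],
                           resolution.sigmas[iq]):
            if a > 0:
                out = out + weight * a * voigt(omega - c, s, gamma)
    return out


def _internal_width(gamma_base: float, gamma_int: float, mode: str) -> float:
    """Width of the internal line given the composition convention.

    "additive": internal and global processes convolve, widths add on top of
    the (broadest) global line.  "standalone": γ_int is used as-is and must
    already exceed the global width.
    """
    if mode == "additive":
        return gamma_base + gamma_int
    if mode == "standalone":
        if gamma_int <= gamma_base:
            raise ValueError(
                f"standalone internal width {gamma_int} must exceed the "
                f"global width {gamma_base}"
            )
        return gamma_int
    raise ValueError(f"unknown internal_width_mode {mode!r}")


def mono_model(omega, q, beta, gamma_glob, gamma_int, A0,
               solvent: SolventModel, resolution: ResolutionModel,
               internal_width_mode: str = "additive"):
    """Monodisperse-average model spectrum (density per μeV) at one q.

    resolution ⊗ [β·(A0·L(γ_glob) + (1−A0)·L(internal)) + solvent term].
    """
    if not (0.0 <= A0 <= 1.0):
        raise ValueError(f"A0 must be in [0, 1], got {A0}")
    if gamma_glob <= 0 or gamma_int <= 0:
        raise ValueError("widths must be > 0")
    g_int = _internal_width(gamma_glob, gamma_int, internal_width_mode)
    isq = solvent.q_index(q)
    components = [
        (beta * A0, gamma_glob),
        (beta * (1.0 - A0), g_int),
        (solvent.amplitude[isq], solvent.gamma[isq]),
    ]
    return convolve_with_resolution(components, resolution, q, omega)


def bidisperse_model(omega, q, D_BSA, D_Ig, weights, beta, A0, gamma_int,
                     solvent: SolventModel, resolution: ResolutionModel,
                     internal_width_mode: str = "additive"):
    """Bidisperse model spectrum (density per μeV) at one q.

    Two center-of-mass Lorentzians with widths ħ·D_i·q², weighted by the
    incoherent weights (s_BSA, s_Ig), sharing one internal line and one EISF:

    resolution ⊗ [β·(A0·(s_B·L(γ_B) + s_I·L(γ_I)) + (1−A0)·L(internal))
                  + solvent term]
    """
    if D_Ig > D_BSA:
        raise ValueError(f"constraint violated: D_Ig ({D_Ig}) must be <= D_BSA ({D_BSA})")
    if D_Ig <= 0:
        raise ValueError("diffusion coefficients must be > 0")
    s_b, s_i = weights
    if abs(s_b + s_i - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {s_b + s_i}")
    if not (0.0 <= A0 <= 1.0):
        raise ValueError(f"A0 must be in [0, 1], got {A0}")
    gamma_b = HBAR_UEV_NS * D_BSA * q**2
    gamma_i = HBAR_UEV_NS * D_Ig * q**2
    g_int = _internal_width(gamma_b, gamma_int, internal_width_mode)
    isq = solvent.q_index(q)
    components = [
        (beta * A0 * s_b, gamma_b),
        (beta * A0 * s_i, gamma_i),
        (beta * (1.0 - A0), g_int),
        (solvent.amplitude[isq], solvent.gamma[isq]),
    ]
    return convolve_with_resolution(components, resolution, q, omega)
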