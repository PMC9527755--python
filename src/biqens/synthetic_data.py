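"""Synthetic neutron backscattering measurements.

Generates the four measurement types the reduction and fitting stages expect
— vanadium (resolution), empty can, pure D₂O (solvent) and protein-mixture
samples — with the exact statistical structure the fits assume: a noise-free
model built from the package's own spectral components, then Poisson counting
noise.  Every generator takes an explicit seed; the generating ground truth
is stored in the spectrum metadata so recovery tests can close the loop.

The default instrument emulates a Si(111) backscattering spectrometer:
16 momentum transfers between 0.2 and 1.9 1/Å and 1024 energy channels over
±30 μeV, with a two-Gaussian resolution of order 1 μeV FWHM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import BSA, IG, ProteinSpecies, SampleComposition, incoherent_weights, volume_fractions
from .constants import HBAR_UEV_NS
from .spectra import SpectrumSet, trapezoid_weights
from .spectral_models import (
    EISFParams,
    JumpDiffusionParams,
    ResolutionModel,
    SolventModel,
    eisf_model,
    jump_width,
)

__all__ = [
    "InstrumentConfig",
    "GroundTruth",
    "make_resolution",
    "make_empty_can",
    "make_d2o",
    "make_mixture_spectra",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Instrument grids: q in 1/Å, ω in μeV.

    ``energy_window`` is the half-width of the usable range; the ω grid is
    uniform and symmetric about zero.
    """

    q_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.2, 1.9, 16))
    energy_window: float = 30.0
    channel_count: int = 1024
    hbar: float = HBAR_UEV_NS

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        object.__setattr__(self, "q_grid", q)
        if np.any(np.diff(q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if q[0] < 0.2 - 1e-9 or q[-1] > 1.9 + 1e-9:
            raise ValueError("q grid must lie within [0.2, 1.9] 1/Å")
        if self.energy_window <= 0 or self.channel_count < 8:
            raise ValueError("invalid energy window / channel count")

    @property
    def omega_grid(self) -> np.ndarray:
        return np.linspace(-self.energy_window, self.energy_window, self.channel_count)

    @property
    def channel_width(self) -> float:
        return 2.0 * self.energy_window / (self.channel_count - 1)


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic protein-mixture measurement.

    Diffusion coefficients in Å²/ns; beta_q (per-q protein amplitude in
    integrated counts) may be left None, in which case it is set from
    ``counts_scale`` (target expected counts in the peak channel) with a
    Debye–Waller-like q decay exp(−q²u²/3).
    """

    D_BSA: float = 4.5
    D_Ig: float = 1.5
    eisf: EISFParams = field(default_factory=lambda: EISFParams(p=0.4, phi_mobile=0.3, R=10.0))
    jump: JumpDiffusionParams = field(default_factory=lambda: JumpDiffusionParams(D_int=100.0, tau=0.1))
    counts_scale: float = 1e4
    beta_q: np.ndarray | None = None
    dw_u: float = 0.45
    internal_width_mode: str = "additive"

    def __post_init__(self) -> None:
        if self.D_BSA <= 0 or self.D_Ig <= 0:
            raise ValueError("diffusion coefficients must be > 0")
        if self.D_Ig >= self.D_BSA:
            raise ValueError(f"D_Ig ({self.D_Ig}) must be < D_BSA ({self.D_BSA})")
        if self.counts_scale <= 0:
            raise ValueError("counts_scale must be > 0")


# ---------------------------------------------------------------------------
# calibration measurements
# ---------------------------------------------------------------------------

def default_resolution_widths(config: InstrumentConfig):
    """Default two-Gaussian resolution parameters: a narrow core plus a wider
    pedestal, with a mild (10%) broadening across the q range."""
    nq = config.q_grid.size
    broaden = 1.0 + 0.1 * (config.q_grid - config.q_grid[0]) / (
        config.q_grid[-1] - config.q_grid[0])
    amplitudes = np.tile([0.75, 0.25], (nq, 1))
    sigmas = np.outer(broaden, [0.35, 1.0])
    return amplitudes, sigmas


def make_resolution(
    config: InstrumentConfig,
    widths: tuple[np.ndarray, np.ndarray] | None = None,
    counts_scale: float = 1e5,
    background: float = 5.0,
    seed: int = 0,
) -> tuple[SpectrumSet, ResolutionModel]:
    """Vanadium-like measurement: per-q two-Gaussian elastic line + Poisson noise.

    Returns the sampled spectra and the exact :class:`ResolutionModel` used.
    ``counts_scale`` is the expected count in the peak channel at each q;
    ``background`` a flat detector-background level in counts per channel.
    """
    if widths is None:
        widths = default_resolution_widths(config)
    amplitudes, sigmas = (np.atleast_2d(np.asarray(a, dtype=float)) for a in widths)
    model = ResolutionModel(q=config.q_grid, amplitudes=amplitudes, sigmas=sigmas)
    omega = config.omega_grid
    weights = trapezoid_weights(omega)
    rng = np.random.default_rng(seed)
    expected = np.empty((model.nq, omega.size))
    for iq in range(model.nq):
        shape = model.kernel(omega, iq) * weights
        expected[iq] = shape * (counts_scale / shape.max()) + background
    counts = rng.poisson(expected).astype(float)
    spec = SpectrumSet(
        q=config.q_grid, omega=omega, counts=counts,
        meta={"kind": "vanadium", "seed": seed, "counts_scale": counts_scale},
    )
    return spec, model


def make_empty_can(
    config: InstrumentConfig,
    level: float = 20.0,
    seed: int = 0,
) -> SpectrumSet:
    """Empty-can measurement: a flat background of ``level`` expected counts
    per channel at every q, Poisson sampled."""
    rng = np.random.default_rng(seed)
    expected = np.full((config.q_grid.size, config.channel_count), float(level))
    return SpectrumSet(
        q=config.q_grid, omega=config.omega_grid,
        counts=rng.poisson(expected).astype(float),
        meta={"kind": "empty_can", "seed": seed, "level": level},
    )


def make_d2o(
    config: InstrumentConfig,
    resolution: ResolutionModel,
    amplitude: float | np.ndarray = 3e4,
    solvent_D: float = 187.0,
    solvent_tau: float = 0.00125,
    can_level: float = 0.0,
    seed: int = 0,
) -> tuple[SpectrumSet, SolventModel]:
    """Pure-D₂O measurement: one broad Lorentzian per q, resolution-convolved.

    The width follows a jump-diffusion law with water-like defaults
    (D ≈ 187 Å²/ns, τ ≈ 1.25 ps), which within a ±30 μeV window appears as a
    nearly flat quasi-elastic background.  Returns the sampled spectra and
    the exact :class:`SolventModel` (amplitudes in integrated counts).
    """
    q = config.q_grid
    gamma = jump_width(JumpDiffusionParams(D_int=solvent_D, tau=solvent_tau), q)
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float), q.shape).copy()
    model = SolventModel(q=q, amplitude=amp, gamma=gamma)
    omega = config.omega_grid
    dens = resolution.convolved_lorentzian(omega, gamma) * amp[:, None]
    expected = dens * trapezoid_weights(omega) + can_level
    rng = np.random.default_rng(seed)
    spec = SpectrumSet(
        q=q, omega=omega, counts=rng.poisson(expected).astype(float),
        meta={"kind": "d2o", "seed": seed, "can_level": can_level},
    )
    return spec, model


# ---------------------------------------------------------------------------
# protein-mixture samples
# ---------------------------------------------------------------------------

def mixture_expected_counts(
    config: InstrumentConfig,
    composition: SampleComposition,
    truth: GroundTruth,
    resolution: ResolutionModel,
    solvent: SolventModel,
    species: tuple[ProteinSpecies, ProteinSpecies] = (BSA, IG),
    can_level: float = 0.0,
):
    """Noise-free expected counts of a mixture measurement, plus the per-q
    amplitudes actually used (resolves ``beta_q`` from ``counts_scale``).

    The model is the bidisperse scattering function: resolution ⊗
    [β(q)·(A0·(s_B·L(ħD_Bq²) + s_I·L(ħD_Iq²)) + (1−A0)·L(internal))
    + (1−φ)·solvent].  Either protein concentration may be zero, in which
    case the corresponding line carries zero weight (monodisperse limit).
    """
    q = config.q_grid
    omega = config.omega_grid
    solvent.require_q(q)
    if composition.c_BSA > 0 or composition.c_Ig > 0:
        s_b, s_i = incoherent_weights(composition, species)
        _, _, phi, _ = volume_fractions(composition, species)
    else:
        s_b, s_i, phi = 1.0, 0.0, 0.0
    A0 = eisf_model(truth.eisf, q)
    g_int = jump_width(truth.jump, q)
    gamma_b = HBAR_UEV_NS * truth.D_BSA * q**2
    gamma_i = HBAR_UEV_NS * truth.D_Ig * q**2
    if truth.internal_width_mode == "additive":
        g_tot = gamma_b + g_int
    else:
        g_tot = g_int
    # protein line shape per unit beta
    protein = (
        A0[:, None] * (
            s_b * resolution.convolved_lorentzian(omega, gamma_b)
            + s_i * resolution.convolved_lorentzian(omega, gamma_i)
        )
        + (1.0 - A0)[:, None] * resolution.convolved_lorentzian(omega, g_tot)
    )
    weights_w = trapezoid_weights(omega)
    if truth.beta_q is None:
        beta_raw = np.exp(-q**2 * truth.dw_u**2 / 3.0)
        peak = ((protein * beta_raw[:, None]) * weights_w).max()
        beta_q = beta_raw * (truth.counts_scale / peak)
    else:
        beta_q = np.asarray(truth.beta_q, dtype=float)
    solv_idx = np.array([solvent.q_index(qi) for qi in q])
    solv_amp = solvent.amplitude[solv_idx] * (1.0 - phi)
    solv_dens = resolution.convolved_lorentzian(omega, solvent.gamma[solv_idx])
    density = protein * beta_q[:, None] + solv_dens * solv_amp[:, None]
    expected = density * weights_w + can_level
    return expected, beta_q


def make_mixture_spectra(
    config: InstrumentConfig,
    composition: SampleComposition,
    truth: GroundTruth,
    resolution: ResolutionModel,
    solvent: SolventModel,
    seed: int = 0,
    species: tuple[ProteinSpecies, ProteinSpecies] = (BSA, IG),
    can_level: float = 0.0,
) -> SpectrumSet:
    """Poisson-sampled protein-mixture measurement.

    The generating ground truth, composition and seed are recorded in the
    spectrum metadata for parameter-recovery tests.
    """
    expected, beta_q = mixture_expected_counts(
        config, composition, truth, resolution, solvent, species, can_level)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(float)
    meta = {
        "kind": "sample",
        "seed": seed,
        "c_BSA": composition.c_BSA,
        "c_Ig": composition.c_Ig,
        "T": composition.T,
        "true_D_BSA": truth.D_BSA,
        "true_D_Ig": truth.D_Ig,
        "true_D_int": truth.jump.D_int,
        "true_tau": truth.jump.tau,
        "true_p": truth.eisf.p,
        "true_phi_mobile": truth.eisf.phi_mobile,
        "true_R": truth.eisf.R,
        "beta_q": beta_q,
        "can_level": can_level,
    }
    return SpectrumSet(q=config.q_grid, omega=config.omega_grid, counts=counts, meta=meta)
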