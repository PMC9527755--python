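"""Spectral fitting strategies.

Three Poisson maximum-likelihood fits of reduced sample spectra:

* :func:`fit_qwise_average` — the simple approach: each momentum transfer is
  fitted independently with one average center-of-mass Lorentzian plus one
  internal line (the monodisperse-average model); :func:`fit_fickian` then
  checks that the fitted widths follow γ = ħ·D·q².
* :func:`fit_monodisperse_global` — the same average model fitted to all q
  simultaneously with a single shared diffusion coefficient.
* :func:`fit_bidisperse_global` — the bidisperse model: two center-of-mass
  Lorentzians with widths ħ·D_BSA·q² and ħ·D_Ig·q² at fixed incoherent
  weights, one shared pair (D_BSA, D_Ig) across all q, per-q nuisance
  amplitudes, a monotonically non-increasing EISF, and one shared internal
  line.  Exactly one more free parameter than the global average fit.

Constraints are built into the parametrization: D_BSA = D_Ig + Δ with Δ > 0;
A0(q) = Π f_j with f_j ∈ [0, 1] (monotone non-increasing by construction);
the internal width is γ_BSA + w(q) with w > 0, hence always broader than the
BSA line.  Uncertainties come from the observed information; profile scans of
χ²_ν are available via :func:`robustness_scan`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._poisson import (
    covariance_from_hessian,
    deviance_hessian,
    deviance_residual_factor,
    minimize_deviance,
    poisson_deviance,
)
from .constants import HBAR_UEV_NS
from .spectra import SpectrumSet, trapezoid_weights
from .spectral_models import (
    EISFParams,
    JumpDiffusionParams,
    ResolutionModel,
    SolventModel,
    eisf_model,
    jump_width,
    voigt,
    voigt_and_dgamma,
)

__all__ = [
    "MonoFitResult",
    "BiFitResult",
    "fit_qwise_average",
    "fit_fickian",
    "fit_monodisperse_global",
    "fit_bidisperse_global",
    "compare_models",
    "robustness_scan",
    "profile_interval",
    "fit_internal_dynamics",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class MonoFitResult:
    """Average-model fit: per-q nuisances plus a single diffusion coefficient.

    ``gamma_int`` is the per-q internal width *offset* w(q); the full internal
    line width is gamma_glob + w(q).
    """

    mode: str                      # "qwise" or "global"
    q: np.ndarray
    beta: np.ndarray
    beta_err: np.ndarray
    gamma_glob: np.ndarray
    gamma_glob_err: np.ndarray
    gamma_int: np.ndarray
    gamma_int_err: np.ndarray
    A0: np.ndarray
    A0_err: np.ndarray
    D_av: float
    D_av_err: float
    chi2nu: float
    deviance: float
    n_free: int
    n_data: int
    converged_q: np.ndarray | None = None
    fickian: dict | None = None
    trace: np.ndarray | None = None
    _ctx: object = field(default=None, repr=False)


@dataclass
class BiFitResult:
    """Bidisperse global fit: the headline pair (D_BSA, D_Ig) with diagnostics."""

    q: np.ndarray
    D_BSA: float
    D_Ig: float
    D_BSA_err: float
    D_Ig_err: float
    weights: tuple[float, float]
    beta: np.ndarray
    A0: np.ndarray
    gamma_int: np.ndarray          # per-q internal width offsets w(q)
    chi2nu: float
    deviance: float
    n_free: int
    n_data: int
    cov_D: np.ndarray | None = None   # covariance of (D_Ig, Delta)
    trace: np.ndarray | None = None
    robustness: dict | None = None
    degenerate: bool = False
    _ctx: object = field(default=None, repr=False)

    @property
    def ci_BSA(self) -> tuple[float, float]:
        """68% (1σ) Wald interval for D_BSA."""
        return self.D_BSA - self.D_BSA_err, self.D_BSA + self.D_BSA_err

    @property
    def ci_Ig(self) -> tuple[float, float]:
        return self.D_Ig - self.D_Ig_err, self.D_Ig + self.D_Ig_err


# ---------------------------------------------------------------------------
# shared model evaluation
# ---------------------------------------------------------------------------

class _GlobalModel:
    """Deviance + analytic gradient for the global (all-q) spectral models.

    Parameter layout:
      mode "bi":   [D_Ig, Delta, beta(nq), f(nq), w(nq)]
      mode "mono": [D_av,        beta(nq), f(nq), w(nq)]
    with A0(q) = Π_{j<=q} f_j and internal width = γ_global(q) + w(q).
    """

    def __init__(self, sample: SpectrumSet, resolution: ResolutionModel,
                 solvent: SolventModel, weights=None, mode="bi", background=0.0):
        if mode not in ("bi", "mono"):
            raise ValueError(mode)
        self.mode = mode
        self.q = sample.q
        self.nq = sample.nq
        self.omega = sample.omega
        self.counts = sample.counts
        self.dw = trapezoid_weights(sample.omega)
        self.hq2 = HBAR_UEV_NS * self.q**2
        self.weights = (1.0, 0.0) if weights is None else tuple(weights)
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("incoherent weights must sum to 1")
        self.resolution = resolution
        if resolution.nq != self.nq or not np.allclose(resolution.q, self.q):
            raise ValueError("resolution model q grid does not match the sample")
        solvent.require_q(self.q)
        idx = np.array([solvent.q_index(qi) for qi in self.q])
        solv_dens = resolution.convolved_lorentzian(self.omega, solvent.gamma[idx])
        self.fixed = (solv_dens * solvent.amplitude[idx][:, None] * self.dw
                      + float(background))
        self.n_data = self.counts.size

    # -- parameter bookkeeping -------------------------------------------
    # Amplitudes and internal-width offsets are optimized on a log scale so
    # that all parameters have comparable magnitudes; ``split`` returns them
    # on the linear scale.
    @property
    def n_free(self) -> int:
        return (2 if self.mode == "bi" else 1) + 3 * self.nq

    def split(self, x):
        ng = 2 if self.mode == "bi" else 1
        nq = self.nq
        return (x[:ng], np.exp(x[ng:ng + nq]), x[ng + nq:ng + 2 * nq],
                np.exp(x[ng + 2 * nq:ng + 3 * nq]))

    def bounds(self):
        ng = [(0.05, 60.0)] if self.mode == "mono" else [(0.05, 60.0), (1e-3, 60.0)]
        return (ng + [(np.log(1e-2), np.log(1e12))] * self.nq
                + [(1e-4, 1.0)] * self.nq
                + [(np.log(0.05), np.log(400.0))] * self.nq)

    # -- evaluation -------------------------------------------------------
    def model_and_parts(self, x):
        glob, beta, f, w = self.split(x)
        A0 = np.cumprod(f)
        if self.mode == "bi":
            d_ig, delta = glob
            gam_b = self.hq2 * (d_ig + delta)
            gam_i = self.hq2 * d_ig
            Vb, dVb = self.resolution.convolved_lorentzian(self.omega, gam_b, with_grad=True)
            Vi, dVi = self.resolution.convolved_lorentzian(self.omega, gam_i, with_grad=True)
        else:
            gam_b = self.hq2 * glob[0]
            Vb, dVb = self.resolution.convolved_lorentzian(self.omega, gam_b, with_grad=True)
            Vi, dVi = Vb, dVb
        gam_t = gam_b + w
        Vt, dVt = self.resolution.convolved_lorentzian(self.omega, gam_t, with_grad=True)
        s_b, s_i = self.weights
        center = s_b * Vb + s_i * Vi if self.mode == "bi" else Vb
        protein = A0[:, None] * center + (1.0 - A0)[:, None] * Vt
        m = self.dw * beta[:, None] * protein + self.fixed
        return m, (A0, beta, center, Vb, Vi, Vt, dVb, dVi, dVt, protein, f)

    def value(self, x) -> float:
        m, _ = self.model_and_parts(x)
        return poisson_deviance(self.counts, m)

    def value_and_grad(self, x):
        m, parts = self.model_and_parts(x)
        A0, beta, center, Vb, Vi, Vt, dVb, dVi, dVt, protein, f = parts
        r = deviance_residual_factor(self.counts, m) * self.dw
        s_b, s_i = self.weights
        grad = np.empty_like(x)
        ng = 2 if self.mode == "bi" else 1
        w = np.exp(x[ng + 2 * self.nq:])
        # log-beta
        grad[ng:ng + self.nq] = np.sum(r * protein, axis=1) * beta
        # A0 (chain through cumulative product of f)
        gA0 = np.sum(r * beta[:, None] * (center - Vt), axis=1)
        csum = np.cumsum((gA0 * A0)[::-1])[::-1]  # Σ_{q>=j} gA0_q·A0_q
        grad[ng + self.nq:ng + 2 * self.nq] = csum / f
        # log internal-width offsets
        gw = np.sum(r * (beta * (1.0 - A0))[:, None] * dVt, axis=1)
        grad[ng + 2 * self.nq:] = gw * w
        # global widths; gamma_base enters the broad line as well
        base_term = np.sum(r * (beta * A0 * s_b)[:, None] * dVb, axis=1) + gw \
            if self.mode == "bi" else \
            np.sum(r * (beta * A0)[:, None] * dVb, axis=1) + gw
        if self.mode == "bi":
            ig_term = np.sum(r * (beta * A0 * s_i)[:, None] * dVi, axis=1)
            grad[0] = np.sum(self.hq2 * (base_term + ig_term))
            grad[1] = np.sum(self.hq2 * base_term)
        else:
            grad[0] = np.sum(self.hq2 * base_term)
        dev = poisson_deviance(self.counts, m)
        return dev, grad

    # -- initialization ---------------------------------------------------
    def initial_guess(self, D0=None):
        beta0 = np.maximum(self.counts.sum(axis=1) - self.fixed.sum(axis=1), 10.0)
        f0 = np.full(self.nq, 0.97)
        f0[0] = 0.95
        logw0 = np.full(self.nq, np.log(4.0))
        if self.mode == "mono":
            if D0 is None:
                D0 = 3.0
            return np.concatenate([[D0], np.log(beta0), f0, logw0])
        if D0 is None:
            D0 = (1.5, 3.0)
        return np.concatenate([list(D0), np.log(beta0), f0, logw0])


def _fit_global(model: _GlobalModel, x0_list, maxiter=600):
    best = None
    for x0 in x0_list:
        res = minimize_deviance(model.value_and_grad, x0, model.bounds(),
                                maxiter=maxiter)
        if best is None or res.fun < best.fun:
            best = res
        dof = model.n_data - model.n_free
        if best.fun / dof < 1.05:       # already a statistically good fit
            break
    return best


def _jittered_starts(x0, n_starts, seed, model):
    rng = np.random.default_rng(seed)
    starts = [x0]
    ng = 2 if model.mode == "bi" else 1
    for _ in range(max(0, n_starts - 1)):
        x = x0.copy()
        x[:ng] = x[:ng] * rng.lognormal(0.0, 0.35, size=ng)
        lo = np.array([b[0] for b in model.bounds()[:ng]])
        hi = np.array([b[1] for b in model.bounds()[:ng]])
        x[:ng] = np.clip(x[:ng], lo * 1.01, hi * 0.99)
        starts.append(x)
    return starts


# ---------------------------------------------------------------------------
# q-wise average fit (per-q independent)
# ---------------------------------------------------------------------------

class _QwiseModel:
    """Single-q average model: [log beta, gamma_glob, A0, w]."""

    def __init__(self, counts, omega, dw, res_amps, res_centers, res_sigmas,
                 fixed):
        self.counts = counts
        self.omega = omega
        self.dw = dw
        self.a = res_amps
        self.c = res_centers
        self.s = res_sigmas
        self.fixed = fixed

    def _conv(self, gamma):
        om = self.omega[None, :] - self.c[:, None]
        v, dv = voigt_and_dgamma(om, self.s[:, None], gamma)
        return (self.a[:, None] * v).sum(axis=0), (self.a[:, None] * dv).sum(axis=0)

    def value_and_grad(self, x):
        logbeta, gam, A0, w = x
        beta = np.exp(logbeta)
        Vg, dVg = self._conv(gam)
        Vt, dVt = self._conv(gam + w)
        protein = A0 * Vg + (1.0 - A0) * Vt
        m = self.dw * beta * protein + self.fixed
        r = deviance_residual_factor(self.counts, m) * self.dw
        grad = np.array([
            np.sum(r * protein) * beta,
            np.sum(r * beta * (A0 * dVg + (1.0 - A0) * dVt)),
            np.sum(r * beta * (Vg - Vt)),
            np.sum(r * beta * (1.0 - A0) * dVt),
        ])
        return poisson_deviance(self.counts, m), grad

    bounds = [(np.log(1e-2), np.log(1e12)), (1e-3, 60.0), (0.0, 1.0), (0.05, 400.0)]


def fit_qwise_average(sample: SpectrumSet, resolution: ResolutionModel,
                      solvent: SolventModel, background: float = 0.0,
                      q_max_cut: float | None = None) -> MonoFitResult:
    """Independent per-q Poisson fits of the monodisperse-average model.

    Each q is fitted with [β, γ_glob, A0, w]; widths are then regressed on q²
    (:func:`fit_fickian`) to extract the average diffusion coefficient.
    Non-converged q values are flagged and excluded from the Fickian fit.
    """
    nq, nw = sample.nq, sample.nw
    dw = trapezoid_weights(sample.omega)
    solvent.require_q(sample.q)
    out = {k: np.full(nq, np.nan) for k in
           ("beta", "beta_err", "gamma", "gamma_err", "A0", "A0_err", "w", "w_err")}
    converged = np.zeros(nq, dtype=bool)
    total_dev = 0.0
    for iq, qv in enumerate(sample.q):
        ir = resolution.q_index(qv)
        isv = solvent.q_index(qv)
        # fixed solvent term: resolution ⊗ solvent Lorentzian
        om = sample.omega[None, :] - resolution.centers[ir][:, None]
        v = voigt(om, resolution.sigmas[ir][:, None], solvent.gamma[isv])
        solv = (resolution.amplitudes[ir][:, None] * v).sum(axis=0)
        fixed = solv * solvent.amplitude[isv] * dw + background
        model = _QwiseModel(sample.counts[iq], sample.omega, dw,
                            resolution.amplitudes[ir], resolution.centers[ir],
                            resolution.sigmas[ir], fixed)
        n_tot = sample.counts[iq].sum()
        beta0 = max(n_tot - fixed.sum(), 10.0)
        best = None
        for gam0 in (0.5, 2.0, 6.0):
            res = minimize_deviance(model.value_and_grad,
                                    np.array([np.log(beta0), gam0, 0.8, 4.0]),
                                    model.bounds, maxiter=400)
            if best is None or res.fun < best.fun:
                best = res
        x = best.x
        beta_fit = np.exp(x[0])
        total_dev += best.fun
        dof_q = nw - 4
        converged[iq] = bool(best.success) and best.fun / dof_q < 3.0
        H = deviance_hessian(model.value_and_grad, x)
        cov = covariance_from_hessian(H, x, model.bounds, best.jac)
        err = np.sqrt(np.maximum(np.diag(cov), 0.0))
        # amplitude consistent with zero (σ_β = β·σ_logβ, so β < 3σ_β is
        # simply σ_logβ > 1/3) or collapsed onto its lower bound: the width
        # is unconstrained -> flag degenerate
        if (not np.isfinite(err[0]) or err[0] > 1.0 / 3.0
                or beta_fit < np.sqrt(max(n_tot, 1.0))):
            converged[iq] = False
        out["beta"][iq], out["gamma"][iq], out["A0"][iq], out["w"][iq] = \
            beta_fit, x[1], x[2], x[3]
        out["beta_err"][iq], out["gamma_err"][iq], out["A0_err"][iq], out["w_err"][iq] = \
            beta_fit * err[0], err[1], err[2], err[3]
    fick = fit_fickian(out["gamma"][converged], out["gamma_err"][converged],
                       sample.q[converged], q_max_cut=q_max_cut) \
        if converged.sum() >= 3 else None
    n_free = 4 * nq
    return MonoFitResult(
        mode="qwise", q=sample.q,
        beta=out["beta"], beta_err=out["beta_err"],
        gamma_glob=out["gamma"], gamma_glob_err=out["gamma_err"],
        gamma_int=out["w"], gamma_int_err=out["w_err"],
        A0=out["A0"], A0_err=out["A0_err"],
        D_av=fick["D_av"] if fick else np.nan,
        D_av_err=fick["D_av_err"] if fick else np.nan,
        chi2nu=total_dev / (sample.counts.size - n_free),
        deviance=total_dev, n_free=n_free, n_data=sample.counts.size,
        converged_q=converged, fickian=fick,
    )


def fit_fickian(gamma, gamma_err, q, q_max_cut: float | None = None) -> dict:
    """Weighted least-squares of γ(q) = slope·q² through the origin.

    Returns D_av = slope/ħ, its standard error, the weighted R², and per-point
    residuals (γ − ħ·D·q²)/σ so deviations at the highest q are visible.
    """
    gamma = np.asarray(gamma, dtype=float)
    gamma_err = np.asarray(gamma_err, dtype=float)
    q = np.asarray(q, dtype=float)
    keep = np.isfinite(gamma) & np.isfinite(gamma_err) & (gamma_err > 0)
    if q_max_cut is not None:
        keep &= q <= q_max_cut
    gamma, gamma_err, q = gamma[keep], gamma_err[keep], q[keep]
    if q.size < 3:
        raise ValueError(f"Fickian fit needs >= 3 usable q points, got {q.size}")
    x = q**2
    w = 1.0 / gamma_err**2
    slope = np.sum(w * x * gamma) / np.sum(w * x * x)
    slope_err = np.sqrt(1.0 / np.sum(w * x * x))
    fitted = slope * x
    ybar = np.sum(w * gamma) / np.sum(w)
    r2 = 1.0 - np.sum(w * (gamma - fitted) ** 2) / np.sum(w * (gamma - ybar) ** 2)
    return {
        "D_av": slope / HBAR_UEV_NS,
        "D_av_err": slope_err / HBAR_UEV_NS,
        "slope": slope,
        "r2_weighted": float(r2),
        "q": q,
        "residuals_sigma": (gamma - fitted) / gamma_err,
    }


# ---------------------------------------------------------------------------
# global fits
# ---------------------------------------------------------------------------

def fit_monodisperse_global(sample: SpectrumSet, resolution: ResolutionModel,
                            solvent: SolventModel, background: float = 0.0,
                            n_starts: int = 3, seed: int = 0,
                            errors: bool = True) -> MonoFitResult:
    """Global average-model fit: one D_av shared across all q."""
    model = _GlobalModel(sample, resolution, solvent, mode="mono",
                         background=background)
    # coarse scan for the shared width scale
    cands = [model.initial_guess(D0=d) for d in (1.0, 2.5, 5.0)]
    vals = [model.value(x) for x in cands]
    x0 = cands[int(np.argmin(vals))]
    best = _fit_global(model, _jittered_starts(x0, n_starts, seed, model))
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("global average fit failed to converge")
    glob, beta, f, w = model.split(best.x)
    A0 = np.cumprod(f)
    dof = model.n_data - model.n_free
    D_err = np.nan
    beta_err = np.full(model.nq, np.nan)
    A0_err = np.full(model.nq, np.nan)
    w_err = np.full(model.nq, np.nan)
    if errors:
        H = deviance_hessian(model.value_and_grad, best.x)
        cov = covariance_from_hessian(H, best.x, model.bounds(), best.jac)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
        D_err = sd[0]
        beta_err = beta * sd[1:1 + model.nq]        # log-scale parameters
        w_err = w * sd[1 + 2 * model.nq:]
        A0_err = _a0_errors(f, cov, offset=1 + model.nq)
    res = MonoFitResult(
        mode="global", q=sample.q,
        beta=beta, beta_err=beta_err,
        gamma_glob=model.hq2 * glob[0],
        gamma_glob_err=model.hq2 * D_err if errors else np.full(model.nq, np.nan),
        gamma_int=w.copy(), gamma_int_err=w_err,
        A0=A0, A0_err=A0_err,
        D_av=float(glob[0]), D_av_err=float(D_err),
        chi2nu=best.fun / dof, deviance=float(best.fun),
        n_free=model.n_free, n_data=model.n_data, trace=best.trace,
    )
    res._ctx = (model, best.x.copy())
    return res


def _a0_errors(f, cov, offset):
    """Propagate f-factor covariance onto A0 = Π f (linearized)."""
    nq = f.size
    A0 = np.cumprod(f)
    errs = np.empty(nq)
    sub = cov[offset:offset + nq, offset:offset + nq]
    for k in range(nq):
        jac = np.zeros(nq)
        jac[:k + 1] = A0[k] / f[:k + 1]
        errs[k] = np.sqrt(max(jac @ sub @ jac, 0.0))
    return errs


def fit_bidisperse_global(sample: SpectrumSet, resolution: ResolutionModel,
                          solvent: SolventModel, weights,
                          background: float = 0.0, n_starts: int = 3,
                          seed: int = 0, errors: bool = True,
                          mono_init: MonoFitResult | None = None) -> BiFitResult:
    """Simultaneous all-q bidisperse fit: one (D_BSA, D_Ig) pair shared.

    ``weights`` are the (s_BSA, s_Ig) incoherent weights from the sample
    composition.  The fit is initialized from a global average fit (computed
    if not passed), has exactly one more free parameter than it, and enforces
    D_Ig < D_BSA through the (D_Ig, Δ) parametrization.
    """
    model = _GlobalModel(sample, resolution, solvent, weights=weights,
                         mode="bi", background=background)
    if mono_init is None:
        mono_init = fit_monodisperse_global(sample, resolution, solvent,
                                            background=background,
                                            n_starts=1, seed=seed, errors=False)
    d_av = max(mono_init.D_av, 0.2)
    nuis = mono_init._ctx[1][1:] if mono_init._ctx is not None \
        else model.initial_guess()[2:]
    starts = []
    for d_ig, delta in ((0.5 * d_av, 0.9 * d_av), (0.8 * d_av, 0.4 * d_av),
                        (0.97 * d_av, 0.06 * d_av)):
        starts.append(np.concatenate([[d_ig, delta], nuis]))
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - len(starts))):
        base = starts[0].copy()
        base[:2] *= rng.lognormal(0, 0.35, 2)
        base[:2] = np.clip(base[:2], [0.06, 2e-3], [55.0, 55.0])
        starts.append(base)
    best = _fit_global(model, starts[:max(n_starts, 1)])
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("bidisperse global fit failed to converge "
                           f"(starts tried: {len(starts)})")
    glob, beta, f, w = model.split(best.x)
    d_ig, delta = glob
    A0 = np.cumprod(f)
    dof = model.n_data - model.n_free
    D_BSA_err = D_Ig_err = np.nan
    cov_D = None
    if errors:
        H = deviance_hessian(model.value_and_grad, best.x)
        cov = covariance_from_hessian(H, best.x, model.bounds(), best.jac)
        cov_D = cov[:2, :2]
        D_Ig_err = np.sqrt(max(cov_D[0, 0], 0.0))
        D_BSA_err = np.sqrt(max(cov_D[0, 0] + cov_D[1, 1] + 2 * cov_D[0, 1], 0.0))
    degenerate = bool(delta <= 3.0 * (np.sqrt(max(cov_D[1, 1], 0.0)) if cov_D is not None else 0.0)) \
        if errors else bool(delta < 0.05)
    res = BiFitResult(
        q=sample.q, D_BSA=float(d_ig + delta), D_Ig=float(d_ig),
        D_BSA_err=float(D_BSA_err), D_Ig_err=float(D_Ig_err),
        weights=tuple(weights), beta=beta, A0=A0, gamma_int=w.copy(),
        chi2nu=best.fun / dof, deviance=float(best.fun),
        n_free=model.n_free, n_data=model.n_data, cov_D=cov_D,
        trace=best.trace, degenerate=degenerate,
    )
    res._ctx = (model, best.x.copy())
    return res


def compare_models(mono: MonoFitResult, bi: BiFitResult) -> dict:
    """Goodness-of-fit comparison between the global average and bidisperse fits."""
    if mono.mode != "global":
        raise ValueError("model comparison requires the *global* average fit")
    if mono.n_data != bi.n_data:
        raise ValueError("fits were not performed on the same spectra")
    return {
        "chi2nu_mono": mono.chi2nu,
        "chi2nu_bi": bi.chi2nu,
        "delta_chi2nu": mono.chi2nu - bi.chi2nu,
        "deviance_mono": mono.deviance,
        "deviance_bi": bi.deviance,
        "n_free_mono": mono.n_free,
        "n_free_bi": bi.n_free,
        "extra_parameters": bi.n_free - mono.n_free,
    }


# ---------------------------------------------------------------------------
# robustness scan / profile likelihood
# ---------------------------------------------------------------------------

def _reduced_objective(model: _GlobalModel, x_opt, param: str, value: float):
    """Objective over nuisances with one global parameter pinned at ``value``."""
    if model.mode == "bi":
        names = {"D_Ig": 0, "Delta": 1}
    else:
        names = {"D_av": 0}
    if param in names:
        k = names[param]

        def fg(xr):
            x = np.concatenate([xr[:k], [value], xr[k:]])
            f, g = model.value_and_grad(x)
            return f, np.concatenate([g[:k], g[k + 1:]])

        x0 = np.concatenate([x_opt[:k], x_opt[k + 1:]])
        bounds = model.bounds()
        bounds = bounds[:k] + bounds[k + 1:]
        return fg, x0, bounds
    if param == "D_BSA" and model.mode == "bi":
        # D_BSA pinned: Delta = value − D_Ig, D_Ig stays free below value
        def fg(xr):
            d_ig = xr[0]
            x = np.concatenate([[d_ig, value - d_ig], xr[1:]])
            f, g = model.value_and_grad(x)
            return f, np.concatenate([[g[0] - g[1]], g[2:]])

        x0 = np.concatenate([[min(x_opt[0], value - 2e-3)], x_opt[2:]])
        bounds = [(0.05, value - 1e-3)] + model.bounds()[2:]
        return fg, x0, bounds
    raise ValueError(f"cannot scan parameter {param!r} in mode {model.mode!r}")


def robustness_scan(fit, param: str, grid) -> dict:
    """χ²_ν profile: re-minimize all nuisance parameters at each pinned value.

    ``fit`` is a result of one of the global fits (it carries its model
    context).  Grid values outside the parameter bounds are clipped with a
    warning.
    """
    if fit._ctx is None:
        raise ValueError("fit carries no model context (was it deserialized?)")
    model, x_opt = fit._ctx
    grid = np.asarray(grid, dtype=float)
    lo, hi = 0.06, 59.0
    if np.any(grid < lo) or np.any(grid > hi):
        warnings.warn("scan grid clipped to parameter bounds")
        grid = np.clip(grid, lo, hi)
    dof = model.n_data - model.n_free
    chi2 = np.empty(grid.size)
    for i, v in enumerate(grid):
        fg, x0, bounds = _reduced_objective(model, x_opt, param, v)
        res = minimize_deviance(fg, x0, bounds, maxiter=300)
        chi2[i] = res.fun / dof
    return {"param": param, "grid": grid, "chi2nu": chi2,
            "chi2nu_min": float(fit.deviance / dof)}


def profile_interval(fit, param: str, halfwidth_factor=4.0, n_grid=9) -> tuple[float, float]:
    """1σ interval from the deviance profile (Δdeviance = 1 crossing)."""
    model, x_opt = fit._ctx
    center = {"D_Ig": fit.D_Ig, "D_BSA": fit.D_BSA}.get(param)
    err = {"D_Ig": fit.D_Ig_err, "D_BSA": fit.D_BSA_err}.get(param)
    if center is None:
        raise ValueError(param)
    if not np.isfinite(err) or err <= 0:
        err = 0.25 * center
    grid = center + np.linspace(-halfwidth_factor, halfwidth_factor, n_grid) * err
    grid = grid[grid > 0.06]
    scan = robustness_scan(fit, param, grid)
    dof = model.n_data - model.n_free
    ddev = (scan["chi2nu"] - scan["chi2nu_min"]) * dof
    lo_side = grid[grid <= center]
    hi_side = grid[grid >= center]
    lo = _crossing(lo_side[::-1], ddev[grid <= center][::-1])
    hi = _crossing(hi_side, ddev[grid >= center])
    return (center - lo if lo is not None else grid[0],
            center + hi if hi is not None else grid[-1])


def _crossing(xs, ds):
    """Distance from xs[0] to the Δdev = 1 crossing (linear interpolation)."""
    for i in range(1, len(xs)):
        if ds[i] >= 1.0:
            frac = (1.0 - ds[i - 1]) / (ds[i] - ds[i - 1])
            return abs(xs[i - 1] + frac * (xs[i] - xs[i - 1]) - xs[0])
    return None


# ---------------------------------------------------------------------------
# internal dynamics: EISF and jump-diffusion parameter fits
# ---------------------------------------------------------------------------

def fit_internal_dynamics(q, A0, A0_err, gamma_int, gamma_int_err,
                          a: float = 1.715) -> dict:
    """Fit the EISF model to A0(q) and the jump-diffusion law to γ_int(q).

    Weighted least squares (lmfit) with the methyl H–H distance ``a`` fixed.
    Returns fitted :class:`EISFParams` / :class:`JumpDiffusionParams` with
    standard errors.
    """
    import lmfit

    q = np.asarray(q, dtype=float)
    A0 = np.asarray(A0, dtype=float)
    A0_err = np.asarray(A0_err, dtype=float)
    gamma_int = np.asarray(gamma_int, dtype=float)
    gamma_int_err = np.asarray(gamma_int_err, dtype=float)
    if q.size < 4:
        raise ValueError("need at least 4 q points to fit (p, phi_mobile, R)")

    def eisf_resid(params):
        model = eisf_model(EISFParams(p=params["p"].value,
                                      phi_mobile=params["phi_mobile"].value,
                                      R=params["R"].value, a=a), q)
        return (A0 - model) / A0_err

    pars = lmfit.Parameters()
    pars.add("p", value=0.3, min=0.0, max=1.0)
    pars.add("phi_mobile", value=0.3, min=0.0, max=1.0)
    pars.add("R", value=8.0, min=0.5, max=100.0)
    eisf_fit = lmfit.minimize(eisf_resid, pars)

    def jump_resid(params):
        model = jump_width(JumpDiffusionParams(D_int=params["D_int"].value,
                                               tau=params["tau"].value), q)
        return (gamma_int - model) / gamma_int_err

    jpars = lmfit.Parameters()
    jpars.add("D_int", value=50.0, min=1.0, max=5000.0)
    jpars.add("tau", value=0.05, min=1e-4, max=10.0)
    jump_fit = lmfit.minimize(jump_resid, jpars)

    ep = eisf_fit.params
    jp = jump_fit.params
    return {
        "eisf": EISFParams(p=ep["p"].value, phi_mobile=ep["phi_mobile"].value,
                           R=ep["R"].value, a=a),
        "eisf_err": {k: (ep[k].stderr if ep[k].stderr is not None else np.nan)
                     for k in ("p", "phi_mobile", "R")},
        "eisf_redchi": eisf_fit.redchi,
        "jump": JumpDiffusionParams(D_int=jp["D_int"].value, tau=jp["tau"].value),
        "jump_err": {k: (jp[k].stderr if jp[k].stderr is not None else np.nan)
                     for k in ("D_int", "tau")},
        "jump_redchi": jump_fit.redchi,
    }
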