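"""Data reduction: empty-can subtraction, resolution and solvent calibration.

The reduction chain mirrors standard backscattering practice: the empty-can
measurement is subtracted from every sample (errors in quadrature, negative
channels clipped to zero), the vanadium spectra are fitted per q with a sum
of two Gaussians by Poisson maximum likelihood to give the analytic
resolution model, and the pure-D₂O spectra fix the solvent Lorentzian whose
amplitude is thereafter rescaled by (1 − φ) and frozen for all sample fits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from ._poisson import (
    covariance_from_hessian,
    deviance_hessian,
    minimize_deviance,
    deviance_residual_factor,
    poisson_deviance,
)
from .spectra import SpectrumSet, trapezoid_weights
from .spectral_models import ResolutionModel, SolventModel, gaussian, voigt_and_dgamma

logger = logging.getLogger(__name__)

__all__ = ["ReductionReport", "subtract_empty_can", "fit_resolution", "fix_solvent"]


@dataclass
class ReductionReport:
    """Bookkeeping of one reduction pass: per-q fit parameters with
    uncertainties, goodness of fit, and subtraction scale factors."""

    resolution_params: list = field(default_factory=list)
    solvent_params: list = field(default_factory=list)
    subtraction: dict = field(default_factory=dict)
    chi2nu_resolution: list = field(default_factory=list)
    chi2nu_solvent: list = field(default_factory=list)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        with open(path, "w") as f:
            json.dump(self.__dict__, f, indent=2, default=default)


def subtract_empty_can(sample: SpectrumSet, empty: SpectrumSet,
                       scale: float = 1.0,
                       report: ReductionReport | None = None) -> SpectrumSet:
    """counts_out = counts_sample − scale·counts_empty, clipped at zero.

    Errors are propagated in quadrature; the number of clipped channels is
    logged (and recorded on the report if one is passed).
    """
    if not sample.same_grid(empty):
        raise ValueError("sample and empty-can spectra are on different (q, ω) grids")
    raw = sample.counts - scale * empty.counts
    clipped = int(np.sum(raw < 0))
    if clipped:
        logger.info("empty-can subtraction clipped %d negative channels", clipped)
    out = SpectrumSet(
        q=sample.q.copy(), omega=sample.omega.copy(),
        counts=np.maximum(raw, 0.0),
        errors=np.sqrt(sample.errors**2 + (scale * empty.errors) ** 2),
        meta={**sample.meta, "can_subtracted": True, "can_scale": scale},
    )
    if report is not None:
        report.subtraction = {"scale": scale, "clipped_channels": clipped}
    return out


class _TwoGaussModel:
    """Per-q vanadium model: [log area, frac, sigma1, sigma2, background]."""

    bounds = [(0.0, np.log(1e12)), (0.0, 1.0), (0.02, 30.0), (0.02, 30.0),
              (0.0, 1e9)]

    def __init__(self, counts, omega, dw):
        self.counts = counts
        self.omega = omega
        self.dw = dw

    def value_and_grad(self, x):
        logarea, frac, s1, s2, bg = x
        area = np.exp(logarea)
        g1 = gaussian(self.omega, s1)
        g2 = gaussian(self.omega, s2)
        shape = frac * g1 + (1.0 - frac) * g2
        m = self.dw * area * shape + bg
        r0 = deviance_residual_factor(self.counts, m)
        r = r0 * self.dw
        dg1 = g1 * (self.omega**2 / s1**3 - 1.0 / s1)
        dg2 = g2 * (self.omega**2 / s2**3 - 1.0 / s2)
        grad = np.array([
            np.sum(r * shape) * area,
            np.sum(r * area * (g1 - g2)),
            np.sum(r * area * frac * dg1),
            np.sum(r * area * (1.0 - frac) * dg2),
            np.sum(r0),
        ])
        return poisson_deviance(self.counts, m), grad


def fit_resolution(vanadium: SpectrumSet,
                   report: ReductionReport | None = None) -> ResolutionModel:
    """Per-q two-Gaussian (+ flat background) Poisson-MLE fit of the vanadium
    spectra.

    Returns the resolution model (area-normalized component fractions and
    widths, ordered narrow-first).  Raises if the fit does not converge at
    some q, naming that q.
    """
    dw = trapezoid_weights(vanadium.omega)
    nq = vanadium.nq
    amplitudes = np.empty((nq, 2))
    sigmas = np.empty((nq, 2))
    for iq, qv in enumerate(vanadium.q):
        counts = vanadium.counts[iq]
        if counts.max() <= 0:
            raise RuntimeError(f"vanadium spectrum empty at q = {qv:.3f}")
        model = _TwoGaussModel(counts, vanadium.omega, dw)
        best = None
        la0 = np.log(max(counts.sum(), 2.0))
        bg0 = float(np.median(counts))
        for x0 in ([la0, 0.7, 0.3, 1.2, bg0], [la0, 0.5, 0.5, 2.0, bg0]):
            res = minimize_deviance(model.value_and_grad, np.asarray(x0, float),
                                    model.bounds, maxiter=400)
            if best is None or res.fun < best.fun:
                best = res
        dof = counts.size - 5
        chi2nu = best.fun / dof
        if not np.isfinite(chi2nu) or chi2nu > 5.0:
            raise RuntimeError(
                f"resolution fit did not converge at q = {qv:.3f} (chi2nu = {chi2nu:.2f})")
        area = float(np.exp(best.x[0]))
        _, frac, s1, s2, bg = best.x
        if s1 > s2:
            s1, s2, frac = s2, s1, 1.0 - frac
        amplitudes[iq] = (frac, 1.0 - frac)
        sigmas[iq] = (s1, s2)
        if report is not None:
            H = deviance_hessian(model.value_and_grad, best.x)
            cov = covariance_from_hessian(H, best.x, model.bounds, best.jac)
            err = np.sqrt(np.maximum(np.diag(cov), 0.0))
            err[0] *= area    # log-area -> area
            report.resolution_params.append(
                {"q": float(qv), "area": area, "frac_narrow": frac,
                 "sigma_narrow": s1, "sigma_broad": s2, "background": bg,
                 "errors": err.tolist(), "chi2nu": chi2nu})
            report.chi2nu_resolution.append(chi2nu)
    return ResolutionModel(q=vanadium.q, amplitudes=amplitudes, sigmas=sigmas)


class _SolventFitModel:
    """Per-q D₂O model: [log amplitude, gamma], resolution-convolved Lorentzian."""

    bounds = [(0.0, np.log(1e12)), (0.01, 5000.0)]

    def __init__(self, counts, omega, dw, res_amps, res_centers, res_sigmas,
                 background=0.0):
        self.counts = counts
        self.omega = omega
        self.dw = dw
        self.a = res_amps
        self.c = res_centers
        self.s = res_sigmas
        self.background = background

    def value_and_grad(self, x):
        amp = np.exp(x[0])
        gam = x[1]
        om = self.omega[None, :] - self.c[:, None]
        v, dv = voigt_and_dgamma(om, self.s[:, None], gam)
        shape = (self.a[:, None] * v).sum(axis=0)
        dshape = (self.a[:, None] * dv).sum(axis=0)
        m = self.dw * amp * shape + self.background
        r = deviance_residual_factor(self.counts, m) * self.dw
        grad = np.array([np.sum(r * shape) * amp, np.sum(r * amp * dshape)])
        return poisson_deviance(self.counts, m), grad


def fix_solvent(d2o: SpectrumSet, resolution: ResolutionModel,
                phi_total: float, background: float = 0.0,
                report: ReductionReport | None = None) -> SolventModel:
    """Fit the per-q solvent Lorentzian from pure D₂O, rescale by (1 − φ).

    The returned model is meant to be frozen for all subsequent sample fits
    of the sample whose total protein volume fraction is ``phi_total``
    (volume displacement: amplitude × (1 − φ); the width is kept).
    """
    if not (0.0 <= phi_total < 1.0):
        raise ValueError(f"phi_total must be in [0, 1), got {phi_total}")
    dw = trapezoid_weights(d2o.omega)
    nq = d2o.nq
    amplitude = np.empty(nq)
    gamma = np.empty(nq)
    for iq, qv in enumerate(d2o.q):
        ir = resolution.q_index(qv)
        model = _SolventFitModel(d2o.counts[iq], d2o.omega, dw,
                                 resolution.amplitudes[ir],
                                 resolution.centers[ir],
                                 resolution.sigmas[ir], background)
        best = None
        for gam0 in (5.0, 30.0, 120.0):
            x0 = np.array([np.log(max(d2o.counts[iq].sum(), 10.0)), gam0])
            res = minimize_deviance(model.value_and_grad, x0, model.bounds,
                                    maxiter=300)
            if best is None or res.fun < best.fun:
                best = res
        if not best.success and best.fun / (d2o.nw - 2) > 5.0:
            raise RuntimeError(f"solvent fit did not converge at q = {qv:.3f}")
        amplitude[iq], gamma[iq] = np.exp(best.x[0]), best.x[1]
        if report is not None:
            H = deviance_hessian(model.value_and_grad, best.x)
            cov = covariance_from_hessian(H, best.x, model.bounds, best.jac)
            err = np.sqrt(np.maximum(np.diag(cov), 0.0))
            err[0] *= amplitude[iq]   # log-amplitude -> amplitude
            chi2nu = best.fun / (d2o.nw - 2)
            report.solvent_params.append(
                {"q": float(qv), "amplitude_pure": amplitude[iq],
                 "gamma": gamma[iq], "errors": err.tolist(),
                 "phi_total": phi_total, "chi2nu": chi2nu})
            report.chi2nu_solvent.append(chi2nu)
    return SolventModel(q=d2o.q, amplitude=amplitude * (1.0 - phi_total),
                        gamma=gamma)
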