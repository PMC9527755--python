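# Methods

`biqens` separates the apparent short-time center-of-mass self-diffusion
coefficients of two label-free proteins — bovine serum albumin (BSA,
66.4 kDa) and polyclonal immunoglobulin (Ig, 150 kDa) — from joint
quasi-elastic neutron backscattering spectra, and compares the result with a
bidisperse hard-sphere colloid description.  Because no measured spectra are
distributed with the package, a synthetic-data module generates
instrument-realistic measurements with known ground truth; every stage of
the pipeline is validated by parameter recovery.

## Scattering model

The measured intensity at momentum transfer q and energy transfer ℏω is
modeled as the instrument resolution R(q, ω) convolved with a sum of
quasi-elastic components:

    S(q, ω) = R ⊗ [ β(q) · S_protein(q, ω) + β_solv(q) · L(ω; γ_solv(q)) ]

* **Resolution.** Per q, a sum of two Gaussians fitted to a vanadium
  measurement by Poisson maximum likelihood (plus a flat background).
  Component areas are normalized to one; line centers are fixed at zero.
* **Protein signal.** The center-of-mass motion of each species is Fickian
  on the accessible time scale, giving Lorentzians of half-width
  γ_i = ħ·D_i·q² (ħ = 0.6582119569 μeV·ns; D in Å²/ns, q in 1/Å, γ in μeV).
  Internal dynamics contribute one additional Lorentzian shared between the
  species, weighted by 1 − A0(q) where A0 is the elastic incoherent
  structure factor.  In the *average* model a single Lorentzian replaces the
  two center-of-mass lines.  The bidisperse protein term reads

      S_protein = A0(q)·[s_BSA·L(γ_BSA) + s_Ig·L(γ_Ig)] + (1 − A0(q))·L(γ_int)

  with spectral weights s_i ∝ (molar concentration)·σ_inc,i normalized to
  s_BSA + s_Ig = 1.  The per-molecule incoherent cross sections shipped as
  defaults are σ_BSA = 464 377.95 barn and σ_Ig = 1 011 495.41 barn
  (computed from the crystal structures 4F5S and 1IGT); a PDB-based
  calculator is included as a cross-check, but its result depends on the
  hydrogen/deuteration convention, so the constants are authoritative for
  the weights.
* **Internal line composition.** The width of the internal line is
  γ_BSA + w(q) ("additive" convention: global and internal processes
  compose), which automatically satisfies the physical constraint that the
  internal line is broader than the broadest center-of-mass line.  A
  `standalone` mode (w used as-is, validated against the constraint) is
  available in the model functions.
* **Solvent.** One broad Lorentzian per q, fitted once to a pure-D₂O
  measurement and then *frozen*; in a protein solution of total volume
  fraction φ its amplitude is rescaled by (1 − φ) (volume displacement;
  amplitude-only, the width is kept).
* **Convolution.** Every Gaussian ⊗ Lorentzian term is a Voigt profile
  evaluated analytically via the Faddeeva function `w(z)`, which also gives
  the exact derivative ∂V/∂γ used by the gradient-based fits.  A
  brute-force FFT convolution is retained as an independent numerical
  oracle in the tests.

## Fitting

All spectral fits minimize the Poisson deviance
D = 2 Σ [m − n + n ln(n/m)] (−2 log L up to a data-only constant), reported
as χ²_ν = D/(n_data − n_free).  Expected counts are model density times
trapezoid channel weights, so total expected counts equal the window
integral of the density.

Three strategies:

1. **q-wise average fit** — each q independently: [β, γ_glob, A0, w].
   The fitted γ_glob(q) is then regressed on q² (weighted least squares
   through the origin) to give D_av; the Fickian law is *not* imposed.
   Degenerate fits (amplitude consistent with zero) are flagged and
   excluded.
2. **Global average fit** — one shared D_av across all q, with per-q
   nuisance parameters β(q), A0(q), w(q).
3. **Global bidisperse fit** — one shared pair (D_BSA, D_Ig), same nuisance
   structure: exactly one more free parameter than the global average fit.

Constraints are enforced by construction rather than by penalties:
D_Ig < D_BSA via D_BSA = D_Ig + Δ with Δ > 0; the EISF is monotonically
non-increasing and bounded via A0(q_k) = Π_{j≤k} f_j with f_j ∈ [0, 1];
internal width offsets w(q) > 0.

Numerical choices: amplitudes and width offsets are optimized in log space
so all parameters have comparable scale; L-BFGS-B with analytic gradients,
relative objective tolerance 1e-10, up to 600 iterations; three starts (one
seeded from the global average fit with small/large splitting ratios, the
rest jittered), stopping early once χ²_ν < 1.05.  The optimizer trace
(best objective per iteration) is recorded and is non-increasing.

Uncertainties are Wald intervals from the observed information: a
central-difference Hessian of the deviance over *all* free parameters
(built from the analytic gradient), inverted with bound-active parameters
held fixed; the covariance of D_BSA follows from that of (D_Ig, Δ).
Profile-likelihood scans (χ²_ν re-minimized over all nuisances at fixed
parameter values) are available for robustness assessment and give 1σ
intervals consistent with the Wald ones on well-conditioned data.

Internal dynamics are summarized after the spectral fits: A0(q) is fitted
with the EISF model

    A0 = p + (1 − p)·[φ_m·(1 + 2 sin(qa)/(qa))/3 + (1 − φ_m)·(3 j₁(qR)/(qR))²]

(immobile fraction p; methyl three-site jumps with fixed H–H distance
a = 1.715 Å; diffusion in a sphere of radius R), and the internal width
offsets with the jump-diffusion law γ = ħ·D_int·q²/(1 + D_int·q²·τ).
These are weighted least-squares fits (lmfit).  The additive mixture of
methyl and sphere terms follows the established EISF literature; a product
form is deliberately not substituted.

## Synthetic data

The generator emulates a Si(111) backscattering spectrometer: 16 momentum
transfers in 0.2–1.9 1/Å, 1024 uniform energy channels over ±30 μeV, a
two-Gaussian resolution (σ = 0.35 and 1.0 μeV, area fractions 0.75/0.25,
broadening by 10% across the q range), a broad solvent line following a
water-like jump-diffusion law (D = 187 Å²/ns, τ = 1.25 ps — essentially
flat within the window), a flat empty-can/detector background, and Poisson
counting noise on every channel.  Default ground truth: D_BSA = 4.5 and
D_Ig = 1.5 Å²/ns, internal dynamics D_int = 100 Å²/ns, τ = 0.1 ns, EISF
(p, φ_m, R) = (0.4, 0.3, 10 Å), per-q amplitudes with a Debye–Waller-like
decay (u = 0.45 Å) scaled so the peak channel expects ~10⁴ counts.  Count
rates are not published for the original experiments, so the counts scale
is a package choice that makes the Poisson likelihood regime realistic
while keeping the suite fast.

What the generator does *not* emulate: coherent scattering and
structure-factor effects, multiple scattering, detector efficiency maps,
self-shielding, anisotropic rotational diffusion, and distinct internal
dynamics per species.  Passing recovery tests therefore demonstrate the
statistical identifiability of the bidisperse decomposition under the
model's own assumptions, not robustness to these instrumental or physical
systematics.

## Colloid theory chain

For each sample composition the theoretical apparent diffusion coefficients
are produced by:

1. **Dilute-limit anchors.** D_t0 = k_BT/(6πηR_H), D_r0 = k_BT/(8πηR_H³),
   with the D₂O viscosity from a Vogel-type correlation
   η(T) = 1.23·2.414e-2·10^{247.8/(T−140)} mPa·s (the light-water Vogel fit
   scaled to heavy water at 298 K).
2. **Effective hard-sphere radii.** The default hydrodynamic radii are
   hydrated equivalent spheres, R_H = (3Mν(1+h)/4πN_A)^{1/3} with hydration
   volume factor h = 0.4: 30.0 Å (BSA) and 39.5 Å (Ig), size ratio 1.32.
   This choice keeps the effective volume fraction φ_theo ≈ 1.40·φ for both
   species, inside the validity range of the mixture expansion at every
   sample condition (DLS-style radii would push φ_theo beyond close
   packing at the highest concentrations).  Both radii are plain
   `ProteinSpecies` fields and can be overridden.
3. **Short-time mixture hydrodynamics.** Normalized self-diffusivities from
   the pairwise-additive first-order expansion
   d_i = 1 + Σ_j I(λ_ij)·φ_j, λ_ij = R_j/R_i, with the size-ratio
   dependence of the leading far-field (method-of-reflections) two-body
   integrals — I_t(λ) = k_t·2/(1+λ), I_r(λ) = k_r·8/(1+λ)³ — calibrated so
   λ = 1 reproduces the exact monodisperse dilute-limit coefficients
   k_t = −1.8315 and k_r = −0.631.  The coefficient table is a dataclass
   that can be replaced wholesale (e.g. by published polynomial fits);
   evaluation refuses to extrapolate beyond φ = 0.45.  The expansion is
   first order in φ: quantitatively rough at the highest concentrations,
   but it preserves the exact dilute limits, the monodisperse reduction,
   and the small-faster/large-slower ordering that the comparison tests.
4. **Apparent diffusion coefficient.** A rigid sphere with uniformly
   distributed incoherent scatterers produces the line
   Σ_l B_l(qR)·L(ħ(D_t·q² + l(l+1)·D_r)) with
   B_l = 3(2l+1)∫₀¹ j_l(qR·u)²u²du; D(q) is its half-width at half-maximum
   divided by ħq², found by bracketed root finding, and is averaged
   (unweighted) over the instrument q grid.  The l-series is truncated when
   the residual weight falls below 1e-6 (cap l = 256, which covers
   qR ≲ 200; exceeding the cap raises rather than truncating silently).
5. **Renormalization to experimental conditions.** Because the mapping
   between experimental φ and φ_theo is only defined for pure solutions,
   the mixture prediction is expressed as
   D_theo(φ) = [D_mix/D_mono](φ_theo) × D_pure(φ): the
   mixture-to-monodisperse ratio at the same effective volume fraction
   multiplies the pure-solution parametrization at the experimental φ.
   At mixing ratios y = 0 and y = 1 this reduces exactly to the pure
   curves.  Pure-solution curves are required inputs (polynomials in φ
   with a validity range); synthetic round trips build them
   self-consistently from the theory chain itself.
6. **Averages and deviations.** The theoretical average D is obtained the
   same way as experimentally: the s-weighted sum of the two Lorentzians is
   approximated by a single Lorentzian by least squares on the line shape
   over the ±30 μeV window (amplitude profiled analytically), per q, then
   averaged.  Relative deviations Δ_i = (D_i − D_pure,i(φ))/D_pure,i(φ) are
   reported in percent; for any genuine mixture Δ_BSA > 0 and Δ_Ig < 0.

## Pipeline

`run_pipeline` chains the stages for a grid of mixing ratios at one total
volume fraction: simulate calibrations → fit resolution → fix solvent →
simulate samples whose ground-truth D values come from the theory chain →
subtract the empty can → q-wise, global-average and global-bidisperse fits
→ theory comparison → CSV/JSON tables.  All randomness derives from a
single root seed (per-stage seeds are deterministic functions of it), so a
rerun with the same seed is bit-identical.

## Problem sizes used in the shipped checks

The default instrument (16 q × 1024 channels, peak ~10⁴ counts) is used for
the headline parameter-recovery checks; reduced grids (8 q × 256–512
channels, proportionally lower counts) are used where many repeated fits
are needed (coverage and interval-growth studies).  These sizes are the
package's own choices for a desk-scale synthetic study; all of them are
set in the test/acceptance code explicitly.

## Known limitations

* The mixture hydrodynamics is a first-order pairwise-additive expansion,
  not the full semi-empirical polynomial parametrization of the underlying
  Stokesian-dynamics work; magnitudes of crowding effects at φ_theo ≳ 0.3
  are approximate (the published coefficient tables can be dropped in via
  `MixtureCoefficients`).
* Ig is treated as a sphere; its anisotropy and any patchy interactions are
  outside the model.
* Wald intervals undercover slightly in strongly asymmetric mixtures where
  the minority-species likelihood is non-quadratic; the profile-likelihood
  scan is the fallback.
* The per-molecule cross-section calculator's absolute values depend on the
  H/D-exchange convention; the shipped constants are used for the weights,
  and the calculator reports its own sum for comparison only.
* After empty-can subtraction the channel counts are treated as Poisson for
  the deviance; strictly they are differences of Poisson variates.  At the
  count levels involved the approximation is excellent.
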