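"""Physical constants and unit conventions.

Unit conventions used throughout the package:

* momentum transfer ``q`` in 1/Å
* energy transfer ``ω`` in μeV
* diffusion coefficients in Å²/ns (1 Å²/ns = 1e-9 m²/s · 1e-2 = 1e-11 m²/s... see
  :data:`M2_PER_S_TO_A2_PER_NS`)
* Lorentzian half-widths (HWHM) in μeV via γ = ħ·D·q² with ħ in μeV·ns
* concentrations in mg/mL, molar masses in kDa, cross sections in barn
"""

#: Reduced Planck constant in μeV·ns (CODATA: 6.582119569e-16 eV·s).
HBAR_UEV_NS = 0.6582119569

#: Boltzmann constant in J/K.
KB_J_PER_K = 1.380649e-23

#: Avogadro constant in 1/mol.
N_AVOGADRO = 6.02214076e23

#: Conversion factor from m²/s to Å²/ns.
M2_PER_S_TO_A2_PER_NS = 1e11

#: Gaussian FWHM / sigma.
GAUSS_FWHM_FACTOR = 2.3548200450309493  # 2 sqrt(2 ln 2)
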