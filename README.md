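# biqens

Separating the short-time self-diffusion of two label-free proteins from
joint quasi-elastic neutron scattering (QENS) spectra, with a bidisperse
hard-sphere colloid theory to compare against.

## The problem

In crowded solutions the diffusion of a protein depends not only on the
total macromolecular volume fraction φ but on the *size distribution* of
the crowders: in a binary mixture the smaller species diffuses faster, and
the larger species slower, than in its own monodisperse solution at the
same φ.  High-resolution neutron backscattering measures the incoherent
(self-) dynamic structure factor of everything hydrogenated in the beam at
once, so a mixture of bovine serum albumin (BSA, 66.4 kDa) and polyclonal
immunoglobulin (Ig, 150 kDa) yields a *joint* spectrum.  This package
implements the analysis that pulls the two apparent center-of-mass
diffusion coefficients apart:

* a spectral model in which each species contributes a Lorentzian of
  half-width γ_i = ħ·D_i·q² (Fickian short-time diffusion), weighted by its
  known incoherent cross section and molar concentration, plus one shared
  internal-dynamics Lorentzian with an elastic incoherent structure factor
  A0(q), a frozen D₂O solvent line, everything convolved with a per-q
  two-Gaussian instrument resolution;
* a *global* Poisson maximum-likelihood fit over all momentum transfers
  simultaneously in which a single pair (D_BSA, D_Ig) is shared across q —
  only one parameter more than the single-species average model;
* a colloid theory chain (pairwise-additive short-time hydrodynamics of a
  binary hard-sphere mixture, apparent-D from translational + rotational
  line superposition, renormalization onto pure-solution curves) that
  predicts the same quantities from the sample composition alone.

The original neutron spectra are not public, so a synthetic-data module
generates instrument-realistic measurements (vanadium, empty can, pure
D₂O, protein mixtures; Poisson counting noise) with known ground truth, and
every pipeline stage is validated by parameter recovery.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from biqens import (InstrumentConfig, GroundTruth, SampleComposition,
                    incoherent_weights, make_resolution, make_d2o,
                    make_mixture_spectra, fit_monodisperse_global,
                    fit_bidisperse_global)

instr = InstrumentConfig()                      # 16 q in 0.2-1.9 1/A, +-30 ueV
_, resolution = make_resolution(instr, seed=1)  # exact two-Gaussian resolution
_, solvent = make_d2o(instr, resolution, seed=2)

comp = SampleComposition(c_BSA=136.1, c_Ig=135.3, T=295.0)  # phi=0.2, y=0.5
truth = GroundTruth(D_BSA=4.5, D_Ig=1.5)        # A^2/ns
sample = make_mixture_spectra(instr, comp, truth, resolution, solvent, seed=3)

weights = incoherent_weights(comp)              # (s_BSA, s_Ig) = (0.51, 0.49)
solvent_in_sample = solvent.scaled(1 - 0.2)     # amplitude x (1 - phi), frozen
mono = fit_monodisperse_global(sample, resolution, solvent_in_sample)
bi = fit_bidisperse_global(sample, resolution, solvent_in_sample, weights,
                           mono_init=mono)
print(f"D_av  = {mono.D_av:.3f} A^2/ns   chi2nu = {mono.chi2nu:.3f}")
print(f"D_BSA = {bi.D_BSA:.3f} +- {bi.D_BSA_err:.3f} A^2/ns")
print(f"D_Ig  = {bi.D_Ig:.3f} +- {bi.D_Ig_err:.3f} A^2/ns   chi2nu = {bi.chi2nu:.3f}")
```

prints

```
D_av  = 2.080 A^2/ns   chi2nu = 1.072
D_BSA = 4.392 +- 0.070 A^2/ns
D_Ig  = 1.501 +- 0.009 A^2/ns   chi2nu = 1.003
```

The average fit lands between the two species (its χ²ν is visibly worse
because a single Lorentzian cannot represent both), while the bidisperse
fit — one extra parameter — recovers the generating coefficients to 2.4%
(about 1.5σ on this realization) and 0.1% (within 1σ).

A full synthetic experiment (simulate → reduce → fit both models → compare
with theory across mixing ratios) runs from the command line:

```bash
biqens run-all --out results/demo --seed 1
biqens theory --phi 0.2 --y 0.5          # theory chain only
biqens xsec structure.pdb                # incoherent cross section from a PDB
```

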