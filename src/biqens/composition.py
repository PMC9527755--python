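"""Sample-composition bookkeeping.

Converts (c_BSA, c_Ig, T) into the quantities the spectral fits and the
colloid-theory comparison need:

* spectral weights (s_BSA, s_Ig) proportional to molar concentration times
  per-molecule incoherent cross section,
* partial and total volume fractions φ_i = c_i·ν_i and the mixing ratio
  y = φ_BSA/φ,
* the effective hard-sphere volume fraction φ_theo from number densities and
  hydrodynamic radii,
* an incoherent cross-section calculator from a PDB structure or a residue
  composition, as a cross-check of the shipped per-molecule constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._residues import RESIDUE_FORMULAS
from .constants import N_AVOGADRO

__all__ = [
    "ProteinSpecies",
    "SampleComposition",
    "BSA",
    "IG",
    "incoherent_weights",
    "volume_fractions",
    "theory_volume_fraction",
    "pdb_cross_section",
    "CrossSectionResult",
]


@dataclass(frozen=True)
class ProteinSpecies:
    """Constants describing one protein species.

    M_w in kDa, sigma_inc in barn per molecule, nu (partial specific volume)
    in mL/g, R_H (effective hydrodynamic radius) in Å.
    """

    name: str
    M_w: float
    sigma_inc: float
    nu: float
    R_H: float

    def __post_init__(self) -> None:
        for f in ("M_w", "sigma_inc", "nu", "R_H"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{self.name}: {f} must be > 0")


#: Bovine serum albumin defaults.  The cross section is the per-molecule
#: incoherent sum computed from PDB 4F5S (all-H convention) used for the
#: spectral weights.  R_H is the effective hydrated-sphere radius
#: (3·M·ν·(1+h)/(4π·N_A))^(1/3) with hydration volume factor h = 0.4, which
#: keeps the effective hard-sphere volume fraction ≈ 1.4·φ and inside the
#: validity range of the short-time mixture theory at all sample conditions.
BSA = ProteinSpecies(name="BSA", M_w=66.4, sigma_inc=464377.95, nu=0.735, R_H=30.0)

#: Polyclonal immunoglobulin defaults (cross section from PDB 1IGT; R_H as
#: the hydrated equivalent sphere — the molecule's anisotropy is not modeled).
IG = ProteinSpecies(name="Ig", M_w=150.0, sigma_inc=1011495.41, nu=0.739, R_H=39.5)


@dataclass(frozen=True)
class SampleComposition:
    """Protein concentrations (mg/mL) and temperature (K) of one sample."""

    c_BSA: float
    c_Ig: float
    T: float = 295.0

    def __post_init__(self) -> None:
        if self.c_BSA < 0 or self.c_Ig < 0:
            raise ValueError("concentrations must be >= 0")
        if self.T <= 0:
            raise ValueError("temperature must be > 0")


def molar_concentrations(
    composition: SampleComposition,
    species: tuple[ProteinSpecies, ProteinSpecies] = (BSA, IG),
) -> tuple[float, float]:
    """Molar concentrations (mol/L) from mg/mL and kDa molar masses."""
    bsa, ig = species
    # mg/mL / (kDa = kg/mol) = mol/m3 * 1e-3 = mol/L
    return composition.c_BSA / bsa.M_w * 1e-3, composition.c_Ig / ig.M_w * 1e-3


def incoherent_weights(
    composition: SampleComposition,
    species: tuple[ProteinSpecies, ProteinSpecies] = (BSA, IG),
) -> tuple[float, float]:
    """Normalized spectral weights (s_BSA, s_Ig).

    Each protein's share of the incoherent signal is proportional to its
    molar concentration times its per-molecule incoherent cross section;
    the pair is normalized to s_BSA + s_Ig = 1.
    """
    m_bsa, m_ig = molar_concentrations(composition, species)
    w_bsa = m_bsa * species[0].sigma_inc
    w_ig = m_ig * species[1].sigma_inc
    total = w_bsa + w_ig
    if total <= 0:
        raise ValueError("both concentrations are zero: spectral weights undefined")
    return w_bsa / total, w_ig / total


def volume_fractions(
    composition: SampleComposition,
    species: tuple[ProteinSpecies, ProteinSpecies] = (BSA, IG),
) -> tuple[float, float, float, float]:
    """(φ_BSA, φ_Ig, φ, y) from φ_i = c_i·ν_i.

    c in mg/mL and ν in mL/g gives the dimensionless volume fraction
    directly (mg/mL · mL/g = 1e-3 · dimensionless scale handled below).
    """
    bsa, ig = species
    phi_bsa = composition.c_BSA * bsa.nu * 1e-3
    phi_ig = composition.c_Ig * ig.nu * 1e-3
    phi = phi_bsa + phi_ig
    if phi <= 0:
        raise ValueError("total volume fraction is zero: mixing ratio undefined")
    return phi_bsa, phi_ig, phi, phi_bsa / phi


def theory_volume_fraction(
    composition: SampleComposition,
    species: tuple[ProteinSpecies, ProteinSpecies] = (BSA, IG),
) -> float:
    """Effective hard-sphere volume fraction φ_theo = Σ_i n_i·(4/3)π R_H,i³.

    Number densities n_i are computed from the mass concentration, the molar
    mass and the Avogadro constant; radii are the hydrodynamic radii.
    """
    phi = 0.0
    for c_mg_ml, sp in ((composition.c_BSA, species[0]), (composition.c_Ig, species[1])):
        # n in 1/Å³: (mg/mL / (kDa·1e6 mg/mol)) · N_A / (1e24 Å³/mL)
        n_per_a3 = c_mg_ml / (sp.M_w * 1e6) * N_AVOGADRO / 1e24
        phi += n_per_a3 * (4.0 / 3.0) * math.pi * sp.R_H**3
    return phi


# ---------------------------------------------------------------------------
# PDB incoherent cross-section calculator
# ---------------------------------------------------------------------------

@dataclass
class CrossSectionResult:
    """Total per-molecule incoherent cross section with element breakdown."""

    sigma_barn: float
    element_counts: dict[str, float]
    exchange_model: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = ", ".join(f"{el}:{n:.0f}" for el, n in self.element_counts.items())
        return f"σ_inc = {self.sigma_barn:.2f} barn ({self.exchange_model}; {parts})"


def _load_xsec_table() -> dict[str, float]:
    with resources.files("biqens.data").joinpath("neutron_incoherent_xsec.csv").open() as f:
        df = pd.read_csv(f, comment="#")
    return dict(zip(df["element"], df["sigma_inc_barn"]))


def _counts_from_residue_table(residues: dict[str, int], exchange_model: str):
    counts: dict[str, float] = {"C": 0, "H": 0, "D": 0, "N": 0, "O": 0, "S": 0}
    for name, n in residues.items():
        key = name.upper()
        if key not in RESIDUE_FORMULAS:
            raise ValueError(f"unknown residue {name!r}: no formula template available")
        c, h, nn, o, s, labile = RESIDUE_FORMULAS[key]
        counts["C"] += n * c
        counts["N"] += n * nn
        counts["O"] += n * o
        counts["S"] += n * s
        if exchange_model == "labile-D":
            counts["H"] += n * (h - labile)
            counts["D"] += n * labile
        else:
            counts["H"] += n * h
    return counts


def _counts_from_pdb(path, exchange_model: str):
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    residues: dict[str, int] = {}
    explicit: dict[str, float] = {}
    has_hydrogens = False
    for model in structure:
        for chain in model:
            for res in chain:
                if res.is_water():
                    continue
                residues[res.name] = residues.get(res.name, 0) + 1
                for atom in res:
                    el = atom.element.name
                    if el == "H":
                        has_hydrogens = True
                    explicit[el] = explicit.get(el, 0.0) + atom.occ
        break  # first model only
    if has_hydrogens:
        if exchange_model == "labile-D":
            raise ValueError(
                "labile-D exchange with explicit hydrogens is not supported; "
                "use a residue-composition table instead"
            )
        return explicit
    return _counts_from_residue_table(residues, exchange_model)


def pdb_cross_section(
    structure_source,
    exchange_model: str = "all-H",
) -> CrossSectionResult:
    """Sum tabulated atomic incoherent cross sections over a structure.

    Parameters
    ----------
    structure_source : path to a PDB file, or dict mapping residue name -> count
        When a PDB file without explicit hydrogens is given, hydrogens are
        added from per-residue formula templates (chain termini ignored).
    exchange_model : {"all-H", "labile-D"}
        "all-H" counts every hydrogen as protium; "labile-D" counts hydrogens
        bound to N/O/S as deuterium (solvent-exchanged in D₂O).

    Returns
    -------
    CrossSectionResult with the total in barn and the element breakdown.
    """
    if exchange_model not in ("all-H", "labile-D"):
        raise ValueError(f"unknown exchange model {exchange_model!r}")
    if isinstance(structure_source, dict):
        counts = _counts_from_residue_table(structure_source, exchange_model)
    elif isinstance(structure_source, (str, Path)):
        counts = _counts_from_pdb(structure_source, exchange_model)
    else:
        raise TypeError("structure_source must be a PDB path or a residue-count dict")
    table = _load_xsec_table()
    sigma = 0.0
    for el, n in counts.items():
        if n == 0:
            continue
        if el not in table:
            raise ValueError(f"element {el!r} missing from the cross-section table")
        sigma += n * table[el]
    counts = {el: n for el, n in counts.items() if n}
    return CrossSectionResult(sigma_barn=float(sigma), element_counts=counts,
                              exchange_model=exchange_model)
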