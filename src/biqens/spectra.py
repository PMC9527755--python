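"""The (q, ω) counts container shared by every pipeline stage.

A :class:`SpectrumSet` holds counts on a rectangular momentum-transfer /
energy-transfer grid together with Poisson-derived errors and free-form
metadata (temperature, concentrations, seed, ...).  It is written/read as
HDF5 (datasets ``/q``, ``/omega``, ``/counts``, ``/errors`` plus root
attributes) and as long-format CSV (columns ``q, omega, counts, error``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["SpectrumSet", "trapezoid_weights"]


def trapezoid_weights(omega: np.ndarray) -> np.ndarray:
    """Per-channel quadrature weights (μeV): trapezoid rule on the ω grid.

    Expected counts are density × weight, so the total expected count equals
    the trapezoid integral of the model density over the energy window
    (endpoint channels carry half a bin).  Generator and fitters share this
    convention.
    """
    omega = np.asarray(omega, dtype=float)
    w = np.empty_like(omega)
    w[1:-1] = 0.5 * (omega[2:] - omega[:-2])
    w[0] = 0.5 * (omega[1] - omega[0])
    w[-1] = 0.5 * (omega[-1] - omega[-2])
    return w


@dataclass
class SpectrumSet:
    """Counts vs energy transfer at a set of momentum transfers.

    Parameters
    ----------
    q : array, shape (nq,)
        Momentum transfers in 1/Å, strictly increasing.
    omega : array, shape (nw,)
        Energy transfers in μeV.
    counts : array, shape (nq, nw)
        Detector counts (or count-like intensities after reduction).
    errors : array, shape (nq, nw), optional
        1σ uncertainties; defaults to sqrt(max(counts, 1)) (Poisson).
    meta : dict
        Free-form metadata; stored as HDF5 attributes / ignored by CSV.
    """

    q: np.ndarray
    omega: np.ndarray
    counts: np.ndarray
    errors: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.q.ndim != 1 or self.omega.ndim != 1:
            raise ValueError("q and omega must be 1-D arrays")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if self.counts.shape != (self.q.size, self.omega.size):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"(nq, nw) = ({self.q.size}, {self.omega.size})"
            )
        if self.errors is None:
            self.errors = np.sqrt(np.maximum(self.counts, 1.0))
        else:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.counts.shape:
                raise ValueError("errors shape must match counts shape")

    # -- grid helpers -----------------------------------------------------
    @property
    def nq(self) -> int:
        return self.q.size

    @property
    def nw(self) -> int:
        return self.omega.size

    @property
    def channel_width(self) -> float:
        """ω bin width in μeV (uniform grids only)."""
        dw = np.diff(self.omega)
        if not np.allclose(dw, dw[0]):
            raise ValueError("omega grid is not uniform")
        return float(dw[0])

    def same_grid(self, other: "SpectrumSet") -> bool:
        return (
            self.q.shape == other.q.shape
            and self.omega.shape == other.omega.shape
            and np.allclose(self.q, other.q)
            and np.allclose(self.omega, other.omega)
        )

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.q.copy(), self.omega.copy(), self.counts.copy(),
            self.errors.copy(), dict(self.meta),
        )

    # -- IO ---------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("q", data=self.q)
            f.create_dataset("omega", data=self.omega)
            f.create_dataset("counts", data=self.counts)
            f.create_dataset("errors", data=self.errors)
            for key, val in self.meta.items():
                try:
                    f.attrs[key] = val
                except TypeError:
                    f.attrs[key] = str(val)

    @classmethod
    def from_hdf5(cls, path) -> "SpectrumSet":
        with h5py.File(path, "r") as f:
            return cls(
                q=f["q"][()],
                omega=f["omega"][()],
                counts=f["counts"][()],
                errors=f["errors"][()],
                meta={k: f.attrs[k] for k in f.attrs},
            )

    def to_dataframe(self) -> pd.DataFrame:
        qq, ww = np.meshgrid(self.q, self.omega, indexing="ij")
        return pd.DataFrame(
            {
                "q": qq.ravel(),
                "omega": ww.ravel(),
                "counts": self.counts.ravel(),
                "error": self.errors.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumSet":
        df = pd.read_csv(path)
        q = np.unique(df["q"].to_numpy())
        omega = np.unique(df["omega"].to_numpy())
        nq, nw = q.size, omega.size
        df = df.sort_values(["q", "omega"])
        return cls(
            q=q,
            omega=omega,
            counts=df["counts"].to_numpy().reshape(nq, nw),
            errors=df["error"].to_numpy().reshape(nq, nw),
        )
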