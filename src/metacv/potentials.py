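"""Analytic toy potentials in CV space.

These are desk-scale stand-ins for the free-energy landscape of a large
conformational transition: the biasing machinery (ratchet-and-pawl,
well-tempered metadynamics) acts on a fictitious particle moving on U(s)
exactly as it would act on a CV of an all-atom system.  Energies are kJ/mol,
CVs are in angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ToyPotential:
    """Interface: analytic energy ``U(s)`` and gradient ``dU/ds``."""

    dimension: int = 1

    def energy(self, s: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, s: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class DoubleWell(ToyPotential):
    """Quartic 1D double well with an optional linear tilt.

    ``U(x) = barrier * ((x/a)^2 - 1)^2 + tilt * (x + a) / (2 a)`` with
    ``x = s - center`` and ``a = separation / 2``: wells near ``center -+ a``,
    barrier height ``barrier`` (kJ/mol) at the midpoint for ``tilt = 0``, and
    an energy offset of about ``tilt`` between the right and left well.
    """

    barrier: float = 35.0
    separation: float = 16.0
    tilt: float = 0.0
    center: float = 0.0
    dimension: int = 1

    @property
    def a(self) -> float:
        return self.separation / 2.0

    def energy(self, s) -> float:
        x = float(np.asarray(s).reshape(-1)[0]) - self.center
        u = (x / self.a) ** 2 - 1.0
        return self.barrier * u * u + self.tilt * (x + self.a) / (2 * self.a)

    def gradient(self, s) -> np.ndarray:
        x = float(np.asarray(s).reshape(-1)[0]) - self.center
        u = (x / self.a) ** 2 - 1.0
        g = self.barrier * 2.0 * u * (2.0 * x / self.a**2) + self.tilt / (2 * self.a)
        return np.array([g])

    def well_positions(self) -> tuple[float, float]:
        """Approximate well locations (exact for tilt = 0)."""
        return (self.center - self.a, self.center + self.a)


@dataclass
class GaussianMixture(ToyPotential):
    """Inverted sum of isotropic Gaussians: ``U(s) = -sum_i depth_i exp(-|s-c_i|^2 / 2 w_i^2)``."""

    centers: np.ndarray  # (k, d)
    widths: np.ndarray   # (k,)
    depths: np.ndarray   # (k,)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.asarray(self.widths, dtype=float).reshape(-1)
        self.depths = np.asarray(self.depths, dtype=float).reshape(-1)
        if not (len(self.centers) == len(self.widths) == len(self.depths)):
            raise ValueError("centers, widths and depths must have equal length")
        self.dimension = self.centers.shape[1]

    def _gaussians(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float).reshape(-1)
        d2 = ((s[None, :] - self.centers) ** 2).sum(axis=1)
        return self.depths * np.exp(-0.5 * d2 / self.widths**2)

    def energy(self, s) -> float:
        return float(-self._gaussians(s).sum())

    def gradient(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float).reshape(-1)
        g = self._gaussians(s)
        diff = s[None, :] - self.centers
        return (g[:, None] * diff / self.widths[:, None] ** 2).sum(axis=0)


@dataclass
class Harmonic(ToyPotential):
    """Isotropic harmonic well ``U(s) = k/2 |s - center|^2`` (k in kJ/mol/A^2)."""

    k: float = 1.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(-1)
        self.dimension = self.center.shape[0]

    def energy(self, s) -> float:
        x = np.asarray(s, dtype=float).reshape(-1) - self.center
        return float(0.5 * self.k * (x @ x))

    def gradient(self, s) -> np.ndarray:
        x = np.asarray(s, dtype=float).reshape(-1) - self.center
        return self.k * x
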