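"""Bingham orientation distributions evaluated on a sphere grid.

Fiber dispersion is parameterized by the orientation dispersion index
ODI in (0, 1] through the standard Watson-model mapping

    ODI = (2 / pi) * arctan(1 / kappa),

so ODI -> 0 is a perfectly coherent fiber (kappa -> inf) and ODI = 1 is
fully isotropic (kappa = 0).  The default distribution is the axially
symmetric Bingham (kappa1 = kappa2), which coincides with the Watson
distribution; anisotropic dispersion (kappa1 > kappa2) is supported but not
sampled by the dictionary priors.

The continuous spherical integral of the forward model is discretized as a
probability-weighted sum over the grid vertices with uniform quadrature
weights absorbed into the normalization; the repulsion grids are near-uniform
by construction, making this a consistent estimator of the continuous
integral as the grid is refined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphere import SphereGrid

__all__ = ["BinghamParams", "odi_to_kappa", "kappa_to_odi", "bingham_density"]


def odi_to_kappa(odi):
    """Concentration kappa for a dispersion index in (0, 1].

    Strictly decreasing; ``odi = 0.5`` maps to ``kappa = 1`` and ``odi = 1``
    to ``kappa = 0`` (isotropic).
    """
    odi = np.asarray(odi, dtype=float)
    if np.any(odi <= 0) or np.any(odi > 1):
        raise ValueError("odi must lie in (0, 1]")
    out = 1.0 / np.tan(np.pi * odi / 2.0)
    return out if out.ndim else float(out)


def kappa_to_odi(kappa):
    """Inverse of :func:`odi_to_kappa` (kappa >= 0)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    out = (2.0 / np.pi) * np.arctan2(1.0, kappa)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BinghamParams:
    """Mean axis and concentrations of one fiber population's dispersion."""

    mu: np.ndarray  # unit 3-vector, principal axis
    kappa1: float
    kappa2: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        n = np.linalg.norm(mu)
        if mu.shape != (3,) or n < 1e-12:
            raise ValueError("mu must be a nonzero 3-vector")
        if not (self.kappa1 >= self.kappa2 >= 0):
            raise ValueError("need kappa1 >= kappa2 >= 0")
        object.__setattr__(self, "mu", mu / n)

    @classmethod
    def from_odi(cls, mu: np.ndarray, odi: float) -> "BinghamParams":
        """Axially symmetric (Watson) parameters for a given dispersion index."""
        k = odi_to_kappa(odi)
        return cls(mu, k, k)


def _orthonormal_frame(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal completion (e2, e3) of the axis mu."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(mu[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(mu, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(mu, e2)
    return e2, e3


def bingham_density(params: BinghamParams, grid: SphereGrid) -> np.ndarray:
    """Discrete Bingham density over the grid vertices (sums to 1).

    The density is proportional to ``exp(n^T Z n)`` with
    ``Z = -kappa1 e2 e2^T - kappa2 e3 e3^T``, which is antipodally symmetric,
    and is normalized over the grid so the normalization constant of the
    continuous distribution never has to be evaluated.
    """
    e2, e3 = _orthonormal_frame(params.mu)
    v = grid.vertices
    expo = -params.kappa1 * (v @ e2) ** 2 - params.kappa2 * (v @ e3) ** 2
    expo -= expo.max()  # stability: density is invariant to this shift
    p = np.exp(expo)
    return p / p.sum()


def watson_log_weights(dots: np.ndarray, kappa) -> np.ndarray:
    """Unnormalized log-density of the axially symmetric case.

    For kappa1 = kappa2 = kappa the Bingham exponent reduces (up to a
    constant) to ``kappa * (mu . n)^2``; ``dots`` holds the ``mu . n``
    values.  Used by the vectorized dictionary builder.
    """
    return np.asarray(kappa, dtype=float) * np.square(dots)
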