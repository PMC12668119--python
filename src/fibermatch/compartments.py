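"""Closed-form single-compartment diffusion signal models.

All signals are attenuations relative to the unweighted signal (S0 = 1):

* stick   — intra-axonal water, zero radial diffusivity,
  ``exp(-b * d_par * (g.n)^2)``;
* zeppelin — hindered extra-axonal water, axially symmetric tensor,
  ``exp(-b * (d_perp + (d_par - d_perp) * (g.n)^2))``;
* isotropic ball — free water or gray matter, ``exp(-b * d_iso)``.

Diffusivities are in mm^2/s and b-values in s/mm^2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "D_GM",
    "D_FW",
    "Diffusivities",
    "stick_signal",
    "zeppelin_signal",
    "isotropic_signal",
]

#: gray-matter diffusivity, mm^2/s
D_GM = 1.0e-3
#: free-water (CSF) diffusivity, mm^2/s
D_FW = 3.0e-3


@dataclass(frozen=True)
class Diffusivities:
    """Diffusivities of one voxel configuration.

    The intra-axonal radial diffusivity is fixed at zero (stick model) and
    the intra- and extra-axonal axial diffusivities are shared, so a single
    ``d_par`` describes both compartments' axial decay.
    """

    d_par: float  # shared intra/extra axial diffusivity
    d_perp_ex: float  # extra-axonal radial diffusivity
    d_gm: float = D_GM
    d_fw: float = D_FW

    def __post_init__(self) -> None:
        for name in ("d_par", "d_perp_ex", "d_gm", "d_fw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.d_perp_ex > self.d_par:
            raise ValueError("d_perp_ex must not exceed d_par")


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b-value")
    return b


def stick_signal(b, g, n, d_par: float):
    """Attenuation of the stick (intra-axonal) compartment.

    ``b`` may be scalar or (V,), ``g`` a 3-vector or (V, 3); ``n`` is the
    fiber axis.  Radial motion is fully restricted, so a gradient
    perpendicular to the axis sees no attenuation at any b.
    """
    b = _check_b(b)
    if d_par < 0:
        raise ValueError("d_par must be >= 0")
    g = np.asarray(g, dtype=float)
    n = np.asarray(n, dtype=float)
    proj2 = np.square(g @ n)
    return np.exp(-b * d_par * proj2)


def zeppelin_signal(b, g, n, d_par_ex: float, d_perp_ex: float):
    """Attenuation of the zeppelin (extra-axonal) compartment."""
    b = _check_b(b)
    if not 0 <= d_perp_ex <= d_par_ex:
        raise ValueError("need 0 <= d_perp_ex <= d_par_ex")
    g = np.asarray(g, dtype=float)
    n = np.asarray(n, dtype=float)
    proj2 = np.square(g @ n)
    return np.exp(-b * (d_perp_ex + (d_par_ex - d_perp_ex) * proj2))


def isotropic_signal(b, d_iso: float):
    """Attenuation of an isotropic ball (free water or gray matter)."""
    b = _check_b(b)
    if d_iso < 0:
        raise ValueError("d_iso must be >= 0")
    return np.exp(-b * d_iso)
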