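"""Voxel-wise degeneracy maps from the top-K similarity profile.

Signal-space degeneracy — distinct configurations producing near-identical
signals — is characterized instead of suppressed, with two measures over the
penalized similarities s_1..s_K of each voxel's candidate neighborhood:

* uncertainty U = IQR(s) = P75(s) - P25(s): the spread of plausible matches;
* ambiguity  A = (1/K) * #{i : s_i > max(s)/2}: the normalized width of the
  similarity peak at half maximum.  A ranges over [1/K, 1]; the minimum
  1/K (not 0) is attained when the maximum alone exceeds half of itself.

Percentiles use linear interpolation between order statistics, and the
half-maximum comparison is strict, so a constant positive profile has
ambiguity exactly 1 and uncertainty exactly 0.
"""

from __future__ import annotations

import numpy as np

from .matching import VolumeFitResult

__all__ = ["uncertainty", "ambiguity", "uncertainty_map", "ambiguity_map"]


def uncertainty(s: np.ndarray) -> float:
    """Interquartile range of one voxel's similarity profile (K >= 2)."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or len(s) < 2:
        raise ValueError("uncertainty needs a 1D profile with K >= 2")
    if not np.all(np.isfinite(s)):
        raise ValueError("similarity profile must be finite")
    p25, p75 = np.percentile(s, [25.0, 75.0])
    return float(p75 - p25)


def ambiguity(s: np.ndarray) -> float:
    """Fraction of profile values strictly above half the maximum.

    Undefined (raises) when the peak similarity is not positive.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or len(s) < 1:
        raise ValueError("ambiguity needs a non-empty 1D profile")
    m = s.max()
    if not m > 0:
        raise ValueError("ambiguity undefined for a non-positive peak")
    return float(np.count_nonzero(s > m / 2.0) / len(s))


def _profile_map(fit: VolumeFitResult, func, min_k: int) -> np.ndarray:
    out = np.full(fit.mask.shape, np.nan)
    K = fit.neighborhood_similarities.shape[-1]
    if K < min_k:
        return out
    for ijk in np.argwhere(fit.mask):
        s = fit.neighborhood_similarities[tuple(ijk)]
        try:
            out[tuple(ijk)] = func(s)
        except ValueError:
            pass  # undefined profile -> missing value
    return out


def uncertainty_map(fit: VolumeFitResult) -> np.ndarray:
    """IQR of the penalized profile per voxel; NaN where undefined."""
    return _profile_map(fit, uncertainty, min_k=2)


def ambiguity_map(fit: VolumeFitResult) -> np.ndarray:
    """Half-maximum width of the penalized profile per voxel; NaN where undefined."""
    return _profile_map(fit, ambiguity, min_k=1)
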