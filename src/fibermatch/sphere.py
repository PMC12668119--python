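"""Discrete orientation grids on the unit sphere.

The forward model samples candidate fiber axes from, and discretizes the
orientation-distribution integral over, a fixed set of unit vectors spread by
electrostatic repulsion.  Because fiber orientations are axial quantities
(``n`` and ``-n`` are the same fiber), the repulsion energy treats every
vertex together with its antipode, so the built grids spread *orientations*
rather than points.

A precomputed 724-vertex grid (the production default) and a 150-vertex
acquisition scheme ship with the package; both were generated by
:func:`build_grid` and round-trip exactly through the plain-text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "SphereGrid",
    "build_grid",
    "default_grid",
    "load_grid",
    "save_grid",
    "angle_between",
    "nearest_neighbor_resolution",
    "repulsion_energy",
]

_MIN_VERTICES = 12


@dataclass(frozen=True)
class SphereGrid:
    """A set of unit vectors sampling the sphere.

    Vertices represent orientations: the grid carries no antipodal
    duplicates, and consumers that care only about axes should fold
    angles with ``antipodal=True``.
    """

    vertices: np.ndarray  # (M, 3) unit vectors
    energy_history: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (M, 3), got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("grid vertices must have unit norm (within 1e-8)")
        # duplicate vertices would make the grid degenerate as a sampling set
        dots = v @ v.T
        np.fill_diagonal(dots, -np.inf)
        if dots.max() > 1.0 - 1e-12:
            raise ValueError("grid contains (near-)identical vertices")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return self.vertices.shape[0]


def _golden_spiral(m: int) -> np.ndarray:
    """Deterministic quasi-uniform starting configuration (Fibonacci spiral)."""
    i = np.arange(m) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / m)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar)],
        axis=1,
    )


def repulsion_energy(vertices: np.ndarray, antipodal: bool = True) -> float:
    """Total inverse-distance (Coulomb) energy of a configuration.

    With ``antipodal=True`` each pair interacts through both the direct and
    the mirrored separation, so antipodally close vertices are penalized the
    same way as close ones.
    """
    v = np.asarray(vertices, dtype=float)
    d = np.linalg.norm(v[:, None] - v[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    e = float(np.sum(1.0 / d)) / 2.0
    if antipodal:
        d2 = np.linalg.norm(v[:, None] + v[None], axis=-1)
        np.fill_diagonal(d2, np.inf)  # exclude the constant self term
        e += float(np.sum(1.0 / d2)) / 2.0
    return e


def build_grid(
    m: int,
    *,
    n_iter: int = 3000,
    tol: float = 1e-10,
    antipodal: bool = True,
    track_energy: bool = False,
) -> SphereGrid:
    """Place ``m`` vertices by electrostatic repulsion.

    Projected gradient descent on the Coulomb energy with a backtracking
    step: a step is only accepted if it lowers the energy, so the energy
    history is non-increasing by construction and the result is fully
    deterministic for fixed ``m`` (the start is a golden spiral, no RNG).

    Parameters
    ----------
    m:
        Number of vertices (>= 12).
    n_iter:
        Maximum number of accepted/attempted descent iterations.
    tol:
        Relative energy decrease below which iteration stops.
    antipodal:
        Repel antipodes too (default), spreading orientations rather than
        points.
    track_energy:
        Store the accepted-energy trace on the returned grid.
    """
    if m < _MIN_VERTICES:
        raise ValueError(f"need at least {_MIN_VERTICES} vertices, got {m}")
    x = _golden_spiral(m)
    lr = 1.0 / m
    e = repulsion_energy(x, antipodal)
    history = [e]
    for _ in range(n_iter):
        diff = x[:, None] - x[None]
        d = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(d, np.inf)
        force = (diff / d[..., None] ** 3).sum(axis=1)
        if antipodal:
            s = x[:, None] + x[None]
            d2 = np.linalg.norm(s, axis=-1)
            np.fill_diagonal(d2, np.inf)
            force += (s / d2[..., None] ** 3).sum(axis=1)
        # tangential projection keeps the step on the sphere to first order
        force -= (force * x).sum(axis=1, keepdims=True) * x
        x_new = x + lr * force
        x_new /= np.linalg.norm(x_new, axis=1, keepdims=True)
        e_new = repulsion_energy(x_new, antipodal)
        if e_new < e:
            if (e - e_new) < tol * e:
                x, e = x_new, e_new
                history.append(e)
                break
            x, e = x_new, e_new
            history.append(e)
            lr *= 1.05
        else:
            lr *= 0.5
            if lr < 1e-14:
                break
    return SphereGrid(x, energy_history=np.array(history) if track_energy else None)


def angle_between(u: np.ndarray, v: np.ndarray, antipodal: bool = False) -> float:
    """Great-circle angle between two unit vectors, in degrees.

    With ``antipodal=True`` the sign of the vectors is ignored and the result
    lies in [0, 90]; otherwise in [0, 180].
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("angle undefined for zero vector")
    c = float(np.dot(u / nu, v / nv))
    c = min(1.0, max(-1.0, c))
    ang = np.degrees(np.arccos(abs(c) if antipodal else c))
    return float(ang)


def nearest_neighbor_resolution(grid: SphereGrid, antipodal: bool = False) -> float:
    """Mean angle (degrees) from each vertex to its nearest distinct vertex.

    Under ``antipodal=True`` angles are folded (``min(a, 180 - a)``), so a
    vertex whose antipode is also in the grid has a folded neighbor at 0.
    """
    v = grid.vertices
    c = v @ v.T
    if antipodal:
        c = np.abs(c)
    np.fill_diagonal(c, -np.inf)
    nearest = np.degrees(np.arccos(np.clip(c.max(axis=1), -1.0, 1.0)))
    return float(nearest.mean())


def save_grid(grid: SphereGrid, path: str | Path) -> None:
    """Write vertices as plain text, one ``x y z`` triple per line."""
    np.savetxt(path, grid.vertices, fmt="%.12g")


def load_grid(path: str | Path) -> SphereGrid:
    """Read a three-column vertex file; vertices are re-normalized."""
    v = np.atleast_2d(np.loadtxt(path))
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError(f"expected a three-column vertex file, got shape {v.shape}")
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    return SphereGrid(v)


def _packaged(name: str) -> SphereGrid:
    with resources.as_file(resources.files("fibermatch") / "data" / name) as p:
        return load_grid(p)


def default_grid() -> SphereGrid:
    """The precomputed 724-vertex repulsion grid used throughout."""
    return _packaged("grid724.txt")


def default_scheme_directions() -> SphereGrid:
    """The precomputed 150-direction gradient scheme used by the phantoms."""
    return _packaged("dirs150.txt")
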