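"""Scalar maps, peaks and tissue fractions from matched configurations.

Because every dictionary entry is a finite mixture of Gaussian
sub-compartments (one stick or zeppelin tensor per fiber and grid vertex,
plus two isotropic balls), its diffusion and kurtosis tensors are available
in closed form from the mixture moments:

    D_bar    = sum_c w_c D_c
    W_ijkl   = (3 / MD^2) * sym( sum_c w_c D_c,ij D_c,kl - D_bar_ij D_bar_kl )

with the apparent kurtosis along direction g given by
K(g) = MD^2 W(g) / D(g)^2.  DTI scalars (FA/MD/AD/RD) come from the
eigen-decomposition of D_bar; DKI scalars are MK (mean of K over the sphere
grid), AK (K along the principal eigenvector), RK (mean of K over
directions perpendicular to it) and KFA (the normalized anisotropic part of
W).  NODDI-style scalars (NDI/ODI/FW) and the fuzzy WM/GM/CSF segmentation
are read directly off the matched configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import MicrostructureConfig, SignalDictionary
from .matching import FitConfig, VolumeFitResult
from .sphere import SphereGrid

__all__ = [
    "CompartmentTensorSet",
    "VoxelMaps",
    "DerivedMaps",
    "mixture_tensors",
    "overall_tensor",
    "dti_scalars",
    "kurtosis_tensor",
    "kurtosis_scalars",
    "noddi_style_maps",
    "peaks_and_segmentation",
    "compute_voxel_maps",
    "derive_maps",
]

_N_RADIAL_DIRECTIONS = 64  # deterministic in-plane average for RK


@dataclass(frozen=True)
class CompartmentTensorSet:
    """Gaussian sub-compartments of one voxel: weights and 3x3 tensors."""

    weights: np.ndarray  # (C,), >= 0, sum 1
    tensors: np.ndarray  # (C, 3, 3) symmetric PSD, mm^2/s

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        t = np.asarray(self.tensors, dtype=float)
        if w.ndim != 1 or t.shape != (len(w), 3, 3):
            raise ValueError("need weights (C,) and tensors (C, 3, 3)")
        if np.any(w < -1e-15) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "tensors", t)


def mixture_tensors(config: MicrostructureConfig, grid: SphereGrid) -> CompartmentTensorSet:
    """Enumerate the Gaussian sub-compartments of a configuration.

    For fiber i and grid vertex n_j: a stick tensor ``d_par n_j n_j^T`` with
    weight ``f_in,i p_ij`` and a zeppelin tensor
    ``d_perp I + (d_par - d_perp) n_j n_j^T`` with weight ``f_ex,i p_ij``;
    plus the free-water and gray-matter balls.
    """
    from .bingham import BinghamParams, bingham_density

    d = config.diffusivities
    eye = np.eye(3)
    weights = []
    tensors = []
    v = grid.vertices
    outer = v[:, :, None] * v[:, None, :]  # (M, 3, 3)
    for i in range(config.n_fibers):
        p = bingham_density(BinghamParams.from_odi(config.fiber_axes[i], config.odis[i]), grid)
        keep = p > 0
        weights.append(config.f_in[i] * p[keep])
        tensors.append(d.d_par * outer[keep])
        weights.append(config.f_ex[i] * p[keep])
        tensors.append(d.d_perp_ex * eye + (d.d_par - d.d_perp_ex) * outer[keep])
    weights.append(np.array([config.f_fw, config.f_gm]))
    tensors.append(np.stack([d.d_fw * eye, d.d_gm * eye]))
    w = np.concatenate(weights)
    t = np.concatenate(tensors)
    return CompartmentTensorSet(w / w.sum() if abs(w.sum() - 1) > 0 else w, t)


def overall_tensor(tset: CompartmentTensorSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted-mean diffusion tensor and its eigen-decomposition.

    Returns ``(D, eigvals, eigvecs)`` with eigenvalues sorted descending and
    ``eigvecs[:, k]`` the unit eigenvector of ``eigvals[k]``.
    """
    D = np.einsum("c,cij->ij", tset.weights, tset.tensors)
    vals, vecs = np.linalg.eigh(D)
    order = np.argsort(vals)[::-1]
    return D, vals[order], vecs[:, order]


def dti_scalars(eigvals: np.ndarray) -> dict[str, float]:
    """FA/MD/AD/RD from descending tensor eigenvalues."""
    l1, l2, l3 = eigvals
    md = (l1 + l2 + l3) / 3.0
    num = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    den = l1**2 + l2**2 + l3**2
    fa = float(np.sqrt(1.5 * num / den)) if den > 0 else 0.0
    return {"fa": fa, "md": float(md), "ad": float(l1), "rd": float((l2 + l3) / 2.0)}


def kurtosis_tensor(
    tset: CompartmentTensorSet, Dbar: np.ndarray | None = None
) -> np.ndarray:
    """Fourth-order kurtosis tensor W of the Gaussian mixture.

    ``W_ijkl = (3 / MD^2) sym(<D_ij D_kl> - D_bar_ij D_bar_kl)`` with full
    index symmetrization; exact for a mixture of Gaussian compartments
    (second cumulant of the compartment tensor distribution).
    """
    if Dbar is None:
        Dbar = np.einsum("c,cij->ij", tset.weights, tset.tensors)
    md = float(np.trace(Dbar)) / 3.0
    if md <= 0:
        raise ValueError("kurtosis undefined for MD <= 0")
    second = np.einsum("c,cij,ckl->ijkl", tset.weights, tset.tensors, tset.tensors)
    T = second - np.einsum("ij,kl->ijkl", Dbar, Dbar)
    # full symmetrization over the three distinct pairings
    T = (T + T.transpose(0, 2, 1, 3) + T.transpose(0, 3, 2, 1)) / 3.0
    return 3.0 / md**2 * T


def apparent_kurtosis(W: np.ndarray, D: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Directional kurtosis K(g) = MD^2 W(g) / D(g)^2 for unit direction(s) g."""
    g = np.atleast_2d(np.asarray(g, dtype=float))
    md = np.trace(D) / 3.0
    wg = np.einsum("ijkl,ni,nj,nk,nl->n", W, g, g, g, g)
    dg = np.einsum("ij,ni,nj->n", D, g, g)
    out = md**2 * wg / dg**2
    return out if len(out) > 1 else float(out[0])


def _radial_directions(e1: np.ndarray, n: int = _N_RADIAL_DIRECTIONS) -> np.ndarray:
    """Equispaced unit directions in the plane perpendicular to e1."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(e1, helper)
    u /= np.linalg.norm(u)
    v = np.cross(e1, u)
    phi = np.linspace(0.0, np.pi, n, endpoint=False)  # axial symmetry: half circle
    return np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v


def kurtosis_scalars(
    W: np.ndarray,
    D: np.ndarray,
    grid: SphereGrid,
) -> dict[str, float]:
    """MK/AK/RK/KFA from the kurtosis and diffusion tensors.

    MK averages K(g) over the sphere grid; AK is K along the principal
    eigenvector; RK averages K over equispaced directions in the
    perpendicular plane; KFA is ``||W - W_iso|| / ||W||`` (Frobenius), with
    ``W_iso`` the isotropic part of W.
    """
    vals, vecs = np.linalg.eigh(D)
    e1 = vecs[:, np.argmax(vals)]
    mk = float(np.mean(apparent_kurtosis(W, D, grid.vertices)))
    ak = float(apparent_kurtosis(W, D, e1[None, :]))
    rk = float(np.mean(apparent_kurtosis(W, D, _radial_directions(e1))))
    # isotropic projection of a fully symmetric rank-4 tensor
    wbar = (
        W[0, 0, 0, 0] + W[1, 1, 1, 1] + W[2, 2, 2, 2]
        + 2.0 * (W[0, 0, 1, 1] + W[0, 0, 2, 2] + W[1, 1, 2, 2])
    ) / 5.0
    eye = np.eye(3)
    iso4 = (
        np.einsum("ij,kl->ijkl", eye, eye)
        + np.einsum("ik,jl->ijkl", eye, eye)
        + np.einsum("il,jk->ijkl", eye, eye)
    ) / 3.0
    Wiso = wbar * iso4
    nw = np.linalg.norm(W)
    kfa = float(np.linalg.norm(W - Wiso) / nw) if nw > 0 else 0.0
    return {"mk": mk, "ak": ak, "rk": rk, "kfa": kfa}


def noddi_style_maps(config: MicrostructureConfig) -> dict[str, float]:
    """NDI, voxel ODI and free-water fraction of a configuration.

    NDI is the intra-axonal share of the fiber-bearing (WM) compartment;
    the voxel ODI is the fiber-weight-weighted mean dispersion, or 1 (fully
    isotropic) for fiber-free voxels.
    """
    fw = float(config.f_fw)
    if config.f_wm > 0:
        ndi = float(config.f_in.sum() / (config.f_in.sum() + config.f_ex.sum()))
    else:
        ndi = 0.0
    if config.n_fibers >= 1:
        odi = float(np.sum(config.fiber_weights * config.odis))
    else:
        odi = 1.0
    return {"ndi": ndi, "odi": odi, "fw": fw}


def peaks_and_segmentation(
    config: MicrostructureConfig,
    fit: FitConfig = FitConfig(),
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Peak axes/weights and the fuzzy (WM, GM, CSF) tissue fractions.

    Peaks are the fiber axes ordered by descending fiber weight, zero-padded
    to three, and suppressed entirely when the WM fraction falls below the
    reporting threshold.
    """
    peaks = np.zeros((3, 3))
    pweights = np.zeros(3)
    if config.n_fibers > 0 and config.f_wm >= fit.wm_threshold:
        order = np.argsort(-config.fiber_weights, kind="stable")
        n = config.n_fibers
        peaks[:n] = config.fiber_axes[order]
        pweights[:n] = config.fiber_weights[order]
    return peaks, pweights, (float(config.f_wm), float(config.f_gm), float(config.f_fw))


@dataclass(frozen=True)
class VoxelMaps:
    """All scalar outputs of one matched voxel."""

    peaks: np.ndarray  # (3, 3)
    peak_weights: np.ndarray  # (3,)
    fa: float
    md: float
    ad: float
    rd: float
    mk: float
    ak: float
    rk: float
    kfa: float
    ndi: float
    odi: float
    fw: float
    f_wm: float
    f_gm: float
    f_csf: float


def compute_voxel_maps(
    config: MicrostructureConfig,
    grid: SphereGrid,
    fit: FitConfig = FitConfig(),
) -> VoxelMaps:
    """Derive every scalar output from one configuration."""
    tset = mixture_tensors(config, grid)
    D, eigvals, _ = overall_tensor(tset)
    dti = dti_scalars(eigvals)
    W = kurtosis_tensor(tset, D)
    dki = kurtosis_scalars(W, D, grid)
    noddi = noddi_style_maps(config)
    peaks, pweights, seg = peaks_and_segmentation(config, fit)
    return VoxelMaps(
        peaks=peaks,
        peak_weights=pweights,
        **dti,
        **dki,
        **noddi,
        f_wm=seg[0],
        f_gm=seg[1],
        f_csf=seg[2],
    )


_SCALARS = ("fa", "md", "ad", "rd", "mk", "ak", "rk", "kfa",
            "ndi", "odi", "fw", "f_wm", "f_gm", "f_csf")


@dataclass
class DerivedMaps:
    """Voxel-wise scalar volumes and peak orientations for a fitted volume."""

    scalars: dict[str, np.ndarray]  # name -> (x, y, z), NaN outside mask
    peaks: np.ndarray  # (x, y, z, 9): three vectors flattened
    peak_weights: np.ndarray  # (x, y, z, 3)
    uncertainty: np.ndarray | None = None
    ambiguity: np.ndarray | None = None


def derive_maps(
    fit: VolumeFitResult,
    dictionary: SignalDictionary,
    grid: SphereGrid,
    with_degeneracy: bool = True,
) -> DerivedMaps:
    """Expand a matched volume into scalar maps, peaks and degeneracy maps.

    Each distinct matched dictionary entry is expanded once and broadcast to
    all voxels that selected it.
    """
    shape = fit.mask.shape
    scalars = {name: np.full(shape, np.nan) for name in _SCALARS}
    peaks = np.zeros(shape + (9,))
    pweights = np.zeros(shape + (3,))

    flat_idx = fit.best_index[fit.mask]
    cache: dict[int, VoxelMaps] = {}
    coords = np.argwhere(fit.mask)
    for (i, j, k), entry in zip(coords, flat_idx):
        entry = int(entry)
        vm = cache.get(entry)
        if vm is None:
            vm = compute_voxel_maps(dictionary.configs.config(entry), grid, fit.fit_config)
            cache[entry] = vm
        for name in _SCALARS:
            scalars[name][i, j, k] = getattr(vm, name)
        peaks[i, j, k] = vm.peaks.ravel()
        pweights[i, j, k] = vm.peak_weights

    unc = amb = None
    if with_degeneracy:
        from .degeneracy import ambiguity_map, uncertainty_map

        unc = uncertainty_map(fit)
        amb = ambiguity_map(fit)
    return DerivedMaps(scalars=scalars, peaks=peaks, peak_weights=pweights,
                       uncertainty=unc, ambiguity=amb)
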