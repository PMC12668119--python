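"""Sampling of voxel configurations and synthesis of their signals.

Every dictionary entry is one plausible voxel: a mixture of up to three
dispersed white-matter fiber populations (stick + zeppelin per fiber), an
isotropic gray-matter ball and an isotropic free-water ball, with all
partial-volume fractions summing to one,

    S(b, g) = sum_i [ f_in,i <stick>_i + f_ex,i <zeppelin>_i ]
              + f_GM exp(-b D_GM) + f_FW exp(-b D_FW),

where <.>_i denotes the average over fiber i's discrete Bingham orientation
density on the sphere grid.  Parameters are drawn from the sampling priors
(tissue fractions Dirichlet(2,1,1); 0-3 fibers; dispersion from ten
equispaced ODI levels on [0.01, 0.30]; diffusivity bands per acquisition
regime).  The production dictionary size is 500,000 entries; smaller
dictionaries are adequate for testing and convergence is flat well before
that size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .acquisition import GradientTable
from .bingham import BinghamParams, bingham_density, odi_to_kappa
from .compartments import D_FW, D_GM, Diffusivities, isotropic_signal
from .sphere import SphereGrid

__all__ = [
    "ODI_LEVELS",
    "PRIOR_BANDS",
    "MIN_FIBER_SEPARATION_DEG",
    "MicrostructureConfig",
    "ConfigArrays",
    "SignalDictionary",
    "sample_config",
    "synthesize_signal",
    "build_dictionary",
    "save_dictionary",
    "load_dictionary",
]

#: ten equispaced white-matter dispersion levels
ODI_LEVELS = np.linspace(0.01, 0.30, 10)

#: minimum pairwise (antipodally folded) angle between fiber axes, degrees
MIN_FIBER_SEPARATION_DEG = 10.0

#: diffusivity sampling bands (low, high) in mm^2/s per acquisition regime.
#: "disco" narrows the bands to stick-like numerical-phantom values and
#: disables the isotropic compartments.
PRIOR_BANDS = {
    "invivo": {"d_par": (2.0e-3, 3.0e-3), "d_perp_ex": (0.1e-3, 1.5e-3)},
    "exvivo": {"d_par": (0.6e-3, 1.0e-3), "d_perp_ex": (0.01e-3, 0.35e-3)},
    "disco": {"d_par": (0.54e-3, 0.66e-3), "d_perp_ex": (0.32e-3, 0.38e-3)},
}

_FRACTION_TOL = 1e-12


@dataclass(frozen=True)
class MicrostructureConfig:
    """Full parameter set of one dictionary entry / voxel configuration."""

    n_fibers: int
    f_wm: float
    f_gm: float
    f_fw: float
    fiber_axes: np.ndarray  # (n_fibers, 3) unit vectors
    fiber_weights: np.ndarray  # (n_fibers,), positive, sum 1
    odis: np.ndarray  # (n_fibers,) dispersion index per fiber
    intra_fraction: float  # intra-axonal share of each fiber's WM volume
    diffusivities: Diffusivities

    def __post_init__(self) -> None:
        n = int(self.n_fibers)
        if n not in (0, 1, 2, 3):
            raise ValueError("n_fibers must be in {0, 1, 2, 3}")
        axes = np.asarray(self.fiber_axes, dtype=float).reshape(n, 3)
        w = np.asarray(self.fiber_weights, dtype=float).reshape(n)
        odis = np.asarray(self.odis, dtype=float).reshape(n)
        if min(self.f_wm, self.f_gm, self.f_fw) < 0:
            raise ValueError("tissue fractions must be >= 0")
        if n == 0 and self.f_wm != 0:
            raise ValueError("a voxel without fibers cannot carry a WM fraction")
        if n > 0:
            if np.any(w <= 0) or abs(w.sum() - 1.0) > _FRACTION_TOL:
                raise ValueError("fiber weights must be positive and sum to 1")
            norms = np.linalg.norm(axes, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-8):
                raise ValueError("fiber axes must be unit vectors")
            if np.any(odis <= 0) or np.any(odis > 1):
                raise ValueError("odi must lie in (0, 1]")
            if n > 1:
                c = np.abs(axes @ axes.T)
                np.fill_diagonal(c, 0.0)
                min_ang = np.degrees(np.arccos(np.clip(c.max(), 0.0, 1.0)))
                if min_ang < MIN_FIBER_SEPARATION_DEG - 1e-9:
                    raise ValueError(
                        f"fiber axes closer than {MIN_FIBER_SEPARATION_DEG} deg "
                        f"(got {min_ang:.3f})"
                    )
        if not 0 <= self.intra_fraction <= 1:
            raise ValueError("intra_fraction must lie in [0, 1]")
        total = self.f_wm * (w.sum() if n else 0.0) + self.f_gm + self.f_fw
        if n == 0:
            total = self.f_gm + self.f_fw
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"compartment fractions sum to {total!r}, not 1")
        object.__setattr__(self, "n_fibers", n)
        object.__setattr__(self, "fiber_axes", axes)
        object.__setattr__(self, "fiber_weights", w)
        object.__setattr__(self, "odis", odis)

    @property
    def f_in(self) -> np.ndarray:
        """Per-fiber intra-axonal fractions ``f_wm * w_i * intra_fraction``."""
        return self.f_wm * self.fiber_weights * self.intra_fraction

    @property
    def f_ex(self) -> np.ndarray:
        """Per-fiber extra-axonal fractions ``f_wm * w_i * (1 - intra_fraction)``."""
        return self.f_wm * self.fiber_weights * (1.0 - self.intra_fraction)

    def fraction_sum(self) -> float:
        """Total compartment fraction; equals 1 up to float round-off."""
        return float(self.f_in.sum() + self.f_ex.sum() + self.f_gm + self.f_fw)


def _draw_axes(rng: np.random.Generator, n: int, grid: SphereGrid, min_sep: float) -> np.ndarray:
    """Draw ``n`` distinct grid vertices with pairwise folded separation."""
    cos_min = np.cos(np.radians(min_sep))
    chosen: list[int] = []
    verts = grid.vertices
    for _ in range(10000):
        idx = int(rng.integers(0, len(verts)))
        if idx in chosen:
            continue
        if all(abs(float(verts[idx] @ verts[j])) < cos_min for j in chosen):
            chosen.append(idx)
            if len(chosen) == n:
                return verts[chosen].copy()
    raise RuntimeError("could not place fiber axes with the requested separation")


def sample_config(
    rng: np.random.Generator,
    mode: str = "invivo",
    grid: SphereGrid | None = None,
    min_separation: float = MIN_FIBER_SEPARATION_DEG,
) -> MicrostructureConfig:
    """Draw one voxel configuration from the sampling priors.

    ``mode`` selects the diffusivity bands ("invivo", "exvivo" or the
    numerical-phantom preset "disco", which also disables the isotropic
    compartments).  The number of fibers is uniform on {0, 1, 2, 3} and
    tissue fractions are Dirichlet(2, 1, 1) over (WM, GM, FW); fiber-free
    voxels redraw (GM, FW) alone with WM fixed at zero.
    """
    if mode not in PRIOR_BANDS:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(PRIOR_BANDS)}")
    from .sphere import default_grid  # local import: packaged data touch

    if grid is None:
        grid = default_grid()
    bands = PRIOR_BANDS[mode]
    isotropic_enabled = mode != "disco"

    if isotropic_enabled:
        n_fibers = int(rng.integers(0, 4))
        if n_fibers == 0:
            f_gm, f_fw = rng.dirichlet([1.0, 1.0])
            f_wm = 0.0
        else:
            f_wm, f_gm, f_fw = rng.dirichlet([2.0, 1.0, 1.0])
    else:
        n_fibers = int(rng.integers(1, 4))
        f_wm, f_gm, f_fw = 1.0, 0.0, 0.0

    if n_fibers == 0:
        axes = np.zeros((0, 3))
        weights = np.zeros(0)
        odis = np.zeros(0)
    else:
        axes = _draw_axes(rng, n_fibers, grid, min_separation)
        if n_fibers == 1:
            weights = np.array([1.0])
        elif n_fibers == 2:
            w = rng.uniform(0.2, 0.8)
            weights = np.array([w, 1.0 - w])
        else:
            weights = rng.dirichlet([1.0, 1.0, 1.0])
        odis = rng.choice(ODI_LEVELS, size=n_fibers)

    d_par = rng.uniform(*bands["d_par"])
    d_perp = rng.uniform(*bands["d_perp_ex"])
    intra = rng.uniform(0.6, 0.9)
    return MicrostructureConfig(
        n_fibers=n_fibers,
        f_wm=float(f_wm),
        f_gm=float(f_gm),
        f_fw=float(f_fw),
        fiber_axes=axes,
        fiber_weights=weights,
        odis=odis,
        intra_fraction=float(intra),
        diffusivities=Diffusivities(d_par=float(d_par), d_perp_ex=float(d_perp)),
    )


def synthesize_signal(
    config: MicrostructureConfig,
    gtab: GradientTable,
    grid: SphereGrid,
) -> np.ndarray:
    """Noiseless attenuation vector of one configuration (S0 convention = 1).

    Reference implementation: loops over fibers and evaluates the dispersed
    stick/zeppelin averages with the discrete Bingham density.  The batched
    path used by :func:`build_dictionary` reproduces this to float precision.
    """
    b = gtab.bvals
    g = gtab.bvecs
    d = config.diffusivities
    signal = config.f_fw * isotropic_signal(b, d.d_fw) + config.f_gm * isotropic_signal(b, d.d_gm)
    f_in, f_ex = config.f_in, config.f_ex
    for i in range(config.n_fibers):
        p = bingham_density(BinghamParams.from_odi(config.fiber_axes[i], config.odis[i]), grid)
        # (M, V) per-vertex compartment signals, averaged under the density
        proj2 = np.square(grid.vertices @ g.T)
        stick = np.exp(-(b[None, :] * d.d_par) * proj2)
        zepp = np.exp(-b[None, :] * (d.d_perp_ex + (d.d_par - d.d_perp_ex) * proj2))
        signal = signal + f_in[i] * (p @ stick) + f_ex[i] * (p @ zepp)
    signal = np.asarray(signal, dtype=float)
    signal[b == 0] = 1.0  # exact by the unit fraction sum
    return signal


@dataclass
class ConfigArrays:
    """Columnar storage of L configurations (unused fiber slots are zero)."""

    n_fibers: np.ndarray  # (L,) int
    fractions: np.ndarray  # (L, 3) -> f_wm, f_gm, f_fw
    axes: np.ndarray  # (L, 3, 3)
    weights: np.ndarray  # (L, 3)
    odis: np.ndarray  # (L, 3)
    intra_fraction: np.ndarray  # (L,)
    d_par: np.ndarray  # (L,)
    d_perp_ex: np.ndarray  # (L,)
    d_gm: float = D_GM
    d_fw: float = D_FW

    def __len__(self) -> int:
        return len(self.n_fibers)

    def config(self, i: int) -> MicrostructureConfig:
        n = int(self.n_fibers[i])
        return MicrostructureConfig(
            n_fibers=n,
            f_wm=float(self.fractions[i, 0]),
            f_gm=float(self.fractions[i, 1]),
            f_fw=float(self.fractions[i, 2]),
            fiber_axes=self.axes[i, :n],
            fiber_weights=self.weights[i, :n],
            odis=self.odis[i, :n],
            intra_fraction=float(self.intra_fraction[i]),
            diffusivities=Diffusivities(
                d_par=float(self.d_par[i]),
                d_perp_ex=float(self.d_perp_ex[i]),
                d_gm=self.d_gm,
                d_fw=self.d_fw,
            ),
        )

    @classmethod
    def from_configs(cls, configs: list[MicrostructureConfig]) -> "ConfigArrays":
        L = len(configs)
        out = cls(
            n_fibers=np.zeros(L, dtype=np.int8),
            fractions=np.zeros((L, 3)),
            axes=np.zeros((L, 3, 3)),
            weights=np.zeros((L, 3)),
            odis=np.zeros((L, 3)),
            intra_fraction=np.zeros(L),
            d_par=np.zeros(L),
            d_perp_ex=np.zeros(L),
        )
        for i, c in enumerate(configs):
            n = c.n_fibers
            out.n_fibers[i] = n
            out.fractions[i] = (c.f_wm, c.f_gm, c.f_fw)
            out.axes[i, :n] = c.fiber_axes
            out.weights[i, :n] = c.fiber_weights
            out.odis[i, :n] = c.odis
            out.intra_fraction[i] = c.intra_fraction
            out.d_par[i] = c.diffusivities.d_par
            out.d_perp_ex[i] = c.diffusivities.d_perp_ex
        if configs:
            out.d_gm = configs[0].diffusivities.d_gm
            out.d_fw = configs[0].diffusivities.d_fw
        return out


@dataclass
class SignalDictionary:
    """L simulated signal vectors, their configurations, and provenance."""

    signals: np.ndarray  # (L, V) noiseless attenuations
    configs: ConfigArrays
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signals.ndim != 2 or len(self.signals) < 1:
            raise ValueError("signals must be a non-empty (L, V) matrix")
        if len(self.signals) != len(self.configs):
            raise ValueError("signals and configs disagree on L")

    def __len__(self) -> int:
        return len(self.signals)

    @property
    def n_volumes(self) -> int:
        return self.signals.shape[1]


def synthesize_batch(
    configs: ConfigArrays,
    gtab: GradientTable,
    grid: SphereGrid,
    block: int = 64,
) -> np.ndarray:
    """Vectorized forward model for many configurations at once.

    Works fiber-slot by fiber-slot in fixed-size blocks with reused buffers;
    agrees with :func:`synthesize_signal` to float precision.
    """
    L = len(configs)
    V = len(gtab)
    M = len(grid)
    b = gtab.bvals
    proj2 = np.square(grid.vertices @ gtab.bvecs.T)  # (M, V)

    out = np.empty((L, V))
    np.multiply(configs.fractions[:, 2:3], isotropic_signal(b, configs.d_fw)[None, :], out=out)
    out += configs.fractions[:, 1:2] * isotropic_signal(b, configs.d_gm)[None, :]

    f_wm = configs.fractions[:, 0]
    args = np.empty((block, M, V))
    expbuf = np.empty((block, M, V))
    for slot in range(3):
        sel = np.flatnonzero(configs.n_fibers > slot)
        for start in range(0, len(sel), block):
            idx = sel[start : start + block]
            nb = len(idx)
            a = args[:nb]
            eb = expbuf[:nb]
            mus = configs.axes[idx, slot]  # (nb, 3)
            kappa = odi_to_kappa(np.maximum(configs.odis[idx, slot], 1e-12))
            dots2 = np.square(grid.vertices @ mus.T)  # (M, nb)
            logp = kappa[None, :] * dots2
            logp -= logp.max(axis=0)
            p = np.exp(logp)
            p /= p.sum(axis=0)
            pT = np.ascontiguousarray(p.T)[:, None, :]  # (nb, 1, M)

            d_par = configs.d_par[idx]
            d_perp = configs.d_perp_ex[idx]
            # dispersed stick: exp(-b d_par (g.n)^2) averaged over vertices
            np.multiply((b[None, :] * d_par[:, None])[:, None, :], proj2[None], out=a)
            np.negative(a, out=a)
            np.exp(a, out=eb)
            s_in = np.matmul(pT, eb).reshape(nb, V)
            # dispersed zeppelin: radial decay factors out of the average
            np.multiply((b[None, :] * (d_par - d_perp)[:, None])[:, None, :], proj2[None], out=a)
            np.negative(a, out=a)
            np.exp(a, out=eb)
            s_ex = np.matmul(pT, eb).reshape(nb, V)
            s_ex *= np.exp(-b[None, :] * d_perp[:, None])

            w = f_wm[idx] * configs.weights[idx, slot]
            intra = configs.intra_fraction[idx]
            out[idx] += (w * intra)[:, None] * s_in + (w * (1.0 - intra))[:, None] * s_ex
    out[:, b == 0] = 1.0
    return out


def build_dictionary(
    n_entries: int,
    gtab: GradientTable,
    grid: SphereGrid,
    mode: str = "invivo",
    seed: int = 0,
    min_separation: float = MIN_FIBER_SEPARATION_DEG,
    max_bytes: int = 4 * 1024**3,
) -> SignalDictionary:
    """Sample ``n_entries`` iid configurations and synthesize their signals.

    Fully reproducible from ``seed``.  Refuses builds whose signal matrix
    would exceed ``max_bytes``.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    need = n_entries * len(gtab) * 8
    if need > max_bytes:
        raise ValueError(
            f"dictionary of {n_entries} x {len(gtab)} float64 signals needs "
            f"{need / 1e9:.1f} GB, over the {max_bytes / 1e9:.1f} GB budget; "
            "lower n_entries or raise max_bytes"
        )
    rng = np.random.default_rng(seed)
    configs = ConfigArrays.from_configs(
        [sample_config(rng, mode, grid, min_separation) for _ in range(n_entries)]
    )
    signals = synthesize_batch(configs, gtab, grid)
    meta = {
        "fingerprint": gtab.fingerprint(),
        "grid_m": len(grid),
        "seed": int(seed),
        "mode": mode,
        "n_entries": int(n_entries),
        "n_volumes": len(gtab),
        "min_separation_deg": float(min_separation),
        "version": 1,
    }
    return SignalDictionary(signals, configs, meta)


def save_dictionary(dictionary: SignalDictionary, path) -> None:
    """Persist a dictionary as a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=dictionary.signals)
        grp = f.create_group("configs")
        c = dictionary.configs
        for name in ("n_fibers", "fractions", "axes", "weights", "odis",
                     "intra_fraction", "d_par", "d_perp_ex"):
            grp.create_dataset(name, data=getattr(c, name))
        grp.attrs["d_gm"] = c.d_gm
        grp.attrs["d_fw"] = c.d_fw
        f.attrs["meta"] = json.dumps(dictionary.meta)


def load_dictionary(path) -> SignalDictionary:
    """Load a dictionary saved by :func:`save_dictionary`."""
    try:
        with h5py.File(path, "r") as f:
            signals = f["signals"][()]
            grp = f["configs"]
            c = ConfigArrays(
                n_fibers=grp["n_fibers"][()],
                fractions=grp["fractions"][()],
                axes=grp["axes"][()],
                weights=grp["weights"][()],
                odis=grp["odis"][()],
                intra_fraction=grp["intra_fraction"][()],
                d_par=grp["d_par"][()],
                d_perp_ex=grp["d_perp_ex"][()],
                d_gm=float(grp.attrs["d_gm"]),
                d_fw=float(grp.attrs["d_fw"]),
            )
            meta = json.loads(f.attrs["meta"])
    except (OSError, KeyError) as exc:
        raise ValueError(f"{path} is not a valid signal dictionary: {exc}") from exc
    return SignalDictionary(signals, c, meta)
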