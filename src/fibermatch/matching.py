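"""Voxel-wise dictionary matching by penalized cosine similarity.

Each measured voxel signal y is compared against every dictionary row S_i
through the cosine

    C_i = (y . S_i) / (||y|| ||S_i||),

which is invariant to any positive rescaling of y — deliberately so, since
b0-based normalization is unstable on real data — and, after optimal
rescaling, equivalent to the L2 misfit: min_beta ||y - beta d||^2 =
||y||^2 (1 - cos^2(y, d)).  The K most similar entries form a local
candidate neighborhood; within it the selected entry maximizes

    cos(y, S_i) - alpha * n_fibers(i),

a complexity penalty that suppresses spurious extra fiber populations.
All acquisition volumes, including every b0 volume, enter the matching
vector; no averaging or normalization is applied to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import GradientTable, VolumeStack
from .dictionary import SignalDictionary

__all__ = [
    "FitConfig",
    "MatchResult",
    "VolumeFitResult",
    "cosine_similarity",
    "top_k",
    "penalized_select",
    "fit_signals",
    "fit_volume",
]


@dataclass(frozen=True)
class FitConfig:
    """Matching hyperparameters.

    ``alpha`` is the fiber-count penalty strength (1e-5 balances sensitivity
    to true crossings against spurious peaks); ``wm_threshold`` is the
    minimum matched WM fraction for reporting peak orientations.
    """

    K: int = 50
    alpha: float = 1e-5
    wm_threshold: float = 0.5
    block_size: int = 128  # voxels per matmul block; memory = block * L * 8 bytes

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 <= self.wm_threshold <= 1:
            raise ValueError("wm_threshold must lie in [0, 1]")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass(frozen=True)
class MatchResult:
    """Best dictionary entry for one voxel plus its top-K neighborhood."""

    best_index: int
    best_similarity: float  # unpenalized cosine of the selected entry
    neighborhood_indices: np.ndarray  # (K,), sorted by unpenalized cosine desc
    neighborhood_similarities: np.ndarray  # (K,) penalized similarities


def cosine_similarity(y: np.ndarray, signals: np.ndarray) -> np.ndarray:
    """Cosine of ``y`` against every dictionary row; values in [-1, 1].

    Negative cosines (possible with noisy data) are retained, never clipped.
    """
    y = np.asarray(y, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if y.ndim != 1 or signals.ndim != 2 or signals.shape[1] != y.shape[0]:
        raise ValueError("y must be (V,) and signals (L, V)")
    ny = np.linalg.norm(y)
    if ny == 0:
        raise ValueError("all-zero signal vector is unmatchable")
    row_norms = np.linalg.norm(signals, axis=1)
    return (signals @ y) / (row_norms * ny)


def top_k(similarities: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices and values of the K largest similarities, descending.

    Ties, including at the K boundary, are broken toward the lower
    dictionary index so results never depend on partition internals.
    """
    s = np.asarray(similarities)
    if k > len(s):
        raise ValueError(f"K={k} exceeds dictionary size {len(s)}")
    if k == len(s):
        cand = np.arange(len(s))
    else:
        kth = np.partition(s, len(s) - k)[len(s) - k]
        cand = np.flatnonzero(s >= kth)  # ascending index order
    order = np.argsort(-s[cand], kind="stable")[:k]
    idx = cand[order]
    return idx, s[idx]


def penalized_select(
    neighborhood_indices: np.ndarray,
    neighborhood_similarities: np.ndarray,
    n_fibers: np.ndarray,
    alpha: float,
) -> tuple[int, np.ndarray]:
    """Apply the fiber-count penalty within a candidate neighborhood.

    Returns the winning dictionary index and the penalized scores.  Exact
    score ties are broken toward fewer fibers, then the lower index.
    """
    idx = np.asarray(neighborhood_indices)
    if len(idx) == 0:
        raise ValueError("empty candidate neighborhood")
    counts = np.asarray(n_fibers)[idx]
    scores = np.asarray(neighborhood_similarities, dtype=float) - alpha * counts
    # lexsort: last key is primary
    order = np.lexsort((idx, counts, -scores))
    return int(idx[order[0]]), scores


def fit_signals(
    signals: np.ndarray,
    dictionary: SignalDictionary,
    config: FitConfig = FitConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Match N measured signal vectors against the dictionary.

    Returns ``(best_index, best_cosine, neighborhood_indices,
    penalized_neighborhood)`` with shapes (N,), (N,), (N, K), (N, K).
    Rows that are entirely zero are unmatchable: best_index = -1 and NaN
    similarities.  Voxels are processed independently, so the output is
    identical for any block partitioning.
    """
    Y = np.asarray(signals, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != dictionary.n_volumes:
        raise ValueError(
            f"signals {Y.shape} incompatible with dictionary of "
            f"{dictionary.n_volumes} volumes"
        )
    L = len(dictionary)
    K = config.K
    if K > L:
        raise ValueError(f"K={K} exceeds dictionary size {L}")
    D = dictionary.signals / np.linalg.norm(dictionary.signals, axis=1, keepdims=True)
    counts = dictionary.configs.n_fibers.astype(np.int64)

    N = len(Y)
    best_index = np.full(N, -1, dtype=np.int64)
    best_cos = np.full(N, np.nan)
    nb_idx = np.zeros((N, K), dtype=np.int64)
    nb_pen = np.full((N, K), np.nan)

    # one matrix-vector product per voxel: the similarity profile of a voxel
    # never depends on which other voxels share its block, so results are
    # bit-identical under any partitioning
    sims = np.empty(L)
    block = config.block_size
    for start in range(0, N, block):
        for v in range(start, min(start + block, N)):
            y = Y[v]
            ny = np.linalg.norm(y)
            if ny == 0:
                continue
            yn = y / ny
            np.dot(D, yn, out=sims)
            idx, _ = top_k(sims, K)
            # refine the neighborhood with the cancellation-free distance
            # form cos = 1 - ||y^ - d^||^2 / 2: near-1 cosines from the dot
            # product carry ~1e-16 noise that can misrank a voxel's exact
            # self-match below a physically duplicate entry, so ranking and
            # penalization both work on delta2 = ||y^ - d^||^2, which
            # resolves matches down to bitwise identity
            diff = D[idx] - yn[None, :]
            delta2 = np.einsum("kv,kv->k", diff, diff)
            order = np.lexsort((idx, delta2))
            idx, delta2 = idx[order], delta2[order]
            vals = 1.0 - 0.5 * delta2
            # argmax of cos - alpha*n == argmin of delta2/2 + alpha*n
            nb_counts = counts[idx]
            sel = np.lexsort((idx, nb_counts, 0.5 * delta2 + config.alpha * nb_counts))[0]
            chosen = int(idx[sel])
            pen = vals - config.alpha * nb_counts
            nb_idx[v] = idx
            nb_pen[v] = pen
            best_index[v] = chosen
            best_cos[v] = vals[np.flatnonzero(idx == chosen)[0]]
    return best_index, best_cos, nb_idx, nb_pen


@dataclass
class VolumeFitResult:
    """Per-voxel matching output over a masked 3D volume."""

    best_index: np.ndarray  # (x, y, z) int, -1 outside mask / unmatchable
    best_similarity: np.ndarray  # (x, y, z) float, NaN outside mask
    neighborhood_indices: np.ndarray  # (x, y, z, K)
    neighborhood_similarities: np.ndarray  # (x, y, z, K) penalized
    mask: np.ndarray  # (x, y, z) bool, voxels actually matched
    fit_config: FitConfig
    dictionary_meta: dict = field(default_factory=dict)

    def result_at(self, i: int, j: int, k: int) -> MatchResult:
        if not self.mask[i, j, k]:
            raise KeyError(f"voxel {(i, j, k)} was not matched")
        return MatchResult(
            best_index=int(self.best_index[i, j, k]),
            best_similarity=float(self.best_similarity[i, j, k]),
            neighborhood_indices=self.neighborhood_indices[i, j, k],
            neighborhood_similarities=self.neighborhood_similarities[i, j, k],
        )


def fit_volume(
    stack: VolumeStack,
    gtab: GradientTable,
    dictionary: SignalDictionary,
    config: FitConfig = FitConfig(),
) -> VolumeFitResult:
    """Match every masked voxel of a 4D stack against the dictionary.

    The dictionary must have been built on the same acquisition: its stored
    gradient-table fingerprint is checked before any work is done.
    """
    fp = dictionary.meta.get("fingerprint")
    if fp is not None and fp != gtab.fingerprint():
        raise ValueError(
            "dictionary was built for a different acquisition "
            f"(fingerprint {fp} != {gtab.fingerprint()})"
        )
    if stack.n_volumes != len(gtab):
        raise ValueError("stack and gradient table disagree on volume count")
    shape = stack.data.shape[:3]
    mask = stack.mask if stack.mask is not None else np.ones(shape, dtype=bool)
    vox = np.flatnonzero(mask.ravel())
    Y = stack.data.reshape(-1, stack.n_volumes)[vox]

    K = config.K
    best_index = np.full(shape, -1, dtype=np.int64).ravel()
    best_cos = np.full(shape, np.nan).ravel()
    nb_idx = np.zeros(shape + (K,), dtype=np.int64).reshape(-1, K)
    nb_pen = np.full(shape + (K,), np.nan).reshape(-1, K)
    matched = np.zeros(shape, dtype=bool).ravel()

    if len(vox):
        bi, bc, ni, npen = fit_signals(Y, dictionary, config)
        best_index[vox] = bi
        best_cos[vox] = bc
        nb_idx[vox] = ni
        nb_pen[vox] = npen
        matched[vox] = bi >= 0
    return VolumeFitResult(
        best_index=best_index.reshape(shape),
        best_similarity=best_cos.reshape(shape),
        neighborhood_indices=nb_idx.reshape(shape + (K,)),
        neighborhood_similarities=nb_pen.reshape(shape + (K,)),
        mask=matched.reshape(shape),
        fit_config=config,
        dictionary_meta=dict(dictionary.meta),
    )
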