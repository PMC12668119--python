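"""Acquisition-scheme and image-volume I/O.

Gradient tables follow the FSL ``bval``/``bvec`` text dialect; volumes are
NIfTI-1/2 via nibabel.  Gradient vectors are kept in image coordinates and
never reoriented by the affine, matching common practice in diffusion
pipelines.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DEFAULT_B0_THRESHOLD",
    "GradientTable",
    "VolumeStack",
    "read_gradient_table",
    "read_volume",
    "write_volume",
]

log = logging.getLogger(__name__)

#: b-value (s/mm^2) below which a volume counts as non-diffusion-weighted
DEFAULT_B0_THRESHOLD = 50.0


@dataclass(frozen=True)
class GradientTable:
    """Per-volume diffusion weightings and unit gradient directions.

    ``bvals`` are in s/mm^2; ``bvecs`` are unit 3-vectors for weighted
    volumes (the zero vector is allowed wherever ``bvals`` falls below
    ``b0_threshold``).
    """

    bvals: np.ndarray  # (V,)
    bvecs: np.ndarray  # (V, 3)
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (V, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs) or len(bvals) < 1:
            raise ValueError(
                f"bvals ({len(bvals)}) and bvecs ({len(bvecs)}) must have equal length >= 1"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        dwi = bvals >= self.b0_threshold
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(norms[dwi] < 1e-12):
            raise ValueError("zero gradient vector on a diffusion-weighted volume")
        bvecs = bvecs.copy()
        bvecs[dwi] /= norms[dwi, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask of non-diffusion-weighted volumes."""
        return self.bvals < self.b0_threshold

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    def fingerprint(self) -> str:
        """Stable hash of the acquisition, used to pair dictionaries with data."""
        h = hashlib.sha256()
        h.update(np.round(self.bvals, 6).tobytes())
        h.update(np.round(self.bvecs, 6).tobytes())
        h.update(np.float64(self.b0_threshold).tobytes())
        return h.hexdigest()[:16]


def _parse_numeric(path: Path) -> np.ndarray:
    rows = []
    text = path.read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise ValueError(f"non-numeric token in {path}: {exc}") from None
    if not rows:
        raise ValueError(f"empty gradient file: {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged rows in {path}")
    return np.asarray(rows, dtype=float)


def read_gradient_table(
    bval_path: str | Path,
    bvec_path: str | Path,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> GradientTable:
    """Read FSL-style ``bval``/``bvec`` files.

    The bvec layout (3 rows x V columns vs. V rows x 3 columns) is detected
    from the array shape; an ambiguous 3x3 file is interpreted as 3 rows of
    components, the FSL convention.
    """
    bvals = _parse_numeric(Path(bval_path)).ravel()
    bvecs = _parse_numeric(Path(bvec_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T  # FSL layout: one row per component
    elif bvecs.shape[1] != 3:
        raise ValueError(f"bvec file must be 3xV or Vx3, got {bvecs.shape}")
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError(
            f"bvals has {bvals.shape[0]} volumes but bvecs has {bvecs.shape[0]}"
        )
    return GradientTable(bvals, bvecs, b0_threshold)


@dataclass
class VolumeStack:
    """A 4D diffusion-weighted volume with its voxel-to-world affine."""

    data: np.ndarray  # (x, y, z, V)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match spatial shape "
                    f"{self.data.shape[:3]}"
                )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def read_volume(path: str | Path, mask: np.ndarray | None = None) -> VolumeStack:
    """Load a 4D NIfTI file (scl slope/intercept applied, nothing else)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    return VolumeStack(data, img.affine, mask)


def write_volume(
    data: np.ndarray | VolumeStack,
    path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """Write a 3D map or 4D stack as NIfTI.

    Non-finite values are written as-is with a logged warning so that missing
    map values (NaN) survive the round trip.
    """
    if isinstance(data, VolumeStack):
        affine = data.affine if affine is None else affine
        arr = data.data
    else:
        arr = np.asarray(data)
    if arr.size == 0:
        raise ValueError("refusing to write an empty array")
    if arr.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D array, got {arr.ndim}D")
    if affine is None:
        affine = np.eye(4)
    if np.issubdtype(arr.dtype, np.floating) and not np.all(np.isfinite(arr)):
        log.warning("writing non-finite values to %s", path)
        warnings.warn(f"non-finite values written to {path}", RuntimeWarning, stacklevel=2)
    nib.save(nib.Nifti1Image(np.asarray(arr), np.asarray(affine, dtype=float)), str(path))
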