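"""Volume and gradient-table I/O.

NIfTI-1 volumes are handled through nibabel. Gradient tables use the
FSL dialect: ``.bval`` is a single whitespace-delimited row of b-values
(s/mm^2), ``.bvec`` holds three rows (x, y, z components), and column i of
both files describes diffusion volume i of the accompanying 4D image.
Affine transforms are serialized as 4x4 ASCII matrices, one row per line.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI-1 volume; returns (data, voxel-to-world affine).

    Data is returned as float unless the on-disk dtype is integral or
    boolean-like, in which case it is preserved. Gzip compression is
    inferred from the extension.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt header / truncated file
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    return np.asarray(data), np.asarray(img.affine, dtype=float)


def write_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a volume as NIfTI-1. Float data is stored as float32-exact
    only when already float32; otherwise the native dtype is kept."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-dialect gradient files -> (bvals (n,), bvecs (n, 3))."""
    try:
        bvals = np.loadtxt(bval_path, ndmin=2)
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"unparseable gradient table: {exc}") from exc
    bvals = bvals.ravel()
    if bvecs.shape[0] != 3:
        if bvecs.shape[1] == 3:  # tolerate transposed tables
            bvecs = bvecs.T
        else:
            raise FormatError(f"bvec file must have 3 rows, got shape {bvecs.shape}")
    if bvecs.shape[1] != bvals.size:
        raise FormatError(
            f"gradient table length mismatch: {bvals.size} b-values, {bvecs.shape[1]} directions"
        )
    return bvals, bvecs.T.copy()


def write_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray, bval_path, bvec_path) -> None:
    """Write FSL-dialect gradient files (bvecs given as (n, 3))."""
    bvals = np.asarray(bvals, float).ravel()
    bvecs = np.asarray(bvecs, float)
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in bvecs.T:
            fh.write(" ".join(f"{v:.10f}" for v in row) + "\n")


_XFM_HEADER = (
    "# 4x4 homogeneous voxel-to-world affine, row-major, one row per line\n"
    "# (FSL-style ordering: y = M @ x with x, y homogeneous world coordinates)\n"
)


def write_transform(matrix: np.ndarray, path) -> None:
    """Serialize a 4x4 transform as an ASCII matrix with a header comment."""
    matrix = np.asarray(matrix, float)
    if matrix.shape != (4, 4):
        raise ValueError(f"transform must be 4x4, got {matrix.shape}")
    with open(path, "w") as fh:
        fh.write(_XFM_HEADER)
        for row in matrix:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_transform(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(v) for v in line.split()])
    matrix = np.asarray(rows, float)
    if matrix.shape != (4, 4):
        raise FormatError(f"expected a 4x4 matrix in {path}, got shape {matrix.shape}")
    return matrix
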