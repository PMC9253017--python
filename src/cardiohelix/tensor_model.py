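"""Diffusion tensor reconstruction from diffusion-weighted MRI.

Implements the log-linear weighted-least-squares (WLS) tensor fit used for
ex vivo cardiac DT-MRI: a first ordinary-least-squares pass on the
log-signal followed by a small fixed number of reweighted passes with
weights equal to the squared predicted signal, which is the standard
variance-stabilising weighting for log-transformed Rician/Gaussian MR
magnitude data.  The primary eigenvector of the fitted tensor is the
per-voxel myofiber direction estimate consumed by the helicity analysis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "DWIVolume",
    "DiffusionTensorField",
    "EigenSystemField",
    "read_scheme",
    "write_scheme",
    "default_scheme",
    "fit_tensor_wls",
    "eigendecompose",
    "fractional_anisotropy",
]

_UNIT_TOL = 1e-4


@dataclasses.dataclass(frozen=True)
class AcquisitionScheme:
    """Diffusion experiment definition: b-values (s/mm^2) and unit gradients.

    ``bvecs`` rows are unit 3-vectors in image coordinates; the zero vector
    marks non-diffusion-weighted (b=0) volumes.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bval/bvec length mismatch: {bvals.shape[0]} vs {bvecs.shape[0]}"
            )
        if bvals.shape[0] == 0:
            raise ValueError("empty acquisition scheme")
        norms = np.linalg.norm(bvecs, axis=1)
        bad = np.where((norms > _UNIT_TOL) & (np.abs(norms - 1.0) > _UNIT_TOL))[0]
        if bad.size:
            raise ValueError(
                f"gradient vector {bad[0]} has norm {norms[bad[0]]:.6f}; "
                "expected unit norm or zero"
            )
        incons = np.where((bvals > 0) & (norms <= _UNIT_TOL))[0]
        if incons.size:
            raise ValueError(
                f"volume {incons[0]} has b={bvals[incons[0]]:g} s/mm^2 but a "
                "zero gradient vector"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    def validate_for_fit(self) -> None:
        """Require >=1 b=0 volume and >=6 unique non-collinear directions."""
        if not np.any(self.b0_mask):
            raise ValueError("scheme has no b=0 volume; tensor fit impossible")
        dirs = self.bvecs[self.dwi_mask]
        # unique up to antipodal symmetry
        uniq: list[np.ndarray] = []
        for g in dirs:
            if not any(abs(abs(g @ u) - 1.0) < 1e-6 for u in uniq):
                uniq.append(g)
        if len(uniq) < 6:
            raise ValueError(
                f"scheme has only {len(uniq)} unique diffusion directions; "
                ">=6 non-collinear directions required"
            )

    def design_matrix(self) -> np.ndarray:
        """Log-linear design: columns [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
        b = self.bvals
        gx, gy, gz = self.bvecs.T
        return np.column_stack(
            [
                np.ones_like(b),
                -b * gx * gx,
                -b * gy * gy,
                -b * gz * gz,
                -2 * b * gx * gy,
                -2 * b * gx * gz,
                -2 * b * gy * gz,
            ]
        )


@dataclasses.dataclass
class DWIVolume:
    """4-D diffusion-weighted dataset (x, y, z, volume) with its scheme."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"{self.data.shape[3]} volumes but scheme has {len(self.scheme)}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def b0_mean(self) -> np.ndarray:
        return self.data[..., self.scheme.b0_mask].mean(axis=-1)


@dataclasses.dataclass
class DiffusionTensorField:
    """Per-voxel symmetric diffusion tensor (mm^2/s).

    ``tensors`` stores the six unique components in the order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz); ``log_s0`` is the fitted ln S0 and
    ``fit_ok`` flags voxels with a usable fit.
    """

    tensors: np.ndarray  # (x, y, z, 6)
    log_s0: np.ndarray  # (x, y, z)
    fit_ok: np.ndarray  # (x, y, z) bool

    def as_matrices(self) -> np.ndarray:
        """Expand to full symmetric (..., 3, 3) matrices."""
        t = self.tensors
        m = np.empty(t.shape[:-1] + (3, 3), dtype=t.dtype)
        m[..., 0, 0] = t[..., 0]
        m[..., 1, 1] = t[..., 1]
        m[..., 2, 2] = t[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = t[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = t[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = t[..., 5]
        return m


@dataclasses.dataclass
class EigenSystemField:
    """Eigen-decomposition of a tensor field, sorted descending.

    ``eigenvectors[..., :, i]`` is the unit eigenvector for ``eigenvalues[..., i]``;
    index 0 is the primary (fiber) direction.  ``degenerate`` flags voxels
    where the two largest eigenvalues are within relative tolerance (fiber
    direction ill-defined) or the tensor was invalid.
    """

    eigenvalues: np.ndarray  # (x, y, z, 3), descending
    eigenvectors: np.ndarray  # (x, y, z, 3, 3)
    degenerate: np.ndarray  # (x, y, z) bool
    valid: np.ndarray  # (x, y, z) bool

    @property
    def e1(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]


def read_scheme(bval_path: str | Path, bvec_path: str | Path) -> AcquisitionScheme:
    """Read an FSL-style ``.bval``/``.bvec`` pair.

    The bval file holds one row of b-values; the bvec file holds three rows
    (x, y, z) with one column per volume.
    """
    if not Path(bval_path).read_text().strip() or not Path(bvec_path).read_text().strip():
        raise ValueError("empty bval or bvec file")
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=float))
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous square case: FSL convention is 3 rows x n columns
        bvecs = bvecs.T
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def write_scheme(scheme: AcquisitionScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write the scheme in the FSL dialect (space-separated, bvec 3 x n)."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10f")


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Roughly uniform unit directions on a hemisphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    z = i / n  # (0, 1): upper hemisphere, avoids antipodal duplicates
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_scheme(b: float = 500.0, n_directions: int = 12, n_b0: int = 4) -> AcquisitionScheme:
    """Default ex vivo scheme: 12 directions at b = 500 s/mm^2 plus 4 b = 0."""
    dirs = _fibonacci_hemisphere(n_directions)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def fit_tensor_wls(
    dwi: DWIVolume,
    scheme: AcquisitionScheme | None = None,
    mask: np.ndarray | None = None,
    n_iter: int = 2,
) -> DiffusionTensorField:
    """Fit a diffusion tensor per voxel by iterated weighted least squares.

    Solves ln S_i = ln S0 - b_i g_i^T D g_i in the 7-parameter log-linear
    design.  The first pass is ordinary least squares; each of the ``n_iter``
    subsequent passes reweights with the squared predicted signal.
    Non-positive measurements are excluded per voxel; a voxel keeping fewer
    than 7 usable measurements is flagged ``fit_ok=False``.

    Parameters
    ----------
    dwi : DWIVolume
    scheme : AcquisitionScheme, optional
        Defaults to ``dwi.scheme``.
    mask : bool array, optional
        Voxels to fit; defaults to all.
    n_iter : int
        Number of reweighted passes after the OLS pass.
    """
    scheme = scheme or dwi.scheme
    scheme.validate_for_fit()
    X = scheme.design_matrix()
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "acquisition scheme yields a rank-deficient design matrix "
            "(degenerate diffusion direction set)"
        )
    shape = dwi.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match DWI {shape}")

    S = dwi.data[mask]  # (n_vox, n_meas)
    n_vox, n_meas = S.shape
    tensors = np.zeros(shape + (6,), dtype=float)
    log_s0 = np.zeros(shape, dtype=float)
    fit_ok = np.zeros(shape, dtype=bool)
    if n_vox == 0:
        return DiffusionTensorField(tensors, log_s0, fit_ok)

    usable = S > 0
    n_usable = usable.sum(axis=1)
    full = n_usable == n_meas
    partial = (~full) & (n_usable >= 7)

    beta = np.full((n_vox, 7), np.nan)
    if np.any(full):
        beta[full] = _wls_batch(X, S[full], n_iter)
    for idx in np.where(partial)[0]:
        keep = usable[idx]
        Xk = X[keep]
        if np.linalg.matrix_rank(Xk) < 7:
            continue
        beta[idx] = _wls_batch(Xk, S[idx][keep][None, :], n_iter)[0]

    ok = np.isfinite(beta).all(axis=1)
    out_beta = np.zeros((n_vox, 7))
    out_beta[ok] = beta[ok]
    full_ok = np.zeros(shape, dtype=bool)
    full_ok[mask] = ok
    log_s0[mask] = out_beta[:, 0]
    tensors[mask] = out_beta[:, 1:]
    fit_ok[:] = full_ok
    return DiffusionTensorField(tensors=tensors, log_s0=log_s0, fit_ok=fit_ok)


def _wls_batch(X: np.ndarray, S: np.ndarray, n_iter: int) -> np.ndarray:
    """Batched OLS + iterated WLS on log-signal. S: (n_vox, n_meas) > 0."""
    y = np.log(S)
    beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T  # (n_vox, 7)
    for _ in range(n_iter):
        w = np.exp(2.0 * (beta @ X.T))  # squared predicted signal
        # normal equations per voxel: (X^T W X) beta = X^T W y
        Xw = w[:, :, None] * X[None, :, :]  # (n_vox, n_meas, 7)
        A = np.einsum("vmi,mj->vij", Xw, X)
        b = np.einsum("vmi,vm->vi", Xw, y)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
    return beta


def eigendecompose(tf: DiffusionTensorField, degeneracy_tol: float = 1e-3) -> EigenSystemField:
    """Symmetric eigen-decomposition of a tensor field, eigenvalues descending.

    Voxels with non-finite tensors are flagged invalid rather than raising.
    Negative eigenvalues are permitted but flag the voxel degenerate.
    """
    m = tf.as_matrices()
    shape = m.shape[:-2]
    finite = np.isfinite(m).all(axis=(-2, -1)) & tf.fit_ok
    evals = np.zeros(shape + (3,))
    evecs = np.tile(np.eye(3), shape + (1, 1))
    if np.any(finite):
        w, v = np.linalg.eigh(m[finite])
        # eigh is ascending; flip to descending
        evals[finite] = w[:, ::-1]
        evecs[finite] = v[:, :, ::-1]
    l1 = evals[..., 0]
    l2 = evals[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_gap = np.where(l1 != 0, (l1 - l2) / np.abs(l1), 0.0)
    degenerate = (~finite) | (rel_gap < degeneracy_tol) | (evals[..., 2] < 0)
    return EigenSystemField(
        eigenvalues=evals, eigenvectors=evecs, degenerate=degenerate, valid=finite
    )


def fractional_anisotropy(es: EigenSystemField) -> np.ndarray:
    """Fractional anisotropy map in [0, 1]; defined as 0 for the zero tensor."""
    lam = es.eigenvalues
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    return np.clip(np.nan_to_num(fa, nan=0.0), 0.0, None)
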