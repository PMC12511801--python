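"""Kernels for density estimation on hemispheric surfaces.

Two families are built spectrally from LBO eigenpairs (λ_m, f_m):

* diffusion (heat) kernel, weights Φ(λ) = exp(−κ²λ/2);
* Matérn kernel in intrinsic dimension 2, weights Φ(λ) = (2ν/κ² + λ)^(−ν−1),
  which converges to the diffusion weights as ν → ∞.

The matrix form is K = F Φ(Λ) Fᵀ. Under the default ``unit_mass``
normalization the weights are divided by Φ(0); since the constant
eigenfunction is the only mode surviving integration against the lumped
mass, every kernel row then integrates to exactly 1 — what a KDE kernel
must do.

The spherical heat kernel (SHK) baseline is the closed-form heat kernel on
the unit sphere: a Legendre series truncated at the smallest J with
(2J+1)·exp(−J(J+1)σ) < 0.001. On S² the diffusion kernel with κ²/2 = σ is
analytically identical to the SHK (addition theorem), which the tests
exploit as a cross-check between the spectral and series routes.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from surfconn.lbo import SpectralBasis

__all__ = [
    "KernelSpec",
    "KernelMatrix",
    "shk_truncation",
    "legendre",
    "shk_matrix",
    "spectral_kernel",
    "matern_limit_check",
    "block_kernel",
    "bandwidth_grid",
    "KAPPA_MIN",
    "KAPPA_MAX",
    "SIGMA_MIN",
    "SIGMA_MAX",
]

# bandwidth grid endpoints: 10 log-spaced values per family
KAPPA_MIN, KAPPA_MAX = 0.6252, 18.9204
SIGMA_MIN, SIGMA_MAX = 0.0001, 0.05

_FAMILIES = ("diffusion", "matern", "spherical_heat")


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Parameters identifying one kernel.

    bandwidth is κ (mesh length units) for diffusion/Matérn and σ
    (unitless, unit sphere) for spherical_heat; ν is the Matérn smoothness.
    """

    family: str
    bandwidth: float
    smoothness: Optional[float] = None
    truncation: Optional[int] = None
    shk_tol: float = 0.001
    normalization: str = "unit_mass"

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.family == "matern":
            if self.smoothness is None or self.smoothness <= 0:
                raise ValueError("matern kernel requires smoothness nu > 0")
        if self.normalization not in ("unit_mass", "raw"):
            raise ValueError("normalization must be 'unit_mass' or 'raw'")


@dataclasses.dataclass(frozen=True)
class KernelMatrix:
    """Dense symmetric kernel evaluations on the vertex grid.

    ``block_sizes`` records per-hemisphere vertex counts after block
    assembly; single-hemisphere matrices have one block.
    """

    values: np.ndarray
    spec: KernelSpec
    block_sizes: tuple[int, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel matrix must be square")
        if sum(self.block_sizes) != v.shape[0]:
            raise ValueError("block sizes must sum to matrix dimension")
        object.__setattr__(self, "values", v)

    @property
    def min_entry(self) -> float:
        """Most negative entry — truncation can produce small negatives."""
        return float(self.values.min())


def shk_truncation(sigma: float, tol: float = 0.001) -> int:
    """Smallest J ≥ 1 with (2J+1)·exp(−J(J+1)σ) < tol."""
    if sigma <= 0 or tol <= 0:
        raise ValueError("sigma and tol must be positive")
    j = 1
    while (2 * j + 1) * np.exp(-j * (j + 1) * sigma) >= tol:
        j += 1
    return j


def legendre(j: int, x) -> np.ndarray | float:
    """Legendre polynomial P_j(x) on [−1, 1] by the three-term recurrence.

    P_0 = 1, P_1 = x, and j·P_j = (2j−1)·x·P_{j−1} − (j−1)·P_{j−2}.
    """
    xa = np.asarray(x, dtype=np.float64)
    if (np.abs(xa) > 1 + 1e-12).any():
        raise ValueError("legendre argument must lie in [-1, 1]")
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    p_prev = np.ones_like(xa)
    if j == 0:
        return float(p_prev[0]) if scalar else p_prev
    p = xa.copy()
    for jj in range(2, j + 1):
        p, p_prev = ((2 * jj - 1) * xa * p - (jj - 1) * p_prev) / jj, p
    return float(p[0]) if scalar else p


def shk_matrix(unit_vectors: np.ndarray, sigma: float, tol: float = 0.001) -> KernelMatrix:
    """Spherical heat kernel matrix on points of the unit sphere.

    k_σ(u, v) = (1/4π) Σ_{j=0}^{J} (2j+1)·exp(−j(j+1)σ)·P_j(uᵀv), with J
    from :func:`shk_truncation`. The series coefficients already make the
    kernel integrate to 1 over S²; no discrete renormalization is applied.
    """
    u = np.asarray(unit_vectors, dtype=np.float64)
    norms = np.linalg.norm(u, axis=1)
    if np.abs(norms - 1.0).max() > 1e-8:
        raise ValueError("rows of unit_vectors must have unit norm")
    J = shk_truncation(sigma, tol)
    M = len(u)
    K = np.empty((M, M))
    # row blocks keep peak memory at a few block-sized buffers; the Legendre
    # recurrence runs in place over each block of dot products
    block = max(1, int(2e7) // M)
    for lo in range(0, M, block):
        dots = np.clip(u[lo : lo + block] @ u.T, -1.0, 1.0)
        p_prev = np.ones_like(dots)
        acc = p_prev.copy()  # j = 0 term: coefficient 1
        p = dots.copy()
        tmp = np.empty_like(dots)
        for j in range(1, J + 1):
            coef = (2 * j + 1) * np.exp(-j * (j + 1) * sigma)
            acc += coef * p
            if j < J:
                # p_next = ((2j+1)·x·p − j·p_prev)/(j+1), buffers recycled
                np.multiply(dots, p, out=tmp)
                tmp *= 2 * j + 1
                p_prev *= j
                tmp -= p_prev
                tmp /= j + 1
                p_prev, p, tmp = p, tmp, p_prev
        K[lo : lo + block] = acc
    K /= 4.0 * np.pi
    K += K.T.copy()
    K *= 0.5
    spec = KernelSpec(family="spherical_heat", bandwidth=sigma, shk_tol=tol)
    return KernelMatrix(values=K, spec=spec, block_sizes=(len(u),))


def _spectral_weights(spec: KernelSpec, eigenvalues: np.ndarray) -> np.ndarray:
    lam = np.asarray(eigenvalues, dtype=np.float64)
    if spec.family == "diffusion":
        phi = np.exp(-0.5 * spec.bandwidth**2 * lam)
        phi0 = 1.0
    elif spec.family == "matern":
        nu = spec.smoothness
        base = 2.0 * nu / spec.bandwidth**2
        phi = (base + lam) ** (-nu - 1.0)
        phi0 = base ** (-nu - 1.0)
    else:
        raise ValueError("spectral_kernel supports diffusion and matern families")
    if spec.normalization == "unit_mass":
        phi = phi / phi0
    return phi


def spectral_kernel(basis: SpectralBasis, spec: KernelSpec) -> KernelMatrix:
    """Spectral kernel matrix K = F Φ(Λ) Fᵀ on one hemisphere.

    With ``unit_mass`` normalization (Φ divided by Φ(0)) the mass-weighted
    row sums equal 1 up to eigensolver tolerance: only the constant mode
    f_0 = 1/√vol survives integration against the lumped mass.
    """
    m_t = spec.truncation if spec.truncation is not None else basis.truncation
    if m_t > basis.truncation:
        raise ValueError("spec.truncation exceeds basis truncation")
    F = basis.eigenvectors[:, :m_t]
    phi = _spectral_weights(spec, basis.eigenvalues[:m_t])
    K = (F * phi[None, :]) @ F.T
    K += K.T.copy()
    K *= 0.5
    return KernelMatrix(values=K, spec=spec, block_sizes=(basis.n_vertices,))


def matern_limit_check(
    lam: float, kappa: float, nu_sequence: np.ndarray
) -> np.ndarray:
    """Deviation of normalized Matérn weights from the diffusion weight.

    Returns |Φ_ν(λ)/Φ_ν(0) − exp(−κ²λ/2)| per ν; the sequence decreases to
    0 as ν → ∞ since (1 + λκ²/2ν)^(−ν−1) → exp(−λκ²/2).
    """
    if lam < 0 or kappa <= 0:
        raise ValueError("lam must be >= 0 and kappa > 0")
    target = np.exp(-0.5 * kappa**2 * lam)
    out = []
    for nu in np.asarray(nu_sequence, dtype=np.float64):
        ratio = (1.0 + lam * kappa**2 / (2.0 * nu)) ** (-(nu + 1.0))
        out.append(abs(ratio - target))
    return np.asarray(out)


def block_kernel(left: KernelMatrix, right: KernelMatrix) -> KernelMatrix:
    """Bi-hemispheric block-diagonal kernel; cross-hemisphere entries are 0.

    Points on different hemispheres are treated as infinitely far apart,
    so no smoothing mass crosses the midline.
    """
    ls, rs = left.spec, right.spec
    if (
        ls.family != rs.family
        or ls.bandwidth != rs.bandwidth
        or ls.smoothness != rs.smoothness
        or ls.normalization != rs.normalization
    ):
        raise ValueError("left/right kernel specs must match")
    nl = left.values.shape[0]
    nr = right.values.shape[0]
    K = np.zeros((nl + nr, nl + nr))
    K[:nl, :nl] = left.values
    K[nl:, nl:] = right.values
    return KernelMatrix(values=K, spec=ls, block_sizes=(nl, nr))


def bandwidth_grid(family: str, *, spacing: str = "log") -> np.ndarray:
    """Ten-point bandwidth grid for a kernel family.

    κ runs log-spaced from 0.6252 to 18.9204 (diffusion/Matérn); σ from
    0.0001 to 0.05 for the spherical heat kernel (log-spaced by default,
    ``spacing='linear'`` available).
    """
    if family in ("diffusion", "matern"):
        lo, hi = KAPPA_MIN, KAPPA_MAX
    elif family == "spherical_heat":
        lo, hi = SIGMA_MIN, SIGMA_MAX
    else:
        raise ValueError(f"unknown family {family!r}")
    if spacing == "log":
        return np.geomspace(lo, hi, 10)
    if spacing == "linear":
        return np.linspace(lo, hi, 10)
    raise ValueError("spacing must be 'log' or 'linear'")


def save_kernel(kernel: KernelMatrix, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=kernel.values)
        fh.attrs["family"] = kernel.spec.family
        fh.attrs["bandwidth"] = kernel.spec.bandwidth
        fh.attrs["normalization"] = kernel.spec.normalization
        if kernel.spec.smoothness is not None:
            fh.attrs["smoothness"] = kernel.spec.smoothness
        fh.attrs["block_sizes"] = list(kernel.block_sizes)


def load_kernel(path: str) -> KernelMatrix:
    import h5py

    with h5py.File(path, "r") as fh:
        spec = KernelSpec(
            family=fh.attrs["family"],
            bandwidth=float(fh.attrs["bandwidth"]),
            smoothness=float(fh.attrs["smoothness"]) if "smoothness" in fh.attrs else None,
            normalization=fh.attrs["normalization"],
        )
        return KernelMatrix(
            values=fh["values"][()],
            spec=spec,
            block_sizes=tuple(int(b) for b in fh.attrs["block_sizes"]),
        )
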