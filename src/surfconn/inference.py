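"""Reduced-rank local inference on connectivity matrices.

Each subject's connectivity is compressed onto K_b mass-orthonormal basis
functions with local support, S_k = ξ_kᵀ M P M ξ_k (the projection onto
the rank-one tensor ξ_k ⊗ ξ_k, M = diag(mass)). Group differences are then
K_b univariate two-sample tests on the coefficients with multiplicity
control; the union of supports of significant basis functions localizes
where on Ω×Ω the groups differ.

The default basis partitions vertices into contiguous patches by seeded
farthest-point region growing — disjoint supports make the columns exactly
orthonormal after mass-normalization. An externally estimated basis can be
supplied instead.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from surfconn.mesh import TriangleMesh, vertex_areas
from surfconn.smoothing import ConnectivityMatrix

__all__ = [
    "LocalBasis",
    "TestResult",
    "build_patch_basis",
    "project_coefficients",
    "group_test",
    "support_region",
]


@dataclasses.dataclass(frozen=True)
class LocalBasis:
    """Mass-orthonormal basis functions with local support.

    functions: (M, K_b); supports: per-column vertex index arrays;
    mass: (M,) lumped weights.
    """

    functions: np.ndarray
    supports: tuple[np.ndarray, ...]
    mass: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.functions, dtype=np.float64)
        m = np.asarray(self.mass, dtype=np.float64)
        if F.shape[0] != m.size or F.shape[1] != len(self.supports):
            raise ValueError("functions must be (M, K_b) with one support per column")
        G = F.T @ (F * m[:, None])
        if np.abs(G - np.eye(F.shape[1])).max() > 1e-8:
            raise ValueError("basis columns must be mass-orthonormal")
        object.__setattr__(self, "functions", F)
        object.__setattr__(self, "mass", m)

    @property
    def k_b(self) -> int:
        return self.functions.shape[1]


@dataclasses.dataclass(frozen=True)
class TestResult:
    """Per-coefficient p-values and the localized difference region."""

    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray  # indices into 0..K_b-1
    region: np.ndarray  # boolean vertex mask (True = in region)
    method: str
    correction: str
    alpha: float


def build_patch_basis(mesh: TriangleMesh, k_b: int, seed: int) -> LocalBasis:
    """Partition the mesh into K_b patches; indicator columns, mass-normalized.

    Patch seeds come from farthest-point sampling started at a seeded
    random vertex; every vertex joins its nearest seed. Disjoint supports
    give exact orthonormality.
    """
    M = mesh.n_vertices
    if not (1 <= k_b <= M):
        raise ValueError("need 1 <= K_b <= M")
    m = vertex_areas(mesh)
    v = mesh.vertices
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(M))]
    d = np.linalg.norm(v - v[seeds[0]], axis=1)
    for _ in range(k_b - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(v - v[nxt], axis=1))
    seed_pts = v[np.asarray(seeds)]
    # assign to nearest seed; ties go to the earlier (lower-label) seed
    d2 = ((v[:, None, :] - seed_pts[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    if len(np.unique(labels)) != k_b:
        raise RuntimeError("empty patch in farthest-point partition; try another seed")
    F = np.zeros((M, k_b))
    supports = []
    for k in range(k_b):
        idx = np.flatnonzero(labels == k)
        supports.append(idx)
        F[idx, k] = 1.0 / np.sqrt(m[idx].sum())
    return LocalBasis(functions=F, supports=tuple(supports), mass=m)


def project_coefficients(
    P: ConnectivityMatrix | np.ndarray, basis: LocalBasis
) -> np.ndarray:
    """Coefficients S_k = ξ_kᵀ diag(m) P diag(m) ξ_k for one matrix."""
    Pv = P.values if isinstance(P, ConnectivityMatrix) else np.asarray(P)
    m = basis.mass
    if Pv.shape != (m.size, m.size):
        raise ValueError("matrix dimension must match basis")
    W = basis.functions * m[:, None]  # M ξ_k columns
    return np.einsum("ik,ij,jk->k", W, Pv, W)


def coefficient_table(
    matrices: Sequence[ConnectivityMatrix | np.ndarray], basis: LocalBasis
) -> np.ndarray:
    """Stack per-subject coefficient vectors into (n_subjects, K_b)."""
    return np.vstack([project_coefficients(P, basis) for P in matrices])


def group_test(
    s_group1: np.ndarray,
    s_group2: np.ndarray,
    basis: LocalBasis,
    *,
    method: str = "welch",
    correction: str = "bh",
    alpha: float = 0.05,
    n_permutations: int = 2000,
    seed: int = 0,
) -> TestResult:
    """Per-coefficient two-sample tests with multiplicity control.

    ``method``: 'welch' (unequal-variance t) or 'permutation' (seeded
    difference-of-means permutation test). ``correction``: 'bh'
    (Benjamini-Hochberg FDR, default), 'bonferroni', or 'none'. A
    coefficient with zero variance in both groups gets p = 1.
    """
    s1 = np.atleast_2d(np.asarray(s_group1, dtype=np.float64))
    s2 = np.atleast_2d(np.asarray(s_group2, dtype=np.float64))
    if s1.shape[1] != s2.shape[1]:
        raise ValueError("groups must share the coefficient dimension")
    if s1.shape[0] < 2 or s2.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    k_b = s1.shape[1]
    p_raw = np.ones(k_b)
    if method == "welch":
        for k in range(k_b):
            a, b = s1[:, k], s2[:, k]
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                p_raw[k] = 1.0
                continue
            p_raw[k] = scipy.stats.ttest_ind(a, b, equal_var=False).pvalue
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.vstack([s1, s2])
        n1 = s1.shape[0]
        obs = np.abs(s1.mean(axis=0) - s2.mean(axis=0))
        exceed = np.ones(k_b)  # observed statistic counts once
        for _ in range(n_permutations):
            perm = rng.permutation(pooled.shape[0])
            pa = pooled[perm[:n1]]
            pb = pooled[perm[n1:]]
            stat = np.abs(pa.mean(axis=0) - pb.mean(axis=0))
            exceed += stat >= obs - 1e-15
        p_raw = exceed / (n_permutations + 1)
    else:
        raise ValueError("method must be 'welch' or 'permutation'")
    if correction == "bh":
        _, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    elif correction == "bonferroni":
        _, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="bonferroni")
    elif correction == "none":
        p_adj = p_raw.copy()
    else:
        raise ValueError("correction must be 'bh', 'bonferroni', or 'none'")
    p_adj = np.maximum(p_adj, p_raw)
    significant = np.flatnonzero(p_adj < alpha)
    region = support_region(basis, significant)
    return TestResult(
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=significant,
        region=region,
        method=method,
        correction=correction,
        alpha=alpha,
    )


def support_region(basis: LocalBasis, significant: Sequence[int]) -> np.ndarray:
    """Union of supports of significant basis functions, as a vertex mask."""
    mask = np.zeros(basis.mass.size, dtype=bool)
    for k in significant:
        if not (0 <= int(k) < basis.k_b):
            raise ValueError("significant index out of range")
        mask[basis.supports[int(k)]] = True
    return mask
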