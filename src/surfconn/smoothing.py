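"""Continuous connectivity estimation from streamline endpoints.

The estimator is a symmetrized product-kernel KDE over endpoint pairs:

    p̂(x, y) = (1/2N) Σ_j [ k(x, s1_j) k(y, s2_j) + k(x, s2_j) k(y, s1_j) ].

On the vertex grid this collapses to three matrix products. With U, V the
M×N half-incidence matrices of snapped endpoints and A = UVᵀ + VUᵀ the
streamline-count adjacency,

    P = (1/2N) · K A Kᵀ,

which is algebraically identical to the explicit double loop but O(M³)
instead of O(M²N). Both routes are provided; the loop is the reference
oracle.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp

from surfconn.kernels import KernelMatrix, KernelSpec
from surfconn.mesh import TriangleMesh, snap_to_vertices

__all__ = [
    "EndpointSet",
    "AdjacencyMatrix",
    "ConnectivityMatrix",
    "endpoints_from_coordinates",
    "build_adjacency",
    "smooth_fast",
    "smooth_exact",
    "apply_medial_mask",
    "downsample_streamlines",
    "read_endpoints_tsv",
    "write_endpoints_tsv",
]


@dataclasses.dataclass(frozen=True)
class EndpointSet:
    """N streamline endpoint pairs as global vertex indices.

    ``coordinates`` optionally retains the raw xyz pairs (N, 2, 3) that
    were snapped at ingestion.
    """

    pairs: np.ndarray
    coordinates: Optional[np.ndarray] = None

    def __post_init__(self):
        p = np.asarray(self.pairs, dtype=np.int64)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 1:
            raise ValueError("pairs must be (N, 2) with N >= 1")
        object.__setattr__(self, "pairs", p)

    @property
    def n_streamlines(self) -> int:
        return self.pairs.shape[0]


@dataclasses.dataclass(frozen=True)
class AdjacencyMatrix:
    """Sparse symmetric streamline-count matrix A = UVᵀ + VUᵀ.

    Total sum is 2N; a streamline with both endpoints at one vertex
    contributes 2 to that diagonal entry.
    """

    values: sp.csr_matrix
    n_streamlines: int


@dataclasses.dataclass(frozen=True)
class ConnectivityMatrix:
    """Dense symmetric density estimate P on the vertex grid."""

    values: np.ndarray
    spec: Optional[KernelSpec] = None
    n_streamlines: Optional[int] = None
    masked: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        object.__setattr__(self, "values", v)


def endpoints_from_coordinates(
    xyz_pairs: np.ndarray,
    meshes: TriangleMesh | tuple[TriangleMesh, TriangleMesh],
) -> EndpointSet:
    """Snap (N, 2, 3) coordinate pairs to nearest vertices.

    With two hemisphere meshes, each endpoint snaps to the globally
    nearest vertex over the concatenated vertex set (left indices first).
    """
    xyz = np.asarray(xyz_pairs, dtype=np.float64)
    if xyz.ndim != 3 or xyz.shape[1:] != (2, 3):
        raise ValueError("xyz_pairs must be (N, 2, 3)")
    if isinstance(meshes, TriangleMesh):
        combined = meshes
    else:
        left, right = meshes
        combined = TriangleMesh(
            vertices=np.vstack([left.vertices, right.vertices]),
            faces=np.vstack([left.faces, right.faces + left.n_vertices]),
        )
    flat = xyz.reshape(-1, 3)
    idx = snap_to_vertices(flat, combined).reshape(-1, 2)
    return EndpointSet(pairs=idx, coordinates=xyz)


def build_adjacency(endpoints: EndpointSet, n_vertices: int) -> AdjacencyMatrix:
    """Streamline-count adjacency A(i, j) over the global vertex grid."""
    pairs = endpoints.pairs
    if pairs.min() < 0 or pairs.max() >= n_vertices:
        raise ValueError("endpoint vertex index out of range")
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    data = np.ones(i.size, dtype=np.int64)
    A = sp.coo_matrix((data, (i, j)), shape=(n_vertices, n_vertices)).tocsr()
    return AdjacencyMatrix(values=A, n_streamlines=endpoints.n_streamlines)


def smooth_fast(K: KernelMatrix, A: AdjacencyMatrix) -> ConnectivityMatrix:
    """P = (1/2N) · K A Kᵀ — the O(M³) estimator."""
    n = A.n_streamlines
    if n == 0:
        raise ValueError("need at least one streamline")
    Kv = K.values
    if Kv.shape[0] != A.values.shape[0]:
        raise ValueError("kernel and adjacency dimensions differ")
    P = Kv @ (A.values @ Kv.T)
    P = np.asarray(P) / (2.0 * n)
    return ConnectivityMatrix(values=P, spec=K.spec, n_streamlines=n)


def smooth_exact(
    kernel_eval: KernelMatrix | Callable[[int, int], float],
    endpoints: EndpointSet,
) -> ConnectivityMatrix:
    """Reference estimator: the explicit O(M²N) sum over streamlines.

    p̂ = (1/2N) Σ_j (k_{s1} k_{s2}ᵀ + k_{s2} k_{s1}ᵀ) with k_v the kernel
    column at vertex v. Exists to cross-check :func:`smooth_fast`.
    """
    if isinstance(kernel_eval, KernelMatrix):
        Kv = kernel_eval.values
        spec = kernel_eval.spec
    else:  # callable over vertex pairs — materialize lazily per column
        raise TypeError("smooth_exact expects a KernelMatrix on the vertex grid")
    n = endpoints.n_streamlines
    M = Kv.shape[0]
    P = np.zeros((M, M))
    for a, b in endpoints.pairs:
        ka = Kv[:, a]
        kb = Kv[:, b]
        P += np.outer(ka, kb)
        P += np.outer(kb, ka)
    P /= 2.0 * n
    return ConnectivityMatrix(values=P, spec=spec, n_streamlines=n)


def apply_medial_mask(P: ConnectivityMatrix, mask: np.ndarray) -> ConnectivityMatrix:
    """Zero rows/columns of excluded vertices (True = excluded).

    Applied post-estimation with no renormalization; idempotent.
    """
    flags = np.asarray(mask, dtype=bool)
    if flags.size != P.values.shape[0]:
        raise ValueError("mask length must match matrix dimension")
    out = P.values.copy()
    out[flags, :] = 0.0
    out[:, flags] = 0.0
    return ConnectivityMatrix(
        values=out, spec=P.spec, n_streamlines=P.n_streamlines, masked=True
    )


def downsample_streamlines(
    endpoints: EndpointSet, rate: float, seed: int
) -> EndpointSet:
    """Simple random sample (without replacement) of floor(rate·N) streamlines."""
    if not (0 < rate <= 1):
        raise ValueError("rate must lie in (0, 1]")
    n = endpoints.n_streamlines
    k = int(np.floor(rate * n))
    if k < 1:
        raise ValueError("rate too small: floor(rate*N) < 1")
    if k == n:
        return endpoints
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=k, replace=False))
    coords = None if endpoints.coordinates is None else endpoints.coordinates[keep]
    return EndpointSet(pairs=endpoints.pairs[keep], coordinates=coords)


# ---------------------------------------------------------------------------
# tabular endpoint I/O

def read_endpoints_tsv(path: str) -> np.ndarray | EndpointSet:
    """Read endpoints from TSV.

    Columns ``v1 v2`` give 0-based global vertex indices and return an
    :class:`EndpointSet`; columns ``x1 y1 z1 x2 y2 z2`` return the raw
    (N, 2, 3) coordinates for snapping by the caller.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if cols == ["v1", "v2"]:
        return EndpointSet(pairs=df.to_numpy(dtype=np.int64))
    if cols == ["x1", "y1", "z1", "x2", "y2", "z2"]:
        arr = df.to_numpy(dtype=np.float64)
        return arr.reshape(-1, 2, 3)
    raise ValueError("endpoint TSV must have columns v1 v2 or x1 y1 z1 x2 y2 z2")


def write_endpoints_tsv(endpoints: EndpointSet, path: str) -> None:
    import pandas as pd

    pd.DataFrame(endpoints.pairs, columns=["v1", "v2"]).to_csv(
        path, sep="\t", index=False
    )
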