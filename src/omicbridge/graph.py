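"""CCA co-projection, mutual-nearest-neighbor discovery and the hybrid graph.

The two modalities share harmonized features but not cells, so the
co-projection is a diagonal CCA: per-gene standardize each dataset, take the
SVD of the cells-by-cells cross-product, and use the left/right singular
vectors as canonical coordinates for source and target cells.  MNN pairs
found in that space define the source-target block of the hybrid graph; a
second MNN graph on the source alone defines the source-source block.  The
target-target block is empty by construction.  The adjacency is then
symmetrically normalized with self-loops for graph convolution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .io import FeatureMatrix

__all__ = [
    "CCAProjection",
    "ProximityParams",
    "HybridGraph",
    "cca_project",
    "proximity",
    "mnn_pairs",
    "build_hybrid_graph",
    "normalize_adjacency",
    "save_graph",
    "load_graph",
]


@dataclass
class CCAProjection:
    src_coords: np.ndarray  # [n_s, d_cca]
    tgt_coords: np.ndarray  # [n_t, d_cca]
    d_cca: int
    canonical_correlations: np.ndarray


@dataclass
class ProximityParams:
    sigma: float | None = None  # None -> median pairwise distance heuristic
    k_mnn: int = 20

    def __post_init__(self):
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k_mnn < 1:
            raise ValueError("k_mnn must be >= 1")


@dataclass
class HybridGraph:
    n_s: int
    n_t: int
    adjacency: np.ndarray  # [(n_s+n_t), (n_s+n_t)], symmetric, zero diagonal
    normalized: np.ndarray | None = field(default=None)

    @property
    def n(self) -> int:
        return self.n_s + self.n_t


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd < 1e-12] = 1.0
    return x / sd


def cca_project(src: FeatureMatrix, tgt: FeatureMatrix, d_cca: int = 20) -> CCAProjection:
    """Project both datasets into a shared space by diagonal CCA.

    Columns (features) must already be harmonized.  Each dataset is per-gene
    standardized; the SVD of ``Z_s @ Z_t.T`` gives paired canonical directions
    over cells.  Coordinates are the singular vectors scaled by the square
    root of the singular values so source and target share one scale.  The
    canonical correlation of component i is the cosine between the gene-space
    representatives ``Z_s.T u_i`` and ``Z_t.T v_i`` (1.0 when the datasets
    are copies); components are ordered so correlations are non-increasing.
    """
    if src.feature_ids != tgt.feature_ids:
        raise ValueError("features must be harmonized before CCA")
    if d_cca < 1:
        raise ValueError("d_cca must be >= 1")
    n_s, n_t, m = src.n_cells, tgt.n_cells, src.n_features
    bound = min(n_s, n_t, m)
    if d_cca > bound:
        raise ValueError(f"d_cca={d_cca} exceeds rank bound {bound}")
    zs = _standardize_columns(src.values)
    zt = _standardize_columns(tgt.values)
    u, s, vt = np.linalg.svd(zs @ zt.T, full_matrices=False)
    u, v, s = u[:, :d_cca], vt.T[:, :d_cca], s[:d_cca]

    # deterministic sign: make the largest-|.| entry of each u column positive
    for j in range(d_cca):
        i_max = np.argmax(np.abs(u[:, j]))
        if u[i_max, j] < 0:
            u[:, j] = -u[:, j]
            v[:, j] = -v[:, j]

    a = zs.T @ u  # gene-space representatives, [m, d]
    b = zt.T @ v
    denom = np.linalg.norm(a, axis=0) * np.linalg.norm(b, axis=0)
    denom[denom < 1e-300] = 1.0
    corr = np.clip((a * b).sum(axis=0) / denom, 0.0, 1.0)

    order = np.argsort(-corr, kind="stable")
    scale = np.sqrt(np.maximum(s[order], 1e-12))
    return CCAProjection(
        src_coords=u[:, order] * scale,
        tgt_coords=v[:, order] * scale,
        d_cca=d_cca,
        canonical_correlations=corr[order],
    )


def proximity(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian proximity exp(-||x-y||^2 / (2 sigma^2)), in (0, 1]."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _knn_indices(dist: np.ndarray, k: int) -> list[set[int]]:
    """Row-wise k nearest columns; ties broken toward the lower index."""
    order = np.argsort(dist, axis=1, kind="stable")
    return [set(row[:k]) for row in order]


def mnn_pairs(a_coords: np.ndarray, b_coords: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Mutual nearest neighbors between two point sets (Euclidean).

    (i, j) is a pair iff j is among the k nearest b-points of a_i and i is
    among the k nearest a-points of b_j.  k is clamped (with a warning) when
    it reaches the size of either side.
    """
    a_coords = np.atleast_2d(np.asarray(a_coords, dtype=float))
    b_coords = np.atleast_2d(np.asarray(b_coords, dtype=float))
    if a_coords.shape[1] != b_coords.shape[1]:
        raise ValueError("point sets must share dimensionality")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_a, n_b = a_coords.shape[0], b_coords.shape[0]
    if k > min(n_a, n_b):
        warnings.warn(f"k={k} clamped to {min(n_a, n_b)}")
        k = min(n_a, n_b)
    dist = cdist(a_coords, b_coords)
    a_nn = _knn_indices(dist, k)        # for each a_i: nearest b indices
    b_nn = _knn_indices(dist.T, k)      # for each b_j: nearest a indices
    return {
        (i, j) for i in range(n_a) for j in a_nn[i] if i in b_nn[j]
    }


def build_hybrid_graph(
    proj: CCAProjection,
    params: ProximityParams | None = None,
    weighted: bool = False,
) -> HybridGraph:
    """Assemble the hybrid adjacency from inter- and intra-dataset MNN pairs.

    Inter block: MNN pairs between source and target coordinates.  Intra
    block: MNN pairs of the source against itself with self-pairs removed.
    Edges are 1, or the Gaussian proximity of the endpoints when `weighted`.
    The result is symmetric with a zero diagonal and an empty target-target
    block; the symmetric normalization is attached as well.
    """
    params = params or ProximityParams()
    n_s, n_t = proj.src_coords.shape[0], proj.tgt_coords.shape[0]
    n = n_s + n_t
    coords = np.vstack([proj.src_coords, proj.tgt_coords])

    sigma = params.sigma
    if sigma is None:
        # median pairwise distance heuristic on a deterministic subsample
        sub = coords[:: max(1, n // 500)]
        d = cdist(sub, sub)
        med = float(np.median(d[np.triu_indices_from(d, k=1)])) if len(sub) > 1 else 1.0
        sigma = med if med > 0 else 1.0

    adj = np.zeros((n, n))
    inter = mnn_pairs(proj.src_coords, proj.tgt_coords, params.k_mnn)
    # intra-source MNN: each point trivially contains itself in its own
    # neighbor list, so search k+1 and drop self-pairs to keep k non-self NNs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        intra_raw = mnn_pairs(proj.src_coords, proj.src_coords,
                              min(params.k_mnn + 1, n_s))
    intra = {(i, j) for (i, j) in intra_raw if i != j}
    for i, j in inter:
        w = proximity(proj.src_coords[i], proj.tgt_coords[j], sigma) if weighted else 1.0
        adj[i, n_s + j] = adj[n_s + j, i] = w
    for i, j in intra:
        w = proximity(proj.src_coords[i], proj.src_coords[j], sigma) if weighted else 1.0
        adj[i, j] = adj[j, i] = w

    g = HybridGraph(n_s=n_s, n_t=n_t, adjacency=adj)
    return normalize_adjacency(g)


def normalize_adjacency(g: HybridGraph) -> HybridGraph:
    """Symmetric GCN normalization: A_hat = A + I, A_norm = D^-1/2 A_hat D^-1/2."""
    a_hat = g.adjacency + np.eye(g.n)
    deg = a_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    g.normalized = a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return g


def save_graph(g: HybridGraph, mtx_path, sidecar_path=None):
    """Write the adjacency as sparse MTX plus a JSON sidecar with n_s, n_t."""
    mtx_path = Path(mtx_path)
    scipy.io.mmwrite(mtx_path, sp.coo_matrix(g.adjacency))
    sidecar = Path(sidecar_path) if sidecar_path else mtx_path.with_suffix(".json")
    sidecar.write_text(json.dumps({"n_s": g.n_s, "n_t": g.n_t}))


def load_graph(mtx_path, sidecar_path=None) -> HybridGraph:
    mtx_path = Path(mtx_path)
    sidecar = Path(sidecar_path) if sidecar_path else mtx_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    adj = np.asarray(scipy.io.mmread(mtx_path).todense())
    return normalize_adjacency(
        HybridGraph(n_s=int(meta["n_s"]), n_t=int(meta["n_t"]), adjacency=adj)
    )
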