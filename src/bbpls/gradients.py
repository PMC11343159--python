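"""Connectivity gradients: cosine affinity + diffusion map embedding.

The group-mean cortical FC matrix is row-thresholded to its strongest
connections (top 10% per row), converted to a cosine-similarity affinity,
and embedded with diffusion maps: with degree matrix D, the density
normalization W' = D^{-α} A D^{-α} (α = 0.5 by default) followed by the
Markov operator P = D'^{-1} W'.  The eigenvectors of P (minus the trivial
constant one) ordered by eigenvalue are the gradients; at diffusion time
t = 0 the multi-scale convention scales component i by λ_i / (1 - λ_i).
Gradients can be aligned to a reference set by orthogonal Procrustes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .synthetic import Parcellation, edges_to_matrix

__all__ = [
    "GradientConfig",
    "GradientSet",
    "group_mean_fc",
    "row_threshold",
    "cosine_affinity",
    "diffusion_embedding",
    "procrustes_align",
]


@dataclass
class GradientConfig:
    alpha: float = 0.5
    diffusion_time: float = 0.0
    row_density: float = 0.10
    n_components: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 < self.row_density <= 1.0:
            raise ValueError("row_density must be in (0, 1]")


@dataclass
class GradientSet:
    embedding: pd.DataFrame  # parcels x n_components
    eigenvalues: np.ndarray  # descending, non-trivial
    variance_explained: np.ndarray
    alignment: np.ndarray | None = None  # orthogonal transform applied


def group_mean_fc(
    fc_edges: pd.DataFrame,
    parcellation: Parcellation,
    fisher_z: bool = False,
    cortical_only: bool = True,
) -> pd.DataFrame:
    """Element-wise mean FC matrix over participants.

    ``fc_edges`` holds vectorized lower triangles (participants x edges).
    Optionally averages Fisher-z-transformed correlations; restricted to
    cortical parcels by default.  Output is symmetric with unit diagonal.
    """
    vals = fc_edges.to_numpy(dtype=float)
    if vals.shape[1] != parcellation.n_edges:
        raise ValueError(
            f"expected {parcellation.n_edges} edges, got {vals.shape[1]}"
        )
    if fisher_z:
        mean_edges = np.tanh(np.arctanh(np.clip(vals, -0.999999, 0.999999)).mean(axis=0))
    else:
        mean_edges = vals.mean(axis=0)
    mat = edges_to_matrix(mean_edges, parcellation.n_parcels)
    ids = parcellation.parcel_ids
    if cortical_only:
        keep = parcellation.cortical_mask
        mat = mat[np.ix_(keep, keep)]
        ids = [p for p, k in zip(ids, keep) if k]
    return pd.DataFrame(mat, index=ids, columns=ids)


def row_threshold(matrix: pd.DataFrame | np.ndarray, row_density: float = 0.10) -> np.ndarray:
    """Keep, per row, the ceil(density·(n-1)) largest off-diagonal entries.

    Ties at the cutoff are all kept; the diagonal is zeroed.  The result
    is generally asymmetric — the cosine-affinity step resolves that.
    """
    A = np.asarray(matrix, dtype=float).copy()
    n = A.shape[0]
    if A.shape[1] != n:
        raise ValueError("row_threshold expects a square matrix")
    k = int(np.ceil(row_density * (n - 1)))
    if k < 1:
        raise ValueError("row_density keeps zero entries per row")
    np.fill_diagonal(A, -np.inf)
    # cutoff = k-th largest off-diagonal value per row; ties at it survive
    cut = np.sort(A, axis=1)[:, -k]
    out = np.where(A >= cut[:, None], A, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def cosine_affinity(thresholded: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of thresholded connectivity rows.

    Negative cosines are clipped to 0 (a valid Markov operator needs a
    non-negative kernel), the result symmetrized against round-off, and
    the diagonal set to 1.
    """
    A = np.asarray(thresholded, dtype=float)
    norms = np.linalg.norm(A, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"all-zero thresholded row for parcel index {bad}")
    sim = (A @ A.T) / np.outer(norms, norms)
    sim = np.clip(sim, 0.0, 1.0)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return sim


def diffusion_embedding(
    affinity: np.ndarray,
    config: GradientConfig | None = None,
    parcel_ids: list[str] | None = None,
) -> GradientSet:
    """Diffusion map embedding of a symmetric non-negative affinity.

    The diagonal is zeroed before building the Markov operator; the
    eigenproblem is solved through the symmetric conjugate
    D'^{1/2} P D'^{-1/2}, the trivial λ=1 constant eigenvector dropped,
    and components ordered by descending eigenvalue.  With
    ``diffusion_time == 0`` component i is scaled by λ_i/(1-λ_i)
    (multi-scale convention); otherwise by λ_i^t.  Variance explained is
    λ_i over the sum of retained non-trivial eigenvalues.
    """
    cfg = config or GradientConfig()
    A = np.asarray(affinity, dtype=float).copy()
    n = A.shape[0]
    if A.shape[1] != n:
        raise ValueError("affinity must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if np.any(A < 0):
        raise ValueError("affinity must be non-negative")
    np.fill_diagonal(A, 0.0)

    n_comp_graph, labels = connected_components(A > 0, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph is disconnected ({n_comp_graph} components, "
            f"sizes {sizes.tolist()})"
        )

    d = A.sum(axis=1)
    W = A / np.power(np.outer(d, d), cfg.alpha)
    dprime = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dprime)
    S = inv_sqrt[:, None] * W * inv_sqrt[None, :]  # symmetric conjugate of P
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if eigvals[0] > 1 + 1e-8:
        raise ValueError("leading eigenvalue exceeds 1: invalid Markov operator")

    # right eigenvectors of P, constant-vector normalized
    psi = eigvecs * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]  # trivial eigenvector becomes the ones vector

    lam = eigvals[1:]
    psi = psi[:, 1:]
    k = min(cfg.n_components, psi.shape[1])
    lam = lam[:k]
    psi = psi[:, :k]
    if cfg.diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**cfg.diffusion_time
    emb = psi * scale[None, :]
    # deterministic per-column sign: largest-|entry| positive
    flip = np.sign(emb[np.abs(emb).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    emb = emb * flip

    ids = parcel_ids if parcel_ids is not None else [str(i) for i in range(n)]
    lam_pos = np.clip(lam, 0.0, None)
    return GradientSet(
        embedding=pd.DataFrame(
            emb, index=ids, columns=[f"g{i + 1}" for i in range(k)]
        ),
        eigenvalues=lam,
        variance_explained=lam_pos / lam_pos.sum(),
        alignment=None,
    )


def procrustes_align(gradients: GradientSet, reference: np.ndarray) -> GradientSet:
    """Align gradients to a reference by orthogonal Procrustes (no scaling)."""
    G = gradients.embedding.to_numpy(dtype=float)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != G.shape:
        raise ValueError(
            f"reference shape {ref.shape} does not match embedding {G.shape}"
        )
    Rot, _ = orthogonal_procrustes(G, ref)
    aligned = pd.DataFrame(
        G @ Rot, index=gradients.embedding.index, columns=gradients.embedding.columns
    )
    return replace(gradients, embedding=aligned, alignment=Rot)
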