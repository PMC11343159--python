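"""Per-modality PCA with a cumulative-variance truncation rule.

Each imaging modality is reduced separately: columns are mean-centered
(not variance-scaled — the PLS step z-scores the concatenated scores),
decomposed exactly, and truncated to the smallest number of components
whose cumulative explained-variance fraction reaches the threshold
(default 50%).  The fitted model supports exact out-of-sample projection,
which the discovery/replication analysis relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCAModel", "fit_pca", "project", "concatenate_blocks"]

_EIG_TIE_RTOL = 1e-12


@dataclass
class PCAModel:
    modality: str
    feature_labels: list[str]
    column_means: np.ndarray
    coefficients: np.ndarray  # features x k, orthonormal columns
    explained_variance_fractions: np.ndarray  # length k
    variance_threshold: float

    @property
    def k(self) -> int:
        return self.coefficients.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "modality": self.modality,
            "feature_labels": self.feature_labels,
            "column_means": self.column_means.tolist(),
            "coefficients": self.coefficients.tolist(),
            "explained_variance_fractions": self.explained_variance_fractions.tolist(),
            "variance_threshold": self.variance_threshold,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            modality=d["modality"],
            feature_labels=list(d["feature_labels"]),
            column_means=np.asarray(d["column_means"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            explained_variance_fractions=np.asarray(
                d["explained_variance_fractions"], dtype=float
            ),
            variance_threshold=float(d["variance_threshold"]),
        )


def _score_columns(modality: str, k: int) -> list[str]:
    return [f"{modality}_pc{i + 1}" for i in range(k)]


def fit_pca(
    matrix: pd.DataFrame, variance_threshold: float = 0.5, modality: str = ""
) -> tuple[PCAModel, pd.DataFrame]:
    """Fit the truncated PCA of one modality.

    ``k`` is the smallest component count whose cumulative variance
    fraction reaches ``variance_threshold``; when the eigenvalue at the
    cut ties with the next one the extra component is retained.  Each
    coefficient column's sign is fixed so its largest-magnitude entry is
    positive, making fitted models reproducible.

    Returns the model and the participant scores (centered data times
    coefficients).
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 participants")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in PCA input")

    means = X.mean(axis=0)
    Xc = X - means
    # exact decomposition via SVD of the centered data
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    nz = eigvals > eigvals[0] * 1e-12 if eigvals.size and eigvals[0] > 0 else eigvals > 0
    eigvals = eigvals[nz]
    Vt = Vt[nz]
    total = eigvals.sum()
    fractions = eigvals / total
    cum = np.cumsum(fractions)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(eigvals))
    while k < len(eigvals) and np.isclose(
        eigvals[k], eigvals[k - 1], rtol=_EIG_TIE_RTOL, atol=0
    ):
        k += 1  # tie at the cut: keep the degenerate partner

    coeff = Vt[:k].T
    flip = np.sign(coeff[np.abs(coeff).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    coeff = coeff * flip

    model = PCAModel(
        modality=modality,
        feature_labels=list(matrix.columns),
        column_means=means,
        coefficients=coeff,
        explained_variance_fractions=fractions[:k],
        variance_threshold=variance_threshold,
    )
    scores = pd.DataFrame(
        Xc @ coeff, index=matrix.index, columns=_score_columns(modality, k)
    )
    return model, scores


def project(model: PCAModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Project new data through a fitted model: (X - means) @ coefficients."""
    if list(matrix.columns) != model.feature_labels:
        extra = set(matrix.columns) - set(model.feature_labels)
        missing = set(model.feature_labels) - set(matrix.columns)
        raise ValueError(
            f"feature labels do not match the model (missing={sorted(missing)[:5]}, "
            f"unexpected={sorted(extra)[:5]})"
        )
    X = matrix.to_numpy(dtype=float)
    return pd.DataFrame(
        (X - model.column_means) @ model.coefficients,
        index=matrix.index,
        columns=_score_columns(model.modality, model.k),
    )


def concatenate_blocks(
    scores: dict[str, pd.DataFrame],
    order: tuple[str, ...] = ("area", "thickness", "volume", "rest_fc"),
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Concatenate per-modality score blocks into the PLS imaging matrix.

    Returns the concatenated matrix and a map modality -> column indices
    (needed later to zero out all but one modality's weights).
    """
    blocks = [scores[m] for m in order]
    index = blocks[0].index
    for m, b in zip(order[1:], blocks[1:]):
        if not b.index.equals(index):
            raise ValueError(f"participant order of block {m!r} does not align")
    X = pd.concat(blocks, axis=1)
    block_index_map: dict[str, np.ndarray] = {}
    start = 0
    for m, b in zip(order, blocks):
        block_index_map[m] = np.arange(start, start + b.shape[1])
        start += b.shape[1]
    return X, block_index_map
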