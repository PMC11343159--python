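"""Partial least squares correlation: SVD of the item x imaging-PC
cross-covariance.

With behavior ``Y`` (participants x items) and the concatenated imaging
PC scores ``X_pca`` (participants x PCs), both z-scored column-wise, the
decomposition is

    R = Yᵀ X_pca = U S Vᵀ

Each latent component pairs a behavioral weight vector (column of U) with
an imaging weight vector (column of V); participants' composite scores
are the projections LX = X_pca V and LY = Y U, and a component's share of
covariance is its squared singular value over the sum of all squared
singular values.  Loadings — the interpretable maps — are Pearson
correlations between original (residualized) variables and the composite
scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "zscore_columns",
    "fit_pls",
    "covariance_explained",
    "compute_loadings",
    "modality_importance",
    "column_correlations",
]


def zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (mean 0, sd 1 with denominator n-1).

    Zero-variance columns are rejected: degenerate behavioral items must
    be filtered before this point.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 rows")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(matrix.columns, sd) if s == 0]
        raise ValueError(f"zero-variance columns: {bad[:5]}")
    return pd.DataFrame(
        (X - X.mean(axis=0)) / sd, index=matrix.index, columns=matrix.columns
    )


def covariance_explained(S: np.ndarray) -> np.ndarray:
    """Fractions S_l² / Σ_j S_j²."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("singular values must be non-negative")
    total = np.sum(S**2)
    if total == 0:
        raise ValueError("all singular values are zero: degenerate decomposition")
    return S**2 / total


@dataclass
class PLSModel:
    U: pd.DataFrame  # items x L behavioral weights
    V: pd.DataFrame  # pcs x L imaging weights
    S: np.ndarray  # length L, descending
    LX: pd.DataFrame  # participants x L imaging composite scores
    LY: pd.DataFrame  # participants x L behavioral composite scores
    covexp: np.ndarray
    block_index_map: dict[str, np.ndarray] | None = None
    loadings: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.S)

    def to_json_dict(self) -> dict:
        return {
            "S": self.S.tolist(),
            "covexp": self.covexp.tolist(),
            "U": self.U.to_numpy().tolist(),
            "V": self.V.to_numpy().tolist(),
            "item_labels": list(self.U.index),
            "pc_labels": list(self.V.index),
        }


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per component, flip so the column sum of U is non-negative.

    Ties (sum exactly 0) fall back to making the largest-|u| entry
    positive.  Flipping u and v jointly leaves the decomposition intact.
    """
    for l in range(U.shape[1]):
        s = U[:, l].sum()
        if s == 0:
            s = U[np.abs(U[:, l]).argmax(), l]
        if s < 0:
            U[:, l] = -U[:, l]
            V[:, l] = -V[:, l]
    return U, V


def fit_pls(
    X_pca: pd.DataFrame,
    Y: pd.DataFrame,
    block_index_map: dict[str, np.ndarray] | None = None,
) -> PLSModel:
    """Fit the PLS correlation model on z-scored blocks.

    Computes all ``L = min(n_items, n_pcs)`` components; downstream
    inference typically examines only the first few.
    """
    if not X_pca.index.equals(Y.index):
        raise ValueError("X_pca and Y participant rows are not aligned")
    Xv = X_pca.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    if not (np.all(np.isfinite(Xv)) and np.all(np.isfinite(Yv))):
        raise ValueError("non-finite entries in PLS input")

    R = Yv.T @ Xv
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    U, V = _fix_signs(U, V)

    comp_labels = [f"lc{l + 1}" for l in range(len(S))]
    LX = pd.DataFrame(Xv @ V, index=X_pca.index, columns=comp_labels)
    LY = pd.DataFrame(Yv @ U, index=Y.index, columns=comp_labels)
    return PLSModel(
        U=pd.DataFrame(U, index=Y.columns, columns=comp_labels),
        V=pd.DataFrame(V, index=X_pca.columns, columns=comp_labels),
        S=S,
        LX=LX,
        LY=LY,
        covexp=covariance_explained(S),
        block_index_map=block_index_map,
    )


def column_correlations(matrix: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r of every matrix column with every score column.

    Zero-variance columns yield NaN (the undefined-loading marker).
    """
    X = np.asarray(matrix, dtype=float)
    Z = np.asarray(scores, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Zc = Z - Z.mean(axis=0)
    xsd = Xc.std(axis=0, ddof=1)
    zsd = Zc.std(axis=0, ddof=1)
    cov = Xc.T @ Zc / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.outer(xsd, zsd)
    r[xsd == 0, :] = np.nan
    return r


def compute_loadings(
    model: PLSModel,
    original: dict[str, pd.DataFrame],
    Y_items: pd.DataFrame,
    n_components: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Loadings: Pearson r between original variables and composite scores.

    Behavioral loadings correlate item columns with LY; imaging loadings
    correlate each original residualized feature (FC at the edge level)
    with LX.  Stored on the model and returned.
    """
    L = n_components or model.n_components
    comp = list(model.LX.columns[:L])
    out: dict[str, pd.DataFrame] = {}
    ly = model.LY.iloc[:, :L]
    if not Y_items.index.equals(ly.index):
        raise ValueError("behavior rows are not aligned with composite scores")
    out["behavior"] = pd.DataFrame(
        column_correlations(Y_items.to_numpy(float), ly.to_numpy(float)),
        index=Y_items.columns,
        columns=comp,
    )
    lx = model.LX.iloc[:, :L]
    for m, mat in original.items():
        if not mat.index.equals(lx.index):
            raise ValueError(f"{m!r} rows are not aligned with composite scores")
        out[m] = pd.DataFrame(
            column_correlations(mat.to_numpy(float), lx.to_numpy(float)),
            index=mat.columns,
            columns=comp,
        )
    model.loadings = out
    return out


def modality_importance(model: PLSModel, X_pca: pd.DataFrame) -> pd.DataFrame:
    """Relative contribution of each modality to each component.

    For modality m, zero every row of V outside m's block and correlate
    the full imaging composite X_pca·V with the modality-restricted
    composite X_pca·V_m, per component.
    """
    if model.block_index_map is None:
        raise ValueError("model carries no block index map")
    Xv = X_pca.to_numpy(dtype=float)
    V = model.V.to_numpy(dtype=float)
    full = Xv @ V
    rows = {}
    for m, idx in model.block_index_map.items():
        if len(idx) == 0:
            raise ValueError(f"empty block for modality {m!r}")
        Vm = np.zeros_like(V)
        Vm[idx, :] = V[idx, :]
        part = Xv @ Vm
        r = np.array(
            [
                column_correlations(part[:, [l]], full[:, [l]])[0, 0]
                for l in range(V.shape[1])
            ]
        )
        rows[m] = r
    return pd.DataFrame(rows, index=model.LX.columns).T
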