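"""Site-constrained resampling inference for the PLS decomposition.

Multi-site cohorts carry site-level batch structure, so both nulls and
stability estimates respect site: permutations only exchange participants
within a site, and bootstrap draws resample with replacement within each
site.  Component significance uses the permutation distribution of the
first few singular values; loading stability uses bootstrap standard
deviations (FC loadings averaged into network blocks first) turned into
z-scores, normal p-values, and Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pls import PLSModel, column_correlations
from .synthetic import Parcellation

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "permute_within_sites",
    "bootstrap_within_sites",
    "permutation_test",
    "block_average_fc",
    "block_labels",
    "bootstrap_loadings",
    "fdr_bh",
]


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _site_groups(sites: np.ndarray) -> list[np.ndarray]:
    sites = np.asarray(sites)
    return [np.flatnonzero(sites == s) for s in pd.unique(sites)]


def permute_within_sites(sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A row permutation that only exchanges rows sharing a site label."""
    sites = np.asarray(sites)
    perm = np.arange(len(sites))
    for idx in _site_groups(sites):
        perm[idx] = idx[rng.permutation(len(idx))]
    return perm


def bootstrap_within_sites(sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A bootstrap index drawing each site's own count with replacement."""
    sites = np.asarray(sites)
    out = np.empty(len(sites), dtype=int)
    for idx in _site_groups(sites):
        out[idx] = idx[rng.integers(0, len(idx), size=len(idx))]
    return out


@dataclass
class PermutationResult:
    observed_S: np.ndarray
    null_S: np.ndarray  # n_perm x n_components
    p_values: np.ndarray
    fdr_mask: np.ndarray
    n_perm: int
    seed: int | None


def permutation_test(
    X_pca: pd.DataFrame,
    Y: pd.DataFrame,
    sites: np.ndarray,
    n_perm: int = 199,
    n_components: int = 5,
    rng: np.random.Generator | None = None,
    q: float = 0.05,
) -> PermutationResult:
    """Permutation significance of the first components' singular values.

    Per permutation the behavior rows are shuffled within site and the
    decomposition refitted; p_l = (1 + #{null ≥ observed}) / (1 + n_perm)
    (add-one convention, so the smallest attainable p is 1/(n_perm+1)),
    followed by BH-FDR across the tested components.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng or np.random.default_rng()
    Xv = X_pca.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    L = min(n_components, min(Yv.shape[1], Xv.shape[1]))

    observed = np.linalg.svd(Yv.T @ Xv, compute_uv=False)[:L]
    null = np.empty((n_perm, L))
    for b in range(n_perm):
        perm = permute_within_sites(sites, rng)
        null[b] = np.linalg.svd(Yv[perm].T @ Xv, compute_uv=False)[:L]
    p = (1 + (null >= observed[None, :]).sum(axis=0)) / (1 + n_perm)
    return PermutationResult(
        observed_S=observed,
        null_S=null,
        p_values=p,
        fdr_mask=fdr_bh(p, q),
        n_perm=n_perm,
        seed=None,
    )


def block_labels(n_networks: int) -> list[str]:
    """Labels of the K(K+1)/2 unordered network-pair blocks."""
    return [
        f"net{a + 1:02d}-net{b + 1:02d}"
        for a in range(n_networks)
        for b in range(a, n_networks)
    ]


def _block_membership(parcellation: Parcellation) -> tuple[list[np.ndarray], list[str]]:
    na, nb = parcellation.edge_networks()
    K = parcellation.n_networks
    labels = block_labels(K)
    members = []
    for a in range(1, K + 1):
        for b in range(a, K + 1):
            members.append(np.flatnonzero((na == a) & (nb == b)))
    return members, labels


def block_average_fc(
    edge_values: np.ndarray, parcellation: Parcellation
) -> pd.Series | pd.DataFrame:
    """Average edge values within each unordered network-pair block.

    Accepts a vector (one value per lower-triangle edge in the
    parcellation's row-major order) or a 2-D array edges x columns;
    blocks with no member edges are NaN.
    """
    members, labels = _block_membership(parcellation)
    vals = np.asarray(edge_values, dtype=float)
    squeeze = vals.ndim == 1
    if squeeze:
        vals = vals[:, None]
    if vals.shape[0] != parcellation.n_edges:
        raise ValueError(
            f"expected {parcellation.n_edges} edge values, got {vals.shape[0]}"
        )
    out = np.full((len(members), vals.shape[1]), np.nan)
    for i, m in enumerate(members):
        if len(m):
            out[i] = vals[m].mean(axis=0)
    if squeeze:
        return pd.Series(out[:, 0], index=labels)
    return pd.DataFrame(out, index=labels)


@dataclass
class BootstrapResult:
    loading_sd: dict[str, pd.DataFrame]
    z_scores: dict[str, pd.DataFrame]
    p_values: dict[str, pd.DataFrame]
    fdr_mask: dict[str, pd.DataFrame]
    n_boot: int
    seed: int | None


def _tolerant_zscore(X: np.ndarray) -> np.ndarray:
    # bootstrap draws can collapse an ordinal item to a constant; such a
    # column carries no information in the replicate and is zeroed
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd_safe
    Z[:, sd == 0] = 0.0
    return Z


def _match_components(U_rep: np.ndarray, U_orig: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy maximal-|dot| matching of replicate components to originals.

    Returns (order, signs): replicate component order[l] aligns with
    original component l after multiplying by signs[l].
    """
    L = U_orig.shape[1]
    dots = U_rep.T @ U_orig  # rep x orig
    order = np.empty(L, dtype=int)
    signs = np.empty(L)
    used = np.zeros(U_rep.shape[1], dtype=bool)
    for l in range(L):
        col = np.abs(dots[:, l]).copy()
        col[used] = -np.inf
        j = int(col.argmax())
        order[l] = j
        signs[l] = 1.0 if dots[j, l] >= 0 else -1.0
        used[j] = True
    return order, signs


def bootstrap_loadings(
    X_pca: pd.DataFrame,
    Y: pd.DataFrame,
    model: PLSModel,
    features: dict[str, pd.DataFrame],
    sites: np.ndarray,
    parcellation: Parcellation | None = None,
    fc_modalities: tuple[str, ...] = ("rest_fc",),
    n_boot: int = 200,
    n_components: int = 5,
    rng: np.random.Generator | None = None,
    q: float = 0.05,
) -> BootstrapResult:
    """Bootstrap stability of the loadings, site-constrained.

    ``features`` maps modality -> residualized original matrix (include
    ``"behavior"`` to bootstrap the item loadings against LY).  Per draw,
    rows are resampled within site, blocks re-z-scored, the decomposition
    refitted, replicate components aligned to the originals by greedy
    maximal-|dot| matching on U (guarding against order flips), and
    loadings recomputed.  FC loadings are averaged into network blocks
    before taking the bootstrap SD.  z = observed loading / SD, two-sided
    normal p, BH-FDR per component across all features of the run.
    """
    rng = rng or np.random.default_rng()
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if any(m in fc_modalities for m in features) and parcellation is None:
        raise ValueError("FC block averaging requires a parcellation")
    L = min(n_components, model.n_components)
    comp = list(model.LX.columns[:L])
    Xv = X_pca.to_numpy(float)
    Yv = Y.to_numpy(float)
    U_orig = model.U.to_numpy(float)[:, :L]

    # observed loadings on the scale actually tested (blocks for FC)
    observed: dict[str, np.ndarray] = {}
    row_labels: dict[str, list[str]] = {}
    feat_vals: dict[str, np.ndarray] = {}
    for m, mat in features.items():
        feat_vals[m] = mat.to_numpy(float)
        obs = model.loadings[m].to_numpy(float)[:, :L]
        if m in fc_modalities:
            blocked = block_average_fc(obs, parcellation)
            observed[m] = blocked.to_numpy(float)
            row_labels[m] = list(blocked.index)
        else:
            observed[m] = obs
            row_labels[m] = list(mat.columns)

    sums = {m: np.zeros_like(observed[m]) for m in features}
    sqs = {m: np.zeros_like(observed[m]) for m in features}

    for _ in range(n_boot):
        idx = bootstrap_within_sites(sites, rng)
        Xb = _tolerant_zscore(Xv[idx])
        Yb = _tolerant_zscore(Yv[idx])
        Ub, Sb, Vbt = np.linalg.svd(Yb.T @ Xb, full_matrices=False)
        Vb = Vbt.T
        order, signs = _match_components(Ub[:, : U_orig.shape[1] + 5], U_orig)
        Ub = Ub[:, order] * signs
        Vb = Vb[:, order] * signs
        LXb = Xb @ Vb
        LYb = Yb @ Ub
        for m in features:
            scores = LYb if m == "behavior" else LXb
            r = column_correlations(feat_vals[m][idx], scores)
            r = np.nan_to_num(r, nan=0.0)
            if m in fc_modalities:
                r = block_average_fc(r, parcellation).to_numpy(float)
            sums[m] += r
            sqs[m] += r * r

    loading_sd, z_scores, p_values = {}, {}, {}
    for m in features:
        var = (sqs[m] - sums[m] ** 2 / n_boot) / (n_boot - 1)
        sd = np.sqrt(np.clip(var, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = observed[m] / sd
        p = 2.0 * stats.norm.sf(np.abs(z))
        loading_sd[m] = pd.DataFrame(sd, index=row_labels[m], columns=comp)
        z_scores[m] = pd.DataFrame(z, index=row_labels[m], columns=comp)
        p_values[m] = pd.DataFrame(p, index=row_labels[m], columns=comp)

    # FDR family: per component, jointly across all features of the run
    fdr_mask = {
        m: pd.DataFrame(False, index=row_labels[m], columns=comp) for m in features
    }
    for l, c in enumerate(comp):
        ps, keys = [], []
        for m in features:
            col = p_values[m][c].to_numpy(float)
            ok = np.isfinite(col)
            ps.append(col[ok])
            keys.append((m, np.flatnonzero(ok)))
        flat = np.concatenate(ps)
        rej = fdr_bh(flat, q) if flat.size else np.zeros(0, bool)
        start = 0
        for (m, ok_idx), chunk in zip(keys, ps):
            mask = fdr_mask[m].to_numpy()
            mask[ok_idx, l] = rej[start : start + len(chunk)]
            fdr_mask[m] = pd.DataFrame(mask, index=row_labels[m], columns=comp)
            start += len(chunk)

    return BootstrapResult(
        loading_sd=loading_sd,
        z_scores=z_scores,
        p_values=p_values,
        fdr_mask=fdr_mask,
        n_boot=n_boot,
        seed=None,
    )
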