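"""Spin permutation nulls for parcel-wise map correlations.

Correlating two cortical maps inflates significance when both are
spatially autocorrelated.  The spin test preserves each map's spatial
structure by applying random 3-D rotations to the spherical parcel
centroids (the right hemisphere gets the x-mirrored rotation, keeping
the null anatomically symmetric) and reassigning each parcel the value
of its nearest rotated neighbor.  Also provides the per-parcel
within/between-network FC-loading summaries that the gradient
comparisons consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import Parcellation

__all__ = [
    "SpinNull",
    "build_spin_null",
    "spin_correlation",
    "fc_loading_parcel_profiles",
]


@dataclass
class SpinNull:
    assignments: np.ndarray  # n_spins x n_cortical, index into cortical parcels
    parcel_ids: list[str]  # cortical parcel ids, in assignment order
    n_spins: int
    seed: int | None = None


def _rotate_assign(
    centroids: np.ndarray, rotation: np.ndarray
) -> np.ndarray:
    """Nearest rotated source parcel for every target parcel."""
    rotated = centroids @ rotation.T
    sims = centroids @ rotated.T  # target x source cosine
    return sims.argmax(axis=1)


def build_spin_null(
    parcellation: Parcellation,
    n_spins: int = 1000,
    rng: np.random.Generator | None = None,
) -> SpinNull:
    """Draw spin assignments: one uniform random rotation per spin.

    The left hemisphere receives rotation R and the right its x-mirrored
    counterpart M R M; each parcel is reassigned the value of the nearest
    rotated source parcel within its hemisphere (duplicates permitted).
    """
    rng = rng or np.random.default_rng()
    cort = parcellation.cortical_mask
    hemi = parcellation.hemisphere[cort]
    cent = parcellation.centroids[cort]
    if np.any(~np.isfinite(cent)):
        raise ValueError("cortical parcels must have finite centroids")
    norms = np.linalg.norm(cent, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("cortical centroids must be unit vectors")
    left = np.flatnonzero(hemi == "left")
    right = np.flatnonzero(hemi == "right")
    mirror = np.diag([-1.0, 1.0, 1.0])

    assignments = np.empty((n_spins, cort.sum()), dtype=int)
    for s in range(n_spins):
        R = stats.special_ortho_group.rvs(3, random_state=rng)
        assignments[s, left] = left[_rotate_assign(cent[left], R)]
        if len(right):
            Rm = mirror @ R @ mirror
            assignments[s, right] = right[_rotate_assign(cent[right], Rm)]
    ids = [p for p, k in zip(parcellation.parcel_ids, cort) if k]
    return SpinNull(assignments=assignments, parcel_ids=ids, n_spins=n_spins)


def spin_correlation(
    map_a: np.ndarray, map_b: np.ndarray, null: SpinNull
) -> tuple[float, float]:
    """Pearson r of two cortical maps with a spin-permutation p-value.

    ``map_a`` is spun against the fixed ``map_b``; two-sided
    p = (1 + #{|r_null| ≥ |r_obs|}) / (1 + n_spins).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be 1-D and on the same parcels")
    if a.shape[0] != null.assignments.shape[1]:
        raise ValueError("maps do not match the spin null's parcel count")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")

    def _corr_rows(rows: np.ndarray) -> np.ndarray:
        rc = rows - rows.mean(axis=1, keepdims=True)
        bc = b - b.mean()
        denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(bc)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (rc @ bc) / denom

    # observed r goes through the same arithmetic as the nulls so that an
    # identity spin ties exactly
    r_obs = float(_corr_rows(a[None, :])[0])
    r_null = _corr_rows(a[null.assignments])
    r_null = r_null[np.isfinite(r_null)]
    p = (1 + np.sum(np.abs(r_null) >= abs(r_obs))) / (1 + null.n_spins)
    return r_obs, float(p)


def fc_loading_parcel_profiles(
    edge_loadings: np.ndarray, parcellation: Parcellation
) -> tuple[pd.Series, pd.Series]:
    """Collapse edge loadings to per-parcel within/between-network means.

    For each cortical parcel p, the within map averages loadings of edges
    joining p to parcels of its own network, the between map those to
    parcels of other networks.  A parcel whose network is a singleton has
    no within edges; its within value is NaN.
    """
    vals = np.asarray(edge_loadings, dtype=float)
    if vals.shape[0] != parcellation.n_edges:
        raise ValueError(
            f"expected {parcellation.n_edges} edge loadings, got {vals.shape[0]}"
        )
    rows, cols = parcellation.edge_index()
    net = parcellation.network
    same = net[rows] == net[cols]
    n = parcellation.n_parcels
    within_sum = np.zeros(n)
    within_cnt = np.zeros(n)
    between_sum = np.zeros(n)
    between_cnt = np.zeros(n)
    for ends in (rows, cols):
        np.add.at(within_sum, ends[same], vals[same])
        np.add.at(within_cnt, ends[same], 1)
        np.add.at(between_sum, ends[~same], vals[~same])
        np.add.at(between_cnt, ends[~same], 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        within = within_sum / within_cnt
        between = between_sum / between_cnt
    cort = parcellation.cortical_mask
    ids = [p for p, k in zip(parcellation.parcel_ids, cort) if k]
    return (
        pd.Series(within[cort], index=ids, name="within"),
        pd.Series(between[cort], index=ids, name="between"),
    )
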