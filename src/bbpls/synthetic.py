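"""Synthetic multimodal cohort with planted brain-behavior structure.

Emulates a parcellated developmental-cohort dataset: a three-level ordinal
symptom checklist (119 items), parcel-wise cortical morphometry (surface
area, thickness, volume), per-participant functional-connectivity edges on
a spherical parcellation with contiguous network caps, held-out task-FC and
tract-diffusion tables, and the covariates a multi-site study carries
(site, age, sex, ethnicity, head motion, volume normalizers).

The generative model is low-rank: latent factor scores ``F`` (participants
x n_latent) drive the behavioral items through item loadings ``B``, the
structural parcels through smooth spatial maps, and the FC edges through
rank-one edge patterns, on top of additive site/age/sex confounds and
Gaussian noise.  The planted quantities are returned as
:class:`SyntheticGroundTruth` so recovery can be verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SynthConfig",
    "Parcellation",
    "SyntheticGroundTruth",
    "SyntheticCohort",
    "generate_parcellation",
    "generate_cohort",
    "edges_to_matrix",
    "matrix_to_edges",
]

#: ordinal thresholds giving marginal level prevalences ~= (70%, 20%, 10%)
_ORDINAL_QUANTILES = (0.70, 0.90)

STRUCTURAL_MODALITIES = ("area", "thickness", "volume")
HELDOUT_TASKS = ("task_fc_mid", "task_fc_nback", "task_fc_sst")
N_TRACTS = 35


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    ``latent_strengths`` scales the latent factors before they hit the
    observed blocks; it must be non-increasing and non-negative (all zeros
    gives a signal-free null cohort).  ``confound_effect_sizes`` holds the
    additive effect scales for the site, age and sex confounds.
    """

    n_participants: int = 600
    n_sites: int = 5
    n_cortical_parcels: int = 100
    n_subcortical_parcels: int = 19
    n_networks: int = 18
    n_items: int = 119
    n_latent: int = 3
    latent_strengths: tuple[float, ...] = (4.0, 2.5, 1.6)
    confound_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"site": 0.3, "age": 0.15, "sex": 0.2}
    )
    noise_sd: float = 1.0
    fc_effect_scale: float = 0.06
    fc_noise_sd: float = 0.08
    n_constant_items: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_participants",
            "n_sites",
            "n_cortical_parcels",
            "n_subcortical_parcels",
            "n_items",
            "n_latent",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_networks < 2:
            raise ValueError("n_networks must be at least 2")
        if self.n_networks > self.n_cortical_parcels + 1:
            raise ValueError("n_networks must be <= n_cortical_parcels + 1")
        s = np.asarray(self.latent_strengths, dtype=float)
        if s.shape != (self.n_latent,):
            raise ValueError("latent_strengths length must equal n_latent")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError("latent_strengths must be finite and non-negative")
        if np.any(np.diff(s) > 0):
            raise ValueError("latent_strengths must be non-increasing")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and non-negative")
        for k, v in self.confound_effect_sizes.items():
            if not np.isfinite(v):
                raise ValueError(f"confound effect size {k!r} is not finite")
        if self.n_constant_items < 0 or self.n_constant_items >= self.n_items:
            raise ValueError("n_constant_items must be in [0, n_items)")


@dataclass
class Parcellation:
    """Parcel table: ids, hemispheres, unit spherical centroids, networks.

    Cortical parcels live on unit spheres (one per hemisphere, the right
    mirrored in x); subcortical centroids are NaN.  Network labels are
    1..n_networks, with the last network reserved for subcortex; cortical
    networks are contiguous spatial caps so that parcel-wise maps carry
    spatial autocorrelation.  ``network_axis`` stores the 1-D position of
    each cortical network along the planted organizational axis.
    """

    parcel_ids: list[str]
    hemisphere: np.ndarray  # 'left' | 'right' | 'subcortical'
    centroids: np.ndarray  # (n_parcels, 3), NaN for subcortical
    network: np.ndarray  # int, 1..n_networks
    n_networks: int
    network_axis: np.ndarray | None = None  # per-network scalar (cortical nets)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def cortical_mask(self) -> np.ndarray:
        return self.hemisphere != "subcortical"

    @property
    def n_edges(self) -> int:
        n = self.n_parcels
        return n * (n - 1) // 2

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the strict lower triangle, row-major."""
        return np.tril_indices(self.n_parcels, k=-1)

    def edge_labels(self) -> list[str]:
        rows, cols = self.edge_index()
        ids = self.parcel_ids
        return [f"{ids[j]}–{ids[i]}" for i, j in zip(rows, cols)]

    def edge_networks(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-edge (network_a, network_b) with a <= b."""
        rows, cols = self.edge_index()
        na = self.network[cols]
        nb = self.network[rows]
        return np.minimum(na, nb), np.maximum(na, nb)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_ids,
                "hemisphere": self.hemisphere,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
                "network": self.network,
            }
        ).set_index("parcel_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_networks: int | None = None) -> "Parcellation":
        net = df["network"].to_numpy(dtype=int)
        return cls(
            parcel_ids=list(df.index.astype(str)),
            hemisphere=df["hemisphere"].to_numpy(dtype=object),
            centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
            network=net,
            n_networks=int(n_networks if n_networks is not None else net.max()),
        )


@dataclass
class SyntheticGroundTruth:
    """Planted quantities enabling parameter-recovery checks."""

    item_loadings: np.ndarray  # items x n_latent, unit-norm columns
    structural_loadings: dict[str, np.ndarray]  # modality -> parcels x n_latent
    edge_loadings: np.ndarray  # edges x n_latent, unit-norm columns
    factor_scores: np.ndarray  # participants x n_latent
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "item_loadings": self.item_loadings.tolist(),
            "structural_loadings": {
                k: v.tolist() for k, v in self.structural_loadings.items()
            },
            "edge_loadings": self.edge_loadings.tolist(),
            "factor_scores": self.factor_scores.tolist(),
            "seed": self.seed,
        }


@dataclass
class SyntheticCohort:
    """Bundle returned by :func:`generate_cohort`."""

    cohort: pd.DataFrame  # participants x covariates
    behavior: pd.DataFrame  # participants x items, ordinal {0,1,2}
    modalities: dict[str, pd.DataFrame]  # primary blocks, participants x features
    heldout: dict[str, pd.DataFrame]  # task FC + tract FA/MD
    parcellation: Parcellation
    truth: SyntheticGroundTruth
    config: SynthConfig


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic even-coverage lattice of n points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_parcellation(config: SynthConfig) -> Parcellation:
    """Build the spherical parcellation with nearest-seed network caps.

    Left-hemisphere parcels come from a Fibonacci lattice on the unit
    sphere; right-hemisphere parcels mirror them in x.  The cortical
    networks (all but the last, which collects subcortex) are assigned by
    nearest network-seed direction, producing contiguous caps shared by
    homotopic parcels.  Deterministic: no random draws are involved.
    """
    n_c = config.n_cortical_parcels
    n_s = config.n_subcortical_parcels
    n_left = (n_c + 1) // 2
    n_right = n_c - n_left

    left = _fibonacci_sphere(n_left)
    right = _fibonacci_sphere(max(n_right, 1))[:n_right] * np.array([-1.0, 1.0, 1.0])
    cortical = np.vstack([left, right])

    n_cort_nets = config.n_networks - 1
    seeds = _fibonacci_sphere(n_cort_nets)
    # assign in left-hemisphere coordinates so homotopic parcels agree
    folded = cortical.copy()
    folded[n_left:] *= np.array([-1.0, 1.0, 1.0])
    sims = folded @ seeds.T
    cort_net = np.argmax(sims, axis=1)

    # order networks along a planted 1-D axis (seed z-coordinate) so that
    # the network index itself tracks the organizational axis
    order = np.argsort(-seeds[:, 2])
    rank = np.empty_like(order)
    rank[order] = np.arange(n_cort_nets)
    cort_net = rank[cort_net] + 1
    network_axis = np.sort(-seeds[:, 2]) * -1.0  # descending z, per new label

    ids = (
        [f"L{i + 1:03d}" for i in range(n_left)]
        + [f"R{i + 1:03d}" for i in range(n_right)]
        + [f"SC{i + 1:02d}" for i in range(n_s)]
    )
    hemisphere = np.array(
        ["left"] * n_left + ["right"] * n_right + ["subcortical"] * n_s, dtype=object
    )
    centroids = np.vstack([cortical, np.full((n_s, 3), np.nan)])
    network = np.concatenate([cort_net, np.full(n_s, config.n_networks, dtype=int)])

    return Parcellation(
        parcel_ids=ids,
        hemisphere=hemisphere,
        centroids=centroids,
        network=network.astype(int),
        n_networks=config.n_networks,
        network_axis=network_axis,
    )


def edges_to_matrix(edge_values: np.ndarray, n_parcels: int) -> np.ndarray:
    """Rebuild a symmetric unit-diagonal matrix from lower-triangle edges."""
    m = np.eye(n_parcels)
    rows, cols = np.tril_indices(n_parcels, k=-1)
    m[rows, cols] = edge_values
    m[cols, rows] = edge_values
    return m


def matrix_to_edges(matrix: np.ndarray) -> np.ndarray:
    rows, cols = np.tril_indices(matrix.shape[0], k=-1)
    return matrix[rows, cols]


def _smooth_maps(
    parcellation: Parcellation, n_maps: int, rng: np.random.Generator
) -> np.ndarray:
    """Spatially autocorrelated maps: kernel-smoothed white noise on the sphere.

    The kernel is computed in folded coordinates (right hemisphere mirrored
    onto the left), so maps are smooth within hemisphere and homotopically
    correlated across hemispheres — the correlation structure a
    mirrored-rotation spin null preserves.  Subcortical parcels get iid
    values.
    """
    n = parcellation.n_parcels
    out = rng.standard_normal((n, n_maps))
    cort_idx = np.flatnonzero(parcellation.cortical_mask)
    c = parcellation.centroids[cort_idx].copy()
    c[parcellation.hemisphere[cort_idx] == "right"] *= np.array([-1.0, 1.0, 1.0])
    gram = np.clip(c @ c.T, -1.0, 1.0)
    geo = np.arccos(gram)
    kernel = np.exp(-((geo / 0.5) ** 2))
    smoothed = kernel @ out[cort_idx]
    smoothed /= smoothed.std(axis=0, keepdims=True)
    out[cort_idx] = smoothed
    return out


def _unit_columns(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=0)
    norms[norms == 0] = 1.0
    return m / norms


def _parcel_axis(parcellation: Parcellation) -> np.ndarray:
    """Per-parcel position along the planted network axis (0 for subcortex)."""
    axis = np.zeros(parcellation.n_parcels)
    na = parcellation.network_axis
    if na is None:
        return axis
    cort = parcellation.cortical_mask
    axis[cort] = na[parcellation.network[cort] - 1]
    return axis


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Draw the full synthetic cohort for ``config``.

    Deterministic for a fixed seed.  See the module docstring for the
    generative model; key properties guaranteed by construction:

    - exactly ``n_constant_items`` behavioral items are constant at 0;
    - FC edge tables correspond to symmetric unit-diagonal matrices with
      entries in [-1, 1];
    - the first latent factor's FC edge pattern follows the planted
      network axis, so between-network loading maps align with the
      principal connectivity gradient.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    parcellation = generate_parcellation(cfg)
    n = cfg.n_participants
    L = cfg.n_latent
    strengths = np.asarray(cfg.latent_strengths, dtype=float)
    es = cfg.confound_effect_sizes

    pids = [f"sub{i + 1:04d}" for i in range(n)]

    # --- covariates -----------------------------------------------------
    site_idx = np.concatenate(
        [np.arange(cfg.n_sites), rng.integers(0, cfg.n_sites, size=n - cfg.n_sites)]
    )[:n]
    rng.shuffle(site_idx)
    age = rng.uniform(9.0, 11.0, size=n)
    sex = rng.integers(0, 2, size=n)
    ethnicity = rng.choice(4, size=n, p=[0.5, 0.2, 0.2, 0.1])
    mean_fd = rng.lognormal(mean=-1.8, sigma=0.5, size=n)
    mean_dvars = rng.normal(30.0, 5.0, size=n)
    icv = rng.normal(1.4e6, 1.2e5, size=n) + 4e4 * sex
    total_area = rng.normal(1.8e5, 1.5e4, size=n) + 6e3 * sex

    cohort = pd.DataFrame(
        {
            "site": [f"site{int(s) + 1:02d}" for s in site_idx],
            "age": age,
            "age2": age**2,
            "sex": sex,
            "ethnicity": [f"eth{int(e) + 1}" for e in ethnicity],
            "mean_fd": mean_fd,
            "mean_dvars": mean_dvars,
            "icv": icv,
            "total_area": total_area,
        },
        index=pd.Index(pids, name="participant_id"),
    )

    z_age = (age - age.mean()) / age.std()
    z_sex = sex - 0.5

    # --- latent factors and behavior ------------------------------------
    F = rng.standard_normal((n, L))

    B = rng.standard_normal((cfg.n_items, L))
    B[:, 0] = np.abs(B[:, 0])  # general factor: all items load positively
    B[: cfg.n_constant_items] = 0.0
    B = _unit_columns(B)

    site_item_off = rng.normal(0.0, es.get("site", 0.0), size=(cfg.n_sites, cfg.n_items))
    item_age_beta = rng.normal(0.0, es.get("age", 0.0), size=cfg.n_items)
    item_sex_beta = rng.normal(0.0, es.get("sex", 0.0), size=cfg.n_items)

    liab = (
        (F * strengths) @ B.T
        + site_item_off[site_idx]
        + np.outer(z_age, item_age_beta)
        + np.outer(z_sex, item_sex_beta)
        + cfg.noise_sd * rng.standard_normal((n, cfg.n_items))
    )
    liab = (liab - liab.mean(axis=0)) / np.where(liab.std(axis=0) == 0, 1, liab.std(axis=0))
    t1, t2 = stats.norm.ppf(_ORDINAL_QUANTILES)
    items = np.zeros_like(liab, dtype=int)
    items[liab >= t1] = 1
    items[liab >= t2] = 2
    items[:, : cfg.n_constant_items] = 0
    behavior = pd.DataFrame(
        items,
        index=cohort.index,
        columns=[f"item{i + 1:03d}" for i in range(cfg.n_items)],
    )

    # --- structural modalities ------------------------------------------
    site_parcel_off = {
        m: rng.normal(0.0, es.get("site", 0.0), size=(cfg.n_sites, parcellation.n_parcels))
        for m in STRUCTURAL_MODALITIES
    }
    z_icv = (icv - icv.mean()) / icv.std()
    z_tsa = (total_area - total_area.mean()) / total_area.std()
    norm_covar = {"area": z_tsa, "thickness": z_icv, "volume": z_icv}

    modalities: dict[str, pd.DataFrame] = {}
    structural_loadings: dict[str, np.ndarray] = {}
    for m in STRUCTURAL_MODALITIES:
        C = _unit_columns(
            _smooth_maps(parcellation, L, rng)
        )
        structural_loadings[m] = C
        age_map = _smooth_maps(parcellation, 1, rng)[
            :, 0
        ]
        X = (
            (F * strengths) @ C.T
            + site_parcel_off[m][site_idx]
            + es.get("age", 0.0) * np.outer(z_age, age_map)
            + 0.3 * np.outer(norm_covar[m], np.ones(parcellation.n_parcels))
            + cfg.noise_sd * rng.standard_normal((n, parcellation.n_parcels))
        )
        modalities[m] = pd.DataFrame(X, index=cohort.index, columns=parcellation.parcel_ids)

    # --- functional connectivity ----------------------------------------
    axis = _parcel_axis(parcellation)
    same_net = parcellation.network[:, None] == parcellation.network[None, :]
    baseline = (
        0.10
        + 0.25 * same_net
        + 0.35 * np.exp(-((axis[:, None] - axis[None, :]) ** 2) / (2 * 0.35**2))
    )
    base_edges = matrix_to_edges(baseline)

    a1 = (axis - axis.mean()) / axis.std()
    # additive node patterns: a parcel's mean edge loading then tracks its
    # own position on the pattern, so loading profiles follow the axis
    edge_pats = [matrix_to_edges(0.5 * (a1[:, None] + a1[None, :]))]
    for _ in range(1, L):
        ak = _smooth_maps(parcellation, 1, rng)[:, 0]
        ak = (ak - ak.mean()) / ak.std()
        edge_pats.append(matrix_to_edges(0.5 * (ak[:, None] + ak[None, :])))
    E = np.column_stack(edge_pats)  # edges x L
    E_scaled = E / np.abs(E).max(axis=0)

    rel = strengths / strengths[0] if strengths[0] > 0 else strengths
    edge_labels = parcellation.edge_labels()

    def _fc_block(noise_sd: float) -> pd.DataFrame:
        data = (
            base_edges[None, :]
            + cfg.fc_effect_scale * (F * rel) @ E_scaled.T
            + noise_sd * rng.standard_normal((n, parcellation.n_edges))
        )
        return pd.DataFrame(
            np.clip(data, -1.0, 1.0), index=cohort.index, columns=edge_labels
        )

    modalities["rest_fc"] = _fc_block(cfg.fc_noise_sd)

    # --- held-out blocks -------------------------------------------------
    heldout: dict[str, pd.DataFrame] = {}
    for task in HELDOUT_TASKS:
        heldout[task] = _fc_block(cfg.fc_noise_sd * 1.5)
    tract_labels = [f"tract{i + 1:02d}" for i in range(N_TRACTS)]
    for dm in ("tract_fa", "tract_md"):
        T = _unit_columns(rng.standard_normal((N_TRACTS, L)))
        X = (F * strengths) @ T.T + cfg.noise_sd * rng.standard_normal((n, N_TRACTS))
        heldout[dm] = pd.DataFrame(X, index=cohort.index, columns=tract_labels)

    truth = SyntheticGroundTruth(
        item_loadings=B,
        structural_loadings=structural_loadings,
        edge_loadings=_unit_columns(E_scaled.copy()),
        factor_scores=F,
        seed=cfg.seed,
    )
    return SyntheticCohort(
        cohort=cohort,
        behavior=behavior,
        modalities=modalities,
        heldout=heldout,
        parcellation=parcellation,
        truth=truth,
        config=cfg,
    )
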