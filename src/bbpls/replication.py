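"""Discovery/replication generalizability analysis.

The cohort is split into matched discovery and replication subsamples
(stratified on site, sex, age tertile, and an overall-psychopathology
tertile computed as the first principal component of the symptom items).
Generalizability is assessed by projecting the discovery PCA coefficients
and PLS weights directly onto replication data — no replication rows ever
inform the discovery model — and correlating the resulting loadings with
the discovery loadings.  Held-out modalities (task FC, tract diffusion
metrics) are contextualized by correlating them with the composite
scores, with site-aware bootstrap stability.  Covariate post hocs test
composite scores against age and sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import reduction
from .confounds import residualize
from .inference import fdr_bh
from .pls import PLSModel, column_correlations, zscore_columns
from .spatial import SpinNull, spin_correlation
from .synthetic import Parcellation

__all__ = [
    "SplitAssignment",
    "matched_split",
    "out_of_sample_project",
    "loading_replication",
    "contextualize_heldout",
    "covariate_associations",
]


@dataclass
class SplitAssignment:
    labels: pd.Series  # participant -> 'discovery' | 'replication'
    ratio: float
    strata: str
    seed: int | None
    balance: pd.DataFrame  # standardized mean differences of matched variables

    @property
    def discovery(self) -> pd.Index:
        return self.labels.index[self.labels == "discovery"]

    @property
    def replication(self) -> pd.Index:
        return self.labels.index[self.labels == "replication"]


def _tertile(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return np.minimum((3 * (ranks - 0.5) / len(x)).astype(int), 2)


def matched_split(
    cohort: pd.DataFrame,
    behavior: pd.DataFrame,
    ratio: float = 2 / 3,
    rng: np.random.Generator | None = None,
) -> SplitAssignment:
    """Stratified random split matched on site, sex, age, psychopathology.

    Overall psychopathology is the first principal component of the item
    table.  Strata are site x sex x age-tertile x psychopathology-tertile;
    each stratum is split at ``ratio`` (singleton strata go to discovery).
    A balance report of standardized mean differences is attached.
    """
    rng = rng or np.random.default_rng()
    if not cohort.index.equals(behavior.index):
        raise ValueError("cohort and behavior rows are not aligned")
    items = behavior.to_numpy(dtype=float)
    items = items[:, items.var(axis=0) > 0]
    _, pc = reduction.fit_pca(
        pd.DataFrame(items, index=behavior.index), variance_threshold=1e-9, modality="psy"
    )
    psy = pc.iloc[:, 0].to_numpy()

    strata_key = (
        cohort["site"].astype(str)
        + "|s"
        + cohort["sex"].astype(int).astype(str)
        + "|a"
        + pd.Series(_tertile(cohort["age"].to_numpy(float)), index=cohort.index).astype(str)
        + "|p"
        + pd.Series(_tertile(psy), index=cohort.index).astype(str)
    )
    labels = pd.Series("replication", index=cohort.index, name="split")
    for _, members in cohort.groupby(strata_key, sort=True).groups.items():
        members = pd.Index(members)
        if len(members) == 1:
            labels.loc[members] = "discovery"
            continue
        n_disc = int(round(ratio * len(members)))
        picked = rng.permutation(len(members))[:n_disc]
        labels.loc[members[picked]] = "discovery"

    disc = (labels == "discovery").to_numpy()
    rows = {}
    for name, x in (
        ("age", cohort["age"].to_numpy(float)),
        ("sex", cohort["sex"].to_numpy(float)),
        ("psychopathology", psy),
    ):
        if disc.all() or not disc.any():
            rows[name] = 0.0
            continue
        pooled = np.sqrt((x[disc].var(ddof=1) + x[~disc].var(ddof=1)) / 2)
        rows[name] = (x[disc].mean() - x[~disc].mean()) / pooled if pooled > 0 else 0.0
    balance = pd.DataFrame({"smd": rows})
    return SplitAssignment(
        labels=labels,
        ratio=ratio,
        strata="site x sex x age tertile x psychopathology tertile",
        seed=None,
        balance=balance,
    )


def out_of_sample_project(
    pca_models: dict[str, reduction.PCAModel],
    pls_model: PLSModel,
    rep_features: dict[str, pd.DataFrame],
    rep_Y: pd.DataFrame,
    order: tuple[str, ...] = ("area", "thickness", "volume", "rest_fc"),
    n_components: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Apply discovery PCA coefficients and PLS weights to replication data.

    Replication blocks are z-scored with their own means/SDs (mirroring
    within-sample residualization), projected through the discovery PCA,
    and multiplied by the discovery singular vectors.  Items present in
    only one sample are intersected (U rows subset accordingly).  Returns
    LX_rep, LY_rep and replication loadings per modality.
    """
    scores = {}
    for m in order:
        proj = reduction.project(pca_models[m], rep_features[m])
        scores[m] = proj
    X_rep, _ = reduction.concatenate_blocks(scores, order)
    X_rep = zscore_columns(X_rep)

    common = [c for c in pls_model.U.index if c in rep_Y.columns]
    U = pls_model.U.loc[common].to_numpy(float)[:, :n_components]
    Yz = zscore_columns(rep_Y[common])
    V = pls_model.V.to_numpy(float)[:, :n_components]
    comp = list(pls_model.LX.columns[:n_components])

    LX = pd.DataFrame(X_rep.to_numpy(float) @ V, index=X_rep.index, columns=comp)
    LY = pd.DataFrame(Yz.to_numpy(float) @ U, index=Yz.index, columns=comp)

    loadings: dict[str, pd.DataFrame] = {
        "behavior": pd.DataFrame(
            column_correlations(Yz.to_numpy(float), LY.to_numpy(float)),
            index=common,
            columns=comp,
        )
    }
    for m in order:
        loadings[m] = pd.DataFrame(
            column_correlations(rep_features[m].to_numpy(float), LX.to_numpy(float)),
            index=rep_features[m].columns,
            columns=comp,
        )
    return LX, LY, loadings


def loading_replication(
    disc_loadings: dict[str, pd.DataFrame],
    rep_loadings: dict[str, pd.DataFrame],
    parcellation: Parcellation | None = None,
    spin_null: SpinNull | None = None,
    fc_modalities: tuple[str, ...] = ("rest_fc",),
) -> pd.DataFrame:
    """Agreement of discovery and replication loadings, per modality x LC.

    Behavioral loadings use plain Pearson r; cortical structural maps use
    spin-corrected correlations when a spin null is supplied; FC loadings
    are compared at the network-block level with plain Pearson r.
    """
    from .inference import block_average_fc

    rows = []
    for m, d in disc_loadings.items():
        if m not in rep_loadings:
            continue
        r_ = rep_loadings[m]
        common = [i for i in d.index if i in r_.index]
        if d.shape[1] != r_.shape[1]:
            raise ValueError(f"component count mismatch for {m!r}")
        dv = d.loc[common].to_numpy(float)
        rv = r_.loc[common].to_numpy(float)
        if m in fc_modalities and parcellation is not None:
            dv = block_average_fc(dv, parcellation).to_numpy(float)
            rv = block_average_fc(rv, parcellation).to_numpy(float)
        for l, c in enumerate(d.columns):
            a, b = dv[:, l], rv[:, l]
            ok = np.isfinite(a) & np.isfinite(b)
            use_spin = (
                spin_null is not None
                and m not in fc_modalities
                and m != "behavior"
                and ok.sum() == len(spin_null.parcel_ids)
            )
            if use_spin:
                r_val, p_val = spin_correlation(a[ok], b[ok], spin_null)
                kind = "p_spin"
            else:
                r_val, p_val = stats.pearsonr(a[ok], b[ok])
                kind = "p"
            rows.append(
                {"modality": m, "component": c, "r": r_val, "p": p_val, "p_kind": kind}
            )
    return pd.DataFrame(rows)


def contextualize_heldout(
    heldout: dict[str, pd.DataFrame],
    model: PLSModel,
    cohort: pd.DataFrame,
    parcellation: Parcellation,
    design_builder=None,
    n_boot: int = 200,
    n_components: int = 5,
    rng: np.random.Generator | None = None,
    q: float = 0.05,
):
    """Correlate held-out modalities with the fitted composite scores.

    Held-out participants must overlap the fitted sample; features are
    residualized with their modality-specific confound set when a design
    builder is supplied, correlated with LX per component, task-FC
    loadings block-averaged to network blocks, and stability assessed via
    the site-constrained bootstrap machinery.
    """
    from .confounds import build_design

    builder = design_builder or build_design
    common = model.LX.index
    out = {}
    for m, mat in heldout.items():
        overlap = mat.index.intersection(common)
        if len(overlap) == 0:
            raise ValueError(f"held-out modality {m!r} has no participant overlap")
        if len(overlap) < 3:
            raise ValueError(
                f"held-out modality {m!r} overlaps only {len(overlap)} participants"
            )
        sub = mat.loc[overlap]
        design = builder(cohort.loc[overlap], m)
        resid = residualize(sub, design)
        lx = model.LX.loc[overlap].iloc[:, :n_components]
        loadings = pd.DataFrame(
            column_correlations(resid.to_numpy(float), lx.to_numpy(float)),
            index=resid.columns,
            columns=lx.columns,
        )
        is_fc = m.endswith("_fc") or m.startswith("task_fc")
        # bootstrap the held-out loadings against the fixed composite scores
        rng_local = rng or np.random.default_rng()
        sites = cohort.loc[overlap, "site"].to_numpy()
        from .inference import bootstrap_within_sites, block_average_fc

        obs = (
            block_average_fc(loadings.to_numpy(float), parcellation).to_numpy(float)
            if is_fc
            else loadings.to_numpy(float)
        )
        sums = np.zeros_like(obs)
        sqs = np.zeros_like(obs)
        rv = resid.to_numpy(float)
        lxv = lx.to_numpy(float)
        for _ in range(n_boot):
            idx = bootstrap_within_sites(sites, rng_local)
            r = np.nan_to_num(column_correlations(rv[idx], lxv[idx]), nan=0.0)
            if is_fc:
                r = block_average_fc(r, parcellation).to_numpy(float)
            sums += r
            sqs += r * r
        var = (sqs - sums**2 / n_boot) / (n_boot - 1)
        sd = np.sqrt(np.clip(var, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = obs / sd
        p = 2.0 * stats.norm.sf(np.abs(z))
        mask = np.zeros_like(p, dtype=bool)
        for l in range(p.shape[1]):
            ok = np.isfinite(p[:, l])
            mask[ok, l] = fdr_bh(p[ok, l], q)
        labels = (
            block_average_fc(loadings.to_numpy(float)[:, :1], parcellation).index
            if is_fc
            else loadings.index
        )
        out[m] = {
            "loadings": loadings,
            "z": pd.DataFrame(z, index=labels, columns=lx.columns),
            "p": pd.DataFrame(p, index=labels, columns=lx.columns),
            "fdr_mask": pd.DataFrame(mask, index=labels, columns=lx.columns),
            "n_overlap": len(overlap),
        }
    return out


def covariate_associations(
    model: PLSModel,
    cohort: pd.DataFrame,
    n_components: int = 5,
    q: float = 0.05,
) -> pd.DataFrame:
    """Post hoc tests of composite scores against sex (t) and age (r)."""
    rows = []
    comp = list(model.LX.columns[:n_components])
    sex = cohort.loc[model.LX.index, "sex"].to_numpy(float)
    two_sexes = len(np.unique(sex)) > 1
    for side, scores in (("LX", model.LX), ("LY", model.LY)):
        sv = scores.loc[:, comp].to_numpy(float)
        for l, c in enumerate(comp):
            if two_sexes:
                t, p = stats.ttest_ind(sv[sex == 0, l], sv[sex == 1, l])
                rows.append(
                    {"scores": side, "component": c, "covariate": "sex", "stat": t, "p": p}
                )
            for cov in ("age", "age2"):
                x = cohort.loc[model.LX.index, cov].to_numpy(float)
                r, p = stats.pearsonr(x, sv[:, l])
                rows.append(
                    {"scores": side, "component": c, "covariate": cov, "stat": r, "p": p}
                )
    table = pd.DataFrame(rows)
    table["fdr_reject"] = fdr_bh(table["p"].to_numpy(), q)
    return table
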