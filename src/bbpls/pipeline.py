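"""End-to-end orchestration of the brain-behavior PLS analysis.

`run_pipeline` wires the stages together on a synthetic cohort: matched
split -> item filtering -> confound residualization -> per-modality PCA
-> PLS -> site-aware permutation and bootstrap -> connectivity gradients
-> spin-corrected gradient/loading correlations -> out-of-sample
replication -> held-out contextualization -> covariate post hocs.  Every
stochastic stage derives its random stream from the master seed through
a keyed scheme (CRC32 of the stage name spawned off the master
SeedSequence), so a config reruns bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import confounds, gradients, inference, pls, reduction, replication, spatial
from .io import write_json, write_table
from .synthetic import SynthConfig, SyntheticCohort, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "prepare_sample", "fit_sample", "stage_rng"]

MODALITY_ORDER = ("area", "thickness", "volume", "rest_fc")


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one named stage, keyed off the master seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


@dataclass
class RunConfig:
    """All analysis parameters of one reproducible run.

    Full-scale values from the study design (10,000 permutations, 1,000
    bootstraps, 1,000 spins, 50% PCA variance, top-10% affinity density,
    α=0.5, t=0, q=0.05, 5 tested components, 2/3 discovery split) are the
    field defaults; smaller resampling counts may be configured for
    desk-scale runs.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    variance_threshold: float = 0.5
    n_perm: int = 10_000
    n_boot: int = 1_000
    n_spins: int = 1_000
    n_components: int = 5
    split_ratio: float = 2 / 3
    fdr_q: float = 0.05
    gradient: gradients.GradientConfig = field(default_factory=gradients.GradientConfig)
    include_heldout: bool = True
    master_seed: int = 0
    out_dir: str | None = None

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["latent_strengths"] = list(d["synth"]["latent_strengths"])
        return d


def prepare_sample(
    data: SyntheticCohort, idx: pd.Index | None = None, variance_threshold: float = 0.5
) -> dict:
    """Filter, residualize, reduce and z-score one (sub)sample.

    Returns a dict with the z-scored PLS blocks (``X``, ``Y``), the
    residualized originals, the fitted PCA models and the block index map
    — everything the decomposition and inference stages consume.
    """
    if idx is None:
        idx = data.cohort.index
    cohort = data.cohort.loc[idx]
    behavior, dropped = confounds.drop_degenerate_items(data.behavior.loc[idx])
    design_b = confounds.build_design(cohort, "behavior")
    Y_resid = confounds.residualize(behavior.astype(float), design_b)
    Y = pls.zscore_columns(Y_resid)

    resid: dict[str, pd.DataFrame] = {}
    pca_models: dict[str, reduction.PCAModel] = {}
    scores: dict[str, pd.DataFrame] = {}
    for m in MODALITY_ORDER:
        design = confounds.build_design(cohort, m)
        resid[m] = confounds.residualize(data.modalities[m].loc[idx], design)
        pca_models[m], scores[m] = reduction.fit_pca(
            resid[m], variance_threshold, modality=m
        )
    X_pca, block_map = reduction.concatenate_blocks(scores, MODALITY_ORDER)
    X = pls.zscore_columns(X_pca)
    return {
        "cohort": cohort,
        "Y": Y,
        "Y_resid": Y_resid,
        "X": X,
        "resid": resid,
        "pca_models": pca_models,
        "block_map": block_map,
        "dropped_items": dropped,
    }


def fit_sample(
    data: SyntheticCohort,
    idx: pd.Index | None = None,
    variance_threshold: float = 0.5,
    n_components: int = 5,
) -> dict:
    """Prepare one sample and fit the PLS decomposition with loadings."""
    out = prepare_sample(data, idx, variance_threshold)
    model = pls.fit_pls(out["X"], out["Y"], out["block_map"])
    out["model"] = model
    out["loadings"] = pls.compute_loadings(
        model, out["resid"], out["Y_resid"], n_components
    )
    return out


def run_pipeline(config: RunConfig, data: SyntheticCohort | None = None) -> dict:
    """Execute the full analysis; returns a result bundle (and writes
    TSV/JSON outputs when ``config.out_dir`` is set)."""
    cfg = config
    if data is None:
        data = generate_cohort(cfg.synth)
    parc = data.parcellation
    manifest: dict = {
        "config": cfg.to_json_dict(),
        "stages": [],
        "decisions": [],
    }

    # --- split -----------------------------------------------------------
    split = replication.matched_split(
        data.cohort, data.behavior, cfg.split_ratio, rng=stage_rng(cfg.master_seed, "split")
    )
    disc_idx, rep_idx = split.discovery, split.replication
    manifest["stages"].append(
        {"stage": "split", "n_discovery": len(disc_idx), "n_replication": len(rep_idx)}
    )

    # --- per-sample preparation ------------------------------------------
    disc = prepare_sample(data, disc_idx, cfg.variance_threshold)
    rep = prepare_sample(data, rep_idx, cfg.variance_threshold)
    manifest["dropped_items"] = {
        "discovery": disc["dropped_items"],
        "replication": rep["dropped_items"],
    }

    # --- PLS -------------------------------------------------------------
    model = pls.fit_pls(disc["X"], disc["Y"], disc["block_map"])
    features = dict(disc["resid"])
    loadings = pls.compute_loadings(model, features, disc["Y_resid"], cfg.n_components)
    importance = pls.modality_importance(model, disc["X"])

    # --- inference -------------------------------------------------------
    sites = disc["cohort"]["site"].to_numpy()
    perm = inference.permutation_test(
        disc["X"],
        disc["Y"],
        sites,
        n_perm=cfg.n_perm,
        n_components=cfg.n_components,
        rng=stage_rng(cfg.master_seed, "permutation"),
        q=cfg.fdr_q,
    )
    boot = inference.bootstrap_loadings(
        disc["X"],
        disc["Y"],
        model,
        {**features, "behavior": disc["Y_resid"]},
        sites,
        parcellation=parc,
        n_boot=cfg.n_boot,
        n_components=cfg.n_components,
        rng=stage_rng(cfg.master_seed, "bootstrap"),
        q=cfg.fdr_q,
    )

    # --- gradients (full sample, as in the study design) -----------------
    mean_fc = gradients.group_mean_fc(data.modalities["rest_fc"], parc)
    thresh = gradients.row_threshold(mean_fc, cfg.gradient.row_density)
    affinity = gradients.cosine_affinity(thresh)
    grad = gradients.diffusion_embedding(
        affinity, cfg.gradient, parcel_ids=list(mean_fc.index)
    )

    # --- spin-corrected gradient/loading correlations --------------------
    spin = spatial.build_spin_null(
        parc, n_spins=cfg.n_spins, rng=stage_rng(cfg.master_seed, "spin")
    )
    g1 = grad.embedding.iloc[:, 0].to_numpy()
    spin_rows = []
    for l, comp in enumerate(model.LX.columns[: cfg.n_components]):
        within, between = spatial.fc_loading_parcel_profiles(
            loadings["rest_fc"].iloc[:, l].to_numpy(), parc
        )
        for kind, prof in (("within", within), ("between", between)):
            vals = prof.to_numpy()
            ok = np.isfinite(vals)
            if ok.all():
                r, p = spatial.spin_correlation(vals, g1, spin)
            else:  # singleton-network parcels excluded upstream
                r, p = np.nan, np.nan
            spin_rows.append(
                {"component": comp, "profile": kind, "r": r, "p_spin": p}
            )
        for m in ("area", "thickness", "volume"):
            cort_ids = [p_ for p_, k in zip(parc.parcel_ids, parc.cortical_mask) if k]
            smap = loadings[m].loc[cort_ids].iloc[:, l].to_numpy()
            r, p = spatial.spin_correlation(smap, g1, spin)
            spin_rows.append({"component": comp, "profile": m, "r": r, "p_spin": p})
    spin_table = pd.DataFrame(spin_rows)
    spin_table["fdr_reject"] = inference.fdr_bh(
        spin_table["p_spin"].fillna(1.0).to_numpy(), cfg.fdr_q
    )

    # --- replication ------------------------------------------------------
    LX_rep, LY_rep, rep_loadings = replication.out_of_sample_project(
        disc["pca_models"], model, rep["resid"], rep["Y_resid"],
        order=MODALITY_ORDER, n_components=cfg.n_components,
    )
    rep_table = replication.loading_replication(
        {k: v.iloc[:, : cfg.n_components] for k, v in loadings.items()},
        rep_loadings,
        parcellation=parc,
        spin_null=spin,
    )

    # --- held-out contextualization and covariate post hocs ---------------
    heldout_results = None
    if cfg.include_heldout and data.heldout:
        heldout_results = replication.contextualize_heldout(
            {k: v.loc[disc_idx] for k, v in data.heldout.items()},
            model,
            disc["cohort"],
            parc,
            n_boot=min(cfg.n_boot, 200),
            n_components=cfg.n_components,
            rng=stage_rng(cfg.master_seed, "heldout"),
            q=cfg.fdr_q,
        )
    covar_table = replication.covariate_associations(
        model, disc["cohort"], cfg.n_components, cfg.fdr_q
    )

    results = {
        "split": split,
        "discovery": disc,
        "replication_sample": rep,
        "model": model,
        "loadings": loadings,
        "modality_importance": importance,
        "permutation": perm,
        "bootstrap": boot,
        "gradients": grad,
        "spin_table": spin_table,
        "replication_table": rep_table,
        "replication_loadings": rep_loadings,
        "heldout": heldout_results,
        "covariate_table": covar_table,
        "parcellation": parc,
        "manifest": manifest,
    }

    manifest["stages"].append(
        {
            "stage": "pls",
            "n_components_tested": int(min(cfg.n_components, model.n_components)),
            "covexp_first5": model.covexp[: cfg.n_components].tolist(),
        }
    )
    manifest["stages"].append(
        {"stage": "bootstrap", "n_fc_blocks": int(boot.z_scores["rest_fc"].shape[0])}
    )
    manifest["permutation_p"] = perm.p_values.tolist()
    manifest["hash"] = _manifest_hash(manifest)

    if cfg.out_dir is not None:
        _write_outputs(Path(cfg.out_dir), cfg, data, results)
    return results


def _manifest_hash(manifest: dict) -> str:
    # out_dir is a location, not an analysis parameter: exclude it so the
    # same config hashes identically wherever its outputs land
    hashed = {k: v for k, v in manifest.items() if k != "hash"}
    hashed["config"] = {k: v for k, v in hashed["config"].items() if k != "out_dir"}
    payload = json.dumps(hashed, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_outputs(out: Path, cfg: RunConfig, data: SyntheticCohort, results: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_table(data.cohort, out / "cohort.tsv")
    write_table(data.behavior, out / "behavior.tsv")
    write_table(data.parcellation.to_frame(), out / "parcellation.tsv")
    model: pls.PLSModel = results["model"]
    write_json(
        {
            "S": model.S[: cfg.n_components],
            "covexp": model.covexp,
            "permutation_p": results["permutation"].p_values,
            "permutation_fdr": results["permutation"].fdr_mask,
        },
        out / "pls_model.json",
    )
    for m, table in results["loadings"].items():
        write_table(table, out / f"loadings_{m}.tsv")
    for m, table in results["bootstrap"].z_scores.items():
        write_table(table, out / f"bootstrap_z_{m}.tsv")
    write_table(results["gradients"].embedding, out / "gradients.tsv")
    write_json(
        {
            "eigenvalues": results["gradients"].eigenvalues,
            "variance_explained": results["gradients"].variance_explained,
        },
        out / "gradients.json",
    )
    write_table(results["spin_table"], out / "spin_correlations.tsv")
    write_table(results["replication_table"], out / "replication.tsv")
    write_table(results["covariate_table"], out / "covariate_posthoc.tsv")
    write_table(results["split"].balance, out / "split_balance.tsv")
    write_json(results["manifest"], out / "manifest.json")
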