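"""Covariate residualization with modality-specific confound sets.

Every block entering the PLS is first residualized against a linear design
of socio-demographic and acquisition covariates: intercept, age, age²,
sex, site and ethnicity for all blocks; functional-connectivity blocks
additionally adjust for head motion (mean FD) and signal variance (mean
DVARS); thickness and volume for intracranial volume; surface area for
total surface area.  Categorical covariates are reference-coded (first
level dropped) so the design stays full rank alongside the intercept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BASE_COVARIATES",
    "modality_extra_covariates",
    "build_design",
    "residualize",
    "drop_degenerate_items",
]

BASE_COVARIATES = ("age", "age2", "sex", "site", "ethnicity")

_EXTRA = {
    "behavior": (),
    "area": ("total_area",),
    "thickness": ("icv",),
    "volume": ("icv",),
    "tract_fa": (),
    "tract_md": (),
}


def modality_extra_covariates(modality: str) -> tuple[str, ...]:
    """Extra covariates for a modality; any FC block adds FD and DVARS."""
    if modality in _EXTRA:
        return _EXTRA[modality]
    if modality.endswith("_fc") or modality.startswith("task_fc"):
        return ("mean_fd", "mean_dvars")
    raise ValueError(f"unknown modality {modality!r}")


def build_design(cohort: pd.DataFrame, modality: str) -> pd.DataFrame:
    """Assemble the full-rank design matrix for one modality.

    Parameters
    ----------
    cohort : DataFrame
        Participant covariates indexed by participant id; must contain
        the base covariates plus any modality extras.
    modality : str
        One of ``behavior``, ``area``, ``thickness``, ``volume``,
        ``tract_fa``, ``tract_md`` or an FC block name.

    Raises
    ------
    ValueError
        If a covariate is missing for some participant (the error names
        both), or the assembled design is rank deficient.
    """
    extras = modality_extra_covariates(modality)
    needed = list(BASE_COVARIATES) + list(extras)
    for cov in needed:
        if cov not in cohort.columns:
            raise ValueError(f"covariate {cov!r} absent from cohort table")
        null = cohort[cov].isna()
        if null.any():
            pid = cohort.index[null][0]
            raise ValueError(f"missing covariate {cov!r} for participant {pid!r}")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    cols["age"] = cohort["age"].to_numpy(dtype=float)
    cols["age2"] = cohort["age2"].to_numpy(dtype=float)
    cols["sex"] = cohort["sex"].to_numpy(dtype=float)
    for cat in ("site", "ethnicity"):
        levels = sorted(pd.unique(cohort[cat].astype(str)))
        for lvl in levels[1:]:  # reference-code: first level dropped
            cols[f"{cat}_{lvl}"] = (cohort[cat].astype(str) == lvl).to_numpy(float)
    for cov in extras:
        cols[cov] = cohort[cov].to_numpy(dtype=float)

    design = pd.DataFrame(cols, index=cohort.index)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"design matrix for {modality!r} is rank deficient")
    return design


def residualize(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Replace every column by its OLS residual against ``design``.

    Rows must align exactly; a rank-deficient design is rejected.  The
    returned residuals are orthogonal to every design column.
    """
    if not matrix.index.equals(design.index):
        raise ValueError("matrix and design rows are not aligned")
    D = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient design")
    Y = matrix.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    return pd.DataFrame(Y - D @ beta, index=matrix.index, columns=matrix.columns)


def drop_degenerate_items(
    behavior: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop zero-variance items (e.g. a symptom no participant endorses).

    Applied per subsample before residualization; returns the filtered
    table and the dropped item labels for the run log.
    """
    variances = behavior.to_numpy(dtype=float).var(axis=0)
    keep = variances > 0
    dropped = [c for c, k in zip(behavior.columns, keep) if not k]
    return behavior.loc[:, keep], dropped
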