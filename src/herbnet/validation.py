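"""Validation arithmetic: Livak 2^-ddCt relative expression and
binding-affinity classification.

The Livak method normalises each sample's target-gene Ct against a
reference gene measured in the same sample (dCt), then against the mean
dCt of the control group (ddCt); relative expression is 2^-ddCt.  Docking
scores (kcal/mol, more negative = tighter binding) are classified as
strong binders strictly below a cutoff, conventionally -7 kcal/mol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError


def delta_delta_ct(
    records: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample 2^-ddCt fold changes and per-group mean +/- SEM.

    Parameters
    ----------
    records
        Long table with columns ``sample_id``, ``group``, ``gene``, ``ct``.
    target_gene, reference_gene
        Gene of interest and the endogenous reference (e.g. GAPDH).
    control_group
        Group label whose mean dCt is the calibrator.

    Returns
    -------
    per_sample
        ``sample_id, group, delta_ct, delta_delta_ct, fold`` (one row per
        sample, input order of first appearance).
    summary
        ``group, n, mean_fold, sem_fold`` with SEM using the n-1 variance.
    """
    for col in ("sample_id", "group", "gene", "ct"):
        if col not in records.columns:
            raise InputError(f"Ct table is missing column {col!r}")
    if not np.isfinite(records["ct"]).all() or (records["ct"] <= 0).any():
        bad = records.loc[~np.isfinite(records["ct"]) | (records["ct"] <= 0), "sample_id"]
        raise ValidationError(f"non-positive or non-finite Ct for samples {sorted(set(bad))}")

    wide = records.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct", aggfunc="mean"
    )
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise InputError(f"gene {gene!r} not present in the Ct table")
    missing = wide.index[wide[reference_gene].isna()].get_level_values("sample_id").tolist()
    if missing:
        raise ValidationError(f"samples missing the reference gene measurement: {missing}")
    missing_t = wide.index[wide[target_gene].isna()].get_level_values("sample_id").tolist()
    if missing_t:
        raise ValidationError(f"samples missing the target gene measurement: {missing_t}")

    per_sample = wide.reset_index()[["sample_id", "group"]].copy()
    per_sample["delta_ct"] = (wide[target_gene] - wide[reference_gene]).to_numpy()
    control = per_sample.loc[per_sample["group"] == control_group, "delta_ct"]
    if control.empty:
        raise InputError(f"control group {control_group!r} has no samples")
    per_sample["delta_delta_ct"] = per_sample["delta_ct"] - control.mean()
    per_sample["fold"] = 2.0 ** (-per_sample["delta_delta_ct"])

    summary = (
        per_sample.groupby("group", sort=True)["fold"]
        .agg(n="count", mean_fold="mean", sem_fold=lambda x: x.sem(ddof=1))
        .reset_index()
    )
    summary["sem_fold"] = summary["sem_fold"].fillna(0.0)
    return per_sample, summary


def classify_binding(
    records: pd.DataFrame, strong_cutoff: float = -7.0
) -> pd.DataFrame:
    """Label each ligand-receptor docking score strong or weak.

    A score strictly below ``strong_cutoff`` kcal/mol is a strong binder;
    a score at the cutoff is weak.  Lowering a score can only move a
    record from weak to strong.
    """
    for col in ("ligand_id", "receptor_id", "score"):
        if col not in records.columns:
            raise InputError(f"affinity table is missing column {col!r}")
    if not np.isfinite(records["score"]).all():
        raise ValidationError("affinity scores must be finite")
    out = records.copy()
    out["label"] = np.where(out["score"] < strong_cutoff, "strong", "weak")
    return out
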