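"""Per-tumor minor-splicing activity and its correlation with spliceosome
component expression.

A tumor's activity is estimated from how far its intron retention sits
below the normal-tissue distribution: for intron *i* with normal-tissue
PSI mean ``mu_i`` and standard deviation ``sigma_i``, a tumor with PSI
``T_i`` contributes::

    beta_i = (mu_i - T_i) / sigma_i

and the activity score is the sum of beta_i over usable introns (tumor
PSI defined, sigma_i > 0). Positive beta means less retention than
normal, i.e. higher minor-splicing activity. A per-patient change score
sums dPSI = normal - tumor over introns observed in both tissues.

Both scores can be correlated (Spearman) with minor-spliceosome component
expression within a cohort, BH-corrected across components.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .stats import bh_fdr, spearman

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "normal_psi_stats",
    "beta_coefficient",
    "tumor_activity",
    "patient_activity_change",
    "component_activity_correlation",
    "change_correlation",
]

CORR_COLUMNS = ["cohort", "feature_id", "n", "rho", "p", "q"]


def normal_psi_stats(psi: pd.DataFrame) -> pd.DataFrame:
    """Per-intron PSI mean/sd across ALL normal samples, per cohort.

    The pool is every normal sample in the cohort with a defined PSI for
    the intron, not only those from matched pairs. The standard deviation
    uses the n-1 denominator; introns with fewer than 2 normal
    observations have no usable sigma and are excluded.
    """
    normals = psi.loc[psi["tissue"] == "normal"]
    stats = (normals.groupby(["cohort", "intron_id"])["psi"]
             .agg(mu="mean", sigma=lambda v: v.std(ddof=1), n_normals="size")
             .reset_index())
    usable = stats["n_normals"] >= 2
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("%d intron(s) dropped from normal stats (<2 normal samples)",
                    n_dropped)
    return stats.loc[usable].reset_index(drop=True)


def beta_coefficient(t_psi: float, mu: float, sigma: float) -> float:
    """Standardized deviation of a tumor PSI from the normal distribution."""
    if sigma <= 0:
        raise ValueError("beta_coefficient requires sigma > 0; degenerate "
                         "introns are excluded from activity sums")
    return (mu - t_psi) / sigma


def tumor_activity(psi: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Summed beta activity score per tumor sample.

    Sums beta_i over introns where the tumor PSI is defined and the
    normal-tissue sigma is positive; ``n_introns_used`` records how many
    introns entered each sum. Tumors with no usable intron are absent
    from the result (logged).
    """
    tumors = psi.loc[psi["tissue"] == "tumor"]
    usable_stats = stats.loc[stats["sigma"] > 0]
    n_sigma0 = len(stats) - len(usable_stats)
    if n_sigma0:
        logger.info("%d intron(s) excluded from activity (sigma = 0)", n_sigma0)
    merged = tumors.merge(usable_stats, on=["cohort", "intron_id"], how="inner")
    if merged.empty:
        logger.warning("no tumor sample has a usable intron for activity scoring")
        return pd.DataFrame(columns=["cohort", "sample_id", "sum_beta",
                                     "n_introns_used"])
    merged["beta"] = (merged["mu"] - merged["psi"]) / merged["sigma"]
    out = (merged.groupby(["cohort", "sample_id"])
           .agg(sum_beta=("beta", "sum"), n_introns_used=("beta", "size"))
           .reset_index())
    n_all_tumors = tumors[["cohort", "sample_id"]].drop_duplicates().shape[0]
    if len(out) < n_all_tumors:
        logger.info("%d tumor sample(s) had no usable intron and carry no score",
                    n_all_tumors - len(out))
    return out.sort_values(["cohort", "sample_id"]).reset_index(drop=True)


def patient_activity_change(paired: pd.DataFrame) -> pd.DataFrame:
    """Summed dPSI (normal - tumor) per patient over shared introns."""
    if paired.empty:
        return pd.DataFrame(columns=["cohort", "patient_id", "sum_dpsi",
                                     "n_introns_used"])
    out = (paired.groupby(["cohort", "patient_id"])
           .agg(sum_dpsi=("dpsi", "sum"), n_introns_used=("dpsi", "size"))
           .reset_index())
    return out.sort_values(["cohort", "patient_id"]).reset_index(drop=True)


def _correlate_features(
    values: pd.Series, feature_table: pd.DataFrame, cohort: str, min_n: int = 3
) -> pd.DataFrame:
    """Spearman of ``values`` (indexed by sample/patient) against each row
    of ``feature_table`` (features x same index), BH across features."""
    rows = []
    for feature, expr in feature_table.iterrows():
        joined = pd.concat([values, expr], axis=1, join="inner").dropna()
        if len(joined) < min_n:
            logger.info("cohort %s: feature %s measured in %d < %d units, skipped",
                        cohort, feature, len(joined), min_n)
            continue
        rho, p = spearman(joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy())
        if math.isnan(rho):
            logger.info("cohort %s: feature %s has zero variance, absent", cohort,
                        feature)
            continue
        rows.append((cohort, feature, len(joined), rho, p))
    out = pd.DataFrame(rows, columns=["cohort", "feature_id", "n", "rho", "p"])
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        return out[CORR_COLUMNS]
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[CORR_COLUMNS]


def component_activity_correlation(
    activity: pd.DataFrame,
    normalized: pd.DataFrame,
    components: list[str],
    cohort: str,
) -> pd.DataFrame:
    """Spearman of per-tumor sum_beta vs component expression, one cohort.

    ``normalized`` is the genes x samples normalized count table; only
    tumor samples holding an activity score enter. BH across components.
    """
    act = activity.loc[activity["cohort"] == cohort]
    values = act.set_index("sample_id")["sum_beta"]
    present = [g for g in components if g in normalized.index]
    shared = [s for s in values.index if s in normalized.columns]
    expr = normalized.loc[present, shared]
    return _correlate_features(values.loc[shared], expr, cohort)


def change_correlation(
    changes: pd.DataFrame,
    component_log2fc: pd.DataFrame,
    components: list[str],
    cohort: str,
) -> pd.DataFrame:
    """Spearman of per-patient summed dPSI vs component log2 fold change.

    ``component_log2fc`` is genes x patients (from
    :func:`minorsplice.expression.paired_log2fc`).
    """
    chg = changes.loc[changes["cohort"] == cohort]
    values = chg.set_index("patient_id")["sum_dpsi"]
    present = [g for g in components if g in component_log2fc.index]
    shared = [p for p in values.index if p in component_log2fc.columns]
    lfc = component_log2fc.loc[present, shared]
    return _correlate_features(values.loc[shared], lfc, cohort)
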