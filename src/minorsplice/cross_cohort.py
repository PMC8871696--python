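"""Cross-cohort screen: which genes' expression changes track the
minor-splicing score?

Each cohort contributes one minor-splicing score and, per gene, one mean
log2 fold change (tumor/normal). For every gene observed in at least
three cohorts, the score vector is Spearman-correlated with the gene's
fold-change vector across cohorts; BH FDR runs across all genes tested.
Being rank-based, the result is invariant to any order-preserving
transform of the scores.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from .stats import bh_fdr, spearman

logger = logging.getLogger(__name__)

__all__ = ["score_expression_correlation"]

RESULT_COLUMNS = ["gene_id", "n_cohorts", "rho", "p", "q"]


def score_expression_correlation(
    scores: pd.Series, mean_log2fc: pd.DataFrame, min_cohorts: int = 3
) -> pd.DataFrame:
    """Correlate per-cohort scores with per-cohort gene fold changes.

    Parameters
    ----------
    scores
        Minor-splicing score per cohort (index: cohort).
    mean_log2fc
        Genes x cohorts table of per-cohort mean log2 fold changes; NaN
        marks a gene untested in that cohort.
    min_cohorts
        Minimum cohorts with both quantities for a gene to be tested.

    Returns
    -------
    DataFrame ``gene_id, n_cohorts, rho, p, q`` sorted by q then gene_id.
    Genes with too few cohorts or zero variance are absent (counted in
    the log).
    """
    shared = [c for c in mean_log2fc.columns if c in scores.index]
    if len(shared) < min_cohorts:
        logger.warning("only %d cohort(s) have scores; need %d", len(shared),
                       min_cohorts)
        return pd.DataFrame(columns=RESULT_COLUMNS)
    lfc = mean_log2fc[shared]
    score_vec = scores.loc[shared]
    rows, n_skipped = [], 0
    for gene, vals in lfc.iterrows():
        mask = vals.notna()
        if int(mask.sum()) < min_cohorts:
            n_skipped += 1
            continue
        rho, p = spearman(score_vec.loc[mask.index[mask]].to_numpy(),
                          vals.loc[mask].to_numpy())
        if math.isnan(rho):
            n_skipped += 1
            continue
        rows.append((gene, int(mask.sum()), rho, p))
    if n_skipped:
        logger.info("%d gene(s) skipped (too few cohorts or zero variance)",
                    n_skipped)
    out = pd.DataFrame(rows, columns=["gene_id", "n_cohorts", "rho", "p"])
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        return out[RESULT_COLUMNS]
    out["q"] = bh_fdr(out["p"].to_numpy())
    return (out[RESULT_COLUMNS]
            .sort_values(["q", "gene_id"], kind="mergesort")
            .reset_index(drop=True))
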