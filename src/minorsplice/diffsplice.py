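"""Per-intron differential splicing tests and cohort-level summaries.

Within each cohort, every testable minor intron (>= 3 complete
tumor/normal pairs) gets a paired Wilcoxon signed-rank test on its dPSI
values, with Benjamini-Hochberg FDR across the cohort's introns. Direction
follows the dPSI = normal - tumor sign convention: positive mean dPSI at
q < alpha means the intron is spliced *more* in the tumor (``up_in_tumor``).

Cohorts are then summarized by the minor-splicing score::

    score = n_up - n_down

(the number of introns with significantly increased splicing in tumors
minus the number significantly decreased), and a two-sided exact binomial
test asks whether significant introns skew to one direction, with BH
correction across the cohorts of the run.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import bh_fdr, paired_wilcoxon, spearman  # noqa: F401  (shared engines)

logger = logging.getLogger(__name__)

__all__ = [
    "paired_wilcoxon",
    "bh_fdr",
    "test_cohort_introns",
    "binomial_skew_test",
    "summarize_cohorts",
]

TEST_COLUMNS = ["cohort", "intron_id", "n_pairs", "mean_dpsi", "statistic",
                "p", "q", "direction"]
SUMMARY_COLUMNS = ["cohort", "n_up", "n_down", "n_ns", "score",
                   "skew_p", "skew_q", "skew_class"]


def test_cohort_introns(
    paired: pd.DataFrame, alpha: float = 0.05, min_pairs: int = 3
) -> pd.DataFrame:
    """Paired Wilcoxon tests for one cohort's introns, FDR within cohort.

    ``paired`` is the paired-PSI table restricted to a single cohort.
    Introns with fewer than ``min_pairs`` pairs are excluded (defensive
    re-application of the testability filter).
    """
    cohorts = paired["cohort"].unique()
    if len(cohorts) > 1:
        raise ValueError("test_cohort_introns expects a single cohort at a time")
    if paired.empty:
        logger.warning("no testable introns in cohort")
        return pd.DataFrame(columns=TEST_COLUMNS)
    cohort = cohorts[0]
    rows = []
    for intron, grp in paired.groupby("intron_id", sort=True):
        d = grp["dpsi"].to_numpy()
        if d.size < min_pairs:
            continue
        stat, p = paired_wilcoxon(d)
        rows.append((cohort, intron, int(d.size), float(d.mean()), stat, p))
    if not rows:
        logger.warning("cohort %s: no introns pass the %d-pair filter",
                       cohort, min_pairs)
        return pd.DataFrame(columns=TEST_COLUMNS)
    out = pd.DataFrame(rows, columns=["cohort", "intron_id", "n_pairs",
                                      "mean_dpsi", "statistic", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    sig = out["q"] < alpha
    out["direction"] = "ns"
    out.loc[sig & (out["mean_dpsi"] > 0), "direction"] = "up_in_tumor"
    out.loc[sig & (out["mean_dpsi"] < 0), "direction"] = "down_in_tumor"
    return out[TEST_COLUMNS].reset_index(drop=True)


def binomial_skew_test(n_up: int, n_down: int) -> float:
    """Exact two-sided binomial test of direction skew at success prob 0.5.

    Uses the minimum-likelihood two-sided definition, which for p = 0.5
    equals twice the smaller tail probability capped at 1.
    """
    n = n_up + n_down
    if n < 1:
        raise ValueError("binomial_skew_test needs at least one directional intron")
    return float(_sps.binomtest(n_up, n, 0.5, alternative="two-sided").pvalue)


def summarize_cohorts(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Cohort summaries: direction counts, minor-splicing score, skew tests.

    The skew q-values are BH-adjusted across all cohorts in ``results``
    that have at least one directional intron; cohorts with none carry
    ``skew_class = "none"`` and no test.
    """
    rows = []
    for cohort, grp in results.groupby("cohort", sort=True):
        n_up = int((grp["direction"] == "up_in_tumor").sum())
        n_down = int((grp["direction"] == "down_in_tumor").sum())
        n_ns = int((grp["direction"] == "ns").sum())
        p = binomial_skew_test(n_up, n_down) if n_up + n_down >= 1 else np.nan
        rows.append((cohort, n_up, n_down, n_ns, n_up - n_down, p))
    out = pd.DataFrame(rows, columns=["cohort", "n_up", "n_down", "n_ns",
                                      "score", "skew_p"])
    out["skew_q"] = np.nan
    tested = out["skew_p"].notna()
    if tested.any():
        out.loc[tested, "skew_q"] = bh_fdr(out.loc[tested, "skew_p"].to_numpy())
    out["skew_class"] = "none"
    sig = tested & (out["skew_q"] < alpha)
    out.loc[sig & (out["n_up"] > out["n_down"]), "skew_class"] = "increased"
    out.loc[sig & (out["n_down"] > out["n_up"]), "skew_class"] = "decreased"
    return out[SUMMARY_COLUMNS].reset_index(drop=True)
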