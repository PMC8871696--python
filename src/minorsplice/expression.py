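"""Gene-expression normalization, paired differential expression, and the
minor-intron-containing-gene (MIG) enrichment test.

Raw counts are scaled by median-of-ratios size factors (the classical
RNA-seq library normalization: per-gene geometric-mean reference over
samples, per-sample median of count/reference ratios). Differential
expression between matched tumor and normal samples uses the same paired
Wilcoxon engine as the splicing tests, with BH FDR within each gene set
per cohort. Enrichment asks whether MIGs are up-regulated more often than
protein-coding genes at large, with a one-sided exact binomial test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import bh_fdr, paired_wilcoxon

logger = logging.getLogger(__name__)

__all__ = [
    "median_of_ratios",
    "normalize_counts",
    "paired_log2fc",
    "test_gene_set_de",
    "mig_enrichment",
    "cohort_mig_enrichment",
]

DE_COLUMNS = ["cohort", "gene_id", "gene_set", "n_pairs", "mean_log2fc",
              "statistic", "p", "q", "direction"]


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors for a genes x samples count table.

    The reference is the per-gene geometric mean across samples, using
    only genes with strictly positive counts in every sample; each
    sample's factor is the median of its count/reference ratios over
    those genes.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; size factors are "
            "undefined — check that samples were filtered to one cohort and "
            "that the count table is raw (not already normalized)")
    sub = mat[all_positive]
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    missing = set(counts.columns) - set(size_factors.index)
    if missing:
        raise ValueError(f"no size factor for samples {sorted(missing)[:5]}")
    return counts / size_factors.loc[counts.columns]


def paired_log2fc(
    normalized: pd.DataFrame, pairs: pd.DataFrame, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-patient and mean log2 fold changes (tumor/normal) per gene.

    Per patient: ``log2((tumor + c) / (normal + c))`` on normalized
    counts, with pseudocount ``c`` guarding zeros.

    Returns
    -------
    (per_patient, mean)
        ``per_patient`` is genes x patients; ``mean`` is the per-gene
        average over patients.
    """
    tumor = normalized[pairs["tumor_sample"].tolist()].to_numpy()
    normal = normalized[pairs["normal_sample"].tolist()].to_numpy()
    lfc = np.log2(tumor + pseudocount) - np.log2(normal + pseudocount)
    per_patient = pd.DataFrame(lfc, index=normalized.index,
                               columns=pairs["patient_id"].tolist())
    return per_patient, per_patient.mean(axis=1).rename("mean_log2fc")


def test_gene_set_de(
    normalized: pd.DataFrame,
    pairs: pd.DataFrame,
    gene_set: list[str],
    set_label: str,
    cohort: str,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Paired Wilcoxon differential expression for one gene set, one cohort.

    Tests tumor-minus-normal differences of normalized counts per gene,
    BH-adjusted within the gene set. Genes absent from the table are
    skipped with a log entry.
    """
    present = [g for g in gene_set if g in normalized.index]
    n_missing = len(gene_set) - len(present)
    if n_missing:
        logger.info("cohort %s set %s: %d gene(s) absent from count table",
                    cohort, set_label, n_missing)
    if not present:
        return pd.DataFrame(columns=DE_COLUMNS)
    tumor = normalized.loc[present, pairs["tumor_sample"].tolist()].to_numpy()
    normal = normalized.loc[present, pairs["normal_sample"].tolist()].to_numpy()
    diffs = tumor - normal
    lfc = np.log2(tumor + pseudocount) - np.log2(normal + pseudocount)
    rows = []
    for i, gene in enumerate(present):
        stat, p = paired_wilcoxon(diffs[i])
        rows.append((cohort, gene, set_label, diffs.shape[1],
                     float(lfc[i].mean()), stat, p))
    out = pd.DataFrame(rows, columns=["cohort", "gene_id", "gene_set", "n_pairs",
                                      "mean_log2fc", "statistic", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    sig = out["q"] < alpha
    out["direction"] = "ns"
    out.loc[sig & (out["mean_log2fc"] > 0), "direction"] = "up"
    out.loc[sig & (out["mean_log2fc"] < 0), "direction"] = "down"
    return out[DE_COLUMNS]


def mig_enrichment(
    n_mig_up: int, n_mig_tested: int, background_prop: float
) -> float:
    """One-sided exact binomial p for MIG up-regulation enrichment.

    ``p = P(X >= n_mig_up)`` for ``X ~ Binomial(n_mig_tested,
    background_prop)``, the background proportion coming from
    protein-coding genes in the same cohort.
    """
    if n_mig_tested <= 0:
        raise ValueError("n_mig_tested must be positive")
    if not 0.0 <= background_prop <= 1.0:
        raise ValueError("background_prop must lie in [0, 1]")
    if n_mig_up > n_mig_tested:
        raise ValueError("n_mig_up cannot exceed n_mig_tested")
    p = float(_sps.binomtest(n_mig_up, n_mig_tested, background_prop,
                             alternative="greater").pvalue)
    # a degenerate background of exactly 0 can yield p = 0; keep p in (0, 1]
    return min(max(p, float(np.finfo(float).tiny)), 1.0)


def cohort_mig_enrichment(
    mig_de: pd.DataFrame,
    pc_de: pd.DataFrame,
    cohort: str,
    contrast: str = "vs_tested",
) -> dict:
    """Assemble one cohort's MIG-enrichment test from its DE tables.

    ``contrast`` selects the success definition: ``"vs_tested"`` compares
    up-regulated fractions among all tested genes; ``"among_significant"``
    compares up/(up+down) among significant genes only.
    """
    if contrast == "vs_tested":
        n_mig_tested = len(mig_de)
        n_mig_up = int((mig_de["direction"] == "up").sum())
        n_pc = len(pc_de)
        n_pc_up = int((pc_de["direction"] == "up").sum())
    elif contrast == "among_significant":
        mig_sig = mig_de.loc[mig_de["direction"] != "ns"]
        pc_sig = pc_de.loc[pc_de["direction"] != "ns"]
        n_mig_tested = len(mig_sig)
        n_mig_up = int((mig_sig["direction"] == "up").sum())
        n_pc = len(pc_sig)
        n_pc_up = int((pc_sig["direction"] == "up").sum())
    else:
        raise ValueError(f"unknown enrichment contrast {contrast!r}")
    if n_mig_tested == 0 or n_pc == 0:
        raise ValueError(f"cohort {cohort}: empty contrast for MIG enrichment")
    background = n_pc_up / n_pc
    p = mig_enrichment(n_mig_up, n_mig_tested, background)
    return {"cohort": cohort, "n_mig_tested": n_mig_tested, "n_mig_up": n_mig_up,
            "background_prop": background, "p": p}
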