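"""Percent-spliced-in (PSI) quantification for intron retention.

For an intron of length ``L`` in one sample, with ``a`` alignments inside
the intron and ``j`` spliced alignments spanning it::

    cov_int = a / L                      (mean per-base intron coverage)
    PSI     = 100 * cov_int / (cov_int + j)

High PSI means high retention, i.e. low splicing of the intron. A sample
contributes a PSI for an intron only when it has at least one informative
read (``a + j >= 1``); otherwise the value is absent, not zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "compute_psi",
    "psi_table",
    "build_paired_psi",
    "filter_testable_introns",
]

PSI_COLUMNS = ["cohort", "intron_id", "sample_id", "patient_id", "tissue",
               "cov_int", "cov_ej", "psi"]
PAIRED_COLUMNS = ["cohort", "intron_id", "patient_id", "psi_normal",
                  "psi_tumor", "dpsi"]


def compute_psi(
    intron_alignment_count: float, intron_length: int, junction_count: int
) -> float | None:
    """PSI for a single (intron, sample) observation, or None if unobserved.

    Returns None when the sample has no informative read for this intron
    (neither retained nor spliced), which the read filter treats as an
    absent observation rather than PSI 0.
    """
    if intron_length <= 0:
        raise ValueError(f"intron length must be positive, got {intron_length}")
    if intron_alignment_count < 0 or junction_count < 0:
        raise ValueError("counts must be non-negative")
    if intron_alignment_count + junction_count < 1:
        return None
    cov_int = intron_alignment_count / intron_length
    return 100.0 * cov_int / (cov_int + junction_count)


def psi_table(
    coverage: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    event_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample PSI for every observed minor intron.

    Parameters
    ----------
    coverage
        Long coverage table (intron_id/sample_id/counts). ``intron_id`` may
        hold raw event ids if ``event_map`` is given.
    annotation
        Intron annotation; only minor introns are quantified, and intron
        lengths come from here.
    samples
        Sample sheet (sample_id/patient_id/tissue/cohort); coverage for
        samples not on the sheet is ignored.
    event_map
        Optional event_id -> intron_id mapping from
        :func:`minorsplice.io.match_events_to_minor_introns`. Events
        without a mapping are dropped (counted in the log).

    Returns
    -------
    DataFrame with columns ``cohort, intron_id, sample_id, patient_id,
    tissue, cov_int, cov_ej, psi``. Observations failing the >=1-read
    filter are absent.
    """
    cov = coverage.copy()
    if event_map is not None:
        mapped = cov["intron_id"].map(event_map)
        n_dropped = int(mapped.isna().sum())
        if n_dropped:
            logger.info("dropping %d coverage rows from unmatched events", n_dropped)
        cov = cov.loc[mapped.notna()].copy()
        cov["intron_id"] = mapped.loc[mapped.notna()]
    minor = annotation.loc[annotation["is_minor"], ["intron_id", "length"]]
    if (minor["length"] <= 0).any():
        raise ValueError("annotation contains non-positive intron lengths")
    cov = cov.merge(minor, on="intron_id", how="inner")
    cov = cov.merge(samples, on="sample_id", how="inner")
    informative = (cov["intron_alignment_count"] + cov["junction_count"]) >= 1
    n_filtered = int((~informative).sum())
    if n_filtered:
        logger.info("%d (intron, sample) observations below the 1-read filter",
                    n_filtered)
    cov = cov.loc[informative].copy()
    cov["cov_int"] = cov["intron_alignment_count"] / cov["length"]
    cov["cov_ej"] = cov["junction_count"]
    cov["psi"] = 100.0 * cov["cov_int"] / (cov["cov_int"] + cov["cov_ej"])
    return (cov[PSI_COLUMNS]
            .sort_values(["cohort", "intron_id", "sample_id"])
            .reset_index(drop=True))


def build_paired_psi(psi: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Join tumor and normal PSI per (intron, patient); dpsi = normal - tumor.

    A pair contributes only for introns where both its samples have a
    defined PSI. Positive dpsi means the intron is spliced more
    efficiently in the tumor (lower tumor retention).
    """
    slim = psi[["intron_id", "sample_id", "psi"]]
    tumor = pairs.merge(slim, left_on="tumor_sample", right_on="sample_id")
    tumor = tumor.rename(columns={"psi": "psi_tumor"})[
        ["cohort", "patient_id", "intron_id", "psi_tumor"]]
    normal = pairs.merge(slim, left_on="normal_sample", right_on="sample_id")
    normal = normal.rename(columns={"psi": "psi_normal"})[
        ["cohort", "patient_id", "intron_id", "psi_normal"]]
    paired = normal.merge(tumor, on=["cohort", "patient_id", "intron_id"],
                          how="inner")
    paired["dpsi"] = paired["psi_normal"] - paired["psi_tumor"]
    return (paired[PAIRED_COLUMNS]
            .sort_values(["cohort", "intron_id", "patient_id"])
            .reset_index(drop=True))


def filter_testable_introns(
    paired: pd.DataFrame, min_pairs: int = 3
) -> dict[str, frozenset[str]]:
    """Introns testable per cohort: at least ``min_pairs`` complete pairs.

    The threshold is inclusive, and scoping is per cohort — an intron can
    be testable in one cohort and not another.
    """
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    counts = paired.groupby(["cohort", "intron_id"]).size()
    out: dict[str, frozenset[str]] = {}
    for cohort in paired["cohort"].unique():
        sub = counts.loc[cohort] if cohort in counts.index.get_level_values(0) else None
        if sub is None:
            out[cohort] = frozenset()
        else:
            out[cohort] = frozenset(sub.index[sub >= min_pairs])
    return out
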