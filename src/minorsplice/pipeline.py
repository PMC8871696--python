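"""End-to-end orchestration: read inputs, run every stage, write TSV results.

The pipeline is deterministic given its inputs and configuration. Every
filtering step logs how many entities it removed, so the funnel from
annotated introns to tested introns (and from samples to matched pairs)
is auditable on any input.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as msio
from . import activity as msactivity
from . import cross_cohort as mscross
from . import expression as msexpr
from .diffsplice import summarize_cohorts, test_cohort_introns
from .psi import build_paired_psi, filter_testable_introns, psi_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_summary", "analyze_splicing"]

GENE_SET_LABELS = ["protein_coding", "MIG", "component", "stem_signature"]
FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run."""

    annotation: str
    coverage: str
    sample_sheet: str
    outdir: str
    coverage_dialect: str = "tsv_long"
    events: str | None = None           # event coordinates for the TSV dialect
    gene_counts: str | None = None
    gene_sets: str | None = None
    alpha: float = 0.05
    min_patients: int = 5
    min_pairs: int = 3
    pseudocount: float = 1.0
    enrichment_contrast: str = "vs_tested"
    min_cohorts_cross: int = 3

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_patients < 1 or self.min_pairs < 1:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_splicing(
    annotation: pd.DataFrame,
    events: pd.DataFrame | None,
    coverage: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    min_patients: int = 5,
    min_pairs: int = 3,
) -> dict[str, pd.DataFrame]:
    """Run the splicing arm (PSI -> paired dPSI -> tests -> summaries).

    When ``events`` is provided, coverage rows are keyed by event id and
    joined to the annotation by exact coordinates; otherwise coverage ids
    are taken to be annotation intron ids directly.

    Returns a dict with keys ``pairs, psi, paired, intron_tests,
    cohort_summary``.
    """
    pairs_all = msio.select_matched_pairs(samples, min_patients=min_patients)
    pairs = pairs_all.loc[pairs_all["cohort_eligible"]].reset_index(drop=True)
    n_dropped = len(pairs_all) - len(pairs)
    if n_dropped:
        logger.info("%d pair(s) in ineligible cohorts excluded", n_dropped)
    event_map = (msio.match_events_to_minor_introns(events, annotation)
                 if events is not None else None)
    if event_map is None:
        known = set(annotation["intron_id"])
        unknown = set(coverage["intron_id"]) - known
        if unknown:
            logger.info("%d coverage id(s) not in the annotation dropped",
                        len(unknown))
            coverage = coverage.loc[coverage["intron_id"].isin(known)]
    psi = psi_table(coverage, annotation, samples, event_map)
    paired = build_paired_psi(psi, pairs)
    testable = filter_testable_introns(paired, min_pairs=min_pairs)
    tests = []
    for cohort in sorted(testable):
        sub = paired.loc[(paired["cohort"] == cohort)
                         & paired["intron_id"].isin(testable[cohort])]
        if sub.empty:
            logger.warning("cohort %s has no testable intron", cohort)
            continue
        tests.append(test_cohort_introns(sub, alpha=alpha, min_pairs=min_pairs))
    intron_tests = (pd.concat(tests, ignore_index=True) if tests
                    else pd.DataFrame(columns=["cohort", "intron_id", "n_pairs",
                                               "mean_dpsi", "statistic", "p",
                                               "q", "direction"]))
    summary = (summarize_cohorts(intron_tests, alpha=alpha)
               if not intron_tests.empty
               else pd.DataFrame(columns=["cohort", "n_up", "n_down", "n_ns",
                                          "score", "skew_p", "skew_q",
                                          "skew_class"]))
    return {"pairs": pairs, "psi": psi, "paired": paired,
            "intron_tests": intron_tests, "cohort_summary": summary}


def _analyze_expression(
    counts: pd.DataFrame,
    gene_sets: pd.DataFrame,
    samples: pd.DataFrame,
    pairs: pd.DataFrame,
    cfg: RunConfig,
) -> dict:
    """Per-cohort normalization, DE for the four gene sets, enrichment.

    Returns DE/enrichment tables plus per-cohort normalized matrices and
    per-patient component log2fc used by the activity correlations.
    """
    sets = {label: gene_sets.loc[gene_sets["set"] == label, "gene_id"].tolist()
            for label in GENE_SET_LABELS}
    de_frames, enrich_rows = [], []
    normalized_by_cohort: dict[str, pd.DataFrame] = {}
    lfc_by_cohort: dict[str, pd.DataFrame] = {}
    mean_lfc_cols: dict[str, pd.Series] = {}
    for cohort, cohort_pairs in pairs.groupby("cohort", sort=True):
        cohort_samples = samples.loc[samples["cohort"] == cohort, "sample_id"]
        cols = [s for s in cohort_samples if s in counts.columns]
        if len(cols) < 2:
            logger.warning("cohort %s: too few samples with counts", cohort)
            continue
        sf = msexpr.median_of_ratios(counts[cols])
        norm = msexpr.normalize_counts(counts[cols], sf)
        normalized_by_cohort[cohort] = norm
        usable = cohort_pairs.loc[
            cohort_pairs["tumor_sample"].isin(norm.columns)
            & cohort_pairs["normal_sample"].isin(norm.columns)]
        if len(usable) < cfg.min_pairs:
            logger.warning("cohort %s: fewer than %d pairs with counts",
                           cohort, cfg.min_pairs)
            continue
        per_patient_lfc, mean_lfc = msexpr.paired_log2fc(
            norm, usable, pseudocount=cfg.pseudocount)
        lfc_by_cohort[cohort] = per_patient_lfc
        mean_lfc_cols[cohort] = mean_lfc
        de_by_set = {}
        for label in GENE_SET_LABELS:
            de = msexpr.test_gene_set_de(norm, usable, sets[label], label,
                                         cohort, alpha=cfg.alpha,
                                         pseudocount=cfg.pseudocount)
            de_by_set[label] = de
            de_frames.append(de)
        if len(de_by_set["MIG"]) and len(de_by_set["protein_coding"]):
            enrich_rows.append(msexpr.cohort_mig_enrichment(
                de_by_set["MIG"], de_by_set["protein_coding"], cohort,
                contrast=cfg.enrichment_contrast))
    gene_de = (pd.concat(de_frames, ignore_index=True) if de_frames
               else pd.DataFrame(columns=msexpr.DE_COLUMNS))
    enrichment = pd.DataFrame(enrich_rows)
    if not enrichment.empty:
        from .stats import bh_fdr
        enrichment["q"] = bh_fdr(enrichment["p"].to_numpy())
    mean_lfc = (pd.DataFrame(mean_lfc_cols) if mean_lfc_cols
                else pd.DataFrame())
    return {"gene_de": gene_de, "enrichment": enrichment,
            "normalized": normalized_by_cohort, "per_patient_lfc": lfc_by_cohort,
            "mean_log2fc": mean_lfc, "sets": sets}


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the result bundle under ``cfg.outdir``.

    Stages whose inputs are absent (e.g. no gene counts) are skipped with
    a log entry; the splicing arm always runs. Returns the result tables.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    annotation = msio.read_intron_annotation(cfg.annotation)
    coverage, events = msio.read_coverage_container(cfg.coverage,
                                                    cfg.coverage_dialect)
    if events is None and cfg.events:
        events = pd.read_csv(cfg.events, sep="\t", dtype={"event_id": str,
                                                          "chrom": str,
                                                          "strand": str})
    samples = msio.read_sample_sheet(cfg.sample_sheet)
    logger.info("inputs: %d annotated introns (%d minor), %d coverage rows, "
                "%d samples", len(annotation), int(annotation["is_minor"].sum()),
                len(coverage), len(samples))

    results = analyze_splicing(annotation, events, coverage, samples,
                               alpha=cfg.alpha, min_patients=cfg.min_patients,
                               min_pairs=cfg.min_pairs)
    pairs = results["pairs"]

    results["activity_stats"] = msactivity.normal_psi_stats(results["psi"])
    results["tumor_activity"] = msactivity.tumor_activity(
        results["psi"], results["activity_stats"])
    results["patient_activity"] = msactivity.patient_activity_change(
        results["paired"])

    if cfg.gene_counts and cfg.gene_sets:
        counts = msio.read_gene_counts(cfg.gene_counts)
        gene_sets = msio.read_gene_sets(cfg.gene_sets)
        expr = _analyze_expression(counts, gene_sets, samples, pairs, cfg)
        results["gene_de"] = expr["gene_de"]
        results["enrichment"] = expr["enrichment"]

        components = expr["sets"]["component"]
        corr_frames, change_frames = [], []
        for cohort, norm in expr["normalized"].items():
            corr_frames.append(msactivity.component_activity_correlation(
                results["tumor_activity"], norm, components, cohort))
            if cohort in expr["per_patient_lfc"]:
                change_frames.append(msactivity.change_correlation(
                    results["patient_activity"], expr["per_patient_lfc"][cohort],
                    components, cohort))
        results["component_activity_corr"] = (
            pd.concat(corr_frames, ignore_index=True) if corr_frames
            else pd.DataFrame(columns=msactivity.CORR_COLUMNS))
        results["component_change_corr"] = (
            pd.concat(change_frames, ignore_index=True) if change_frames
            else pd.DataFrame(columns=msactivity.CORR_COLUMNS))

        summary = results["cohort_summary"]
        if len(summary) >= cfg.min_cohorts_cross and not expr["mean_log2fc"].empty:
            scores = summary.set_index("cohort")["score"]
            pc_genes = [g for g in expr["sets"]["protein_coding"]
                        if g in expr["mean_log2fc"].index]
            results["cross_cohort_corr"] = mscross.score_expression_correlation(
                scores, expr["mean_log2fc"].loc[pc_genes],
                min_cohorts=cfg.min_cohorts_cross)
        else:
            logger.info("cross-cohort screen skipped (needs >= %d cohorts)",
                        cfg.min_cohorts_cross)
    else:
        logger.info("gene counts/sets not provided; expression arm skipped")

    results["report"] = render_summary(results)
    _write_results(results, cfg, outdir)
    return results


def render_summary(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cohort-level report: intron and MIG direction counts, score, skew.

    Rows are ordered by minor-splicing score, descending.
    """
    summary = results.get("cohort_summary")
    if summary is None or summary.empty:
        return pd.DataFrame(columns=["cohort", "n_pairs", "introns_tested",
                                     "introns_up", "introns_down", "introns_ns",
                                     "score", "skew_class"])
    report = summary.rename(columns={
        "n_up": "introns_up", "n_down": "introns_down", "n_ns": "introns_ns"})
    report["introns_tested"] = (report["introns_up"] + report["introns_down"]
                                + report["introns_ns"])
    pairs = results.get("pairs")
    if pairs is not None and not pairs.empty:
        counts = pairs.groupby("cohort").size().rename("n_pairs")
        report = report.merge(counts, on="cohort", how="left")
    else:
        report["n_pairs"] = 0
    gene_de = results.get("gene_de")
    if gene_de is not None and not gene_de.empty:
        migs = gene_de.loc[gene_de["gene_set"] == "MIG"]
        gcounts = (migs.pivot_table(index="cohort", columns="direction",
                                    values="gene_id", aggfunc="count",
                                    fill_value=0)
                   .reindex(columns=["up", "down", "ns"], fill_value=0)
                   .rename(columns={"up": "mig_up", "down": "mig_down",
                                    "ns": "mig_ns"}))
        report = report.merge(gcounts, on="cohort", how="left")
    cols = ["cohort", "n_pairs", "introns_tested", "introns_up", "introns_down",
            "introns_ns", "score", "skew_class"]
    cols += [c for c in ("mig_up", "mig_down", "mig_ns") if c in report.columns]
    return (report[cols]
            .sort_values(["score", "cohort"], ascending=[False, True],
                         kind="mergesort")
            .reset_index(drop=True))


_OUTPUT_FILES = {
    "psi": "psi.tsv",
    "paired": "paired_psi.tsv",
    "intron_tests": "intron_tests.tsv",
    "cohort_summary": "cohort_summary.tsv",
    "gene_de": "gene_de.tsv",
    "enrichment": "enrichment.tsv",
    "activity_stats": "normal_psi_stats.tsv",
    "tumor_activity": "tumor_activity.tsv",
    "patient_activity": "patient_activity.tsv",
    "component_activity_corr": "component_activity_corr.tsv",
    "component_change_corr": "component_change_corr.tsv",
    "cross_cohort_corr": "cross_cohort_corr.tsv",
    "pairs": "matched_pairs.tsv",
    "report": "report.tsv",
}


def _write_results(results: dict, cfg: RunConfig, outdir: Path) -> None:
    for key, fname in _OUTPUT_FILES.items():
        table = results.get(key)
        if isinstance(table, pd.DataFrame):
            table.to_csv(outdir / fname, sep="\t", index=False,
                         float_format=FLOAT_FORMAT)
    # outdir is self-referential (the manifest lives there) and is omitted,
    # and input paths are reduced to basenames — their content identity is
    # carried by the sha256 digests — so that reruns of identical inputs
    # from any location produce byte-identical bundles
    params = {k: v for k, v in asdict(cfg).items() if k != "outdir"}
    for key in ("annotation", "coverage", "events", "sample_sheet",
                "gene_counts", "gene_sets"):
        if params.get(key):
            params[key] = Path(params[key]).name
    manifest = {
        "minorsplice_version": __version__,
        "parameters": params,
        "inputs": {name: _sha256(path) for name, path in {
            "annotation": cfg.annotation, "coverage": cfg.coverage,
            "sample_sheet": cfg.sample_sheet, "gene_counts": cfg.gene_counts,
            "gene_sets": cfg.gene_sets, "events": cfg.events,
        }.items() if path},
        "outputs": sorted(fname for key, fname in _OUTPUT_FILES.items()
                          if isinstance(results.get(key), pd.DataFrame)),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
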