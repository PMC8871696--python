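"""Seeded synthetic matched tumor/normal cohorts with known ground truth.

The generator emits exactly the inputs the pipeline ingests — minor-intron
annotation (BED6+2), per-(event, sample) retention/junction coverage,
gene counts, sample sheets with TCGA-style barcodes — plus the ground
truth used to score recovery.

Data model, per (intron, sample): a total informative read count ``N`` is
drawn from a negative-binomial depth model, the spanning-junction count
from ``Binomial(N, 1 - PSI_true/100)``, and the intron alignment count is
emitted as ``N_retained * intron_length`` so that the mean-coverage
numerator of the PSI estimator equals ``N_retained`` exactly. This makes
the PSI estimator's sampling distribution purely binomial and analytically
checkable; read-level effects (non-uniform coverage, edge effects) are
deliberately not modelled. True tumor PSI is the baseline minus the
injected dPSI effect (dPSI = normal - tumor convention), plus a per-tumor
global activity shift and per-observation biological jitter, clipped to
[0, 100].

Gene counts are negative-binomial with lognormal per-sample size factors;
a configurable fraction of minor-intron-containing genes (MIGs) is
up-regulated in tumors, and spliceosome-component genes can be coupled to
the simulated per-tumor activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as msio

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Study",
    "simulate_study",
    "write_study",
    "simulate_null_pvalue_study",
    "component_gene_ids",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the dimensions of a pan-cancer matched-pair analysis
    at desk scale: 14 cohorts of 20 matched pairs, a panel of 110 detected
    minor introns out of 673 annotated, and 5,000 genes of which 623 are
    MIGs, 15 are minor-spliceosome components and 48 form a stem-cell
    signature.
    """

    seed: int = 0
    cohorts: Sequence[str] = tuple(f"CH{i:02d}" for i in range(1, 15))
    n_patients: int | Mapping[str, int] = 20
    # intron panel
    n_minor_introns: int = 110          # detected as retention events
    n_annotated_extra: int = 563        # annotated minor introns without events
    n_major_introns: int = 25           # major introns in the annotation
    intron_length_bounds: tuple[int, int] = (80, 1200)
    baseline_psi_beta: tuple[float, float] = (2.0, 8.0)  # on 0-1, times 100
    # depth and noise model
    depth_mean: float = 200.0           # mean informative reads per (intron, sample)
    depth_dispersion: float = 10.0      # NB size; larger = closer to Poisson
    psi_sample_sd: float = 3.0          # biological PSI jitter, PSI points
    dropout: float = 0.05               # P(observation missing) per (intron, sample)
    # injected splicing effects: cohort -> {intron index -> dPSI (normal - tumor)}
    dpsi_effects: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    activity_sd: float = 0.0            # sd of per-tumor global PSI shift
    # gene expression model
    n_genes: int = 5000
    n_migs: int = 623
    n_components: int = 15
    n_stem_genes: int = 48
    n_snrna_components: int = 4         # components not labelled protein_coding
    gene_log_mean: float = math.log(200.0)
    gene_log_sd: float = 1.0
    gene_dispersion: float = 0.15
    size_factor_sd: float = 0.3
    mig_up_fraction: float = 0.3
    mig_up_log2fc: float = 1.0
    # extra expression effects: cohort -> {gene_id -> log2fc}
    de_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    # component gene_id -> (slope vs activity z-score, log2-scale noise sd)
    component_coupling: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must lie in [0, 1]")
        if not 0.0 <= self.mig_up_fraction <= 1.0:
            raise ValueError("mig_up_fraction must lie in [0, 1]")
        lo, hi = self.intron_length_bounds
        if lo <= 0 or hi < lo:
            raise ValueError("intron_length_bounds must satisfy 0 < lo <= hi")
        a, b = self.baseline_psi_beta
        if a <= 0 or b <= 0:
            raise ValueError("baseline PSI Beta shapes must be positive")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth model parameters must be positive")
        if self.n_genes and self.n_genes < self.n_migs + self.n_components + self.n_stem_genes:
            raise ValueError("n_genes must hold all labelled gene sets")
        for cohort, effects in self.dpsi_effects.items():
            if cohort not in self.cohorts:
                raise ValueError(f"dpsi_effects for unknown cohort {cohort!r}")
            for idx in effects:
                if not 0 <= idx < self.n_minor_introns:
                    raise ValueError(f"dpsi_effects intron index {idx} out of range")

    def patients_for(self, cohort: str) -> int:
        if isinstance(self.n_patients, Mapping):
            return int(self.n_patients[cohort])
        return int(self.n_patients)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "dpsi_effects" in raw:
            raw["dpsi_effects"] = {c: {int(k): float(v) for k, v in eff.items()}
                                   for c, eff in raw["dpsi_effects"].items()}
        if "component_coupling" in raw:
            raw["component_coupling"] = {g: tuple(v) for g, v in
                                         raw["component_coupling"].items()}
        for key in ("intron_length_bounds", "baseline_psi_beta"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "cohorts" in raw:
            raw["cohorts"] = tuple(raw["cohorts"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """True simulation parameters, aligned with the emitted data."""

    introns: pd.DataFrame   # intron_id, gene_id, length, baseline_psi
    effects: pd.DataFrame   # cohort, intron_id, true_dpsi
    genes: pd.DataFrame     # cohort, gene_id, true_log2fc
    cohorts: pd.DataFrame   # cohort, n_up_injected, n_down_injected, true_score_sign
    samples: pd.DataFrame   # sample_id, cohort, tissue, activity_shift, true_activity


@dataclass
class Study:
    """An in-memory synthetic study: inputs plus ground truth."""

    config: SimulationConfig
    annotation: pd.DataFrame
    events: pd.DataFrame
    coverage: pd.DataFrame
    samples: pd.DataFrame
    gene_counts: pd.DataFrame | None
    gene_sets: pd.DataFrame | None
    truth: GroundTruth


def _gene_ids(config: SimulationConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def component_gene_ids(config: SimulationConfig) -> list[str]:
    """Gene ids of the simulated minor-spliceosome components."""
    start = config.n_migs
    return [f"G{i:05d}" for i in range(start, start + config.n_components)]


def _gene_sets_table(config: SimulationConfig) -> pd.DataFrame:
    ids = _gene_ids(config)
    migs = ids[:config.n_migs]
    comps = component_gene_ids(config)
    snrna = set(comps[-config.n_snrna_components:]) if config.n_snrna_components else set()
    stem_start = config.n_migs + config.n_components
    stems = ids[stem_start:stem_start + config.n_stem_genes]
    rows = [(g, "protein_coding") for g in ids if g not in snrna]
    rows += [(g, "MIG") for g in migs]
    rows += [(g, "component") for g in comps]
    rows += [(g, "stem_signature") for g in stems]
    return pd.DataFrame(rows, columns=["gene_id", "set"])


def _site_code(k: int) -> str:
    return chr(ord("A") + k // 26) + chr(ord("A") + k % 26)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_study(config: SimulationConfig) -> Study:
    """Generate a full synthetic study; the seed fully determines the output."""
    rng = np.random.default_rng(config.seed)
    n_det = config.n_minor_introns
    n_total = n_det + config.n_annotated_extra + config.n_major_introns

    lengths = rng.integers(config.intron_length_bounds[0],
                           config.intron_length_bounds[1] + 1, n_total)
    a, b = config.baseline_psi_beta
    baseline_psi = rng.beta(a, b, n_det) * 100.0

    gene_ids = _gene_ids(config) if config.n_genes else []
    mig_ids = gene_ids[:config.n_migs] if gene_ids else []

    ann_rows = []
    for i in range(n_total):
        chrom = f"chr{(i % 22) + 1}"
        start = 10_000 + 10_000 * (i // 22)
        is_minor = i < n_det + config.n_annotated_extra
        if mig_ids and is_minor:
            host = mig_ids[i % len(mig_ids)]
        else:
            host = f"HOST{i:05d}"
        ann_rows.append((f"MI{i:05d}", chrom, start, start + int(lengths[i]),
                         "+" if i % 2 == 0 else "-", int(lengths[i]), host, is_minor))
    annotation = pd.DataFrame(ann_rows, columns=[
        "intron_id", "chrom", "start", "end", "strand", "length", "gene_id",
        "is_minor"])
    detected = annotation.iloc[:n_det]
    events = pd.DataFrame({
        "event_id": [f"EV{i:05d}" for i in range(n_det)],
        "chrom": detected["chrom"].to_numpy(),
        "start": detected["start"].to_numpy(),
        "end": detected["end"].to_numpy(),
        "strand": detected["strand"].to_numpy(),
    })
    det_lengths = lengths[:n_det].astype(np.int64)

    # gene base expression levels (drawn once, shared across cohorts)
    if config.n_genes:
        base_mean = rng.lognormal(config.gene_log_mean, config.gene_log_sd,
                                  config.n_genes)
        gene_sets = _gene_sets_table(config)
        n_mig_up = math.ceil(config.mig_up_fraction * config.n_migs)
        mig_up_genes = mig_ids[:n_mig_up]
        comp_ids = component_gene_ids(config)
        gene_index = {g: i for i, g in enumerate(gene_ids)}
    else:
        gene_sets = None

    sample_rows, coverage_frames, count_frames = [], [], []
    truth_effects, truth_genes, truth_cohorts, truth_samples = [], [], [], []

    for k, cohort in enumerate(config.cohorts):
        n_pat = config.patients_for(cohort)
        site = _site_code(k)
        patients = [f"TCGA-{site}-{p:04d}" for p in range(1, n_pat + 1)]
        tumor_ids = [f"{p}-01A" for p in patients]
        normal_ids = [f"{p}-11A" for p in patients]
        for p, t, n in zip(patients, tumor_ids, normal_ids):
            sample_rows.append((t, p, "tumor", cohort))
            sample_rows.append((n, p, "normal", cohort))

        effects = dict(config.dpsi_effects.get(cohort, {}))
        dpsi_vec = np.zeros(n_det)
        for idx, dpsi in effects.items():
            dpsi_vec[idx] = dpsi
            truth_effects.append((cohort, f"MI{idx:05d}", float(dpsi)))
        n_up_inj = int((dpsi_vec > 0).sum())
        n_down_inj = int((dpsi_vec < 0).sum())
        truth_cohorts.append((cohort, n_up_inj, n_down_inj,
                              int(np.sign(n_up_inj - n_down_inj))))

        delta = rng.normal(0.0, 1.0, n_pat) * config.activity_sd
        for p, t, n, d in zip(patients, tumor_ids, normal_ids, delta):
            truth_samples.append((t, cohort, "tumor", float(d), float(-d)))
            truth_samples.append((n, cohort, "normal", 0.0, 0.0))

        # true PSI per (sample, intron); rows = tumors then normals
        jitter = rng.normal(0.0, 1.0, (2 * n_pat, n_det)) * config.psi_sample_sd
        true_psi = np.empty((2 * n_pat, n_det))
        true_psi[:n_pat] = baseline_psi[None, :] - dpsi_vec[None, :] + delta[:, None]
        true_psi[n_pat:] = baseline_psi[None, :]
        true_psi = np.clip(true_psi + jitter, 0.0, 100.0)

        depth = _nb_draw(rng, np.full((2 * n_pat, n_det), config.depth_mean),
                         config.depth_dispersion)
        keep = rng.random((2 * n_pat, n_det)) >= config.dropout
        junction = rng.binomial(depth, 1.0 - true_psi / 100.0)
        retained = depth - junction
        align = retained * det_lengths[None, :]

        all_ids = tumor_ids + normal_ids
        rows_idx, cols_idx = np.nonzero(keep)
        coverage_frames.append(pd.DataFrame({
            "intron_id": events["event_id"].to_numpy()[cols_idx],
            "sample_id": np.asarray(all_ids, dtype=object)[rows_idx],
            "intron_alignment_count": align[rows_idx, cols_idx],
            "junction_count": junction[rows_idx, cols_idx],
        }))

        if config.n_genes:
            lfc = np.zeros((config.n_genes,))
            for g in mig_up_genes:
                lfc[gene_index[g]] += config.mig_up_log2fc
            for g, fc in config.de_effects.get(cohort, {}).items():
                lfc[gene_index[g]] += float(fc)
            for g in gene_ids:
                i = gene_index[g]
                if lfc[i] != 0.0:
                    truth_genes.append((cohort, g, float(lfc[i])))
            sf = rng.lognormal(0.0, config.size_factor_sd, 2 * n_pat)
            mu = base_mean[:, None] * sf[None, :]
            mu[:, :n_pat] *= np.exp2(lfc)[:, None]
            if config.component_coupling and config.activity_sd > 0:
                z = -delta / config.activity_sd
                for g, (slope, noise_sd) in config.component_coupling.items():
                    noise = rng.normal(0.0, 1.0, n_pat) * noise_sd
                    mu[gene_index[g], :n_pat] *= np.exp2(slope * z + noise)
            counts = _nb_draw(rng, mu, 1.0 / config.gene_dispersion)
            count_frames.append(pd.DataFrame(counts, index=gene_ids,
                                             columns=all_ids))

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "patient_id",
                                                 "tissue", "cohort"])
    coverage = pd.concat(coverage_frames, ignore_index=True)
    gene_counts = (pd.concat(count_frames, axis=1).rename_axis("gene_id")
                   if count_frames else None)

    truth = GroundTruth(
        introns=pd.DataFrame({
            "intron_id": detected["intron_id"].to_numpy(),
            "gene_id": detected["gene_id"].to_numpy(),
            "length": det_lengths,
            "baseline_psi": baseline_psi,
        }),
        effects=pd.DataFrame(truth_effects,
                             columns=["cohort", "intron_id", "true_dpsi"]),
        genes=pd.DataFrame(truth_genes,
                           columns=["cohort", "gene_id", "true_log2fc"]),
        cohorts=pd.DataFrame(truth_cohorts,
                             columns=["cohort", "n_up_injected",
                                      "n_down_injected", "true_score_sign"]),
        samples=pd.DataFrame(truth_samples,
                             columns=["sample_id", "cohort", "tissue",
                                      "activity_shift", "true_activity"]),
    )
    return Study(config=config, annotation=annotation, events=events,
                 coverage=coverage, samples=samples, gene_counts=gene_counts,
                 gene_sets=gene_sets, truth=truth)


def write_study(study: Study, outdir: str | Path,
                coverage_dialect: str = "tsv_long") -> dict[str, Path]:
    """Write a study to disk in the formats the ingest layer reads.

    Returns a name -> path mapping of everything written. Output is
    byte-identical for identical studies (fixed column order and float
    formatting).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["annotation"] = outdir / "annotation.bed"
    msio.write_intron_annotation(study.annotation, paths["annotation"])
    paths["events"] = outdir / "events.tsv"
    study.events.to_csv(paths["events"], sep="\t", index=False)
    if coverage_dialect == "tsv_long":
        paths["coverage"] = outdir / "coverage.tsv"
        msio.write_coverage_tsv(study.coverage, paths["coverage"])
    elif coverage_dialect == "hdf5_hierarchical":
        paths["coverage"] = outdir / "coverage.h5"
        msio.write_coverage_hdf5(study.coverage, study.events, paths["coverage"])
    else:
        raise ValueError(f"unknown coverage dialect {coverage_dialect!r}")
    paths["samples"] = outdir / "samples.tsv"
    msio.write_sample_sheet(study.samples, paths["samples"])
    if study.gene_counts is not None:
        paths["gene_counts"] = outdir / "gene_counts.tsv"
        study.gene_counts.to_csv(paths["gene_counts"], sep="\t")
        paths["gene_sets"] = outdir / "gene_sets.tsv"
        study.gene_sets.to_csv(paths["gene_sets"], sep="\t", index=False)
    truth_tables = {
        "truth_introns": study.truth.introns,
        "truth_effects": study.truth.effects,
        "truth_genes": study.truth.genes,
        "truth_cohorts": study.truth.cohorts,
        "truth_samples": study.truth.samples,
    }
    for name, table in truth_tables.items():
        paths[name] = outdir / f"{name}.tsv"
        table.to_csv(paths[name], sep="\t", index=False, float_format="%.6f")
    return paths


def simulate_null_pvalue_study(
    config: SimulationConfig, n_reps: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Type-I-error study: simulate effect-free cohorts and test them.

    Each replicate re-simulates ``config`` (with effects stripped and the
    gene model disabled) under a derived seed, runs the PSI and
    differential-splicing stages, and reports the fraction of introns at
    raw ``p < alpha`` and the count at ``q < alpha``.
    """
    from .diffsplice import test_cohort_introns
    from .psi import build_paired_psi, filter_testable_introns, psi_table

    if config.dpsi_effects:
        raise ValueError("null study requires an empty dpsi_effects spec")
    rows = []
    for rep in range(n_reps):
        cfg = replace(config, seed=(config.seed + 100_003 * rep + 1) % (2**31),
                      dpsi_effects={}, n_genes=0, activity_sd=0.0)
        study = simulate_study(cfg)
        pairs = msio.select_matched_pairs(study.samples, min_patients=1)
        event_map = msio.match_events_to_minor_introns(study.events,
                                                       study.annotation)
        psi = psi_table(study.coverage, study.annotation, study.samples,
                        event_map)
        paired = build_paired_psi(psi, pairs)
        testable = filter_testable_introns(paired)
        results = []
        for cohort, introns in testable.items():
            sub = paired.loc[(paired["cohort"] == cohort)
                             & paired["intron_id"].isin(introns)]
            if not sub.empty:
                results.append(test_cohort_introns(sub, alpha=alpha))
        res = pd.concat(results, ignore_index=True) if results else pd.DataFrame(
            columns=["p", "q"])
        n_tested = len(res)
        rows.append((rep, n_tested,
                     float((res["p"] < alpha).mean()) if n_tested else math.nan,
                     int((res["q"] < alpha).sum()) if n_tested else 0))
    return pd.DataFrame(rows, columns=["rep", "n_introns_tested",
                                       "frac_p_below_alpha", "n_q_below_alpha"])
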