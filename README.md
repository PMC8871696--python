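# minorsplice

Differential **minor-intron (U12-type) splicing** analysis for matched
tumor/normal bulk RNA-seq cohorts.

About 0.5% of human introns are excised by the minor (U12) spliceosome.
Because retention of a minor intron typically lowers the output of its host
gene, coordinated changes in minor-spliceosome activity leave a footprint in
intron-retention levels across the ~100 minor introns detectable in typical
splice-graph output. `minorsplice` quantifies that footprint in cancer
cohorts with matched tumor and adjacent-normal samples: it measures
per-sample retention, tests per-intron differential splicing within each
cohort, summarizes each cohort's overall shift, estimates per-tumor splicing
activity, and asks whether gene expression — of minor-intron-containing
genes (MIGs), of spliceosome components, or genome-wide — tracks those
splicing changes. It is aimed at computational biologists working with
TCGA-style retention-event counts, and ships a seeded synthetic-cohort
generator so every stage can be validated against known ground truth.

## The statistics

**PSI (percent spliced in).** For intron *i* of length *L* in one sample,
with *a* alignments inside the intron and *j* spliced junction reads
spanning it,

```
cov_int = a / L                      mean per-base intron coverage
PSI     = 100 · cov_int / (cov_int + j)
```

High PSI = high retention = low splicing. A sample contributes a PSI only if
it has ≥ 1 informative read for the intron.

**Differential splicing.** For every intron with ≥ 3 complete pairs in a
cohort, dPSI = PSI_normal − PSI_tumor is tested with a paired Wilcoxon
signed-rank test (exact null for n ≤ 25, ties handled exactly; corrected
normal approximation above), with Benjamini–Hochberg FDR across the
cohort's introns. Positive mean dPSI at q < 0.05 means splicing increased
in the tumor.

**Minor-splicing score.** Per cohort, `score = INT_up − INT_down`, the
number of introns with significantly increased minus significantly
decreased tumor splicing; an exact two-sided binomial test (BH-corrected
across cohorts) classifies cohorts as skewed toward increased or decreased
minor splicing.

**Activity.** A tumor's minor-splicing activity is
`Σᵢ βᵢ` with `βᵢ = (μᵢ − Tᵢ)/σᵢ`, where μᵢ, σᵢ are the mean and SD of
intron *i*'s PSI across all normal samples in the cohort and Tᵢ is the
tumor's PSI. A per-patient change score sums dPSI over shared introns.
Both are Spearman-correlated with spliceosome-component expression.

**Expression.** Counts are normalized with median-of-ratios size factors;
paired Wilcoxon tests per gene set (protein-coding, MIGs, 15 components, 48
stem-signature genes); a one-sided exact binomial test asks whether MIGs
are up-regulated more often than the protein-coding background. Across
cohorts, every gene's mean log2 fold change is Spearman-correlated with the
cohort scores.

## Worked example

```bash
python - <<'EOF'
from minorsplice.simulate import SimulationConfig, simulate_study, write_study
from minorsplice.pipeline import RunConfig, run_pipeline

cfg = SimulationConfig(
    seed=7, cohorts=("CA", "CB", "CC"), n_patients=12, n_minor_introns=30,
    n_annotated_extra=12, n_major_introns=4, n_genes=400, n_migs=120,
    n_components=15, n_stem_genes=30,
    dpsi_effects={"CA": {i: 15.0 for i in range(8)},     # more splicing in tumor
                  "CB": {i: -15.0 for i in range(6)}})   # less splicing in tumor
paths = write_study(simulate_study(cfg), "demo")
res = run_pipeline(RunConfig(
    annotation=str(paths["annotation"]), coverage=str(paths["coverage"]),
    events=str(paths["events"]), sample_sheet=str(paths["samples"]),
    gene_counts=str(paths["gene_counts"]), gene_sets=str(paths["gene_sets"]),
    outdir="demo/out"))
print(res["report"].to_string(index=False))
EOF
```

prints

```
cohort  n_pairs  introns_tested  introns_up  introns_down  introns_ns  score skew_class  mig_up  mig_down  mig_ns
    CA       12              30           9             1          20      8  increased      25         1      94
    CC       12              30           0             0          30      0       none      23         3      94
    CB       12              30           1             6          23     -5       none      25         5      90
```

Cohort CA, where 8 introns were injected with dPSI +15, recovers a strongly
positive minor-splicing score (9 introns up, 1 down, score +8) and is
classified as skewed toward increased splicing; CB, injected in the
opposite direction, scores −5; the effect-free CC scores 0. The
`mig_up`/`mig_down` columns count significantly up-/down-regulated MIGs per
cohort (the generator up-regulates 30% of MIGs in tumors by default, and
the MIG-enrichment binomial test flags all three cohorts at q ≪ 0.05). The
full bundle under `demo/out/` also contains the per-intron test table,
activity scores, component correlations, the cross-cohort screen and a run
manifest.

The same pipeline is available from the shell:

```bash
minorsplice simulate --seed 7 --outdir demo
minorsplice run --annotation demo/annotation.bed --coverage demo/coverage.tsv \
    --events demo/events.tsv --sample-sheet demo/samples.tsv \
    --gene-counts demo/gene_counts.tsv --gene-sets demo/gene_sets.tsv \
    --outdir demo/out
```

with stage-wise subcommands (`psi`, `diffsplice`, `expression`, `activity`,
`correlate`, `report`) for partial reruns.

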