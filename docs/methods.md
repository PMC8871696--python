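# Methods

## Retention quantification

PSI for an intron in a sample is `100 · cov_int / (cov_int + cov_ej)`,
where `cov_int` is the mean per-base coverage of the intron (total
alignments to the intron divided by intron length) and `cov_ej` is the
count of spliced alignments spanning it. The ingested "intron alignment
count" is taken as the container provides it; whether it counts all
overlapping alignments or only fully contained ones is a property of the
upstream splice-graph tool, not of this package. `cov_int` is carried as a
real number and PSI at full precision — rounding is applied only in
reports, because premature rounding manufactures rank ties in the
signed-rank tests.

A sample contributes a PSI for an intron only when it has at least one
informative read (retained or spliced) for that intron; zero-coverage
observations are absent, not zero. Coordinates are 0-based half-open
throughout; BED input is taken as-is and any 1-based inclusive source must
be converted on read, so that event-to-annotation joins are exact. Events
are joined to annotated minor introns by exact (chrom, start, end, strand)
match; unmatched events are dropped and counted, and every filtering stage
logs its removals so the funnel from annotated to tested introns is
auditable. A patient with multiple tumor (or normal) aliquots keeps the
lexicographically smallest sample id — a deterministic convention for a
situation the underlying data model leaves open.

## Differential splicing and the cohort summary

Within a cohort, an intron is testable with ≥ 3 complete tumor/normal
pairs (cohorts themselves require ≥ 5 matched patients). dPSI = normal −
tumor is tested with the paired Wilcoxon signed-rank test: zero
differences are dropped, tied absolute differences get average ranks, and
the two-sided p-value is exact — computed by dynamic programming over the
2^n sign assignments, which handles ties exactly — whenever the post-drop
n ≤ 25, with the tie- and continuity-corrected normal approximation above
that. The exact-with-ties choice matters in practice: a gene or intron
with identical differences across pairs is precisely the strong-signal
case, and the normal approximation is at its worst there. FDR is
Benjamini–Hochberg within cohort; pooling across cohorts would couple
cohorts of very different sizes.

The minor-splicing score is `n_up − n_down` over significantly shifted
introns. Direction skew per cohort uses the exact two-sided binomial test
at success probability 0.5 (minimum-likelihood two-sided definition),
BH-corrected across the cohorts of the run; a cohort with no directional
intron carries no test and class `none`.

## Activity estimation

Normal-tissue reference statistics (μᵢ, σᵢ) are computed per cohort from
**all** normal samples with a defined PSI, not only those in matched
pairs; σ uses the n−1 denominator and needs ≥ 2 normals. β sums run over
the introns actually available for a tumor (σ > 0, PSI defined), with
`n_introns_used` reported rather than rescaling to the full panel —
rescaling would assume exchangeability across introns that nothing in the
model justifies. The per-patient change score simply sums dPSI over
introns observed in both tissues.

## Expression

Size factors are classical median-of-ratios: per-gene geometric-mean
reference over the cohort's samples (genes with a zero anywhere excluded
from the reference), per-sample median ratio. Normalization is scoped per
cohort. Differential expression uses the same paired Wilcoxon engine on
normalized counts, with BH within each gene set per cohort — deliberately
not a negative-binomial regression, so the splicing and expression arms
share one robust nonparametric engine. Log2 fold changes use pseudocount 1
on normalized counts, which guards zeros without distorting moderate
counts.

MIG enrichment is a one-sided exact binomial test of the number of
significantly up-regulated MIGs against the fraction of significantly
up-regulated protein-coding genes in the same cohort, BH across cohorts.
The contrast is configurable (`vs_tested`, the default, or
`among_significant`, i.e. up/(up+down) among significant genes) because
the up-regulation baseline can reasonably be defined either way; the
default conditions on all tested genes. A degenerate background of exactly
zero would produce p = 0, so enrichment p-values are floored at the
smallest positive float to stay inside the (0, 1] domain of the FDR step.

## Correlations

Spearman rho is computed on average ranks; the p-value is exact by
permutation enumeration for n ≤ 7 and a t approximation with n − 2 degrees
of freedom otherwise (floored at the smallest positive float when
|rho| = 1). Component–activity correlations are BH-corrected across
components within cohort; the cross-cohort screen of per-gene mean log2
fold change against cohort scores is BH-corrected across all genes tested,
requires ≥ 3 cohorts per gene, and — being rank-based — is invariant to
any order-preserving transform of the scores. Zero-variance vectors yield
no correlation (absent, counted in the log) rather than a coerced value.

## Synthetic cohorts

The generator emulates the data model the pipeline assumes: matched
tumor/normal pairs with TCGA-style barcodes, a panel of detected minor
introns plus annotated-but-undetected ones, per-(intron, sample) retention
and junction counts, and NB gene counts with labelled gene sets.

Per (intron, sample), total informative reads `N` follow a
negative-binomial depth model; the junction count is
`Binomial(N, 1 − PSI_true/100)`; the intron alignment count is emitted as
`N_retained · length` so that `cov_int = N_retained` exactly and the PSI
estimator's sampling distribution is purely binomial (and hence
analytically checkable). True tumor PSI is the baseline minus the injected
dPSI effect, plus an optional per-tumor global shift (the handle for
activity–expression coupling studies) and per-observation Gaussian jitter,
clipped to [0, 100].

Defaults — the study conditions for all calibration results:

| parameter | default | rationale |
|---|---|---|
| cohorts × pairs | 14 × 20 | pan-cancer matched-pair design at desk scale |
| detected minor introns | 110 (+563 annotated-only, +25 major) | realistic detected/annotated funnel |
| intron length | uniform 80–1200 bp | typical minor-intron lengths |
| baseline PSI | Beta(2, 8) × 100 (~20) | moderate retention, right-skewed |
| depth per (intron, sample) | NB mean 200, size 10 | moderately overdispersed coverage |
| biological PSI jitter | sd 3 PSI points | inter-sample variability beyond counting noise |
| dropout | 0.05 per observation | sporadic missing observations |
| genes | 5000; 623 MIGs, 15 components (4 snRNA), 48 stem | matches the labelled gene-set sizes |
| gene counts | lognormal means (log 200, sd 1), NB dispersion 0.15 | bulk RNA-seq-like |
| size factors | lognormal sd 0.3 | library-size variation |
| MIG effect | 30% of MIGs at log2FC +1 in tumors | detectable but not saturated up-regulation |

The seed fully determines the output; identical configurations write
byte-identical files (fixed column order and float formatting). Effect
specs are given in dPSI points (normal − tumor), matching the analysis
convention: a +15 effect means the intron is spliced more in the tumor.

What the generator does **not** emulate: read-level artifacts (non-uniform
coverage, mapping bias, edge effects), correlated intron effects within a
gene, tumor purity/stromal contamination, batch structure, and count
dependence between the splicing and expression arms beyond the optional
component–activity coupling. Passing calibration on this generator
therefore demonstrates correctness of the estimators and tests under the
stated sampling model, not robustness to those real-data complications.

## Numerical and design choices

- Exact tests everywhere feasible: signed-rank (n ≤ 25, ties included),
  binomial (both skew and enrichment), Spearman permutation (n ≤ 7).
- BH q-values are computed with a vectorized step-up, validated against an
  independent textbook implementation; inputs outside (0, 1] are rejected
  rather than clipped.
- Calibration experiments in the acceptance suite use Beta(10, 10)
  mid-range baselines when injecting ±15-point dPSI effects, since a
  ~20-PSI baseline would truncate a +15 effect against the PSI floor; the
  default Beta(2, 8) conditions are used everywhere else. Problem sizes:
  2,000 introns × 20 pairs for null calibration, 50 pairs × 20 introns ×
  100 replicates for score-sign recovery, 30 samples × 30 introns for
  activity calibration, 500 decoys × 14 cohorts × 20 replicates for the
  cross-cohort screen.
- In the decoy screen, BH at q < 0.05 over 501 tests admits an occasional
  permuted decoy (~once per ten replicates in expectation); the acceptance
  checks therefore assert recovery of the constructed gene and a low mean
  decoy-discovery count, which is what FDR control actually promises.
- The run manifest records package/parameter state and sha256 digests of
  the inputs; input paths are reduced to basenames and the output
  directory is omitted so identical inputs give byte-identical bundles
  regardless of location.

## Known limitations

- The PSI definition is the mean-coverage/junction ratio only; no
  junction-ratio or splice-event alternatives, and no length-bias
  correction beyond mean-coverage normalization.
- No dispersion modelling or shrinkage in the expression arm; the paired
  Wilcoxon on normalized counts trades power for robustness.
- Correlations are reported as-is; no causal interpretation, partial
  correlation, or covariate adjustment.
- Mutation-frequency tables and GO/Reactome enrichment are out of scope;
  the pipeline exports gene lists suitable for external enrichment tools.
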