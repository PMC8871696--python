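"""Normalization, paired differential expression, MIG enrichment."""

import numpy as np
import pandas as pd
import pytest

from minorsplice.expression import (
    cohort_mig_enrichment,
    median_of_ratios,
    mig_enrichment,
    normalize_counts,
    paired_log2fc,
    test_gene_set_de as gene_set_de,
)


def pairs_frame(n):
    return pd.DataFrame({
        "cohort": ["X"] * n,
        "patient_id": [f"P{i}" for i in range(n)],
        "tumor_sample": [f"T{i}" for i in range(n)],
        "normal_sample": [f"N{i}" for i in range(n)]})


class TestSizeFactors:
    def test_doubled_sample(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                              index=["g1", "g2", "g3"])
        sf = median_of_ratios(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples(self):
        counts = pd.DataFrame({"s1": [5, 9], "s2": [5, 9]}, index=["g1", "g2"])
        assert median_of_ratios(counts).tolist() == pytest.approx([1.0, 1.0])

    def test_zero_gene_excluded_from_reference(self):
        counts = pd.DataFrame({"s1": [10, 0, 30], "s2": [20, 50, 60]},
                              index=["g1", "g2", "g3"])
        with_zero = median_of_ratios(counts)
        without = median_of_ratios(counts.drop("g2"))
        assert with_zero.tolist() == pytest.approx(without.tolist())

    def test_no_all_positive_gene_fatal(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="no gene"):
            median_of_ratios(counts)

    def test_equivariance_under_sample_scaling(self, rng):
        # scaling one library by c moves its factor by c relative to the rest
        counts = pd.DataFrame(rng.integers(1, 1000, (50, 4)).astype(float),
                              columns=list("abcd"))
        sf = median_of_ratios(counts)
        scaled = counts.copy()
        scaled["b"] *= 3.0
        sf2 = median_of_ratios(scaled)
        assert (sf2["b"] / sf2["a"]) / (sf["b"] / sf["a"]) == pytest.approx(3.0)

    def test_library_size_only_simulation_flattens(self, rng):
        base = rng.integers(50, 500, 200).astype(float)
        counts = pd.DataFrame({f"s{j}": rng.poisson(base * f)
                               for j, f in enumerate([0.5, 1.0, 2.0, 4.0])})
        norm = normalize_counts(counts, median_of_ratios(counts))
        means = norm.mean(axis=0)
        assert means.max() / means.min() < 1.1


class TestPairedLog2fc:
    def test_worked_example(self):
        norm = pd.DataFrame({"T0": [16.0], "N0": [4.0]}, index=["g1"])
        per_patient, mean = paired_log2fc(norm, pairs_frame(1))
        assert mean["g1"] == pytest.approx(np.log2(17 / 5))

    def test_equal_and_zero_guards(self):
        norm = pd.DataFrame({"T0": [7.0, 0.0], "N0": [7.0, 0.0]},
                            index=["g1", "g2"])
        _, mean = paired_log2fc(norm, pairs_frame(1))
        assert mean.tolist() == [0.0, 0.0]


class TestGeneSetDe:
    def test_doubled_gene_significant_up(self):
        n = 6
        norm = pd.DataFrame(
            {f"T{i}": [20.0 + i] for i in range(n)} |
            {f"N{i}": [10.0 + i] for i in range(n)}, index=["g1"]).astype(float)
        res = gene_set_de(norm, pairs_frame(n), ["g1"], "MIG", "X")
        row = res.iloc[0]
        assert row["p"] == pytest.approx(0.03125)
        assert row["direction"] == "up"

    def test_constant_gene_is_ns(self):
        n = 6
        norm = pd.DataFrame({f"T{i}": [5.0] for i in range(n)} |
                            {f"N{i}": [5.0] for i in range(n)}, index=["g1"])
        res = gene_set_de(norm, pairs_frame(n), ["g1"], "MIG", "X")
        assert res.iloc[0]["p"] == 1.0
        assert res.iloc[0]["direction"] == "ns"

    def test_empty_set_and_missing_genes(self):
        norm = pd.DataFrame({"T0": [1.0], "N0": [1.0]}, index=["g1"])
        assert gene_set_de(norm, pairs_frame(1), [], "MIG", "X").empty
        res = gene_set_de(norm, pairs_frame(1), ["g1", "absent"], "MIG", "X")
        assert set(res["gene_id"]) == {"g1"}


class TestEnrichment:
    @pytest.mark.parametrize("k, n, pi, expected", [
        (9, 10, 0.5, 11 / 1024),
        (5, 10, 0.5, 638 / 1024),
        (0, 10, 0.5, 1.0),
    ])
    def test_exact_tail_values(self, k, n, pi, expected):
        assert mig_enrichment(k, n, pi) == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            mig_enrichment(1, 0, 0.5)
        with pytest.raises(ValueError):
            mig_enrichment(5, 10, 1.5)
        with pytest.raises(ValueError):
            mig_enrichment(11, 10, 0.5)

    def test_cohort_contrast_switch(self):
        mig = pd.DataFrame({"direction": ["up"] * 8 + ["down"] * 1 + ["ns"] * 1})
        pc = pd.DataFrame({"direction": ["up"] * 10 + ["down"] * 10 + ["ns"] * 80})
        vs_tested = cohort_mig_enrichment(mig, pc, "X", "vs_tested")
        assert vs_tested["background_prop"] == pytest.approx(0.1)
        assert vs_tested["n_mig_tested"] == 10
        among_sig = cohort_mig_enrichment(mig, pc, "X", "among_significant")
        assert among_sig["background_prop"] == pytest.approx(0.5)
        assert among_sig["n_mig_tested"] == 9

    def test_injected_mig_upregulation_detected(self):
        """30% of MIGs at +1 log2fc, 20 pairs: enrichment p < 0.05 in most reps."""
        from minorsplice.pipeline import RunConfig, _analyze_expression
        from minorsplice.simulate import SimulationConfig, simulate_study
        from minorsplice import io as msio

        cfg = RunConfig(annotation="-", coverage="-", sample_sheet="-",
                        outdir="-", min_patients=5)
        hits = 0
        n_reps = 5
        for rep in range(n_reps):
            sim = SimulationConfig(seed=900 + rep, cohorts=("X",), n_patients=20,
                                   n_minor_introns=5, n_annotated_extra=0,
                                   n_major_introns=0, n_genes=300, n_migs=100,
                                   n_components=15, n_stem_genes=20,
                                   mig_up_fraction=0.3, mig_up_log2fc=1.0)
            study = simulate_study(sim)
            pairs = msio.select_matched_pairs(study.samples, min_patients=5)
            expr = _analyze_expression(study.gene_counts, study.gene_sets,
                                       study.samples, pairs, cfg)
            hits += expr["enrichment"]["p"].iloc[0] < 0.05
        assert hits >= n_reps - 1
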