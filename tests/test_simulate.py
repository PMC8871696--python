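"""Synthetic-data generator: determinism, estimator calibration, recovery."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from minorsplice import io as msio
from minorsplice.psi import build_paired_psi, psi_table
from minorsplice.simulate import (
    SimulationConfig,
    component_gene_ids,
    simulate_study,
    write_study,
)
from conftest import tiny_config


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dropout": 1.5},
        {"intron_length_bounds": (0, 100)},
        {"baseline_psi_beta": (0.0, 2.0)},
        {"dpsi_effects": {"NOPE": {0: 5.0}}},
        {"dpsi_effects": {"CA": {99: 5.0}}},
        {"n_genes": 10, "n_migs": 60},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(cohorts=("CA",), n_minor_introns=20, n_migs=60,
                    n_components=15, n_stem_genes=20, n_genes=150)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = tiny_config()
        dirs = []
        for name in ("a", "b"):
            paths = write_study(simulate_study(cfg), tmp_path / name)
            dirs.append({k: p for k, p in paths.items()})
        for key in dirs[0]:
            if dirs[0][key].suffix == ".h5":
                continue
            assert filecmp.cmp(dirs[0][key], dirs[1][key], shallow=False), key

    def test_different_seed_differs(self):
        a = simulate_study(tiny_config(seed=1))
        b = simulate_study(tiny_config(seed=2))
        assert not a.coverage.equals(b.coverage)


class TestEmittedStructure:
    def test_shapes_and_gene_sets(self, tiny_study):
        cfg = tiny_study.config
        ann = tiny_study.annotation
        assert len(ann) == (cfg.n_minor_introns + cfg.n_annotated_extra
                            + cfg.n_major_introns)
        assert int(ann["is_minor"].sum()) == cfg.n_minor_introns + cfg.n_annotated_extra
        assert len(tiny_study.events) == cfg.n_minor_introns
        sets = tiny_study.gene_sets.groupby("set").size()
        assert sets["MIG"] == cfg.n_migs
        assert sets["component"] == cfg.n_components
        assert sets["stem_signature"] == cfg.n_stem_genes
        assert sets["protein_coding"] == cfg.n_genes - cfg.n_snrna_components
        comps = component_gene_ids(cfg)
        assert set(comps) <= set(tiny_study.gene_counts.index)

    def test_barcodes_parse_and_pair(self, tiny_study):
        for sid, pid, tissue in tiny_study.samples[
                ["sample_id", "patient_id", "tissue"]].itertuples(index=False):
            parsed = msio.parse_sample_barcode(sid)
            assert parsed == (pid, tissue)
        pairs = msio.select_matched_pairs(tiny_study.samples)
        assert len(pairs) == len(tiny_study.config.cohorts) * 8

    def test_truth_tables_consistent(self, tiny_study):
        truth = tiny_study.truth
        assert len(truth.effects) == 3
        ca = truth.cohorts.set_index("cohort").loc["CA"]
        assert (ca["n_up_injected"], ca["n_down_injected"]) == (2, 1)
        assert ca["true_score_sign"] == 1


class TestEstimatorCalibration:
    def test_psi_estimator_unbiased_at_depth(self, rng):
        """Mean bias of the PSI estimator < 0.5 points at depth >= 100."""
        from minorsplice.psi import compute_psi

        for true_psi in (5.0, 20.0, 60.0):
            n = rng.negative_binomial(10, 10 / (10 + 150), 10_000)
            retained = rng.binomial(n, true_psi / 100.0)
            keep = n > 0
            psis = 100.0 * retained[keep] / n[keep]
            assert abs(psis.mean() - true_psi) < 0.5
            # spot-check that the emitted counts reproduce the same estimate
            assert compute_psi(retained[keep][0] * 300, 300,
                               int(n[keep][0] - retained[keep][0])) == \
                pytest.approx(psis[0])

    def test_null_construction_has_no_mean_shift(self):
        cfg = tiny_config(dpsi_effects={}, activity_sd=0.0, n_genes=0,
                          n_patients=40, dropout=0.0)
        study = simulate_study(cfg)
        pairs = msio.select_matched_pairs(study.samples)
        emap = msio.match_events_to_minor_introns(study.events, study.annotation)
        paired = build_paired_psi(
            psi_table(study.coverage, study.annotation, study.samples, emap),
            pairs)
        mean = paired.groupby("intron_id")["dpsi"].mean()
        se = paired.groupby("intron_id")["dpsi"].sem()
        assert ((mean.abs() <= 3 * se).mean()) > 0.9

    def test_injected_shift_recovered_within_two_psi_points(self):
        """dPSI -20 at depth 200, 50 pairs: recovered mean within +-2."""
        cfg = SimulationConfig(
            seed=8, cohorts=("X",), n_patients=50, n_minor_introns=4,
            n_annotated_extra=0, n_major_introns=0, n_genes=0, dropout=0.0,
            dpsi_effects={"X": {0: -20.0}})
        study = simulate_study(cfg)
        pairs = msio.select_matched_pairs(study.samples)
        emap = msio.match_events_to_minor_introns(study.events, study.annotation)
        paired = build_paired_psi(
            psi_table(study.coverage, study.annotation, study.samples, emap),
            pairs)
        shifted = paired.loc[paired["intron_id"] == "MI00000", "dpsi"]
        assert shifted.mean() == pytest.approx(-20.0, abs=2.0)

    def test_recovered_effects_track_truth(self):
        """Spearman(true dPSI, recovered mean dPSI) > 0.9 for |shift| >= 10."""
        from minorsplice.stats import spearman

        effects = {i: float(s) for i, s in enumerate(
            [15, -15, 10, -10, 20, -20, 12, -12, 18, -18])}
        cfg = SimulationConfig(
            seed=21, cohorts=("X",), n_patients=50, n_minor_introns=10,
            n_annotated_extra=0, n_major_introns=0, n_genes=0, dropout=0.0,
            dpsi_effects={"X": effects})
        study = simulate_study(cfg)
        pairs = msio.select_matched_pairs(study.samples)
        emap = msio.match_events_to_minor_introns(study.events, study.annotation)
        paired = build_paired_psi(
            psi_table(study.coverage, study.annotation, study.samples, emap),
            pairs)
        recovered = paired.groupby("intron_id")["dpsi"].mean()
        truth = study.truth.effects.set_index("intron_id")["true_dpsi"]
        rho, _ = spearman(truth.loc[recovered.index].to_numpy(),
                          recovered.to_numpy())
        assert rho > 0.9


class TestNullStudy:
    def test_zero_reps_empty_table(self):
        from minorsplice.simulate import simulate_null_pvalue_study

        cfg = tiny_config(dpsi_effects={}, n_genes=0)
        assert simulate_null_pvalue_study(cfg, 0).empty

    def test_effects_rejected(self):
        from minorsplice.simulate import simulate_null_pvalue_study

        with pytest.raises(ValueError):
            simulate_null_pvalue_study(tiny_config(), 1)
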