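"""Activity estimation (summed beta, summed dPSI) and correlations."""

import numpy as np
import pandas as pd
import pytest

from minorsplice.activity import (
    beta_coefficient,
    change_correlation,
    component_activity_correlation,
    normal_psi_stats,
    patient_activity_change,
    tumor_activity,
)


def psi_frame(rows):
    return pd.DataFrame(rows, columns=["cohort", "intron_id", "sample_id",
                                       "patient_id", "tissue", "cov_int",
                                       "cov_ej", "psi"])


class TestBeta:
    def test_worked_example(self):
        assert beta_coefficient(40.0, 60.0, 10.0) == pytest.approx(2.0)

    def test_zero_at_the_normal_mean(self):
        assert beta_coefficient(60.0, 60.0, 7.3) == 0.0

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(ValueError):
            beta_coefficient(40.0, 60.0, 0.0)

    def test_location_equivariance(self):
        # shifting the tumor PSI by -delta raises beta by delta/sigma
        delta, sigma = 8.0, 4.0
        base = beta_coefficient(50.0, 60.0, sigma)
        shifted = beta_coefficient(50.0 - delta, 60.0, sigma)
        assert shifted - base == pytest.approx(delta / sigma)


class TestNormalStats:
    def test_mean_sd_and_minimum_pool(self):
        rows = [("X", "i1", f"N{k}", f"P{k}", "normal", 1, 1, v)
                for k, v in enumerate([50.0, 60.0, 70.0])]
        rows.append(("X", "i2", "N0", "P0", "normal", 1, 1, 30.0))  # n=1: dropped
        rows.append(("X", "i1", "T0", "P0", "tumor", 1, 1, 20.0))   # ignored
        stats = normal_psi_stats(psi_frame(rows))
        assert len(stats) == 1
        row = stats.iloc[0]
        assert row["mu"] == pytest.approx(60.0)
        assert row["sigma"] == pytest.approx(10.0)  # ddof=1
        assert row["n_normals"] == 3


class TestTumorActivity:
    @staticmethod
    def stats():
        return pd.DataFrame({
            "cohort": ["X", "X", "X"], "intron_id": ["i1", "i2", "i3"],
            "mu": [60.0, 40.0, 50.0], "sigma": [10.0, 20.0, 0.0],
            "n_normals": [5, 5, 5]})

    def test_additivity_and_sigma_zero_exclusion(self):
        psi = psi_frame([
            ("X", "i1", "T1", "P1", "tumor", 1, 1, 40.0),   # beta +2.0
            ("X", "i2", "T1", "P1", "tumor", 1, 1, 50.0),   # beta -0.5
            ("X", "i3", "T1", "P1", "tumor", 1, 1, 10.0)])  # sigma 0: excluded
        scores = tumor_activity(psi, self.stats())
        row = scores.iloc[0]
        assert row["sum_beta"] == pytest.approx(1.5)
        assert row["n_introns_used"] == 2

    def test_tumor_matching_normal_means_scores_zero(self):
        psi = psi_frame([("X", "i1", "T1", "P1", "tumor", 1, 1, 60.0),
                         ("X", "i2", "T1", "P1", "tumor", 1, 1, 40.0)])
        assert tumor_activity(psi, self.stats()).iloc[0]["sum_beta"] == 0.0

    def test_missing_intron_reflected_in_count(self):
        psi = psi_frame([("X", "i1", "T1", "P1", "tumor", 1, 1, 40.0)])
        assert tumor_activity(psi, self.stats()).iloc[0]["n_introns_used"] == 1

    def test_heldout_normals_center_at_zero(self, rng):
        """Leave-one-out normal scoring is distributed around 0."""
        n_normals, n_introns = 30, 40
        psis = rng.normal(50, 6, (n_normals, n_introns))
        sums = []
        for held in range(n_normals):
            rest = np.delete(psis, held, axis=0)
            beta = (rest.mean(axis=0) - psis[held]) / rest.std(axis=0, ddof=1)
            sums.append(beta.sum())
        se = np.std(sums, ddof=1) / np.sqrt(n_normals)
        assert abs(np.mean(sums)) <= 3 * se


class TestPatientChange:
    def test_additivity(self):
        paired = pd.DataFrame({
            "cohort": ["X", "X"], "intron_id": ["i1", "i2"],
            "patient_id": ["P1", "P1"],
            "psi_normal": [50.0, 30.0], "psi_tumor": [40.0, 35.0],
            "dpsi": [10.0, -5.0]})
        out = patient_activity_change(paired)
        assert out.iloc[0]["sum_dpsi"] == pytest.approx(5.0)
        assert out.iloc[0]["n_introns_used"] == 2

    def test_empty_input(self):
        assert patient_activity_change(pd.DataFrame(
            columns=["cohort", "intron_id", "patient_id", "psi_normal",
                     "psi_tumor", "dpsi"])).empty


class TestCorrelations:
    @staticmethod
    def activity():
        return pd.DataFrame({"cohort": ["X"] * 5,
                             "sample_id": [f"T{i}" for i in range(5)],
                             "sum_beta": [1.0, 3.0, 2.0, 5.0, 4.0],
                             "n_introns_used": [10] * 5})

    def test_monotone_expression_gives_rho_one(self):
        act = self.activity()
        expr = pd.DataFrame([act["sum_beta"].to_numpy() * 7 + 2],
                            index=["C1"], columns=act["sample_id"])
        res = component_activity_correlation(act, expr, ["C1"], "X")
        assert res.iloc[0]["rho"] == pytest.approx(1.0)

    def test_two_tumor_component_skipped(self):
        act = self.activity().iloc[:2]
        expr = pd.DataFrame([[1.0, 2.0]], index=["C1"],
                            columns=act["sample_id"])
        assert component_activity_correlation(act, expr, ["C1"], "X").empty

    def test_constant_expression_absent(self):
        act = self.activity()
        expr = pd.DataFrame([[3.0] * 5], index=["C1"], columns=act["sample_id"])
        assert component_activity_correlation(act, expr, ["C1"], "X").empty

    def test_change_correlation_signs(self):
        changes = pd.DataFrame({"cohort": ["X"] * 4,
                                "patient_id": [f"P{i}" for i in range(4)],
                                "sum_dpsi": [1.0, 4.0, 2.0, 3.0],
                                "n_introns_used": [10] * 4})
        lfc = pd.DataFrame(
            [changes["sum_dpsi"].to_numpy(), -changes["sum_dpsi"].to_numpy()],
            index=["C1", "C2"], columns=changes["patient_id"])
        res = change_correlation(changes, lfc, ["C1", "C2"], "X")
        by = res.set_index("feature_id")["rho"]
        assert by["C1"] == pytest.approx(1.0)
        assert by["C2"] == pytest.approx(-1.0)


class TestRecoveryOnSyntheticCohort:
    def test_global_retention_shift_recovered(self):
        """Tumors shifted by dPSI +10 on all introns: summed dPSI recovers
        n_introns * 10 and sum_beta is positive for nearly every tumor."""
        from minorsplice import io as msio
        from minorsplice.psi import build_paired_psi, psi_table
        from minorsplice.simulate import SimulationConfig, simulate_study

        n_introns = 25
        cfg = SimulationConfig(
            seed=77, cohorts=("X",), n_patients=25, n_minor_introns=n_introns,
            n_annotated_extra=0, n_major_introns=0, n_genes=0, dropout=0.0,
            psi_sample_sd=5.0, baseline_psi_beta=(4.0, 8.0),
            dpsi_effects={"X": {i: 10.0 for i in range(n_introns)}})
        study = simulate_study(cfg)
        pairs = msio.select_matched_pairs(study.samples)
        emap = msio.match_events_to_minor_introns(study.events, study.annotation)
        psi = psi_table(study.coverage, study.annotation, study.samples, emap)
        paired = build_paired_psi(psi, pairs)
        changes = patient_activity_change(paired)
        per_intron_mean = changes["sum_dpsi"] / changes["n_introns_used"]
        assert per_intron_mean.mean() == pytest.approx(10.0, abs=2.0)

        stats = normal_psi_stats(psi)
        scores = tumor_activity(psi, stats)
        assert (scores["sum_beta"] > 0).mean() >= 0.95
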