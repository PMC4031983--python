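"""Screen normalization, Z-scores, toxicity and hit calling."""

import numpy as np
import pandas as pd
import pytest

from mirloh import (
    AnalysisParams,
    analyze_screen,
    call_hits,
    fold_enrichment,
    neg_control_stats,
    percent_control_viability,
    toxicity_filter,
    zscore,
)
from mirloh.screen import NegControlStats


def wells_frame(luminescence_by_role, plate="P1", treatment="drug"):
    rows = []
    for (role, content), values in luminescence_by_role.items():
        for i, v in enumerate(values):
            rows.append((plate, f"W{i:03d}", content, role, treatment, v))
    return pd.DataFrame(
        rows,
        columns=["plate_id", "well", "content_id", "role", "treatment", "luminescence"],
    )


class TestNegControlStats:
    def test_two_point_formula(self):
        wells = wells_frame({("neg_control", "neg"): [90.0, 110.0]})
        stats = neg_control_stats(wells, "P1", "drug")
        assert stats.mu == 100.0
        assert stats.sigma == pytest.approx(14.142, abs=1e-3)
        assert stats.n == 2

    def test_degenerate_sigma_rejected(self):
        wells = wells_frame({("neg_control", "neg"): [100.0, 100.0]})
        with pytest.raises(ValueError, match="SD is zero"):
            neg_control_stats(wells, "P1", "drug")

    def test_single_control_rejected(self):
        wells = wells_frame({("neg_control", "neg"): [100.0]})
        with pytest.raises(ValueError, match=">= 2"):
            neg_control_stats(wells, "P1", "drug")

    def test_moments_match_generator(self):
        rng = np.random.default_rng(0)
        cv = 0.1
        sigma_log = np.sqrt(np.log1p(cv**2))
        values = 100.0 * rng.lognormal(-sigma_log**2 / 2, sigma_log, size=1000)
        wells = wells_frame({("neg_control", "neg"): values})
        stats = neg_control_stats(wells, "P1", "drug")
        assert stats.mu == pytest.approx(100.0, rel=0.02)
        assert stats.sigma == pytest.approx(100.0 * cv, rel=0.1)


class TestNormalization:
    stats = NegControlStats("P1", "drug", mu=100.0, sigma=10.0, n=8)

    def test_percent_viability(self):
        assert percent_control_viability(100.0, self.stats) == 100.0
        assert percent_control_viability(0.0, self.stats) == 0.0
        assert percent_control_viability(75.0, self.stats) == 75.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_control_viability(
                10.0, NegControlStats("P1", "drug", mu=0.0, sigma=1.0, n=2)
            )

    def test_zscore_centering_and_threshold_value(self):
        assert zscore(100.0, self.stats) == 0.0
        assert zscore(80.0, self.stats) == -2.0

    def test_zscore_affine_invariance(self):
        # rescaling every luminescence on a plate leaves z unchanged
        rng = np.random.default_rng(1)
        x = rng.uniform(50, 150, size=20)
        for c in (2.0, 0.5):
            scaled = NegControlStats(
                "P1", "drug", mu=self.stats.mu * c, sigma=self.stats.sigma * c, n=8
            )
            for xi in x:
                assert zscore(xi * c, scaled) == pytest.approx(zscore(xi, self.stats))


class TestToxicity:
    def test_loss_at_least_brca2_is_toxic(self):
        assert toxicity_filter(50.0, 60.0)

    def test_healthy_mimic_not_toxic(self):
        assert not toxicity_filter(95.0, 60.0)

    def test_exact_equality_is_toxic(self):
        assert toxicity_filter(60.0, 60.0)


class TestHitCalling:
    def make_results(self, rows):
        return pd.DataFrame(
            rows, columns=["mimic", "pct_viability_drug", "z", "toxic"]
        )

    def test_empty_input(self, params):
        hits = call_hits(self.make_results([]), params)
        assert hits.empty

    def test_forced_hit(self, params):
        res = self.make_results([("m1", 50.0, -3.0, False)])
        hits = call_hits(res, params)
        assert hits["mimic"].tolist() == ["m1"]
        assert hits["rank"].tolist() == [1.0]

    def test_boundaries_are_strict(self, params):
        res = self.make_results(
            [
                ("at-cutoffs", 75.0, -2.0, False),  # neither strict inequality holds
                ("below", 74.9, -2.01, False),
                ("toxic", 40.0, -5.0, True),
            ]
        )
        hits = call_hits(res, params)
        assert hits["mimic"].tolist() == ["below"]

    def test_ranking_order(self, params):
        res = self.make_results(
            [
                ("b", 50.0, -4.0, False),
                ("a", 50.0, -4.0, False),  # tie on pct and z -> id order
                ("c", 40.0, -3.0, False),
                ("d", 50.0, -5.0, False),  # tie on pct -> lower z first
            ]
        )
        hits = call_hits(res, params)
        assert hits["mimic"].tolist() == ["c", "d", "a", "b"]

    def test_loosening_z_cutoff_only_adds_hits(self, params):
        rng = np.random.default_rng(3)
        res = self.make_results(
            [
                (f"m{i}", rng.uniform(30, 120), rng.uniform(-6, 2), False)
                for i in range(200)
            ]
        )
        tight = set(call_hits(res, AnalysisParams(z_cutoff=-2.5))["mimic"])
        loose = set(call_hits(res, AnalysisParams(z_cutoff=-1.5))["mimic"])
        assert tight <= loose


class TestPlantedRecovery:
    def test_all_planted_hits_no_false_positives(self, screen_sim, params):
        plates, truth = screen_sim
        results = analyze_screen(plates, params)
        called = set(results.loc[results["hit"], "mimic"])
        assert called == truth.planted_hit_ids
        # independent re-check of the thresholds on the scored table
        recheck = results[
            (~results["toxic"])
            & (results["z"] < params.z_cutoff)
            & (results["pct_viability_drug"] < params.viability_cutoff_pct)
        ]
        assert set(recheck["mimic"]) == called

    def test_toxic_mimics_flagged_and_never_hits(self, screen_sim, params):
        plates, truth = screen_sim
        results = analyze_screen(plates, params)
        flagged = set(results.loc[results["toxic"], "mimic"])
        assert flagged == truth.toxic_ids
        assert not (results["toxic"] & results["hit"]).any()

    def test_negative_control_z_mean_zero_sd_one(self, screen_sim):
        from mirloh.screen import neg_control_stats, zscore

        plates, _ = screen_sim
        for plate in plates["plate_id"].unique():
            stats = neg_control_stats(plates, plate, "drug")
            negs = plates[
                (plates["plate_id"] == plate)
                & (plates["treatment"] == "drug")
                & (plates["role"] == "neg_control")
            ]["luminescence"]
            zs = np.array([zscore(x, stats) for x in negs])
            assert zs.mean() == pytest.approx(0.0, abs=1e-12)
            assert zs.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_brca2_z_reference_mode_runs(self, screen_sim, params):
        plates, truth = screen_sim
        results = analyze_screen(plates, params, z_reference="brca2")
        # BRCA2-siRNA drug-arm viability (20%) sits far below the planted
        # hits (50%), so the positive-control Z cutoff calls no hits here
        called = set(results.loc[results["hit"], "mimic"])
        assert called <= truth.planted_hit_ids


class TestFoldEnrichment:
    def test_null_enrichment(self):
        assert fold_enrichment(2.0, 2.0, 2.0, 2.0) == 1.0

    def test_arithmetic(self):
        assert fold_enrichment(8.0, 2.0, 2.0, 2.0) == 4.0

    def test_pulldown_scaling_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.uniform(0.1, 10.0, size=4)
            k = rng.uniform(0.1, 10.0)
            assert fold_enrichment(a * k, b * k, c, d) == pytest.approx(
                fold_enrichment(a, b, c, d)
            )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(0.0, 1.0, 1.0, 1.0)
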