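"""LOH classification: coverage rule, SNP rule, boundaries, partition."""

import numpy as np
import pandas as pd
import pytest

from mirloh import AnalysisParams, classify_acgh, classify_snp, cnloh_count_per_sample
from mirloh.loh import LABEL_DELETION, LABEL_NEUTRAL, LABEL_UNLABELLED, covered_fraction
from mirloh.simulate import boundary_fixtures

from conftest import make_cn, make_events, make_markers


class TestCoveredFraction:
    def test_no_overlap(self):
        assert covered_fraction(0, 1000, [2000], [3000]) == 0.0

    def test_containment(self):
        assert covered_fraction(100, 1100, [0], [5000]) == 1.0

    def test_union_not_double_counted(self):
        assert covered_fraction(0, 1000, [0, 400], [500, 900]) == pytest.approx(0.9)


class TestAcghRule:
    def test_forced_labels(self, params):
        events = make_events(
            [
                ("s1", "chr1", 0, 2_000_000),  # 85% covered by deep deletion
                ("s1", "chr2", 0, 2_000_000),  # 10% covered
                ("s1", "chr3", 0, 500_000),  # uncovered but too small
            ]
        )
        cn = make_cn(
            [
                ("s1", "chr1", 0, 1_700_000, -0.5),
                ("s1", "chr2", 0, 200_000, -0.5),
            ]
        )
        out = classify_acgh(events, cn, params).set_index("chrom")
        assert out.loc["chr1", "label"] == LABEL_DELETION
        assert not out.loc["chr1", "retained"]
        assert out.loc["chr2", "label"] == LABEL_NEUTRAL
        assert out.loc["chr2", "retained"]
        assert out.loc["chr3", "label"] == LABEL_NEUTRAL
        assert not out.loc["chr3", "retained"]

    def test_segments_of_other_samples_ignored(self, params):
        events = make_events([("s1", "chr1", 0, 2_000_000)])
        cn = make_cn([("s2", "chr1", 0, 2_000_000, -0.5)])
        out = classify_acgh(events, cn, params)
        assert out.loc[0, "label"] == LABEL_NEUTRAL
        assert out.loc[0, "covered_fraction"] == 0.0

    def test_raising_del_threshold_moves_only_toward_deletion(self):
        rng = np.random.default_rng(11)
        events = make_events(
            [("s1", "chr1", i * 10_000, i * 10_000 + 5_000) for i in range(100)]
        )
        cn = make_cn(
            [
                (
                    "s1",
                    "chr1",
                    i * 10_000,
                    i * 10_000 + int(rng.uniform(3500, 5000)),
                    float(rng.uniform(-0.5, 0.1)),
                )
                for i in range(100)
            ]
        )
        strict = classify_acgh(events, cn, AnalysisParams(del_log2_threshold=-0.30))
        loose = classify_acgh(events, cn, AnalysisParams(del_log2_threshold=-0.10))
        was_del = set(strict.index[strict["label"] == LABEL_DELETION])
        now_del = set(loose.index[loose["label"] == LABEL_DELETION])
        assert was_del <= now_del


class TestSnpRule:
    def test_fraction_boundary_and_below(self, params):
        # 10 markers, 8 low -> n/N = 0.8 exactly -> deletion-mediated
        events = make_events([("s1", "chr1", 0, 100_000)])
        markers8 = make_markers(
            [("s1", "chr1", 5_000 + 10_000 * i, 1.0 if i < 8 else 2.0) for i in range(10)]
        )
        out = classify_snp(events, markers8, params)
        assert out.loc[0, "label"] == LABEL_DELETION
        assert out.loc[0, "n_markers"] == 10 and out.loc[0, "n_low"] == 8

        markers7 = make_markers(
            [("s1", "chr1", 5_000 + 10_000 * i, 1.0 if i < 7 else 2.0) for i in range(10)]
        )
        out = classify_snp(events, markers7, params)
        assert out.loc[0, "label"] == LABEL_NEUTRAL

    def test_no_marker_event_excluded_with_warning(self, params, caplog):
        events = make_events([("s1", "chr1", 0, 100_000)])
        markers = make_markers([("s1", "chr2", 50_000, 1.0)])
        with caplog.at_level("WARNING"):
            out = classify_snp(events, markers, params)
        assert out.loc[0, "label"] == LABEL_UNLABELLED
        assert not out.loc[0, "retained"]
        assert "no marker" in caplog.text

    def test_unsorted_markers_rejected(self, params):
        events = make_events([("s1", "chr1", 0, 100_000)])
        markers = make_markers(
            [("s1", "chr1", 50_000, 1.0), ("s1", "chr1", 10_000, 1.0)]
        )
        with pytest.raises(ValueError, match="not.*sorted"):
            classify_snp(events, markers, params)

    def test_labels_match_independent_recount(self, params):
        """100 random events labelled identically by a brute-force recount."""
        rng = np.random.default_rng(2)
        events = make_events(
            [
                (
                    "s1",
                    "chr1",
                    s := int(rng.integers(0, 10**7)),
                    s + int(rng.integers(5_000, 200_000)),
                )
                for _ in range(100)
            ]
        )
        pos = np.sort(rng.choice(10**7 + 10**6, size=3000, replace=False))
        cn = rng.choice([1.0, 2.0], size=3000, p=[0.5, 0.5])
        markers = make_markers(
            [("s1", "chr1", int(p), float(c)) for p, c in zip(pos, cn)]
        )
        out = classify_snp(events, markers, params)
        for _, row in out.iterrows():
            if row["end"] - row["start"] <= params.min_loh_size_snp:
                assert row["label"] == LABEL_UNLABELLED
                continue
            inside = (pos >= row["start"]) & (pos < row["end"])
            N = int(inside.sum())
            if N == 0:
                assert row["label"] == LABEL_UNLABELLED
                continue
            n = int((cn[inside] < params.snp_cn_threshold).sum())
            expected = (
                LABEL_DELETION if n / N >= params.snp_frac_cutoff else LABEL_NEUTRAL
            )
            assert row["label"] == expected
            assert row["n_markers"] == N and row["n_low"] == n


class TestBoundaryFixtures:
    """The printed strict/non-strict inequalities, pinned one by one."""

    @pytest.mark.parametrize(
        "name",
        ["acgh_coverage_exact_080", "acgh_log2_exact_threshold", "acgh_size_exact_1mb"],
    )
    def test_acgh_boundaries(self, name, params):
        fx = boundary_fixtures()[name]
        out = classify_acgh(fx["events"], fx["cn"], params)
        assert out.loc[0, "label"] == fx["expected_label"]
        assert bool(out.loc[0, "retained"]) == fx["expected_retained"]

    @pytest.mark.parametrize(
        "name", ["snp_frac_exact_080", "snp_cn_exact_19", "snp_size_exact_10kb"]
    )
    def test_snp_boundaries(self, name, params):
        fx = boundary_fixtures()[name]
        out = classify_snp(fx["events"], fx["markers"], params)
        assert out.loc[0, "label"] == fx["expected_label"]


class TestPartitionAndCounts:
    def test_every_event_gets_exactly_one_outcome(self, cohort_sim, params):
        data, _ = cohort_sim
        for labelled in (
            classify_acgh(data.loh, data.cn, params),
            classify_snp(data.loh, data.markers, params),
        ):
            assert len(labelled) == len(data.loh)
            assert set(labelled["label"]) <= {
                LABEL_DELETION,
                LABEL_NEUTRAL,
                LABEL_UNLABELLED,
            }
            # retained implies copy-neutral; deletion-mediated never retained
            assert not (
                labelled["retained"] & (labelled["label"] != LABEL_NEUTRAL)
            ).any()

    def test_cnloh_counts_match_truth_tallies(self, params):
        from mirloh import simulate_cohort

        data, truth = simulate_cohort(
            n_wt=6, n_del=2, layers=("loh", "cn"), seed=3
        )
        labelled = classify_acgh(data.loh, data.cn, params)
        counts = cnloh_count_per_sample(labelled, samples=data.samples)
        expected = (
            truth.events[
                (truth.events["true_label"] == "copy_neutral")
                & truth.events["above_1mb"]
            ]
            .groupby("sample")
            .size()
            .reindex(data.samples, fill_value=0)
        )
        assert (counts == expected).all()

    def test_zero_event_samples_appear_with_zero(self, params):
        labelled = classify_acgh(
            make_events([("s1", "chr1", 0, 2_000_000)]),
            make_cn([]),
            params,
        )
        counts = cnloh_count_per_sample(labelled, samples=["s1", "s2"])
        assert counts["s1"] == 1
        assert counts["s2"] == 0


class TestSensitivityCutoff:
    def test_080_deletion_set_subset_of_075(self, cohort_sim):
        data, _ = cohort_sim
        at_080 = classify_snp(data.loh, data.markers, AnalysisParams())
        at_075 = classify_snp(
            data.loh, data.markers, AnalysisParams(snp_frac_cutoff=0.75)
        )
        set_080 = set(at_080.index[at_080["label"] == LABEL_DELETION])
        set_075 = set(at_075.index[at_075["label"] == LABEL_DELETION])
        assert set_080 <= set_075
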