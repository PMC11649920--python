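"""RIP-seq enrichment tests: pipeline arithmetic, invariances, Welch test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from padk import ripseq, synthetic


class TestComputeEnrichment:
    def test_toy_matrix_matches_hand_arithmetic(self):
        """Six-feature fixture: expected enrichments by direct arithmetic.

        Every input replicate has total 1000·c and f1 count 100·c, every IP
        replicate total 1300·c and f1 count 400·c, so the f1 enrichment is
        log2((400/1300)/(100/1000)) = log2(40/13) and every other feature is
        log2(10/13); the single purification median-centers to zero.
        """
        counts, samples = synthetic.ripseq_toy_matrix()
        result = ripseq.compute_enrichment(counts, samples)
        expected_f1 = math.log2(40 / 13)
        expected_rest = math.log2(10 / 13)
        uncentered = result.uncentered["IP"]
        assert uncentered["f1"] == pytest.approx(expected_f1, abs=1e-12)
        for f in ["f2", "f3", "f4", "f5", "f6"]:
            assert uncentered[f] == pytest.approx(expected_rest, abs=1e-12)
        # single purification: per-feature median centering zeroes everything
        assert result.enrichment["IP"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_ip_equal_to_input_gives_zero(self):
        counts, samples = synthetic.ripseq_toy_matrix()
        for rep in (1, 2, 3):
            counts[f"IP_rep{rep}"] = counts[f"input_rep{rep}"]
        result = ripseq.compute_enrichment(counts, samples)
        assert result.uncentered["IP"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_low_count_features_filtered(self):
        counts, samples = synthetic.ripseq_toy_matrix()
        counts.loc[2, "IP_rep2"] = 9  # below the 10-read floor in one sample
        result = ripseq.compute_enrichment(counts, samples)
        assert result.n_features_filtered == 1
        assert "f3" not in result.enrichment.index

    def test_depth_invariance(self):
        """Multiplying one sample's counts by an integer changes nothing
        after the per-sample total normalization."""
        counts, samples = synthetic.ripseq_toy_matrix()
        base = ripseq.compute_enrichment(counts, samples)
        counts["IP_rep1"] = counts["IP_rep1"] * 3
        scaled = ripseq.compute_enrichment(counts, samples)
        pd.testing.assert_frame_equal(base.uncentered, scaled.uncentered)

    def test_median_centering_invariant(self):
        """With several purifications, each feature's median across the
        centered enrichment columns is zero."""
        counts, samples, _ = synthetic.gen_ripseq(n_features=50, seed=2)
        counts2, samples2, _ = synthetic.gen_ripseq(
            n_features=50, enriched=frozenset(range(10)), seed=3
        )
        ip2 = samples2.loc[~samples2["is_input"]].copy()
        renames = {
            row["sample"]: f"IP2_rep{row['replicate']}" for _, row in ip2.iterrows()
        }
        merged_counts = counts.join(counts2[list(renames)].rename(columns=renames))
        ip2["sample"] = ip2["sample"].map(renames)
        ip2["condition"] = "IP2"
        merged_samples = pd.concat([samples, ip2], ignore_index=True)
        result = ripseq.compute_enrichment(merged_counts, merged_samples)
        medians = result.enrichment.median(axis=1)
        assert medians.abs().max() < 1e-12

    def test_permutation_safety(self):
        counts, samples = synthetic.ripseq_toy_matrix()
        shuffled = counts.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = ripseq.compute_enrichment(counts, samples).uncentered.sort_index()
        b = ripseq.compute_enrichment(shuffled, samples).uncentered.sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestRawEnrichment:
    def test_fraction_doubling_is_one(self):
        """Totals 1e6 vs 2e6 with equal counts: the IP fraction is half the
        input fraction... built the other way: count fraction doubles."""
        counts = pd.DataFrame(
            {
                "feature_id": ["f1", "f2"],
                "input_rep1": [100, 2_000_000 - 100],
                "IP_rep1": [100, 1_000_000 - 100],
            }
        )
        samples = pd.DataFrame(
            {
                "sample": ["input_rep1", "IP_rep1"],
                "condition": ["input", "IP"],
                "replicate": [1, 1],
                "is_input": [True, False],
            }
        )
        raw = ripseq.raw_enrichment(counts, samples)
        f1 = raw.loc[raw["feature_id"] == "f1", "raw_log2_enrichment"].iloc[0]
        assert f1 == pytest.approx(1.0, abs=1e-9)

    def test_equal_fractions_give_zero(self):
        counts, samples = synthetic.ripseq_toy_matrix()
        for rep in (1, 2, 3):
            counts[f"IP_rep{rep}"] = counts[f"input_rep{rep}"]
        raw = ripseq.raw_enrichment(counts, samples)
        assert raw["raw_log2_enrichment"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_zero_counts_skipped_and_counted(self):
        counts, samples = synthetic.ripseq_toy_matrix()
        counts.loc[0, "IP_rep1"] = 0
        raw = ripseq.raw_enrichment(counts, samples)
        assert raw.attrs["n_skipped_zero"] == 1
        skipped = raw[(raw["feature_id"] == "f1") & (raw["replicate"] == 1)]
        assert skipped["raw_log2_enrichment"].isna().all()


class TestCategoryTest:
    @staticmethod
    def long_table(values_a, values_b):
        features = [f"a{i}" for i in range(len(values_a))] + [
            f"b{i}" for i in range(len(values_b))
        ]
        table = pd.DataFrame(
            {
                "feature_id": features,
                "purification": "IP",
                "log2_enrichment": np.concatenate([values_a, values_b]),
            }
        )
        cats = pd.Series(
            ["grpA"] * len(values_a) + ["grpB"] * len(values_b), index=features
        )
        return table, cats

    def test_identical_groups(self):
        v = np.linspace(-1, 1, 20)
        table, cats = self.long_table(v, v)
        report = ripseq.category_test(table, cats, "grpA", "grpB")
        assert report["t_statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert report["p_value"].iloc[0] == pytest.approx(1.0)

    def test_shifted_groups_highly_significant(self):
        rng = np.random.default_rng(17)
        table, cats = self.long_table(
            rng.normal(0, 1, 200), rng.normal(1, 1, 200)
        )
        report = ripseq.category_test(table, cats, "grpA", "grpB")
        assert report["p_value"].iloc[0] < 1e-10
        # quartile summaries match the raw data
        assert report["median_grpA"].iloc[0] == pytest.approx(
            np.median(table["log2_enrichment"][:200])
        )

    def test_welch_equals_student_for_equal_variances_and_sizes(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 50)
        b = a + 0.4  # identical sample variance, equal sizes
        table, cats = self.long_table(a, b)
        report = ripseq.category_test(table, cats, "grpA", "grpB")
        t_student, p_student = stats.ttest_ind(a, b, equal_var=True)
        assert report["t_statistic"].iloc[0] == pytest.approx(t_student, abs=1e-9)
        assert report["p_value"].iloc[0] == pytest.approx(p_student, abs=1e-9)

    def test_degenerate_group_gets_summary_only(self):
        table, cats = self.long_table(np.array([0.5]), np.linspace(0, 1, 10))
        report = ripseq.category_test(table, cats, "grpA", "grpB")
        assert math.isnan(report["p_value"].iloc[0])
        assert report["n_grpA"].iloc[0] == 1
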