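"""SNP filters, masking, metrics, ROC and the scenario evaluation loop."""

import numpy as np
import pandas as pd
import pytest

from iqspred.scenario import (
    apply_snp_filters,
    filtering_labels,
    mask_training_snps,
    regression_metrics,
    roc_auc,
    run_scenario,
)


def auc_pair_count_oracle(scores, labels):
    """Mann-Whitney AUC by exhaustive pair counting (concordant + half ties)."""
    s = -np.asarray(scores, float)  # low quality ranks as more positive
    pos = s[np.asarray(labels, bool)]
    neg = s[~np.asarray(labels, bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


class TestFilters:
    def test_maf_strict_inequality_boundary(self):
        snps = pd.DataFrame(
            {"panel_maf": [0.009, 0.01, 0.011, 0.005, 0.3]},
            index=[f"s{i}" for i in range(5)],
        )
        retained, log = apply_snp_filters(snps)
        assert list(retained) == ["s1", "s2", "s4"]  # == 0.01 is kept
        assert log["maf_below_threshold"] == 2 and log["retained"] == 3

    def test_strand_flip_reconciled_and_irreconcilable_dropped(self):
        snps = pd.DataFrame(
            {
                "panel_maf": [0.2, 0.2],
                "platform_a": ["A", "A"],
                "platform_b": ["C", "G"],
                "panel_a": ["G", "A"],   # A/C complements to T/G = G/T
                "panel_b": ["T", "C"],
            },
            index=["flip_ok", "bad"],
        )
        retained, log = apply_snp_filters(snps)
        assert list(retained) == ["flip_ok"]
        assert log["inconsistent_alleles"] == 1

    def test_ambiguous_at_snp_dropped_near_half_frequency(self):
        snps = pd.DataFrame(
            {
                "panel_maf": [0.45, 0.2],
                "platform_a": ["A", "A"],
                "platform_b": ["T", "T"],
                "panel_a": ["A", "A"],
                "panel_b": ["T", "T"],
                "platform_freq": [0.45, 0.2],
                "panel_freq": [0.55, 0.21],
            },
            index=["ambig_5050", "ambig_clear"],
        )
        retained, _ = apply_snp_filters(snps)
        assert list(retained) == ["ambig_clear"]

    def test_undefined_iqs_dropped_when_supplied(self):
        snps = pd.DataFrame({"panel_maf": [0.2, 0.3]}, index=["a", "b"])
        sc = pd.Series([0.5, np.nan], index=["a", "b"])
        retained, log = apply_snp_filters(snps, drop_undefined_iqs=sc)
        assert list(retained) == ["a"] and log["undefined_iqs"] == 1


class TestMasking:
    def test_exact_count_partition_and_determinism(self):
        ids = [f"snp{i}" for i in range(1000)]
        kept, masked = mask_training_snps(ids, fraction=0.1, seed=5)
        assert len(masked) == 100
        assert sorted(kept + masked) == sorted(ids)
        assert set(kept).isdisjoint(masked)
        again = mask_training_snps(ids, fraction=0.1, seed=5)
        assert again == (kept, masked)

    def test_bad_fraction_errors(self):
        with pytest.raises(ValueError, match="fraction"):
            mask_training_snps([str(i) for i in range(20)], fraction=1.5)


class TestMetrics:
    def test_examples(self):
        assert regression_metrics([1, 2, 3], [1, 2, 3]) == (0.0, pytest.approx(1.0))
        mse, r = regression_metrics([1.0, 2.0], [1.1, 2.1])
        assert mse == pytest.approx(0.01) and r == pytest.approx(1.0)
        mse, r = regression_metrics([0.0, 1.0], [1.0, 0.0])
        assert mse == pytest.approx(1.0) and r == pytest.approx(-1.0)

    def test_constant_vector_gives_nan_r(self):
        mse, r = regression_metrics([1.0, 1.0], [0.5, 0.7])
        assert np.isnan(r)


class TestFilteringLabels:
    def test_strict_below_threshold(self):
        labels = filtering_labels([0.49, 0.5, 0.51], 0.5)
        assert list(labels) == [True, False, False]

    def test_threshold_monotonicity(self, rng):
        iqs_vals = rng.random(50)
        low = filtering_labels(iqs_vals, 0.5)
        high = filtering_labels(iqs_vals, 0.9)
        assert np.all(high[low])  # 0.9-positives are a superset

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="defined"):
            filtering_labels([0.5, np.nan], 0.5)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])  # low score = bad SNP
        labels = np.array([False, False, True, True])
        assert roc_auc(scores, labels)[2] == 1.0

    def test_independent_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.5
        assert roc_auc(scores, labels)[2] == pytest.approx(0.5, abs=0.05)

    def test_matches_pair_count_oracle(self, rng):
        """AUC equals the exhaustive Mann-Whitney count on 200 random instances."""
        for _ in range(200):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.random(n), 1)  # coarse grid to force ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels)[2] == pytest.approx(
                auc_pair_count_oracle(scores, labels), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [True, True])


class TestRunScenario:
    def test_report_structure_and_bookkeeping(self, small_fixture):
        train, test = small_fixture
        report, preds, models = run_scenario(train, test)
        d = report.to_dict()
        assert set(d["regression"]) == {"IQS", "Po", "Pc"}
        for kind in d["regression"]:
            assert 0 <= d["regression"][kind]["mse"]
        log = d["counts"]["test"]
        assert log["retained"] == log["used_for_testing"]
        assert log["input"] == test.n_snps
        for thr, entry in d["filtering"].items():
            for v in entry.values():
                assert 0.0 <= v <= 1.0
        assert len(preds) == log["used_for_testing"]

    def test_fixed_seeds_give_identical_reports(self, small_fixture):
        train, test = small_fixture
        a = run_scenario(train, test, seed=3)[0].to_json()
        b = run_scenario(train, test, seed=3)[0].to_json()
        assert a == b

    def test_in_distribution_beats_shifted_test(self, small_fixture):
        """Testing on the training scenario's own SNPs is at least as easy."""
        train, test = small_fixture
        r_shift = run_scenario(train, test, targets=("IQS",))[0]
        r_self = run_scenario(train, train, targets=("IQS",))[0]
        assert (
            r_self.regression["IQS"]["pearson_r"]
            >= r_shift.regression["IQS"]["pearson_r"] - 0.05
        )

    def test_file_round_trip_preserves_report(self, small_fixture, tmp_path):
        from iqspred.scenario import ImputationScenario

        train, test = small_fixture
        scns = {}
        for name, scn in (("train", train), ("test", test)):
            paths = scn.write_files(tmp_path, name)
            scns[name] = ImputationScenario.from_files(
                truth=paths["truth"], gprobs=paths["gprobs"],
                annotation=paths["annotation"], typed=paths["typed"],
                panel_counts=paths["panel_counts"], baf_truth=paths["baf_truth"],
                hotspots=paths["hotspots"],
            )
        direct = run_scenario(train, test)[0].to_json()
        via_files = run_scenario(scns["train"], scns["test"])[0].to_json()
        assert direct == via_files
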