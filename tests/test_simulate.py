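"""Synthetic-scenario generator: recombination structure, study sampling,
surrogate imputation, and fixture construction."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from iqspred.iqs import build_contingency, iqs as compute_iqs
from iqspred.simulate import (
    SimulationParams,
    build_fixture,
    generate_panel,
    sample_study,
    scaled_params,
    surrogate_impute,
)

SMALL = scaled_params(0.125, seed=11)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationParams(n_founders=0)
        with pytest.raises(ValueError):
            SimulationParams(mask_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationParams(decay_scale_bp=0)


class TestGeneratePanel:
    def test_deterministic_given_seed(self):
        a = generate_panel(SMALL)
        b = generate_panel(SMALL)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)
        c = generate_panel(dataclasses.replace(SMALL, seed=99))
        assert not np.array_equal(a.haplotypes, c.haplotypes)

    def test_alleles_binary_positions_increasing_maf_floor(self):
        p = generate_panel(SMALL)
        assert set(np.unique(p.haplotypes)) <= {0, 1}
        assert np.all(np.diff(p.positions) > 0)
        # founder frequencies respect the MAF floor; realized panel MAF is close
        assert p.maf.min() >= 0.0 and p.maf.max() <= 0.5

    def test_hotspot_odds_one_is_null(self):
        """odds=1: switch rates indistinguishable between interval classes."""
        hot_n = bg_n = hot_k = bg_k = 0
        for rep in range(50):
            params = dataclasses.replace(
                SMALL, hotspot_odds=1.0, p_switch_bg=0.01, seed=1000 + rep,
                n_haplotypes=40,
            )
            panel = generate_panel(params)
            mask = panel.interval_has_hotspot()
            sw = panel.switch_events
            hot_k += sw[:, mask].sum(); hot_n += sw[:, mask].size
            bg_k += sw[:, ~mask].sum(); bg_n += sw[:, ~mask].size
        table = [[hot_k, hot_n - hot_k], [bg_k, bg_n - bg_k]]
        _, pval = sps.chi2_contingency(table)[:2]
        assert pval > 0.01

    def test_hotspot_odds_concentrate_switches(self):
        """odds=50: hotspot intervals switch more in every replicate."""
        for rep in range(20):
            params = dataclasses.replace(
                SMALL, hotspot_odds=50.0, p_switch_bg=0.005, seed=2000 + rep,
                n_haplotypes=40,
            )
            panel = generate_panel(params)
            mask = panel.interval_has_hotspot()
            sw = panel.switch_events
            assert sw[:, mask].mean() > sw[:, ~mask].mean()


class TestSampleStudy:
    def test_genotypes_in_range_and_deterministic(self):
        panel = generate_panel(SMALL)
        g = sample_study(panel, 1, seed=4)
        assert g.shape == (1, SMALL.n_snps)
        assert set(np.unique(g)) <= {0, 1, 2}
        assert np.array_equal(g, sample_study(panel, 1, seed=4))

    def test_study_frequencies_track_panel(self):
        """Study allele frequency within 3 binomial SE of panel for >=95% of SNPs."""
        panel = generate_panel(SMALL)
        n = 200
        g = sample_study(panel, n, seed=5)
        f_study = g.mean(axis=0) / 2
        f_panel = panel.allele_freq
        se = np.sqrt(np.maximum(f_panel * (1 - f_panel), 1e-6) / (2 * n))
        ok = np.abs(f_study - f_panel) <= 3 * se
        assert ok.mean() >= 0.95


class TestSurrogateImpute:
    def setup_method(self):
        self.panel = generate_panel(SMALL)
        self.truth = sample_study(self.panel, 150, seed=6)
        rng = np.random.default_rng(0)
        m = SMALL.n_snps
        self.typed = np.sort(rng.choice(m, size=m // 2, replace=False))
        self.masked = np.setdiff1d(np.arange(m), self.typed)[:40]

    def test_posteriors_normalized(self):
        post = surrogate_impute(self.truth, self.panel, self.typed, self.masked, SMALL)
        assert post.shape == (40, 150, 3)
        assert np.allclose(post.sum(axis=2), 1.0, atol=1e-9)
        assert post.min() >= 0

    def test_perfect_ld_neighbor_pins_posterior(self):
        """A masked SNP duplicating an adjacent typed column is imputed almost surely."""
        panel = generate_panel(SMALL)
        masked = int(self.masked[5])
        # make a typed neighbor a perfect copy of the masked SNP, 1 bp away
        neighbor = int(self.typed[np.argmin(np.abs(panel.positions[self.typed]
                                                    - panel.positions[masked]))])
        panel.haplotypes[:, neighbor] = panel.haplotypes[:, masked]
        panel.positions[neighbor] = panel.positions[masked] + 1
        order = np.argsort(panel.positions)
        assert np.all(np.diff(panel.positions[order]) >= 0)
        truth = sample_study(panel, 150, seed=8)
        post = surrogate_impute(truth, panel, self.typed,
                                np.array([masked]), SMALL)[0]
        # crossovers in the 1 bp between the two columns are essentially absent
        p_true = post[np.arange(150), truth[:, masked]]
        assert (p_true >= 0.95).mean() >= 0.95

    def test_zero_alpha_limit_is_hardy_weinberg(self):
        params = dataclasses.replace(SMALL, decay_scale_bp=1e-6)  # alpha -> 0
        post = surrogate_impute(self.truth, self.panel, self.typed,
                                self.masked[:5], params)
        for k, mi in enumerate(self.masked[:5]):
            f = self.panel.allele_freq[mi]
            hw = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
            assert np.allclose(post[k], hw / hw.sum(), atol=1e-9)

    def test_typed_masked_overlap_rejected(self):
        with pytest.raises(ValueError, match="masked"):
            surrogate_impute(self.truth, self.panel, self.typed,
                             self.typed[:3], SMALL)
        with pytest.raises(ValueError, match="typed set is empty"):
            surrogate_impute(self.truth, self.panel, np.array([], dtype=int),
                             self.masked, SMALL)


class TestBuildFixture:
    def test_train_test_disjoint_and_reproducible(self, small_fixture):
        train, test = small_fixture
        assert set(train.snp_ids).isdisjoint(test.snp_ids)
        train2, test2 = build_fixture(scaled_params(0.25, seed=11))
        assert train2.snp_ids == train.snp_ids
        assert np.array_equal(train2.posteriors, train.posteriors)
        assert np.array_equal(test2.truth, test.truth)

    def test_changing_seed_changes_outputs(self, small_fixture):
        train, _ = small_fixture
        other, _ = build_fixture(scaled_params(0.125, seed=12))
        assert not np.array_equal(other.posteriors, train.posteriors)

    def test_mask_is_ten_percent_of_old_platform(self, small_fixture):
        train, test = small_fixture
        n_old = train.typed_positions[1].size + train.n_snps
        assert train.n_snps == round(0.1 * n_old)

    def test_iqs_span_crosses_both_filter_thresholds(self, reference_fixture):
        """The reference fixture exercises both the 0.5 and 0.9 thresholds."""
        _, test = reference_fixture
        iqs_vals = test.scores()["iqs"].dropna()
        assert (iqs_vals < 0.5).any()
        assert (iqs_vals > 0.9).any()

    def test_quality_linked_to_features(self, reference_fixture):
        """IQS falls with distance to typed SNPs and rises with mean posterior."""
        _, test = reference_fixture
        sc = test.scores()["iqs"]
        feats = test.feature_matrix()
        ok = sc.notna()
        rho_dist = sps.spearmanr(feats.loc[ok, "dist_nearest_typed_bp"], sc[ok]).statistic
        rho_post = sps.spearmanr(feats.loc[ok, "mean_posterior"], sc[ok]).statistic
        assert rho_dist <= -0.2
        assert rho_post >= 0.2

    def test_soft_scores_consistent_with_tables(self, small_fixture):
        train, _ = small_fixture
        sc = train.scores()
        k = 0
        s = compute_iqs(build_contingency(train.truth[k], train.posteriors[k]))
        assert sc.iloc[k]["po"] == pytest.approx(s.po)
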