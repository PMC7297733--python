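"""Normalisation, batch correction, rank tests and multiple testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from mthijack.synthetic_cohort import simulate_expression_counts
from mthijack.transcript_abundance import (batch_correct, bh_adjust,
                                           group_abundance_change,
                                           mann_whitney,
                                           normalised_log_abundance,
                                           per_gene_differential, size_factors)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_scale_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=50)
        counts = pd.DataFrame({"s1": base, "s2": base * 2})
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_matches_independent_median_of_ratios(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 500, size=(40, 6)),
                              columns=[f"s{i}" for i in range(6)])
        sf = size_factors(counts)
        # oracle: hand median-of-ratios, then rescale to geometric mean 1
        mat = counts.to_numpy(float)
        geo = np.exp(np.log(mat).mean(axis=1))
        raw = np.median(mat / geo[:, None], axis=0)
        oracle = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(sf.to_numpy(), oracle)

    def test_no_universally_expressed_gene_rejected(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)


class TestBatchCorrect:
    def _frame(self, mat, samples):
        return pd.DataFrame(mat, columns=samples)

    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(2)
        log_ab = self._frame(rng.uniform(1, 10, (5, 4)), list("abcd"))
        batch = pd.Series(["b1"] * 4, index=list("abcd"))
        group = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        out = batch_correct(log_ab, batch, group)
        assert np.allclose(out, (2.0 ** log_ab - 1))

    def test_planted_offset_removed_exactly(self):
        """A pure additive batch shift leaves equal group means behind."""
        samples = [f"s{i}" for i in range(8)]
        gene_means = np.array([5.0, 8.0, 11.0])
        batch = pd.Series(["b1", "b2"] * 4, index=samples)
        group = pd.Series(["g1"] * 4 + ["g2"] * 4, index=samples)
        log_ab = np.tile(gene_means[:, None], (1, 8))
        log_ab[:, batch.to_numpy() == "b2"] += 1.0
        out = batch_correct(self._frame(log_ab, samples), batch, group)
        means_g1 = out.loc[:, group == "g1"].mean(axis=1)
        means_g2 = out.loc[:, group == "g2"].mean(axis=1)
        assert np.allclose(means_g1, means_g2, atol=1e-9)

    def test_group_effect_survives_batch_noise(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(40)]
        batch = pd.Series(["b1", "b2"] * 20, index=samples)
        group = pd.Series(["g1"] * 20 + ["g2"] * 20, index=samples)
        log_ab = rng.normal(8, 0.1, size=(6, 40))
        log_ab[:, batch.to_numpy() == "b2"] += 0.7
        log_ab[:, group.to_numpy() == "g2"] -= 1.0  # true group effect
        out = batch_correct(self._frame(log_ab, samples), batch, group)
        ratio = out.loc[:, group == "g2"].mean(axis=1) \
            / out.loc[:, group == "g1"].mean(axis=1)
        assert np.allclose(ratio, 2.0 ** -1.0, rtol=0.1)

    def test_confounded_design_rejected(self):
        samples = list("abcd")
        batch = pd.Series(["b1", "b1", "b2", "b2"], index=samples)
        group = pd.Series(["g1", "g1", "g2", "g2"], index=samples)
        log_ab = self._frame(np.ones((3, 4)), samples)
        with pytest.raises(ValueError, match="confounded"):
            batch_correct(log_ab, batch, group)


class TestMannWhitney:
    def test_exact_enumeration_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_identical_singletons(self):
        _, p = mann_whitney([1.0], [1.0])
        assert p == 1.0

    def test_large_shifted_groups_highly_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 200)
        b = rng.normal(3, 1, 200)
        _, p = mann_whitney(a, b)
        assert p < 1e-6

    def test_matches_scipy_in_both_regimes(self):
        rng = np.random.default_rng(5)
        small_a, small_b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 6)
        _, p_small = mann_whitney(small_a, small_b)
        ref_small = sstats.mannwhitneyu(small_a, small_b,
                                        alternative="two-sided",
                                        method="exact").pvalue
        assert p_small == pytest.approx(float(ref_small), abs=1e-9)
        big_a, big_b = rng.normal(0, 1, 30), rng.normal(0.3, 1, 25)
        _, p_big = mann_whitney(big_a, big_b)
        ref_big = sstats.mannwhitneyu(big_a, big_b, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert p_big == pytest.approx(float(ref_big), rel=1e-6)

    def test_type_one_error_calibrated_at_n10(self):
        rng = np.random.default_rng(6)
        n_sims, rejections = 4000, 0
        for _ in range(n_sims):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0, 1, 10)
            _, p = mann_whitney(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestBHAdjust:
    def test_stepup_hand_computation(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1, 1, 1]), 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 30)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_ref)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _workflow(cm):
    log_ab = normalised_log_abundance(cm.counts)
    return batch_correct(log_ab, cm.samples["batch"], cm.samples["group"])


class TestGroupComparison:
    def test_null_effect_gives_no_change(self):
        cm = simulate_expression_counts({"A1d1a": 10, "CTVT_HT": 10}, "A1d1a",
                                        effect_fraction=0.0, seed=9)
        corrected = _workflow(cm)
        pct, p = group_abundance_change(corrected, cm.samples, "A1d1a",
                                        "CTVT_HT", cm.gene_classes)
        assert abs(pct) < 12
        assert p > 0.05

    def test_planted_decrease_recovered(self):
        cm = simulate_expression_counts({"A1d1a": 15, "CTVT_HT": 15}, "A1d1a",
                                        effect_fraction=0.39, seed=10)
        corrected = _workflow(cm)
        pct, p = group_abundance_change(corrected, cm.samples, "A1d1a",
                                        "CTVT_HT", cm.gene_classes)
        assert pct == pytest.approx(39, abs=5)
        assert p < 0.05

    def test_nuclear_genes_unchanged(self):
        cm = simulate_expression_counts({"A1d1a": 15, "CTVT_HT": 15}, "A1d1a",
                                        effect_fraction=0.39, seed=11)
        corrected = _workflow(cm)
        pct, _ = group_abundance_change(corrected, cm.samples, "A1d1a",
                                        "CTVT_HT", cm.gene_classes,
                                        gene_class="nuclear")
        assert abs(pct) < 12

    def test_empty_gene_class_rejected(self):
        cm = simulate_expression_counts({"A1d1a": 5, "CTVT_HT": 5}, "A1d1a",
                                        seed=12)
        corrected = _workflow(cm)
        with pytest.raises(ValueError):
            group_abundance_change(corrected, cm.samples, "A1d1a", "CTVT_HT",
                                   cm.gene_classes, gene_class="missing")


class TestPerGeneDifferential:
    def test_planted_subset_detected_exactly(self):
        """With a strong decrease planted in 7 of 13 mtDNA genes at large n,
        exactly those 7 genes reach q < 0.05."""
        affected = [f"MT-G{i}" for i in range(1, 8)]
        cm = simulate_expression_counts({"A1d1a": 40, "CTVT_HT": 40}, "A1d1a",
                                        effect_fraction=0.6, dispersion=0.05,
                                        seed=13, affected_genes=affected)
        corrected = _workflow(cm)
        restricted = [g for g in cm.gene_classes.index
                      if cm.gene_classes[g] in ("mtDNA", "nuclear")]
        result = per_gene_differential(corrected, cm.samples, "A1d1a",
                                       "CTVT_HT", restricted)
        hits = set(result.index[(result["q"] < 0.05)
                                & (result["direction"] == "down")])
        assert hits == set(affected)

    def test_empty_gene_list_rejected(self):
        cm = simulate_expression_counts({"A1d1a": 5, "CTVT_HT": 5}, "A1d1a",
                                        seed=14)
        corrected = _workflow(cm)
        with pytest.raises(ValueError):
            per_gene_differential(corrected, cm.samples, "A1d1a", "CTVT_HT",
                                  [])

    def test_null_false_positive_rate_bounded(self):
        """Under the null the mtDNA false-positive count stays near the
        nominal rate (clearly below one gene per cohort on average)."""
        rng = np.random.default_rng(15)
        total_fp = 0
        n_sims = 40
        for _ in range(n_sims):
            cm = simulate_expression_counts(
                {"A1d1a": 10, "CTVT_HT": 10}, "A1d1a", effect_fraction=0.0,
                n_genes_other=100, seed=int(rng.integers(2 ** 31)))
            corrected = _workflow(cm)
            genes = [g for g in cm.gene_classes.index
                     if cm.gene_classes[g] in ("mtDNA", "nuclear")]
            result = per_gene_differential(corrected, cm.samples, "A1d1a",
                                           "CTVT_HT", genes)
            total_fp += int((result["q"] < 0.05).sum())
        assert total_fp / n_sims <= 0.05 * 13 + 0.35  # mean + slack
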