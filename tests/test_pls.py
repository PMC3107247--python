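"""Mean-centered task PLS: decomposition, permutation, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from neurotraffic.pls import (
    BOOTSTRAP_RATIO_THRESHOLD,
    PLSDataset,
    bootstrap_saliences,
    build_pls_dataset,
    mean_centered_pls,
    permutation_test,
    run_pls,
)


def _fit_table(n_subjects=3, n_channels=2, freqs=(5.0, 10.0), value=None, rng=None):
    rows = []
    for s in range(n_subjects):
        for cond in ("a", "b"):
            for ch in range(n_channels):
                for f in freqs:
                    v = value(s, cond, ch, f) if value else rng.normal()
                    rows.append((f"s{s}", cond, ch, f, v))
    return pd.DataFrame(
        rows, columns=["subject", "condition", "channel", "frequency_hz", "shape"]
    )


class TestBuildDataset:
    def test_shape_and_block_ordering(self, rng):
        table = _fit_table(rng=rng)
        ds = build_pls_dataset(table, "shape")
        assert ds.data.shape == (6, 4)
        assert ds.n_subjects == 3 and ds.n_conditions == 2
        # rows are [a: s0..s2, b: s0..s2]
        v = table.set_index(["condition", "subject", "channel", "frequency_hz"])
        expect00 = v.loc[("a", "s0", 0, 5.0), "shape"]
        assert ds.data[0, 0] == expect00

    def test_missing_condition_raises(self, rng):
        table = _fit_table(rng=rng)
        table = table[~((table.subject == "s1") & (table.condition == "b"))]
        with pytest.raises(ValueError, match="s1"):
            build_pls_dataset(table, "shape")

    def test_column_order_invariant_to_input_row_order(self, rng):
        table = _fit_table(rng=rng)
        ds1 = build_pls_dataset(table, "shape")
        ds2 = build_pls_dataset(table.sample(frac=1, random_state=0), "shape")
        np.testing.assert_array_equal(ds1.data, ds2.data)
        assert ds1.element_labels == ds2.element_labels

    def test_round_trip_table_to_dataset(self, rng):
        table = _fit_table(rng=rng)
        ds = build_pls_dataset(table, "shape")
        # reconstruct the long table from the matrix and compare cell-wise
        for ci, cond in enumerate(ds.condition_labels):
            for si, subj in enumerate(ds.subject_labels):
                for ei, (ch, f) in enumerate(ds.element_labels):
                    v = table[
                        (table.subject == subj) & (table.condition == cond)
                        & (table.channel == ch) & (table.frequency_hz == f)
                    ]["shape"].item()
                    assert ds.data[ci * ds.n_subjects + si, ei] == v

    def test_nan_cells_rejected(self, rng):
        table = _fit_table(rng=rng)
        table.loc[0, "shape"] = np.nan
        with pytest.raises(ValueError, match="empty cells"):
            build_pls_dataset(table, "shape")


class TestDecomposition:
    def test_single_element_effect_concentrates_salience(self, element_dataset_factory):
        ds = element_dataset_factory(30, 4, effect_elements=(0,), delta=5.0,
                                     seed=1, within_sd=1e-6)
        res = mean_centered_pls(ds)
        v = res.element_saliences[:, 0]
        assert abs(v[0]) / np.linalg.norm(v) > 0.99
        assert res.singular_values[0] > 0
        # with 2 conditions there is a single LV after mean-centering
        assert res.n_lvs == 1

    def test_identical_condition_means_all_zero(self):
        base = np.tile(np.arange(8.0).reshape(2, 4), (2, 1))
        ds = PLSDataset(base, n_subjects=2, n_conditions=2,
                        element_labels=tuple(range(4)))
        with pytest.warns(UserWarning, match="identical condition means"):
            res = mean_centered_pls(ds)
        assert np.all(res.singular_values == 0)

    def test_effect_sizes_sum_to_one(self, element_dataset_factory):
        ds = element_dataset_factory(10, 6, effect_elements=(1, 2), delta=1.0, seed=3)
        res = mean_centered_pls(ds)
        assert res.effect_sizes.sum() == pytest.approx(1.0, abs=1e-12)

    def test_svd_reconstructs_centered_means(self, element_dataset_factory):
        ds = element_dataset_factory(10, 6, effect_elements=(1,), delta=1.5, seed=4)
        res = mean_centered_pls(ds)
        means = ds.condition_means()
        centered = means - means.mean(axis=0, keepdims=True)
        recon = res.design_saliences @ np.diag(res.singular_values) \
            @ res.element_saliences.T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_saliences_orthonormal(self, element_dataset_factory):
        ds = element_dataset_factory(12, 5, effect_elements=(0, 1), delta=1.0, seed=5)
        res = mean_centered_pls(ds)
        u, v = res.design_saliences, res.element_saliences
        np.testing.assert_allclose(u.T @ u, np.eye(res.n_lvs), atol=1e-8)
        np.testing.assert_allclose(v.T @ v, np.eye(res.n_lvs), atol=1e-8)


class TestPermutation:
    def test_strong_effect_is_significant(self, element_dataset_factory):
        ds = element_dataset_factory(20, 24, effect_elements=tuple(range(6)),
                                     delta=2.0, seed=6)
        p = permutation_test(ds, n_permutations=500, seed=1)
        assert p[0] <= 0.002

    def test_pvalues_invariant_to_positive_scaling(self, element_dataset_factory):
        ds = element_dataset_factory(10, 8, effect_elements=(0,), delta=1.0, seed=7)
        scaled = PLSDataset(ds.data * 37.5, ds.n_subjects, ds.n_conditions,
                            ds.element_labels)
        p1 = permutation_test(ds, 200, seed=5)
        p2 = permutation_test(scaled, 200, seed=5)
        np.testing.assert_array_equal(p1, p2)

    def test_null_pvalues_not_extreme(self, element_dataset_factory):
        """Without an effect, small p-values appear at the nominal rate."""
        hits = 0
        for d in range(60):
            ds = element_dataset_factory(12, 8, seed=1000 + d)
            if permutation_test(ds, 100, seed=d)[0] < 0.05:
                hits += 1
        assert hits <= 9  # ~5% expected; allow sampling slack

    def test_add_one_estimator_never_zero(self, element_dataset_factory):
        ds = element_dataset_factory(20, 24, effect_elements=tuple(range(6)),
                                     delta=2.0, seed=8)
        p = permutation_test(ds, 100, seed=2, add_one=True)
        assert np.all(p > 0)

    def test_invalid_counts_rejected(self, element_dataset_factory):
        ds = element_dataset_factory(5, 4, seed=9)
        with pytest.raises(ValueError):
            permutation_test(ds, 0, seed=0)


class TestBootstrap:
    def test_recovers_affected_elements(self, element_dataset_factory):
        affected = tuple(range(5))  # 25% of 20 elements
        ds = element_dataset_factory(20, 20, effect_elements=affected, delta=2.0,
                                     seed=10)
        ratios, se, reliable = bootstrap_saliences(ds, 500, seed=3)
        rel = reliable[:, 0]
        assert rel[list(affected)].mean() >= 0.9
        assert rel[5:].mean() <= 0.10

    def test_identical_subjects_hit_zero_se_sentinel(self):
        row = np.arange(4.0)
        data = np.vstack([np.tile(row, (3, 1)), np.tile(row + [1, 0, 0, 0], (3, 1))])
        ds = PLSDataset(data, 3, 2, tuple(range(4)))
        with pytest.warns(UserWarning, match="zero bootstrap SE"):
            ratios, se, reliable = bootstrap_saliences(ds, 50, seed=4)
        assert np.all(se == 0)
        assert np.all(np.isinf(ratios[np.abs(ratios) > 0]))

    def test_ratios_invariant_to_global_sign_flip(self, element_dataset_factory):
        ds = element_dataset_factory(15, 8, effect_elements=(0, 1), delta=1.5, seed=11)
        flipped = PLSDataset(-ds.data, ds.n_subjects, ds.n_conditions,
                             ds.element_labels)
        r1, _, _ = bootstrap_saliences(ds, 200, seed=6)
        r2, _, _ = bootstrap_saliences(flipped, 200, seed=6)
        np.testing.assert_allclose(np.abs(r1), np.abs(r2), atol=1e-10)

    def test_threshold_is_normal_99_critical_value(self):
        """The default reliability cutoff is the two-sided standard-normal
        99% critical value at two-decimal precision (2.5758... -> 2.57)."""
        import math

        from scipy.stats import norm

        z = float(norm.ppf(0.995))
        assert BOOTSTRAP_RATIO_THRESHOLD == math.floor(z * 100) / 100
        assert abs(BOOTSTRAP_RATIO_THRESHOLD - z) < 0.01


def test_run_pls_is_reproducible(element_dataset_factory):
    ds = element_dataset_factory(12, 10, effect_elements=(0,), delta=1.0, seed=12)
    r1 = run_pls(ds, 100, 100, seed=7)
    r2 = run_pls(ds, 100, 100, seed=7)
    np.testing.assert_array_equal(r1.permutation_p, r2.permutation_p)
    np.testing.assert_array_equal(r1.bootstrap_ratios, r2.bootstrap_ratios)
    assert r1.lv_table().shape[0] == r1.n_lvs
    assert "reliable" in r1.salience_table(0).columns
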