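"""Abundance filtering, TMM/logCPM, qsmooth and the quantro-style test."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from damidcall.counting import CountMatrix, GROUP_DAM, GROUP_POI
from damidcall.normalize import (abundance_cutoff, ave_log_cpm,
                                 filter_low_abundance, log_cpm, qsmooth,
                                 quantro_test, tmm_factors)


def make_matrix(counts, libs=None, groups=None):
    counts = np.asarray(counts)
    n = counts.shape[1]
    libs = np.asarray(libs) if libs is not None else counts.sum(axis=0)
    groups = groups or [GROUP_DAM] * (n // 2) + [GROUP_POI] * (n - n // 2)
    return CountMatrix(counts, np.arange(counts.shape[0]),
                       [f"s{i}" for i in range(n)], groups, libs)


class TestAveLogCpm:
    def test_stated_formula(self):
        cm = make_matrix([[10, 10]], libs=[10 ** 6, 10 ** 6])
        expected = np.log2(12e6 / (1e6 + 4))
        assert ave_log_cpm(cm)[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(3.5849, abs=1e-4)

    def test_zero_counts_finite(self):
        cm = make_matrix([[0, 0]], libs=[10 ** 6, 10 ** 6])
        assert np.isfinite(ave_log_cpm(cm)[0])
        assert ave_log_cpm(cm)[0] == pytest.approx(np.log2(2e6 / (1e6 + 4)))

    def test_approximate_scale_invariance(self):
        # at counts >> pseudocount, doubling counts and libraries cancels
        cm1 = make_matrix([[10 ** 7, 10 ** 7]], libs=[10 ** 9, 10 ** 9])
        cm2 = make_matrix([[2 * 10 ** 7, 2 * 10 ** 7]],
                          libs=[2 * 10 ** 9, 2 * 10 ** 9])
        assert ave_log_cpm(cm1)[0] == pytest.approx(ave_log_cpm(cm2)[0],
                                                    abs=1e-6)

    def test_zero_library_rejected(self):
        cm = make_matrix([[1, 1]], libs=[0, 10])
        with pytest.raises(ValueError):
            ave_log_cpm(cm)


class TestAbundanceFilter:
    def test_threshold_ten_is_removed_eleven_retained(self):
        cm = make_matrix([[10, 10], [11, 11], [200, 200]],
                         libs=[10 ** 6, 10 ** 6])
        kept, mask = filter_low_abundance(cm, count_threshold=10)
        assert mask.tolist() == [False, True, True]
        assert kept.fragment_index.tolist() == [1, 2]

    def test_zero_threshold_zero_prior(self):
        cm = make_matrix([[0, 0], [1, 0]], libs=[10 ** 6, 10 ** 6])
        _, mask = filter_low_abundance(cm, count_threshold=0, prior=0)
        assert mask.tolist() == [False, True]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            abundance_cutoff(1e6, count_threshold=-1)

    def test_removal_leaves_other_abundances_unchanged(self):
        rng = np.random.default_rng(0)
        cm = make_matrix(rng.integers(0, 500, (50, 4)),
                         libs=[10 ** 5] * 4)
        before = ave_log_cpm(cm)
        kept, mask = filter_low_abundance(cm)
        after = ave_log_cpm(kept)
        assert np.allclose(after, before[mask])


class TestTmm:
    def test_identical_columns_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 1000, 500)
        cm = make_matrix(np.column_stack([col, col]), libs=[10 ** 6] * 2)
        assert np.allclose(tmm_factors(cm), 1.0)

    def test_doubled_column_closed_form(self):
        rng = np.random.default_rng(2)
        col = rng.integers(10, 1000, 500)
        cm = make_matrix(np.column_stack([col, 2 * col]), libs=[10 ** 6] * 2)
        f = np.sort(tmm_factors(cm))
        assert f == pytest.approx([2 ** -0.5, 2 ** 0.5], abs=1e-6)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        cm = make_matrix(rng.integers(0, 300, (400, 5)), libs=[10 ** 5] * 5)
        f = tmm_factors(cm)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(4)
        base = rng.negative_binomial(10, 0.05, size=(2000, 3))
        scaled = base.copy()
        scaled[:, 0] = (3 * base[:, 0])
        libs = [int(base[:, j].sum()) for j in range(3)]
        f_base = tmm_factors(make_matrix(base, libs=libs))
        f_scaled = tmm_factors(make_matrix(scaled, libs=libs))
        # factors are rescaled to geometric mean 1, so the *relative*
        # factor of the scaled sample moves by ~c
        ratio = (f_scaled[0] / f_scaled[1]) / (f_base[0] / f_base[1])
        assert ratio == pytest.approx(3.0, rel=0.05)


class TestLogCpm:
    def test_reduces_to_plain_logcpm_with_unit_factors(self):
        cm = make_matrix([[5, 7], [0, 1]], libs=[10 ** 6, 10 ** 6])
        got = log_cpm(cm, np.ones(2))
        expected = np.log2((cm.counts + 2) / (1e6 + 4) * 1e6)
        assert np.allclose(got, expected)

    def test_zero_counts_constant_columns(self):
        cm = make_matrix(np.zeros((5, 3), dtype=int), libs=[10 ** 6] * 3)
        got = log_cpm(cm, np.ones(3))
        assert np.allclose(got, got[0, 0])

    def test_consistent_with_ave_log_cpm_at_equal_depth(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 200, (100, 4))
        cm = make_matrix(counts, libs=[10 ** 6] * 4)
        per_cell = log_cpm(cm, np.ones(4))
        # mean count vs mean of per-sample values agree when counts equal
        cm_const = make_matrix(np.repeat(counts[:, :1], 4, axis=1),
                               libs=[10 ** 6] * 4)
        assert np.allclose(log_cpm(cm_const, np.ones(4)).mean(axis=1),
                           ave_log_cpm(cm_const), atol=1e-6)


def brute_quantile_norm(values, groups=None):
    """Oracle: classic quantile normalization (optionally within groups)."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    cols = range(values.shape[1])
    if groups is None:
        ref = np.sort(values, axis=0).mean(axis=1)
        for j in cols:
            order = np.argsort(values[:, j], kind="stable")
            out[order, j] = ref
    else:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            sub = values[:, groups == g]
            ref = np.sort(sub, axis=0).mean(axis=1)
            block = np.empty_like(sub)
            for j in range(sub.shape[1]):
                order = np.argsort(sub[:, j], kind="stable")
                block[order, j] = ref
            out[:, groups == g] = block
    return out


class TestQsmooth:
    def test_single_group_equals_quantile_normalization(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(1000, 6))
        got = qsmooth(values, ["Dam"] * 6)
        assert np.allclose(got, brute_quantile_norm(values), atol=1e-8)

    def test_between_group_shift_preserved(self):
        rng = np.random.default_rng(7)
        base = np.sort(rng.normal(size=200))
        col_a = base.copy()
        col_b = base + 5.0
        values = np.column_stack([col_a, col_a, col_b, col_b])
        groups = ["Dam", "Dam", "DamPOI", "DamPOI"]
        got = qsmooth(values, groups)
        # identical within groups, shifted between: SST == SSB, w == 0,
        # so each group keeps its own reference
        assert np.allclose(got[:, :2], values[:, :2], atol=1e-8)
        assert np.allclose(got[:, 2:], values[:, 2:], atol=1e-8)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(300, 4))
        got = qsmooth(values, ["Dam", "Dam", "DamPOI", "DamPOI"])
        for j in range(4):
            # near-monotone map: the quantile-varying weight can introduce
            # tiny local inversions, but ranks are essentially preserved
            rho = spearmanr(values[:, j], got[:, j]).statistic
            assert rho > 0.999

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(400, 6)) + np.repeat([0, 1], 3)[None, :]
        groups = ["Dam"] * 3 + ["DamPOI"] * 3
        once = qsmooth(values, groups)
        twice = qsmooth(once, groups)
        assert np.allclose(once, twice, atol=1e-8)

    def test_ties_get_mean_of_tied_positions(self):
        values = np.array([[1.0, 3.0], [1.0, 2.0], [5.0, 1.0]])
        got = qsmooth(values, ["Dam", "Dam"])
        # tied inputs map to one common output value
        assert got[0, 0] == got[1, 0]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            qsmooth(np.zeros((5, 1)), ["Dam"])
        with pytest.raises(ValueError):
            qsmooth(np.zeros((5, 2)), ["Dam", "Dam"], span=0)


class TestQuantro:
    def test_identical_groups_p_one(self):
        col = np.arange(50, dtype=float)
        values = np.column_stack([col] * 4)
        res = quantro_test(values, ["Dam", "Dam", "DamPOI", "DamPOI"],
                           n_perm=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(10)
        dam = rng.normal(0, 1, size=(500, 3))
        poi = rng.normal(5, 1, size=(500, 3))
        values = np.hstack([dam, poi])
        res = quantro_test(values, ["Dam"] * 3 + ["DamPOI"] * 3,
                           n_perm=19, seed=1)
        assert res.p_value <= 0.1

    def test_seed_reproducible(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(100, 6))
        groups = ["Dam"] * 3 + ["DamPOI"] * 3
        a = quantro_test(values, groups, n_perm=50, seed=42)
        b = quantro_test(values, groups, n_perm=50, seed=42)
        assert a.p_value == b.p_value
        assert np.array_equal(a.permuted, b.permuted)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            quantro_test(np.zeros((5, 4)), ["Dam"] * 4, n_perm=10)
        with pytest.raises(ValueError):
            quantro_test(np.zeros((5, 4)), ["Dam", "Dam", "DamPOI", "DamPOI"],
                         n_perm=0)
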