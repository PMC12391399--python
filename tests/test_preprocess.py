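import numpy as np
import pandas as pd
import pytest

from lfqpipe import preprocess
from lfqpipe.preprocess import (center_by_sample_mean, filter_by_validity,
                                impute_min_probabilistic, log_transform,
                                replay, scale_by_sample_width, scale_widths)
from lfqpipe.synthetic_data import generate_lfq
from lfqpipe.tables_io import TableValidationError

from conftest import make_design, make_matrix


def chain(matrix, seed=None):
    m = log_transform(matrix)
    m = center_by_sample_mean(m)
    m = scale_by_sample_width(m)
    if m.n_missing:
        m = impute_min_probabilistic(m, seed=seed)
    return m


class TestLogTransform:
    def test_known_values_and_missingness(self, design_1iso):
        vals = np.full((2, 6), np.nan)
        vals[0] = [1, 1024, 4, 8, 2, 16]
        vals[1] = [2, 2, np.nan, 2, 2, 2]
        m = log_transform(make_matrix(vals, design_1iso), base=2)
        np.testing.assert_allclose(m.values.iloc[0], [0, 10, 2, 3, 1, 4])
        assert np.isnan(m.values.iloc[1, 2])  # missing preserved
        assert m.n_missing == 1


class TestCenterAndScale:
    def test_center_subtracts_valid_mean(self, design_1iso):
        vals = [[2, 4, 6, 2, 4, 6],
                [1, np.nan, 3, 1, np.nan, 3],
                [3, 2, 3, 3, 2, 3]]
        m = log_transform(make_matrix(np.exp2(vals), design_1iso))
        c = center_by_sample_mean(m)
        # valid-cell column means: [2, 3, 4, 2, 3, 4]
        np.testing.assert_allclose(c.values.iloc[0], [0, 1, 2, 0, 1, 2])
        np.testing.assert_allclose(
            c.values.iloc[1], [-1, np.nan, -1, -1, np.nan, -1]
        )
        np.testing.assert_allclose(c.values.iloc[2], [1, -1, -1, 1, -1, -1])

    def test_center_idempotent_on_centered_input(self, design_1iso):
        rng = np.random.default_rng(0)
        m = log_transform(make_matrix(np.exp2(rng.normal(20, 2, (30, 6))), design_1iso))
        once = center_by_sample_mean(m)
        twice = center_by_sample_mean(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_scale_example_column(self, design_1iso):
        vals = np.tile([[0.0], [2.0], [4.0]], (1, 6))  # centered: -2, 0, 2
        m = center_by_sample_mean(log_transform(make_matrix(np.exp2(vals), design_1iso)))
        s = scale_by_sample_width(m)
        np.testing.assert_allclose(s.values.iloc[:, 0], [-1, 0, 1])  # SD(ddof=1)=2

    def test_center_scale_equals_zscore_oracle(self, design_1iso):
        rng = np.random.default_rng(7)
        log2 = rng.normal(18, 3, (5, 6))
        m = chain(make_matrix(np.exp2(log2), design_1iso))
        for j in range(6):
            col = log2[:, j]
            z = (col - col.mean()) / col.std(ddof=1)
            np.testing.assert_allclose(m.values.iloc[:, j], z, atol=1e-10)
        # post-conditions: per-sample mean 0, SD 1 over valid values
        np.testing.assert_allclose(m.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(m.values.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_zero_width_rejected(self, design_1iso):
        vals = np.tile([[1.0]], (3, 6))
        m = center_by_sample_mean(log_transform(make_matrix(vals, design_1iso)))
        with pytest.raises(TableValidationError, match="width"):
            scale_by_sample_width(m)

    def test_row_permutation_commutes(self, design_1iso):
        rng = np.random.default_rng(3)
        vals = np.exp2(rng.normal(20, 2, (20, 6)))
        m = chain(make_matrix(vals, design_1iso))
        perm = rng.permutation(20)
        mp = chain(make_matrix(vals[perm], design_1iso))
        np.testing.assert_allclose(
            m.values.to_numpy()[perm], mp.values.to_numpy(), atol=1e-12
        )


class TestFilterByValidity:
    def test_extremes(self, design_1iso):
        vals = np.exp2(np.random.default_rng(0).normal(20, 1, (2, 6)))
        vals[0] = np.nan  # missing everywhere
        m = log_transform(make_matrix(vals, design_1iso))
        out, removed = filter_by_validity(m, min_valid_per_group=2)
        assert removed == ["P000"]
        assert list(out.values.index) == ["P001"]

    def test_mixed_patterns_match_brute_force(self, design_1iso):
        rng = np.random.default_rng(5)
        vals = np.exp2(rng.normal(20, 1, (10, 6)))
        vals[rng.random((10, 6)) < 0.5] = np.nan
        vals[0] = 1.0  # guarantee at least one fully valid protein
        m = log_transform(make_matrix(vals, design_1iso))
        out, removed = filter_by_validity(m, min_valid_per_group=2)
        groups = design_1iso.groups()
        for i, acc in enumerate(m.values.index):
            expected_keep = any(
                np.isfinite(vals[i][[m.values.columns.get_loc(s) for s in cols]]).sum() >= 2
                for cols in groups.values()
            )
            assert (acc in out.values.index) == expected_keep
            assert (acc in removed) == (not expected_keep)


class TestImputation:
    def test_no_missing_is_identity_with_zero_flags(self, design_1iso):
        rng = np.random.default_rng(1)
        m = chain(make_matrix(np.exp2(rng.normal(20, 2, (50, 6))), design_1iso))
        out = impute_min_probabilistic(m, seed=None)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert out.n_imputed == 0

    def test_seed_mandatory_when_missing(self, design_1iso):
        vals = np.exp2(np.random.default_rng(2).normal(20, 2, (10, 6)))
        vals[0, 0] = np.nan
        m = center_by_sample_mean(log_transform(make_matrix(vals, design_1iso)))
        m = scale_by_sample_width(m)
        with pytest.raises(ValueError, match="seed"):
            impute_min_probabilistic(m)

    def test_downshift_distribution_at_10000_draws(self, design_1iso):
        """10,000 imputed cells in a standardized sample should land at
        mean -2.0 (down-shift) with SD 0.3 (resampling width)."""
        rng = np.random.default_rng(9)
        n = 20_000
        vals = np.exp2(rng.normal(20, 2, (n, 6)))
        miss = np.zeros((n, 6), bool)
        miss[:10_000, 0] = True
        vals[miss] = np.nan
        m = chain(make_matrix(vals, design_1iso), seed=123)
        imputed = m.values.to_numpy()[:10_000, 0]
        # sample 0 was standardized: mu=0, sigma=1 over valid values
        assert abs(imputed.mean() - (-2.0)) < 0.01
        assert abs(imputed.std(ddof=1) - 0.3) < 0.01

    def test_same_seed_bit_identical(self, design_1iso):
        rng = np.random.default_rng(4)
        vals = np.exp2(rng.normal(20, 2, (100, 6)))
        vals[rng.random((100, 6)) < 0.1] = np.nan
        a = chain(make_matrix(vals, design_1iso), seed=77)
        b = chain(make_matrix(vals, design_1iso), seed=77)
        assert a.values.equals(b.values)
        assert a.imputed.equals(b.imputed)

    def test_flag_count_equals_missing_count(self, design_1iso):
        rng = np.random.default_rng(6)
        vals = np.exp2(rng.normal(20, 2, (80, 6)))
        vals[rng.random((80, 6)) < 0.15] = np.nan
        pre = center_by_sample_mean(log_transform(make_matrix(vals, design_1iso)))
        pre = scale_by_sample_width(pre)
        n_missing = pre.n_missing
        out = impute_min_probabilistic(pre, seed=8)
        assert out.n_missing == 0
        assert out.n_imputed == n_missing


class TestProvenance:
    def test_replay_reproduces_normalized_matrix_exactly(self):
        matrix, design, _ = generate_lfq(n_proteins=150, isolates=("I",), seed=21)
        m = log_transform(matrix)
        m = center_by_sample_mean(m)
        m = scale_by_sample_width(m)
        m, _ = filter_by_validity(m)
        m = impute_min_probabilistic(m, seed=42)
        again = replay(matrix, m.provenance)
        pd.testing.assert_frame_equal(m.values, again.values)
        pd.testing.assert_frame_equal(m.imputed, again.imputed)

    def test_scale_widths_recorded(self, design_1iso):
        rng = np.random.default_rng(10)
        log2 = rng.normal(20, 2, (40, 6))
        m = chain(make_matrix(np.exp2(log2), design_1iso))
        widths = scale_widths(m)
        expected = pd.Series(
            {s: log2[:, j].std(ddof=1) - 0 for j, s in enumerate(m.values.columns)}
        )
        # widths are the post-centering SDs, which equal the raw log2 SDs
        np.testing.assert_allclose(widths.to_numpy(), expected.to_numpy(), atol=1e-10)
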