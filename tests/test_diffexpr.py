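import math

import numpy as np
import pytest
from scipy import stats

from lfqpipe.diffexpr import (HETEROSCEDASTIC, HOMOSCEDASTIC, classify_volcano,
                              fold_change, gated_t_test, p_axis_transform,
                              run_de_table, variance_gate)
from lfqpipe.preprocess import (center_by_sample_mean, impute_min_probabilistic,
                                log_transform, scale_by_sample_width)
from lfqpipe.synthetic_data import generate_lfq

from conftest import make_matrix
from oracles import oracle_f_test, oracle_pooled_t, oracle_welch_t


class TestVarianceGate:
    def test_equal_variances_are_homoscedastic(self):
        mode, f, p = variance_gate([0, 1, 2], [5, 6, 7])
        assert mode == HOMOSCEDASTIC
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_hundredfold_variance_matches_reference_cdf(self):
        a = [0.0, 1.0, 2.0]            # variance 1
        b = [0.0, 10.0, 20.0]          # variance 100
        mode, f, p = variance_gate(a, b, alpha_f=0.05)
        f_exp, p_exp = oracle_f_test(a, b)
        assert f == pytest.approx(f_exp, rel=1e-12)
        assert p == pytest.approx(p_exp, rel=1e-12)
        assert mode == HETEROSCEDASTIC

    def test_single_zero_variance_routes_to_welch(self):
        mode, f, p = variance_gate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert mode == HETEROSCEDASTIC
        assert math.isinf(f) and p == 0.0

    def test_double_zero_variance_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            variance_gate([1.0, 1.0], [2.0, 2.0])


class TestGatedT:
    def test_identical_groups(self):
        t, df, p = gated_t_test([1, 2, 3], [1, 2, 3], HOMOSCEDASTIC)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_pooled_branch_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, df, p = gated_t_test(a, b, HOMOSCEDASTIC)
        assert df == 4
        assert t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), rel=1e-12)
        t_exp, df_exp, p_exp = oracle_pooled_t(a, b)
        assert (t, df, p) == pytest.approx((t_exp, df_exp, p_exp), rel=1e-12)

    def test_welch_branch_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.5, 2.2], [4.0, 9.0, 6.0]
        t, df, p = gated_t_test(a, b, HETEROSCEDASTIC)
        t_exp, df_exp, p_exp = oracle_welch_t(a, b)
        assert (t, df, p) == pytest.approx((t_exp, df_exp, p_exp), rel=1e-12)

    def test_group_swap_negates_t_preserves_p(self):
        a, b = [1.0, 2.5, 3.0], [2.0, 4.0, 7.0]
        for mode in (HOMOSCEDASTIC, HETEROSCEDASTIC):
            t1, _, p1 = gated_t_test(a, b, mode)
            t2, _, p2 = gated_t_test(b, a, mode)
            assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestFoldChangeAndVolcano:
    def test_fold_change_definition_and_antisymmetry(self):
        assert fold_change([2, 2], [2, 2]) == 0.0
        assert fold_change([3, 3], [2, 2]) == pytest.approx(1.0)
        a, b = [1.3, 2.1], [0.2, 0.9]
        assert fold_change(a, b) == pytest.approx(-fold_change(b, a))

    @pytest.mark.parametrize("fc,p,expected", [
        (1.5, 0.01, "up"),
        (-1.5, 0.01, "down"),
        (0.5, 0.001, "not_significant"),
        (1.5, 0.5, "not_significant"),
        (-1.0, 0.01, "not_significant"),  # boundary excluded under strict rule
        (1.0, 0.01, "not_significant"),
    ])
    def test_strict_classification(self, fc, p, expected):
        assert classify_volcano(fc, p) == expected

    def test_inclusive_variant_admits_boundary(self):
        assert classify_volcano(-1.0, 0.01, strict=False) == "down"
        assert classify_volcano(1.0, 0.01, strict=False) == "up"

    def test_p_axis_maps_005_to_432(self):
        assert round(p_axis_transform(0.05), 2) == 4.32
        assert p_axis_transform(1.0) == 0.0
        assert p_axis_transform(0.25) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            p_axis_transform(0.0)


def normalized_from_log2(log2_matrix, design, seed=None):
    m = log_transform(make_matrix(np.exp2(log2_matrix), design))
    m = center_by_sample_mean(m)
    m = scale_by_sample_width(m)
    return impute_min_probabilistic(m, seed=seed)


class TestRunDETable:
    def test_every_protein_matches_brute_force_oracle(self, design_1iso):
        """Each protein's F/t/df/p must equal an independent textbook
        recomputation to 1e-10 relative tolerance."""
        matrix, design, _ = generate_lfq(
            n_proteins=300, isolates=("ISO1",), de_fraction=0.1,
            group_sds=(0.3, 0.5), seed=31,
        )
        m = log_transform(matrix)
        m = center_by_sample_mean(m)
        m = scale_by_sample_width(m)
        m = impute_min_probabilistic(m, seed=32)
        table, _ = run_de_table(m, "ISO1")
        treated = design.samples_for("ISO1", "treated")
        control = design.samples_for("ISO1", "control")
        for _, row in table.iterrows():
            a = m.values.loc[row["accession"], treated].to_numpy()
            b = m.values.loc[row["accession"], control].to_numpy()
            f_exp, fp_exp = oracle_f_test(a, b)
            assert row["f_pvalue"] == pytest.approx(fp_exp, rel=1e-10)
            if fp_exp < 0.05:
                t_exp, df_exp, p_exp = oracle_welch_t(a, b)
                assert row["variance_mode"] == HETEROSCEDASTIC
            else:
                t_exp, df_exp, p_exp = oracle_pooled_t(a, b)
                assert row["variance_mode"] == HOMOSCEDASTIC
            assert row["t_stat"] == pytest.approx(t_exp, rel=1e-10)
            assert row["df"] == pytest.approx(df_exp, rel=1e-10)
            assert row["p_value"] == pytest.approx(p_exp, rel=1e-10)
            assert row["log2_fc"] == pytest.approx(a.mean() - b.mean(), rel=1e-10)

    def test_null_type_one_error_near_alpha(self, design_1iso):
        """With no planted effects the raw p < 0.05 fraction should sit
        within 3 binomial SDs of 0.05."""
        matrix, _, _ = generate_lfq(
            n_proteins=1000, isolates=("ISO1",), de_fraction=0.0,
            dropout_midpoint=0.0, seed=41,  # midpoint far below abundances: no dropout
        )
        m = normalized_from_log2(np.log2(matrix.values.to_numpy()), design_1iso)
        table, _ = run_de_table(m, "ISO1")
        frac = (table["p_value"] < 0.05).mean()
        sd = math.sqrt(0.05 * 0.95 / len(table))
        assert abs(frac - 0.05) <= 3 * sd

    def test_null_pooled_p_values_are_uniform(self):
        """Homoscedastic-branch p-values under the null are U(0,1)
        (Kolmogorov-Smirnov at 10,000 simulated proteins)."""
        rng = np.random.default_rng(55)
        a = rng.normal(0, 1, (10_000, 3))
        b = rng.normal(0, 1, (10_000, 3))
        pvals = [gated_t_test(a[i], b[i], HOMOSCEDASTIC)[2] for i in range(10_000)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_group_label_symmetry(self, design_1iso):
        """Swapping treated/control labels flips fold changes and up/down
        counts while leaving p-values untouched."""
        matrix, design, _ = generate_lfq(
            n_proteins=400, isolates=("ISO1",), de_fraction=0.1, seed=61,
        )
        m = log_transform(matrix)
        m = center_by_sample_mean(m)
        m = scale_by_sample_width(m)
        m = impute_min_probabilistic(m, seed=62)
        table, summary = run_de_table(m, "ISO1", fc_threshold=0.4)
        swapped_design = design.table.copy()
        swapped_design["treatment"] = swapped_design["treatment"].map(
            {"control": "treated", "treated": "control"}
        )
        from lfqpipe.tables_io import SampleDesign
        from lfqpipe.preprocess import NormalizedMatrix
        m2 = NormalizedMatrix(m.values, SampleDesign(swapped_design), m.imputed,
                              m.provenance)
        table2, summary2 = run_de_table(m2, "ISO1", fc_threshold=0.4)
        np.testing.assert_allclose(table["log2_fc"], -table2["log2_fc"], atol=1e-12)
        np.testing.assert_allclose(table["p_value"], table2["p_value"], atol=1e-12)
        assert summary["n_up"] == summary2["n_down"]
        assert summary["n_down"] == summary2["n_up"]

    def test_p_monotone_in_mean_difference(self):
        """With fixed group spread, a larger mean shift never raises p."""
        base = np.array([-0.3, 0.0, 0.3])
        last = 1.0
        for delta in np.linspace(0, 3, 13):
            _, _, p = gated_t_test(base + delta, base, HOMOSCEDASTIC)
            assert p <= last + 1e-12
            last = p

    def test_constant_matrix_yields_no_calls(self, design_1iso):
        from lfqpipe.preprocess import NormalizedMatrix
        import pandas as pd
        vals = pd.DataFrame(
            np.tile(np.arange(10, dtype=float)[:, None], (1, 6)),
            index=[f"P{i}" for i in range(10)],
            columns=design_1iso.sample_ids,
        )
        flags = vals.astype(bool) & False
        m = NormalizedMatrix(vals, design_1iso, flags, ({"op": "log_transform", "base": 2},))
        table, summary = run_de_table(m, "ISO1")
        assert summary["n_up"] == 0 and summary["n_down"] == 0
        assert summary["n_tested"] == 0          # all rows degenerate
        assert len(summary["excluded"]) == 10
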