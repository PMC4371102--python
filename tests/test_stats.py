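import math

import numpy as np
import pandas as pd
import pytest

from helpers import icc_oracle
from mirqc import stats
from mirqc.errors import InsufficientDataError, ZeroVarianceError


def rand_matrix(rng, n=None, k=None):
    n = n or int(rng.integers(4, 21))
    k = k or int(rng.integers(2, 5))
    subj = rng.normal(0, 3, size=(n, 1))
    rater = rng.normal(0, 1, size=(1, k))
    return subj + rater + rng.normal(0, 1, size=(n, k))


class TestICCTwowayMixed:
    def test_equal_columns_give_unity(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        for definition in ("consistency", "absolute_agreement"):
            assert stats.icc_twoway_mixed(x, definition).icc == pytest.approx(
                1.0, abs=1e-12
            )

    def test_column_offset_separates_definitions(self):
        a = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        x = np.column_stack([a, a + 10.0])
        cons = stats.icc_twoway_mixed(x, "consistency")
        agree = stats.icc_twoway_mixed(x, "absolute_agreement")
        assert cons.icc == pytest.approx(1.0, abs=1e-12)
        assert agree.icc < 1.0

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            x = rand_matrix(rng)
            for definition in ("consistency", "absolute_agreement"):
                got = stats.icc_twoway_mixed(x, definition).icc
                assert got == pytest.approx(
                    icc_oracle(x, definition), abs=1e-10
                )

    def test_classic_judges_fixture_matches_pingouin(self, shrout_fleiss):
        """Cross-check against an independent published implementation
        on the standard 6-target x 4-judge dataset."""
        pg = pytest.importorskip("pingouin")
        n, k = shrout_fleiss.shape
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": shrout_fleiss.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            long, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")["ICC"]

        def lookup(*labels):
            for lab in labels:  # label style varies across versions
                if lab in ref.index:
                    return float(ref[lab])
            raise KeyError(labels)

        agree = stats.icc_twoway_mixed(shrout_fleiss, "absolute_agreement")
        cons = stats.icc_twoway_mixed(shrout_fleiss, "consistency")
        assert agree.icc == pytest.approx(lookup("ICC2", "ICC(A,1)"), abs=1e-6)
        assert cons.icc == pytest.approx(lookup("ICC3", "ICC(C,1)"), abs=1e-6)

    def test_average_measure_forms(self, shrout_fleiss):
        """ICC(C,k)/(A,k) follow from the same mean squares; checked
        against the Spearman-Brown relation to the single forms."""
        n, k = shrout_fleiss.shape
        for definition in ("consistency", "absolute_agreement"):
            single = stats.icc_twoway_mixed(shrout_fleiss, definition).icc
            avg = stats.icc_twoway_mixed(
                shrout_fleiss, definition, average=True
            ).icc
            if definition == "consistency":
                expected = k * single / (1 + (k - 1) * single)
                assert avg == pytest.approx(expected, abs=1e-10)
            assert avg > single

    def test_f_test_degrees_of_freedom(self, shrout_fleiss):
        res = stats.icc_twoway_mixed(shrout_fleiss, "consistency")
        assert (res.df1, res.df2) == (5, 15)
        assert 0 <= res.p_value <= 1

    def test_consistency_invariant_to_column_shift(self):
        rng = np.random.default_rng(5)
        x = rand_matrix(rng, n=12, k=3)
        shifted = x.copy()
        shifted[:, 1] += 7.5
        a = stats.icc_twoway_mixed(x, "consistency").icc
        b = stats.icc_twoway_mixed(shifted, "consistency").icc
        assert a == pytest.approx(b, abs=1e-10)
        agree_before = stats.icc_twoway_mixed(x, "absolute_agreement").icc
        agree_after = stats.icc_twoway_mixed(shifted, "absolute_agreement").icc
        assert agree_after < agree_before

    def test_constant_matrix_rejected(self):
        with pytest.raises(ZeroVarianceError):
            stats.icc_twoway_mixed(np.full((5, 2), 3.0), "consistency")

    def test_too_small_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.icc_twoway_mixed(np.ones((2, 2)), "consistency")


class TestBuildPairedMatrix:
    def _mat(self, values, samples=None):
        values = np.asarray(values, dtype=float)
        samples = samples or [f"S{i}" for i in range(values.shape[0])]
        return pd.DataFrame(
            values, index=samples,
            columns=[f"m{j}" for j in range(values.shape[1])],
        )

    def test_incomplete_cells_dropped_and_counted(self):
        a = self._mat(np.arange(10.0).reshape(5, 2) + 20)
        bvals = np.arange(10.0).reshape(5, 2) + 21
        bvals[0, 0] = np.nan
        bvals[3, 1] = np.nan
        pm = stats.build_paired_matrix(a, self._mat(bvals),
                                       exclude_censored=False)
        assert pm.n == 8
        assert pm.dropped_incomplete == 2

    def test_censored_values_excluded_by_default(self):
        a = self._mat([[25.0, 40.0], [26.0, 30.0], [27.0, 31.0], [24.0, 33.0]])
        b = self._mat([[25.5, 39.0], [26.5, 30.5], [27.5, 31.5], [24.5, 33.5]])
        pm = stats.build_paired_matrix(a, b, cq_ceiling=40.0)
        assert pm.n == 7  # the Cq-40 cell in a is a floor, not a measurement
        pm_inc = stats.build_paired_matrix(a, b, exclude_censored=False)
        assert pm_inc.n == 8

    def test_disjoint_assays_insufficient(self):
        a = pd.DataFrame([[1.0], [2.0], [3.0]], columns=["m1"],
                         index=["S0", "S1", "S2"])
        b = pd.DataFrame([[1.0], [2.0], [3.0]], columns=["m2"],
                         index=["S0", "S1", "S2"])
        with pytest.raises(InsufficientDataError):
            stats.build_paired_matrix(a, b, exclude_censored=False)

    def test_identical_matrices(self):
        a = self._mat(np.arange(8.0).reshape(4, 2))
        pm = stats.build_paired_matrix(a, a.copy(), exclude_censored=False)
        assert pm.k == 2
        np.testing.assert_array_equal(pm.values[:, 0], pm.values[:, 1])


class TestPairedTTest:
    def test_identical_vectors(self):
        res = stats.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # d = {1, 2, 3}: t = mean/sd*sqrt(n) = 2/(1/sqrt(3)) = 2*sqrt(3)
        res = stats.paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * math.sqrt(3), abs=1e-9)
        assert res.df == 2
        assert res.p_two_tailed == pytest.approx(0.0742, abs=5e-4)
        assert res.mean_diff == pytest.approx(2.0)

    def test_sign_flip_symmetry(self):
        x = [3.0, 1.0, 4.0, 1.5]
        y = [2.0, 2.0, 3.0, 2.5]
        a = stats.paired_t_test(x, y)
        b = stats.paired_t_test(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p_two_tailed == pytest.approx(b.p_two_tailed)

    def test_matches_one_sample_test_on_differences(self):
        from scipy import stats as sps

        rng = np.random.default_rng(9)
        x = rng.normal(30, 2, 15)
        y = x + rng.normal(0.3, 0.5, 15)
        res = stats.paired_t_test(x, y)
        ref = sps.ttest_1samp(x - y, 0.0)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_nonzero_difference_flagged(self):
        res = stats.paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.zero_variance
        assert res.p_two_tailed == 0.0
        assert math.isinf(res.t)

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.paired_t_test([1.0], [2.0])


class TestPairwiseAgreement:
    def _mats(self, rng, n_conditions, offset_per_condition=0.0):
        truth = rng.normal(30, 3, size=(8, 4))
        out = {}
        for c in range(n_conditions):
            vals = truth + c * offset_per_condition + rng.normal(0, 0.3,
                                                                 truth.shape)
            out[f"K{c}"] = pd.DataFrame(
                vals, index=[f"S{i}" for i in range(8)],
                columns=[f"m{j}" for j in range(4)],
            )
        return out

    def test_two_conditions_single_off_diagonal(self):
        rng = np.random.default_rng(2)
        table, results = stats.pairwise_agreement(
            self._mats(rng, 2), exclude_censored=False
        )
        assert table.shape == (2, 2)
        assert table.loc["K0", "K0"] == 1.0
        assert table.loc["K0", "K1"] == table.loc["K1", "K0"]
        assert ("K0", "K1") in results

    def test_copied_condition_gives_unity(self):
        rng = np.random.default_rng(2)
        mats = self._mats(rng, 1)
        mats["K1"] = mats["K0"].copy()
        table, _ = stats.pairwise_agreement(mats, exclude_censored=False)
        assert table.loc["K0", "K1"] == pytest.approx(1.0, abs=1e-12)

    def test_single_condition_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.pairwise_agreement({"K0": pd.DataFrame()})
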