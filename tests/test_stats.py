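"""Two-sample tests, agreement, and independence statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from baduanjin.stats import (
    kendall_tau_b,
    levene_test,
    mann_whitney,
    mann_whitney_from_ranks,
    pearson_chi_square,
    students_t,
    students_t_raw,
)


class TestStudentsT:
    # published two-group DTW-distance summaries (n, mean, SD per group)
    # and the t statistics they imply
    @pytest.mark.parametrize(
        "g1,g2,expected_t",
        [
            ((27, 640.76, 74.38), (33, 565.72, 61.64), 4.28),
            ((27, 543.46, 78.92), (33, 455.75, 54.30), 5.09),
            ((27, 536.45, 41.44), (33, 468.66, 47.70), 5.81),
        ],
    )
    def test_pooled_t_from_summaries(self, g1, g2, expected_t):
        r = students_t(*g1, *g2)
        assert r.statistic == pytest.approx(expected_t, abs=0.02)
        assert r.df == 58
        assert r.p_value < 0.001

    @pytest.mark.parametrize(
        "g1,g2,expected_t",
        [
            ((27, 640.76, 74.38), (33, 565.72, 61.64), 4.20),
            ((27, 543.46, 78.92), (33, 455.75, 54.30), 4.90),
            ((27, 536.45, 41.44), (33, 468.66, 47.70), 5.89),
        ],
    )
    def test_welch_t_from_summaries(self, g1, g2, expected_t):
        r = students_t(*g1, *g2, equal_var=False)
        assert r.statistic == pytest.approx(expected_t, abs=0.02)
        assert r.method == "welch"

    def test_identical_groups_zero(self):
        assert students_t(10, 5.0, 1.0, 10, 5.0, 1.0).statistic == 0.0

    def test_zero_variance_equal_means(self):
        assert students_t(5, 3.0, 0.0, 5, 3.0, 0.0).statistic == 0.0

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            students_t(5, 3.0, 0.0, 5, 4.0, 0.0)

    def test_raw_overload_matches_scipy(self, rng):
        x = rng.normal(0, 1, size=25)
        y = rng.normal(0.5, 1.2, size=30)
        r = students_t_raw(x, y)
        t, p = sps.ttest_ind(x, y)
        assert r.statistic == pytest.approx(t)
        assert r.p_value == pytest.approx(p)
        rw = students_t_raw(x, y, equal_var=False)
        tw, pw = sps.ttest_ind(x, y, equal_var=False)
        assert rw.statistic == pytest.approx(tw)
        assert rw.p_value == pytest.approx(pw)


class TestMannWhitney:
    def test_u_and_z_from_printed_rank_sums(self):
        r = mann_whitney_from_ranks(27, 33, 1040.0)
        assert r.statistic == 229.0
        assert r.z == pytest.approx(-3.22, abs=0.02)
        assert r.p_value == pytest.approx(0.001, abs=0.001)

    def test_motion5_z(self):
        r = mann_whitney_from_ranks(27, 33, 1133.0)
        assert r.statistic == 136.0
        assert r.z == pytest.approx(-4.60, abs=0.02)

    def test_identical_multisets_zero_z(self):
        x = [1.0, 2.0, 3.0, 3.0]
        r = mann_whitney(x, list(x))
        assert r.z == pytest.approx(0.0, abs=1e-12)

    def test_u1_plus_u2_identity(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(2, 15))
            n2 = int(rng.integers(2, 15))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            ranks = sps.rankdata(np.concatenate([x, y]))
            u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            u2 = ranks[n1:].sum() - n2 * (n2 + 1) / 2
            assert u1 + u2 == pytest.approx(n1 * n2)
            assert mann_whitney(x, y).statistic == pytest.approx(min(u1, u2))

    def test_u_matches_scipy(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(0.8, 1, size=24)
        r = mann_whitney(x, y)
        u1 = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
        assert r.statistic == min(u1, len(x) * len(y) - u1)

    def test_tie_correction_reduces_variance(self):
        # heavy ties: the corrected Z must exceed the uncorrected one in magnitude
        x = [1, 1, 1, 2, 2]
        y = [2, 2, 3, 3, 3]
        r = mann_whitney(x, y)
        u = r.statistic
        z_uncorrected = (u - 12.5) / np.sqrt(5 * 5 * 11 / 12)
        assert abs(r.z) > abs(z_uncorrected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_incompatible_rank_sum_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_from_ranks(5, 5, 4.0)  # below the minimum possible rank sum


class TestKendallTauB:
    def test_perfect_agreement(self):
        r = kendall_tau_b([0, 1, 2, 2, 1], [0, 1, 2, 2, 1])
        assert r.statistic == pytest.approx(1.0)

    def test_perfect_reversal(self):
        r = kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1])
        assert r.statistic == pytest.approx(-1.0)

    def test_tied_example_matches_pair_counting(self):
        x = [1, 2, 2, 3]
        y = [1, 3, 2, 4]
        n = len(x)
        conc = disc = tx = ty = 0
        for i in range(n):
            for j in range(i + 1, n):
                a = np.sign(x[i] - x[j])
                b = np.sign(y[i] - y[j])
                if a == 0 and b == 0:
                    continue
                elif a == 0:
                    tx += 1
                elif b == 0:
                    ty += 1
                elif a == b:
                    conc += 1
                else:
                    disc += 1
        n0 = n * (n - 1) / 2
        expected = (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))
        assert kendall_tau_b(x, y).statistic == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau_b([1, 1, 1], [1, 2, 3])


class TestChiSquare:
    def test_recognizer_error_table(self):
        # six recognizers, correct/incorrect counts out of 760 trials each
        table = [[756, 4], [754, 6], [758, 2], [756, 4], [757, 3], [753, 7]]
        r = pearson_chi_square(table)
        assert r.statistic == pytest.approx(4.023, abs=0.01)
        assert r.df == 5
        assert "low_expected_count" in r.flags  # min expected count 4.33

    def test_table_equal_to_expected_zero(self):
        r = pearson_chi_square([[10, 20], [20, 40]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.flags == ()

    def test_2x2_hand_formula(self):
        r = pearson_chi_square([[10, 20], [20, 10]])
        assert r.statistic == pytest.approx(20 / 3, abs=1e-9)
        assert r.df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_square([[0, 0], [5, 5]])


class TestLevene:
    def test_identical_groups_zero_f(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert levene_test(x, list(x)).statistic == pytest.approx(0.0, abs=1e-12)

    def test_type_one_error_near_alpha(self):
        g = np.random.default_rng(11)
        rejections = sum(
            levene_test(g.normal(size=30), g.normal(size=30)).p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 < rejections / 400 < 0.09

    def test_power_under_variance_ratio_four(self):
        g = np.random.default_rng(12)
        rejections = sum(
            levene_test(g.normal(size=30), g.normal(scale=2.0, size=30)).p_value < 0.05
            for _ in range(200)
        )
        assert rejections / 200 > 0.5
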