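"""Correlation machinery against closed-form and brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

import corticov as cv

# Reference Z values for the backtransformed-average dependent-correlation
# test, frozen from an independent straight-line transcription of the
# published formula (Fisher z, Dunn-Clark c with r_bar substituted).
HITTNER_GRID = [
    (0.5, 0.3, 0.2, 100, 1.7783319695060213),
    (0.2, 0.5, 0.1, 50, -1.7107557042778407),
    (-0.3, 0.4, 0.0, 200, -7.270586284299316),
    (0.7, 0.6, 0.5, 30, 0.7596275268786052),
    (0.1, -0.1, 0.3, 1000, 5.355099160960756),
]


class TestSpearman:
    def test_identity_and_reversal(self):
        assert cv.spearman([1, 2, 3, 4], [1, 2, 3, 4]).rs == pytest.approx(1.0)
        assert cv.spearman([1, 2, 3, 4], [4, 3, 2, 1]).rs == pytest.approx(-1.0)

    def test_closed_form_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (0,1,-1,1,-1,0) -> sum d^2 = 4
        res = cv.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rs == pytest.approx(0.8)

    def test_all_permutations_n5_match_rank_formula(self):
        """Exhaustive oracle: untied data, all 5! y-orderings."""
        x = np.arange(1.0, 6.0)
        for perm in itertools.permutations(range(5)):
            y = np.array(perm, dtype=float)
            d = x - 1 - y
            expected = 1 - 6 * np.sum(d**2) / (5 * 24)
            assert cv.spearman(x, y).rs == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cv.spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_p_in_unit_interval_even_for_perfect_rank(self):
        res = cv.spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert 0 < res.p <= 1


class TestBootstrapCI:
    def test_degenerate_perfect_correlation(self):
        x = np.arange(10.0)
        res = cv.bootstrap_ci(x, x, n_boot=200, rng_seed=0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 50))
        a = cv.bootstrap_ci(x, y, rng_seed=7)
        b = cv.bootstrap_ci(x, y, rng_seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        res = cv.bootstrap_ci(x, y, rng_seed=3)
        assert -1 <= res.ci_low <= res.rs <= res.ci_high <= 1

    def test_unpaired_mode_destroys_association(self):
        """Resampling only the x margin against fixed y should center the
        bootstrap distribution near zero for strongly correlated data."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        y = x + 0.1 * rng.standard_normal(100)
        res = cv.bootstrap_ci(x, y, rng_seed=5, paired=False)
        assert res.ci_low < 0.3   # paired interval would sit near 1

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            cv.bootstrap_ci(np.arange(5.0), np.arange(5.0))


class TestFdrBH:
    def test_handworked_step_up(self):
        p_adj, reject = cv.fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()          # thresholds .0125,.025,.0375,.05
        assert np.allclose(p_adj, 0.04)

    def test_none_rejected(self):
        _, reject = cv.fdr_bh([0.2, 0.5])
        assert not reject.any()

    def test_single_p(self):
        p_adj, reject = cv.fdr_bh([0.04])
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    def test_brute_force_oracle_random_vectors(self):
        """Step-up rule applied literally, 300 random vectors m <= 20."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = int(rng.integers(1, 21))
            p = rng.uniform(0.001, 1.0, m)
            p_adj, reject = cv.fdr_bh(p, q=0.05)
            order = np.argsort(p)
            # brute-force adjusted p: min over j>=i of p_(j)*m/j
            adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            adj = np.clip(adj, 0, 1)
            expected = np.empty(m)
            expected[order] = adj
            assert np.allclose(p_adj, expected, atol=1e-12)
            k = np.nonzero(p[order] <= np.arange(1, m + 1) * 0.05 / m)[0]
            expected_reject = np.zeros(m, bool)
            if len(k):
                expected_reject[order[: k[-1] + 1]] = True
            assert np.array_equal(reject, expected_reject)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            cv.fdr_bh([0.0, 0.5])
        with pytest.raises(ValueError):
            cv.fdr_bh([1.2])


class TestPartialSpearman:
    def test_partialling_out_y_itself(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        res = cv.partial_spearman(x, y, y)
        assert abs(res.rs) < 1e-10

    def test_closed_form_n5(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 5.0, 3.0])
        c = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rx, ry, rc = (stats.rankdata(v) for v in (x, y, c))
        r_xy = np.corrcoef(rx, ry)[0, 1]
        r_xc = np.corrcoef(rx, rc)[0, 1]
        r_yc = np.corrcoef(ry, rc)[0, 1]
        expected = (r_xy - r_xc * r_yc) / np.sqrt((1 - r_xc**2) * (1 - r_yc**2))
        assert cv.partial_spearman(x, y, c).rs == pytest.approx(expected, abs=1e-12)

    def test_independent_covariate_leaves_rs(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(1000)
        y = 0.5 * x + rng.standard_normal(1000)
        c = rng.standard_normal(1000)
        plain = cv.spearman(x, y).rs
        partial = cv.partial_spearman(x, y, c).rs
        assert abs(plain - partial) < 0.05

    def test_against_pingouin(self):
        """Independent cross-check: pingouin's Spearman partial correlation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((60, 3)), columns=["x", "y", "c"])
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c", method="spearman")
        res = cv.partial_spearman(df["x"], df["y"], df["c"])
        assert res.rs == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant covariate"):
            cv.partial_spearman([1, 2, 3, 4, 5], [2, 3, 1, 5, 4], [1, 1, 1, 1, 1])


class TestHittnerCompare:
    def test_equal_correlations_give_zero(self):
        res = cv.hittner_compare(0.4, 0.4, 0.3, 50)
        assert res.z_stat == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("r_jk,r_jh,r_kh,n,expected", HITTNER_GRID)
    def test_reference_grid(self, r_jk, r_jh, r_kh, n, expected):
        res = cv.hittner_compare(r_jk, r_jh, r_kh, n)
        assert res.z_stat == pytest.approx(expected, abs=1e-10)

    def test_antisymmetry(self):
        a = cv.hittner_compare(0.5, 0.2, 0.3, 80)
        b = cv.hittner_compare(0.2, 0.5, 0.3, 80)
        assert a.z_stat == pytest.approx(-b.z_stat, abs=1e-14)

    def test_one_sided_vs_two_sided(self):
        one = cv.hittner_compare(0.5, 0.2, 0.3, 80)
        two = cv.hittner_compare(0.5, 0.2, 0.3, 80, two_sided=True)
        assert two.p == pytest.approx(2 * one.p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match=r"\|r\| < 1"):
            cv.hittner_compare(1.0, 0.2, 0.3, 50)
        with pytest.raises(ValueError, match="PSD"):
            cv.hittner_compare(0.9, -0.9, 0.9, 50)

    def test_null_calibration(self):
        """Under equal population correlations the two-sided test rejects at
        ~alpha (trivariate normal, n=100)."""
        rng = np.random.default_rng(3)
        S = np.array([[1, 0.3, 0.3], [0.3, 1, 0.2], [0.3, 0.2, 1]])
        chol = np.linalg.cholesky(S)
        rej = 0
        reps = 800
        for _ in range(reps):
            X = rng.standard_normal((100, 3)) @ chol.T
            R = stats.spearmanr(X).statistic
            res = cv.hittner_compare(R[0, 1], R[0, 2], R[1, 2], 100, two_sided=True)
            rej += res.p < 0.05
        assert 0.03 <= rej / reps <= 0.07
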