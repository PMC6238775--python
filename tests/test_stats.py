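import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pheasantcog.stats import (
    icc_oneway,
    spearman,
    standardize,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# intraclass correlation


class TestICC:
    def test_duplicated_measurements_give_one(self):
        pairs = [(1.0, 1.0), (2.0, 2.0), (5.0, 5.0), (3.0, 3.0), (7.0, 7.0), (4.0, 4.0)]
        res = icc_oneway(pairs)
        assert res.icc == pytest.approx(1.0)

    def test_within_pair_noise_dominating_gives_negative(self):
        pairs = [(0.0, 10.0), (10.0, 0.0), (0.1, 9.9), (9.9, 0.1), (0.2, 9.8), (9.8, 0.2)]
        res = icc_oneway(pairs)
        assert res.icc < 0

    def test_matches_hand_anova_on_fixed_table(self):
        pairs = [(3.0, 4.0), (5.0, 5.5), (8.0, 7.0), (2.0, 2.5), (6.0, 6.5), (9.0, 8.0)]
        arr = np.array(pairs)
        n, k = arr.shape
        row_means = arr.mean(axis=1)
        grand = arr.mean()
        ms_among = k * ((row_means - grand) ** 2).sum() / (n - 1)
        ms_within = ((arr - row_means[:, None]) ** 2).sum() / (n * (k - 1))
        expected = (ms_among - ms_within) / (ms_among + (k - 1) * ms_within)
        assert icc_oneway(pairs).icc == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_pingouin_icc1(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        subj = np.repeat(np.arange(8), 2)
        vals = rng.normal(np.repeat(rng.normal(0, 2, 8), 2), 1.0)
        df = pd.DataFrame(
            {"subject": subj, "rater": np.tile([0, 1], 8), "score": vals}
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        labels = ref["Type"].astype(str).str.replace(" ", "")
        icc1 = float(ref.loc[labels.isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0])
        pairs = list(zip(vals[::2], vals[1::2]))
        assert icc_oneway(pairs).icc == pytest.approx(icc1, abs=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, (10, 2))
        pairs = [tuple(r) for r in base]
        shifted = [tuple(3.5 * np.array(r) - 11.0) for r in base]
        assert icc_oneway(pairs).icc == pytest.approx(icc_oneway(shifted).icc, abs=1e-10)

    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(6)
        pairs = [tuple(rng.normal(mu, 0.5, 2)) for mu in rng.normal(0, 2, 12)]
        res = icc_oneway(pairs)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway([(1.0, 2.0), (2.0, 3.0)])


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_monotone_map_gives_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [v**3 for v in x]
        res = spearman(x, y)
        assert res.r_s == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3, 4], [5, 5, 5, 5])

    def test_exact_p_equals_full_enumeration_length8(self):
        """Exact permutation p reproduced from all 8! pairings using the
        no-ties rank-difference formula 1 - 6*sum(d^2)/(n(n^2-1))."""
        x = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8]
        y = [2.7, 1.8, 2.8, 1.2, 8.2, 8.4, 5.9, 0.4]
        res = spearman(x, y)
        assert res.method == "exact-permutation"
        n = 8
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            d = rx - ry[list(perm)]
            rho = 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))
            total += 1
            if abs(rho) >= abs(res.r_s) - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_large_sample_method_beyond_exact_limit(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 1, 30)
        res = spearman(x, y)
        assert res.method == "large-sample"
        assert 0 < res.p < 1


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _enumerated_two_sided_p(diffs):
    """Brute-force exact p over all 2^n sign assignments (no ties/zeros)."""
    d = np.asarray(diffs, float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    dev = abs(w_obs - mean)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean) >= dev - 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_five_positive_distinct_gives_exact_0625(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.method == "exact"
        assert res.p == pytest.approx(0.0625)
        assert res.statistic == 15.0
        assert res.n_used == 5

    def test_crow_rate_policy_zeros_force_normal_cc(self):
        """Zero differences trigger zero removal + normal approximation with
        continuity correction (the policy matching a printed p of 0.014 on
        8 positive and 2 zero paired differences)."""
        diffs = [4.679, 4.263, 0.188, 3.367, 5.400, 0.0, 10.767, 0.0, 3.233, 0.067]
        res = wilcoxon_signed_rank(diffs)
        assert res.method == "normal-cc"
        assert res.n_used == 8
        assert res.p == pytest.approx(0.014, abs=5e-4)

    def test_exact_p_equals_sign_enumeration_length10(self):
        diffs = [0.7, -1.3, 2.9, 3.4, -0.2, 5.5, 1.9, -4.4, 6.1, 0.9]
        res = wilcoxon_signed_rank(diffs)
        assert res.method == "exact"
        assert res.p == pytest.approx(_enumerated_two_sided_p(diffs), abs=1e-12)

    @given(
        st.lists(
            st.integers(min_value=-60, max_value=60).filter(lambda v: v != 0),
            min_size=3,
            max_size=12,
            unique_by=abs,
        )
    )
    def test_exact_p_matches_enumeration_for_all_small_samples(self, diffs):
        res = wilcoxon_signed_rank([float(d) for d in diffs])
        assert res.method == "exact"
        assert res.p == pytest.approx(_enumerated_two_sided_p(diffs), abs=1e-9)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])

    def test_statistic_within_range(self):
        res = wilcoxon_signed_rank([1.5, -0.5, 2.5, -3.5])
        assert 0 <= res.statistic <= res.n_used * (res.n_used + 1) / 2

    def test_null_type_one_error_at_or_below_nominal(self):
        """Exact test rejects at <= 5% under a symmetric null."""
        rng = np.random.default_rng(9)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            d = rng.normal(0, 1, 8)
            if wilcoxon_signed_rank(d).p <= 0.05:
                rejections += 1
        # exact test at n=8 has attainable size 0.0391; allow MC error
        assert rejections / n_sim <= 0.05 + 2.5 * math.sqrt(0.05 * 0.95 / n_sim)


# ---------------------------------------------------------------------------
# standardization


class TestStandardize:
    def test_basic_moments(self):
        z = standardize([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_on_standardized_input(self):
        z = standardize([4.0, -1.0, 0.5, 2.2])
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    @given(
        st.lists(
            st.floats(min_value=-1e4, max_value=1e4),
            min_size=2,
            max_size=20,
        ).filter(lambda v: max(v) - min(v) > 1e-6)
    )
    def test_round_trip_recovers_input(self, values):
        v = np.asarray(values)
        z = standardize(v)
        back = z * v.std(ddof=1) + v.mean()
        np.testing.assert_allclose(back, v, rtol=1e-9, atol=1e-9)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])
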