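"""Validation statistics against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from pspstage.validate import (
    anova_by_stage,
    proportion_le,
    residualized_correlation,
    spearman_agreement,
)


def rank_midranks(x):
    """Independent midrank implementation (average rank of ties)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of midranks, computed from first principles."""
    rx, ry = rank_midranks(x), rank_midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestAnova:
    def test_matches_textbook_ratio_on_integer_fixture(self):
        """Hand-computable 3-group fixture: F equals the between/within
        mean-square ratio computed here from the definition."""
        groups = {"I": [10.0, 12, 14], "II": [20.0, 22, 24], "III": [30.0, 32, 34]}
        psprs = sum(groups.values(), [])
        labels = sum(([k] * 3 for k in groups), [])
        F, p, means = anova_by_stage(psprs, labels)
        grand = np.mean(psprs)
        ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        F_hand = (ssb / 2) / (ssw / 6)
        assert F == pytest.approx(F_hand, rel=1e-12)
        assert means == {"I": 12.0, "II": 22.0, "III": 32.0}

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(30, 10, 12), rng.normal(40, 10, 15)
        F, p, _ = anova_by_stage(np.concatenate([a, b]), ["A"] * 12 + ["B"] * 15)
        t, pt = stats.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 5, 30)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        F1, _, _ = anova_by_stage(y, labels)
        F2, _, _ = anova_by_stage(y + 100.0, labels)
        assert F1 == pytest.approx(F2, rel=1e-9)

    def test_small_groups_dropped_and_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_by_stage([1.0, 2.0, 3.0], ["a", "a", "b"])  # b dropped -> 1 group
        with pytest.raises(ValueError):
            anova_by_stage([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])  # zero variance


class TestSpearman:
    def test_perfect_agreement_and_disagreement(self):
        r, _ = spearman_agreement([1, 2, 3, 4], [2, 3, 5, 6])
        assert r == pytest.approx(1.0)
        r, _ = spearman_agreement([1, 2, 3, 4], [9, 7, 5, 1])
        assert r == pytest.approx(-1.0)

    def test_nine_pair_tied_fixture_matches_rank_formula(self):
        """A fixed 9-pair fixture with ties: r equals the midrank Pearson
        formula to 1e-12."""
        invivo = np.array([2.0, 4, 4, 4, 4, 1, 3, 5, 4])
        postmortem = np.array([3.0, 4, 6, 5, 4, 2, 6, 6, 4])
        r, p = spearman_agreement(invivo, postmortem)
        assert r == pytest.approx(spearman_oracle(invivo, postmortem), abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_exact_p_for_small_n_matches_enumeration_bound(self):
        """At n=4 with distinct ranks the exact two-sided p of perfect
        agreement is 2/4! (the two perfectly monotone orderings)."""
        r, p = spearman_agreement([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(2 / 24)

    def test_monotone_recoding_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.integers(1, 7, 12).astype(float)
        y = rng.integers(1, 7, 12).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            pytest.skip("degenerate draw")
        r1, _ = spearman_agreement(x, y)
        r2, _ = spearman_agreement(np.exp(x), y**3 + 5)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_guards(self):
        with pytest.raises(ValueError):
            spearman_agreement([1, 2], [1, 2])
        with pytest.raises(ValueError):
            spearman_agreement([1, 1, 1], [1, 2, 3])


class TestResidualizedCorrelation:
    def test_orthogonal_covariates_reduce_to_plain_spearman(self):
        """Covariates orthogonal to both staging vectors leave the
        correlation unchanged (after centring, residuals are shifts)."""
        invivo = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9])
        postmortem = np.array([2.0, 1, 4, 3, 6, 5, 8, 7, 9])
        # project candidate covariates onto the orthogonal complement of
        # span{1, invivo, postmortem} so the OLS adjustment is a pure shift
        S = np.column_stack([np.ones(9), invivo, postmortem])
        proj = lambda z: z - S @ np.linalg.lstsq(S, z, rcond=None)[0]
        z1 = proj(np.array([1.0, 0, -1, 2, -1, 0, 1, -2, 0]))
        z2 = proj(np.array([0.0, 1, 0, -1, 2, 0, -2, 1, -1]))
        r_plain, _ = spearman_agreement(invivo, postmortem)
        r_res, _ = residualized_correlation(invivo, postmortem, z1, z2)
        assert r_res == pytest.approx(r_plain, abs=1e-10)

    def test_matches_two_step_ols_oracle(self):
        """Fixed 9-subject fixture: residual Spearman equals an independent
        normal-equations OLS + midrank correlation to 1e-10."""
        rng = np.random.default_rng(99)
        invivo = rng.integers(1, 7, 9).astype(float)
        postmortem = np.minimum(invivo + rng.integers(0, 3, 9), 6).astype(float)
        psprs = rng.normal(36, 14, 9)
        interval = rng.normal(2.45, 0.98, 9)
        r, p = residualized_correlation(invivo, postmortem, psprs, interval)

        X = np.column_stack([np.ones(9), psprs, interval])
        beta_x = np.linalg.solve(X.T @ X, X.T @ invivo)
        beta_y = np.linalg.solve(X.T @ X, X.T @ postmortem)
        r_oracle = spearman_oracle(invivo - X @ beta_x, postmortem - X @ beta_y)
        assert r == pytest.approx(r_oracle, abs=1e-10)

    def test_exact_linear_staging_degenerates(self):
        psprs = np.arange(9.0)
        interval = np.array([2.0, 1, 3, 2, 4, 1, 3, 2, 4])
        invivo = 1.0 + 0.5 * psprs + 0.25 * interval  # exact function
        postmortem = np.array([1.0, 2, 3, 4, 5, 6, 1, 2, 3])
        with pytest.raises(ValueError, match="degenerate|residual"):
            residualized_correlation(invivo, postmortem, psprs, interval)

    def test_collinear_covariates_rejected(self):
        x = np.arange(9.0)
        with pytest.raises(ValueError, match="collinear"):
            residualized_correlation(x, x[::-1], x, 2 * x)


class TestProportionLE:
    def test_equality_and_violation_cases(self):
        assert proportion_le([1, 2, 3], [1, 2, 3]) == 1.0
        assert proportion_le([6, 6], [1, 1]) == 0.0
        assert proportion_le([1, 6], [2, 1]) == 0.5

    def test_generator_construction_yields_one(self):
        """Postmortem stages are true stage plus a nonnegative increment, so
        true in vivo stage <= postmortem stage always."""
        from pspstage.synthetic import CohortConfig, generate_cohort

        df = generate_cohort(CohortConfig(seed=33))
        donors = df[df["postmortem_stage"].notna()]
        assert proportion_le(donors["true_stage"], donors["postmortem_stage"]) == 1.0

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            proportion_le([np.nan], [1.0])
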