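"""Observer-study metrics against hand-computed oracles."""

import numpy as np
import pytest
from oracles import icc21_anova, kappa_2x2, qwk_bruteforce

from ermquant import ObserverStudy
from ermquant.agreement import (
    acceptability,
    agreement_report,
    binary_accept_kappa,
    bland_altman,
    correlations,
    icc21,
    quadratic_weighted_kappa,
)


def study(a, b, threshold=4):
    return ObserverStudy(
        ratings=np.column_stack([a, b]), accept_threshold=threshold
    )


class TestCorrelations:
    def test_perfect_agreement(self):
        c = correlations(study([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]))
        assert c.pearson_r == pytest.approx(1.0)
        assert c.spearman_rho == pytest.approx(1.0)

    def test_perfect_inversion(self):
        c = correlations(study([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]))
        assert c.spearman_rho == pytest.approx(-1.0)

    def test_single_swap_rank_correlation(self):
        # d² = 2 over n=5: rho = 1 - 6*2/(5*24) = 0.9
        c = correlations(study([1, 2, 3, 4, 5], [1, 2, 3, 5, 4]))
        assert c.spearman_rho == pytest.approx(0.9)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            correlations(study([3, 3, 3, 3], [1, 2, 3, 4]))


class TestQuadraticWeightedKappa:
    def test_identical_ratings(self):
        assert quadratic_weighted_kappa(study([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])) == pytest.approx(1.0)

    def test_maximal_constant_disagreement_not_positive(self):
        a = [1] * 10
        b = [5] * 10
        assert quadratic_weighted_kappa(study(a, b)) <= 0.0

    def test_single_shared_category_defined_as_one(self):
        assert quadratic_weighted_kappa(study([4] * 5, [4] * 5)) == 1.0

    def test_matches_contingency_table_oracle(self, rng):
        for _ in range(30):
            a = rng.integers(1, 6, size=25)
            b = np.clip(a + rng.integers(-2, 3, size=25), 1, 5)
            s = study(a.tolist(), b.tolist())
            assert quadratic_weighted_kappa(s) == pytest.approx(
                qwk_bruteforce(a, b), abs=1e-10
            )

    def test_invariant_to_case_reordering(self, rng):
        a = rng.integers(1, 6, size=20)
        b = rng.integers(1, 6, size=20)
        perm = rng.permutation(20)
        assert quadratic_weighted_kappa(study(a, b)) == pytest.approx(
            quadratic_weighted_kappa(study(a[perm], b[perm]))
        )


class TestICC21:
    def test_identical_raters_with_case_variance(self):
        a = [1, 2, 3, 4, 5, 4]
        assert icc21(study(a, a)).value == pytest.approx(1.0)

    def test_all_variance_between_raters(self):
        result = icc21(study([2] * 6, [4] * 6))
        assert result.value <= 0.0 + 1e-12

    def test_matches_manual_anova_oracle(self, rng):
        for _ in range(10):
            mat = rng.integers(1, 6, size=(6, 2))
            if mat.std() == 0:
                continue
            s = ObserverStudy(ratings=mat)
            assert icc21(s).value == pytest.approx(icc21_anova(mat), abs=1e-8)

    def test_ci_brackets_estimate(self, rng):
        mat = np.column_stack([[1, 2, 3, 4, 5, 4, 3, 2], [2, 2, 3, 5, 5, 4, 3, 1]])
        result = icc21(ObserverStudy(ratings=mat))
        assert result.ci_low <= result.value <= result.ci_high

    def test_no_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            icc21(study([5] * 6, [5] * 6))


class TestBlandAltman:
    def test_identical_ratings(self):
        ba = bland_altman(study([1, 2, 3, 4], [1, 2, 3, 4]))
        assert ba.mean_diff == 0.0
        assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)

    def test_symmetric_disagreement_cancels(self):
        ba = bland_altman(study([1, 2], [2, 1]))
        assert ba.mean_diff == 0.0

    def test_single_discrepancy_over_thirty_cases(self):
        a = [4] * 30
        b = [4] * 29 + [5]
        ba = bland_altman(study(a, b))
        assert ba.mean_diff == pytest.approx(-1 / 30)
        assert ba.loa_low <= ba.mean_diff <= ba.loa_high


class TestAcceptability:
    def test_unanimous_acceptance(self):
        acc = acceptability(study([5] * 10, [5] * 10))
        assert acc.aas_pooled == 5.0
        assert acc.ar_pooled_pct == 100.0
        assert acc.nas == 1.0

    def test_unanimous_rejection(self):
        acc = acceptability(study([1] * 10, [1] * 10))
        assert acc.nas == -1.0

    def test_pooled_rate_from_per_rater_counts(self):
        # 25/30 and 26/30 acceptances pool to 51/60 = 85.0%
        a = [5] * 25 + [3] * 5
        b = [4] * 26 + [2] * 4
        acc = acceptability(study(a, b))
        assert acc.ar_per_rater_pct[0] == pytest.approx(83.3, abs=0.05)
        assert acc.ar_per_rater_pct[1] == pytest.approx(86.7, abs=0.05)
        assert acc.ar_pooled_pct == pytest.approx(85.0)

    def test_pooled_equals_ratings_weighted_mean(self, rng):
        mat = rng.integers(1, 6, size=(17, 3))
        acc = acceptability(ObserverStudy(ratings=mat))
        assert acc.ar_pooled_pct == pytest.approx(np.mean(acc.ar_per_rater_pct))

    def test_neutral_rating_counts_in_neither_direction(self):
        acc = acceptability(study([3] * 10, [3] * 10))
        assert acc.nas == 0.0
        assert acc.ar_pooled_pct == 0.0


class TestBinaryAcceptKappa:
    def test_identical_mixed_decisions(self):
        s = study([5, 5, 1, 1, 4], [4, 5, 2, 1, 5])
        assert binary_accept_kappa(s) == pytest.approx(1.0)

    def test_hand_built_two_by_two_table(self):
        # cells: both-accept 20, r1-only 2, r2-only 3, both-reject 5
        a = [5] * 20 + [4] * 2 + [1] * 3 + [2] * 5
        b = [4] * 20 + [2] * 2 + [5] * 3 + [1] * 5
        assert binary_accept_kappa(study(a, b)) == pytest.approx(
            kappa_2x2(20, 2, 3, 5), abs=1e-12
        )

    def test_constant_identical_decisions_defined_as_one(self):
        assert binary_accept_kappa(study([5] * 6, [4] * 6)) == 1.0

    def test_independent_raters_near_zero_on_average(self, rng):
        kappas = []
        for _ in range(200):
            a = rng.integers(0, 2, size=30) * 4 + 1  # 1 or 5, 50/50
            b = rng.integers(0, 2, size=30) * 4 + 1
            s = study(a.tolist(), b.tolist())
            if len(set(a) | set(b)) == 1:
                continue
            kappas.append(binary_accept_kappa(s))
        assert abs(np.mean(kappas)) < 0.05


def test_report_bundles_all_metrics_and_reorders_cases(rng):
    a = rng.integers(2, 6, size=20)
    b = np.clip(a + rng.integers(-1, 2, size=20), 1, 5)
    s1 = study(a.tolist(), b.tolist())
    perm = rng.permutation(20)
    s2 = study(a[perm].tolist(), b[perm].tolist())
    r1, r2 = agreement_report(s1), agreement_report(s2)
    assert r1.correlations.pearson_r == pytest.approx(r2.correlations.pearson_r)
    assert r1.icc21.value == pytest.approx(r2.icc21.value)
    assert r1.bland_altman.mean_diff == pytest.approx(r2.bland_altman.mean_diff)
    assert r1.acceptability.ar_pooled_pct == r2.acceptability.ar_pooled_pct
    d = r1.to_dict()
    assert set(d) >= {"pearson_r", "weighted_kappa", "icc21", "bland_altman", "nas"}
    assert isinstance(r1.to_text(), str)
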