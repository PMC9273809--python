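import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mct_kit.estimation import (
    EstimationError,
    MCTCandidate,
    change_from_means,
    fit_change_regression,
    half_sd_mct,
    project_regression_mct,
    summarize_group,
    triangulate,
    RegressionFit,
)

# t(0.975, df=2), frozen from the closed form for the CI oracle below
T_975_DF2 = 4.302652729911275


class TestSummarizeGroup:
    def test_constant_vector_has_undefined_srm(self):
        s = summarize_group([-8.0, -8.0, -8.0])
        assert s.mean == -8.0
        assert s.sd == 0.0
        assert s.median == -8.0
        assert s.srm is None
        assert s.ci_low == s.ci_high == -8.0

    def test_ci_matches_closed_form(self):
        """(-4, -8, -12): mean -8, SD 4, CI = -8 -+ t(.975,2) * 4/sqrt(3)."""
        s = summarize_group([-4.0, -8.0, -12.0])
        half = T_975_DF2 * 4.0 / math.sqrt(3.0)
        assert s.ci_low == pytest.approx(-8.0 - half, abs=1e-9)
        assert s.ci_high == pytest.approx(-8.0 + half, abs=1e-9)

    def test_ses_times_baseline_sd_recovers_mean(self):
        s = summarize_group([-4.0, -9.0, -11.0], baseline_sd=6.4)
        assert s.ses * 6.4 == pytest.approx(s.mean)

    def test_single_observation_reports_undefined_ci(self):
        s = summarize_group([-8.0])
        assert s.n == 1
        assert s.ci_low is None and s.ci_high is None and s.srm is None

    def test_empty_vector_rejected(self):
        with pytest.raises(EstimationError):
            summarize_group([])

    def test_even_count_median_is_midpoint_of_middle_two(self):
        s = summarize_group([-2.0, -4.0, -10.0, -20.0])
        assert s.median == -7.0

    @given(st.integers(min_value=1, max_value=6), st.integers(0, 2**31 - 1))
    def test_ci_width_shrinks_as_sqrt_n(self, factor, seed):
        """Replicating a sample k^2-fold shrinks the CI roughly k-fold
        (t-quantile converges, so allow slack)."""
        rng = np.random.default_rng(seed)
        base = list(rng.normal(-8, 3, size=12))
        small = summarize_group(base)
        big = summarize_group(base * factor**2)
        w_small = small.ci_high - small.ci_low
        w_big = big.ci_high - big.ci_low
        if w_small == 0:
            assert w_big == 0
        else:
            assert w_big <= w_small / factor * 1.01


class TestRegression:
    def test_exact_line_recovered(self):
        x = np.array([-3.0, -1.0, 0.0, 2.0, 5.0])
        fit = fit_change_regression(x, 1 + 2 * x)
        assert fit.beta0 == pytest.approx(1.0)
        assert fit.beta1 == pytest.approx(2.0)

    def test_constant_target_gives_zero_slope(self):
        fit = fit_change_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.beta1 == pytest.approx(0.0)
        assert fit.beta0 == pytest.approx(5.0)

    def test_monte_carlo_recovery_within_three_ses(self):
        rng = np.random.default_rng(42)
        x = rng.normal(20, 10, size=500)
        y = -8.0 - 0.25 * x + rng.normal(0, 9, size=500)
        fit = fit_change_regression(x, y)
        assert abs(fit.beta0 - (-8.0)) < 3 * fit.se_beta0
        assert abs(fit.beta1 - (-0.25)) < 3 * fit.se_beta1
        assert fit.pvalue_beta1 < 1e-4

    def test_zero_anchor_variance_rejected(self):
        with pytest.raises(EstimationError, match="degenerate"):
            fit_change_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_pairwise_complete(self):
        x = [1.0, 2.0, np.nan, 4.0]
        y = [2.0, 4.0, 6.0, 8.0]
        assert fit_change_regression(x, y).n == 3


class TestProjection:
    @pytest.mark.parametrize(
        "beta0, beta1, anchor_mct, expected",
        [
            (-7.84, -0.26, 7.0, -9.66),   # second-trial published projection
            (0.0, -1.0, 7.0, -7.0),
            (-8.00, -0.24, 7.0, -9.68),   # rounded first-trial coefficients
        ],
    )
    def test_projection_arithmetic(self, beta0, beta1, anchor_mct, expected):
        fit = RegressionFit(beta0, beta1, 0.0, 0.0, 0.1, 0.1, 100)
        cand = project_regression_mct(fit, anchor_mct)
        assert cand.value == pytest.approx(expected, abs=1e-9)

    def test_projection_at_zero_anchor_change_is_intercept(self):
        fit = RegressionFit(-7.84, -0.26, 0.0, 0.0, 0.1, 0.1, 100)
        assert project_regression_mct(fit, 0.0).value == pytest.approx(-7.84)


class TestHalfSd:
    @pytest.mark.parametrize(
        "sd, sign, expected",
        [(11.26, 1, 5.63), (11.20, -1, -5.60), (0.0, -1, 0.0)],
    )
    def test_half_sd_values(self, sd, sign, expected):
        assert half_sd_mct(sd, sign).value == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_linear_in_sd(self, sd):
        assert half_sd_mct(2 * sd).value == pytest.approx(2 * half_sd_mct(sd).value)

    def test_negative_sd_rejected(self):
        with pytest.raises(EstimationError):
            half_sd_mct(-1.0)


class TestTriangulation:
    def test_identical_candidates(self):
        cands = [MCTCandidate("anchor_mean", -8.0) for _ in range(3)]
        t = triangulate(cands)
        assert t.mean == t.median == -8.0
        assert t.recommended == -8

    def test_pooling_arithmetic(self):
        values = [-8.22, -8.30, -8.20, -9.69]
        t = triangulate([MCTCandidate("anchor_mean", v) for v in values])
        assert t.mean == pytest.approx(-8.6025)
        assert t.median == pytest.approx(-8.26)
        assert t.range == (-9.69, -8.20)
        assert t.recommended == -8

    def test_single_candidate(self):
        t = triangulate([MCTCandidate("half_sd", -5.6)])
        assert t.mean == t.median == -5.6
        assert t.recommended == -6

    def test_median_rounds_half_away_from_zero(self):
        t = triangulate([MCTCandidate("anchor_mean", -8.5)])
        assert t.recommended == -9
        t = triangulate([MCTCandidate("anchor_mean", 8.5)])
        assert t.recommended == 9

    @given(st.permutations(list(range(5))))
    def test_permutation_invariance(self, order):
        values = [-8.22, -8.30, -8.20, -9.69, -5.63]
        base = triangulate([MCTCandidate("anchor_mean", v) for v in values])
        permuted = triangulate(
            [MCTCandidate("anchor_mean", values[i]) for i in order]
        )
        assert permuted.mean == pytest.approx(base.mean, abs=1e-12)
        assert permuted.median == base.median

    def test_include_mask_filters_candidates(self):
        cands = [MCTCandidate("anchor_mean", -8.0), MCTCandidate("half_sd", -5.6)]
        t = triangulate(cands, include=[True, False])
        assert len(t.candidates) == 1
        assert t.median == -8.0

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(EstimationError):
            triangulate([])

    def test_non_finite_candidate_rejected(self):
        with pytest.raises(EstimationError):
            MCTCandidate("half_sd", float("nan"))


def test_group_mean_change_from_visit_means():
    """Published visit means determine the published mean change."""
    assert change_from_means(41.1, 17.9) == pytest.approx(-23.2, abs=1e-9)
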