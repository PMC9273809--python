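import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import spearman_oracle

from mct_kit.changes import (
    AnchorSpec,
    ChangeError,
    compute_changes,
    group_by_anchor_change,
    qualify_anchor,
    spearman_rho,
)
from mct_kit.instruments import builtin_criteria, records_to_frame, VisitRecord


def _two_visit_frame(rows):
    return records_to_frame([VisitRecord(**r) for r in rows])


MADRS_SPEC = AnchorSpec(
    "madrs_total", "severity_categorical", criteria=builtin_criteria("criteria_1")
)


class TestComputeChanges:
    def test_signed_change_and_category_change(self):
        df = _two_visit_frame([
            dict(patient_id="p1", arm="a", visit="baseline",
                 qlds_total=27, madrs_total=41, cgi_ss_r=4, cgi_sr_i=4, eq_vas=40),
            dict(patient_id="p1", arm="a", visit="endpoint",
                 qlds_total=15, madrs_total=17, cgi_ss_r=2, cgi_sr_i=3, eq_vas=60),
        ])
        changes, dropped = compute_changes(df)
        row = changes.iloc[0]
        assert row["qlds_change"] == -12
        assert row["madrs_change"] == -24
        assert row["eq_vas_change"] == 20
        # 41 (severe, idx 3) -> 17 (slight, idx 1) = two-category improvement
        assert row["madrs_cat_change_criteria_1"] == 2
        # CGI point change is improvement-positive: baseline - endpoint
        assert row["cgi_ss_r_point_change"] == 2
        assert row["cgi_sr_i_point_change"] == 1
        assert dropped == {"missing_baseline_visit": [], "missing_endpoint_visit": []}

    def test_patient_missing_endpoint_dropped_and_logged(self):
        df = _two_visit_frame([
            dict(patient_id="p1", arm="a", visit="baseline", qlds_total=20),
            dict(patient_id="p2", arm="a", visit="baseline", qlds_total=25),
            dict(patient_id="p2", arm="a", visit="endpoint", qlds_total=10),
        ])
        changes, dropped = compute_changes(df)
        assert list(changes["patient_id"]) == ["p2"]
        assert dropped["missing_endpoint_visit"] == ["p1"]

    def test_duplicate_patient_visit_rejected(self):
        df = _two_visit_frame([
            dict(patient_id="p1", arm="a", visit="baseline", qlds_total=20),
            dict(patient_id="p1", arm="a", visit="endpoint", qlds_total=25),
        ])
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ChangeError, match="duplicate"):
            compute_changes(dup)

    def test_category_change_depends_on_criteria_only_through_banding(self):
        """MADRS 41 -> 17: +2 under criteria_1 (severe->slight) but +2 under
        criteria_2 (severe 35-60 -> slight 7-19) and +2 under criteria_3."""
        df = _two_visit_frame([
            dict(patient_id="p1", arm="a", visit="baseline", madrs_total=41),
            dict(patient_id="p1", arm="a", visit="endpoint", madrs_total=17),
        ])
        changes, _ = compute_changes(df)
        assert changes.loc[0, "madrs_cat_change_criteria_1"] == 2
        assert changes.loc[0, "madrs_cat_change_criteria_2"] == 2
        assert changes.loc[0, "madrs_cat_change_criteria_3"] == 2
        # but 20 -> 13 differs: criteria_1 slight->slight (0) vs
        # criteria_2 moderate->slight (+1)
        df2 = _two_visit_frame([
            dict(patient_id="p1", arm="a", visit="baseline", madrs_total=20),
            dict(patient_id="p1", arm="a", visit="endpoint", madrs_total=13),
        ])
        changes2, _ = compute_changes(df2)
        assert changes2.loc[0, "madrs_cat_change_criteria_1"] == 0
        assert changes2.loc[0, "madrs_cat_change_criteria_2"] == 1


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert spearman_rho(x, [2.0, 4.0, 9.0, 11.0]).rho == pytest.approx(1.0)
        assert spearman_rho(x, [11.0, 9.0, 4.0, 2.0]).rho == pytest.approx(-1.0)

    def test_tied_example_matches_bruteforce_oracle(self):
        x, y = (1, 2, 2, 4), (10, 9, 7, 5)
        result = spearman_rho(x, y)
        assert result.rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_pairwise_complete_filtering(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 5.0, np.nan]
        result = spearman_rho(x, y)
        assert result.n == 3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ChangeError, match=">= 3"):
            spearman_rho([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ChangeError, match="zero variance"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_exact_permutation_p_for_tiny_n(self):
        # perfectly concordant n=4: only the identity and reverse
        # permutations reach |rho| = 1, so p = 2/24
        result = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40], method="exact")
        assert result.pvalue == pytest.approx(2 / 24)

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False).map(
                lambda v: round(v, 3)  # keep transforms injective in floats
            ),
            min_size=4,
            max_size=12,
        ).filter(lambda v: len(set(v)) >= 3)
    )
    def test_invariant_under_strictly_monotone_transforms(self, x):
        rng = np.random.default_rng(0)
        y = list(rng.permutation(x))
        if len(set(y)) < 2:
            return
        base = spearman_rho(x, y).rho
        assert spearman_rho([3 * v + 1 for v in x], y).rho == pytest.approx(base)
        assert spearman_rho(x, [v**3 for v in y]).rho == pytest.approx(base)


class TestQualification:
    @pytest.mark.parametrize(
        "rho, qualified",
        [(0.66, True), (-0.53, True), (0.40, True), (0.39, False), (-0.39, False)],
    )
    def test_magnitude_rule(self, rho, qualified):
        decision = qualify_anchor(rho, MADRS_SPEC)
        assert decision.qualified is qualified
        assert decision.rho == rho

    def test_rho_outside_unit_interval_rejected(self):
        with pytest.raises(ChangeError):
            qualify_anchor(1.5, MADRS_SPEC)


class TestGrouping:
    def test_all_unchanged_is_single_zero_group(self):
        df = _two_visit_frame(
            [dict(patient_id=f"p{i}", arm="a", visit=v,
                  qlds_total=20 - (5 if v == "endpoint" else 0), madrs_total=40)
             for i in range(4) for v in ("baseline", "endpoint")]
        )
        changes, _ = compute_changes(df)
        groups = group_by_anchor_change(changes, MADRS_SPEC)
        assert set(groups.groups) == {0}
        assert groups.sizes[0] == 4
        np.testing.assert_allclose(groups.groups[0], [-5, -5, -5, -5])

    def test_group_sizes_sum_to_complete_cases(self, demo_changes):
        groups = group_by_anchor_change(demo_changes, MADRS_SPEC)
        complete = demo_changes[["madrs_cat_change_criteria_1", "qlds_change"]].dropna()
        assert groups.n_total == len(complete)

    def test_cumulative_grouping_nests_exact_groups(self, demo_changes):
        exact = group_by_anchor_change(demo_changes, MADRS_SPEC)
        cumulative = group_by_anchor_change(demo_changes, MADRS_SPEC, cumulative=True)
        ks = [k for k in exact.groups if k > 0]
        for k in ks:
            expected = sum(exact.sizes[j] for j in ks if j >= k)
            assert cumulative.sizes[k] == expected

    def test_small_groups_flagged(self, demo_changes):
        groups = group_by_anchor_change(demo_changes, MADRS_SPEC, min_group_n=25)
        for k in groups.flagged_small:
            assert groups.sizes[k] < 25

    def test_unqualified_anchor_requires_forcing_with_warning(self, demo_changes):
        with pytest.warns(UserWarning, match="qualification"):
            group_by_anchor_change(demo_changes, MADRS_SPEC, qualified=False)

    def test_continuous_anchor_cannot_be_grouped(self, demo_changes):
        vas = AnchorSpec("eq_vas", "continuous", external_mct=7.0)
        with pytest.raises(ChangeError, match="continuous"):
            group_by_anchor_change(demo_changes, vas)

    def test_empty_table_rejected(self):
        with pytest.raises(ChangeError, match="empty"):
            group_by_anchor_change(pd.DataFrame(), MADRS_SPEC)


class TestAnchorSpec:
    def test_continuous_anchor_requires_external_mct(self):
        with pytest.raises(ChangeError, match="external_mct"):
            AnchorSpec("eq_vas", "continuous")

    def test_categorical_anchor_requires_criteria(self):
        with pytest.raises(ChangeError, match="criteria"):
            AnchorSpec("madrs_total", "severity_categorical")
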