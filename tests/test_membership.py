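"""Membership-weight construction, HCPM aggregation, and covariate averaging."""

import numpy as np
import pandas as pd
import pytest

from mmhurdle import (
    CareProfile,
    aggregate_weighted_covariates,
    build_membership_table,
    derive_hcpm_weights,
    weight_sum_squares,
)
from mmhurdle.membership import MembershipError, validate_membership

from conftest import random_membership


class TestBuildMembership:
    def test_single_membership_weight_is_one(self):
        visits = pd.DataFrame(
            {"individual_id": ["a"], "hcp_id": ["h1"], "care_units": [5.0]}
        )
        mt = build_membership_table(visits)
        assert mt["weight_w"].tolist() == [1.0]

    def test_equal_care_gives_equal_weights(self):
        visits = pd.DataFrame(
            {
                "individual_id": ["a", "a"],
                "hcp_id": ["h1", "h2"],
                "care_units": [3.0, 3.0],
            }
        )
        mt = build_membership_table(visits)
        assert mt["weight_w"].tolist() == [0.5, 0.5]

    def test_duplicate_rows_are_summed_before_weighting(self):
        visits = pd.DataFrame(
            {
                "individual_id": ["a", "a", "a"],
                "hcp_id": ["h1", "h1", "h2"],
                "care_units": [1.0, 2.0, 1.0],
            }
        )
        mt = build_membership_table(visits).set_index("hcp_id")
        assert mt.loc["h1", "weight_w"] == 0.75
        assert len(mt) == 2

    def test_random_weights_sum_to_one_against_brute_force(self):
        rng = np.random.default_rng(1)
        visits = random_membership(rng, 50, 12)
        mt = build_membership_table(visits)
        # independent oracle: recompute each individual's sum from raw visits
        for ind, grp in visits.groupby("individual_id"):
            total = grp["care_units"].sum()
            expected = grp.groupby("hcp_id")["care_units"].sum() / total
            got = mt[mt["individual_id"] == ind].set_index("hcp_id")["weight_w"]
            assert np.allclose(got.sort_index(), expected.sort_index(), atol=1e-15)
            assert abs(got.sum() - 1.0) < 1e-12
        validate_membership(mt)

    def test_zero_total_care_rejected_with_individual_named(self):
        visits = pd.DataFrame(
            {"individual_id": ["bad"], "hcp_id": ["h1"], "care_units": [0.0]}
        )
        with pytest.raises(MembershipError, match="bad"):
            build_membership_table(visits)

    def test_negative_care_rejected(self):
        visits = pd.DataFrame(
            {"individual_id": ["a"], "hcp_id": ["h1"], "care_units": [-1.0]}
        )
        with pytest.raises(MembershipError, match="negative"):
            build_membership_table(visits)


class TestHcpmWeights:
    def test_colocated_hcps_collapse_to_single_municipality(self, tiny_hcps):
        mt = pd.DataFrame(
            {
                "individual_id": ["a", "a"],
                "hcp_id": ["h1", "h3"],
                "weight_w": [0.5, 0.5],
            }
        )
        omega = derive_hcpm_weights(mt, tiny_hcps)
        assert omega["municipality_id"].tolist() == ["G"]
        assert omega["weight_omega"].tolist() == [1.0]

    def test_equal_care_across_two_municipalities(self, tiny_hcps):
        # an individual attending one provider in G and one in V with equal
        # care splits omega equally between the two municipalities
        mt = pd.DataFrame(
            {
                "individual_id": ["black", "black"],
                "hcp_id": ["h1", "h2"],
                "weight_w": [0.5, 0.5],
            }
        )
        omega = derive_hcpm_weights(mt, tiny_hcps).set_index("municipality_id")
        assert omega.loc["G", "weight_omega"] == 0.5
        assert omega.loc["V", "weight_omega"] == 0.5

    def test_conservation_under_group_sum_oracle(self):
        rng = np.random.default_rng(2)
        visits = random_membership(rng, 40, 30)
        hcps = pd.DataFrame(
            {
                "hcp_id": [f"h{j}" for j in range(30)],
                "hcp_type": ["GP"] * 30,
                "municipality_id": [f"m{j % 20}" for j in range(30)],
            }
        )
        mt = build_membership_table(visits)
        omega = derive_hcpm_weights(mt, hcps)
        w_sums = mt.groupby("individual_id")["weight_w"].sum()
        o_sums = omega.groupby("individual_id")["weight_omega"].sum()
        assert np.allclose(w_sums, 1.0, atol=1e-12)
        assert np.allclose(o_sums.reindex(w_sums.index), w_sums, atol=1e-12)

    def test_unknown_hcp_rejected(self, tiny_hcps):
        mt = pd.DataFrame(
            {"individual_id": ["a"], "hcp_id": ["nope"], "weight_w": [1.0]}
        )
        with pytest.raises(MembershipError, match="nope"):
            derive_hcpm_weights(mt, tiny_hcps)


class TestWeightSumSquares:
    @pytest.mark.parametrize(
        "w,expected",
        [
            ((1.0,), 1.0),
            ((1 / 3, 1 / 3, 1 / 3), 1 / 3),
            ((0.75, 0.12, 0.12), 0.5913),
        ],
    )
    def test_profile_sum_squares(self, w, expected):
        profile = CareProfile(w, (1.0,), literal=True)
        sw2, so2 = weight_sum_squares(profile)
        assert sw2 == pytest.approx(expected, abs=1e-12)
        assert so2 == 1.0

    def test_strictly_decreasing_in_equal_split_count(self):
        vals = [
            weight_sum_squares(CareProfile.equal(k))[0] for k in range(1, 14)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_table_form_matches_profile_form(self, tiny_hcps):
        mt = pd.DataFrame(
            {
                "individual_id": ["a", "a", "a"],
                "hcp_id": ["h1", "h2", "h3"],
                "weight_w": [0.5, 0.25, 0.25],
            }
        )
        omega = derive_hcpm_weights(mt, tiny_hcps)
        out = weight_sum_squares(mt, omega)
        assert out.loc[0, "sum_w2"] == pytest.approx(0.375)
        # h1 and h3 are co-located: omega = (0.75, 0.25)
        assert out.loc[0, "sum_omega2"] == pytest.approx(0.75**2 + 0.25**2)


class TestAggregateCovariates:
    def test_single_membership_passes_covariate_through(self, tiny_hcps):
        mt = pd.DataFrame(
            {"individual_id": ["a"], "hcp_id": ["h2"], "weight_w": [1.0]}
        )
        agg = aggregate_weighted_covariates(mt, tiny_hcps, hcp_covariates=["beds"])
        assert agg["hcp_beds"].tolist() == [30.0]

    def test_halves_average_midpoint(self, tiny_hcps):
        mt = pd.DataFrame(
            {
                "individual_id": ["a", "a"],
                "hcp_id": ["h1", "h2"],
                "weight_w": [0.5, 0.5],
            }
        )
        agg = aggregate_weighted_covariates(mt, tiny_hcps, hcp_covariates=["beds"])
        assert agg["hcp_beds"].tolist() == [20.0]

    def test_matches_dense_matrix_product_oracle(self):
        rng = np.random.default_rng(3)
        n_ind, n_hcp = 30, 15
        visits = random_membership(rng, n_ind, n_hcp)
        mt = build_membership_table(visits)
        hcps = pd.DataFrame(
            {
                "hcp_id": [f"h{j}" for j in range(n_hcp)],
                "hcp_type": ["GP"] * n_hcp,
                "municipality_id": ["m0"] * n_hcp,
                "x1": rng.normal(size=n_hcp),
                "x2": rng.normal(size=n_hcp),
            }
        )
        agg = aggregate_weighted_covariates(
            mt, hcps, hcp_covariates=["x1", "x2"]
        ).set_index("individual_id")
        # dense oracle: explicit weight matrix times covariate matrix
        inds = sorted(mt["individual_id"].unique())
        W = np.zeros((len(inds), n_hcp))
        for _, r in mt.iterrows():
            W[inds.index(r["individual_id"]), int(r["hcp_id"][1:])] = r["weight_w"]
        dense = W @ hcps[["x1", "x2"]].to_numpy()
        got = agg.loc[inds, ["hcp_x1", "hcp_x2"]].to_numpy()
        assert np.allclose(got, dense, atol=1e-12)

    def test_missing_covariate_values_listed(self, tiny_hcps):
        hcps = tiny_hcps.copy()
        hcps.loc[1, "beds"] = np.nan
        mt = pd.DataFrame(
            {"individual_id": ["a"], "hcp_id": ["h2"], "weight_w": [1.0]}
        )
        with pytest.raises(MembershipError, match="h2"):
            aggregate_weighted_covariates(mt, hcps, hcp_covariates=["beds"])
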