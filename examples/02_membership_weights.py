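"""Build multiple-membership weights from a visit log.

Care-share weights w (per provider) sum to one for each individual;
summing them over co-located providers gives the provider-municipality
weights omega. The sums of squared weights drive the total-variance
formula downstream.
"""

import pandas as pd

from mmhurdle import (
    aggregate_weighted_covariates,
    build_membership_table,
    derive_hcpm_weights,
    weight_sum_squares,
)

visits = pd.DataFrame(
    {
        "individual_id": ["anna", "anna", "anna", "bo"],
        "hcp_id": ["gp1", "gp2", "dept1", "gp1"],
        "care_units": [6, 2, 2, 4],  # e.g. visit counts
    }
)
hcps = pd.DataFrame(
    {
        "hcp_id": ["gp1", "gp2", "dept1"],
        "hcp_type": ["GP", "GP", "hospital_department"],
        "municipality_id": ["Aarhus", "Aarhus", "Odense"],
        "bed_capacity": [0.0, 0.0, 25.0],
    }
)

mt = build_membership_table(visits)
print("provider weights:")
print(mt.to_string(index=False))

omega = derive_hcpm_weights(mt, hcps)
print("\nprovider-municipality weights:")
print(omega.to_string(index=False))

print("\nsums of squared weights (1 = all care in one unit):")
print(weight_sum_squares(mt, omega).to_string(index=False))

agg = aggregate_weighted_covariates(mt, hcps, hcp_covariates=["bed_capacity"])
print("\ncare-weighted provider covariates:")
print(agg.to_string(index=False))
# anna splits care 0.6/0.2/0.2, so 80% of her care-time weight is in Aarhus;
# her weighted bed capacity is 0.2 * 25 = 5 beds.
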