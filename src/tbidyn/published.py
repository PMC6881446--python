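"""Feature lists of the published dynamic algorithms.

These are the final selections reported for the original three-center cohort:
14 dynamic features (plus the age category) for the ICP-MAP-CPP algorithm and
13 (plus age) for the ICP-MAP-CPP-GCS algorithm, in relative importance order.
The published regression coefficients belong to that cohort and are not
packaged; refitting on the cohort at hand with these fixed feature lists
reproduces the published model *structure* without feature selection.
"""

from __future__ import annotations

from .features import enumerate_features

#: dynamic features of the published ICP-MAP-CPP algorithm, importance order
PUBLISHED_ICP_MAP_CPP = (
    "icp_end",
    "map_q10_coef",
    "cpp_diff_begin",
    "map_q90_end",
    "map_coef",
    "icp_q90_end",
    "icp_diff_end",
    "icp_diff_coef",
    "map_var_begin",
    "icp_var_begin",
    "icp_diff_begin",
    "cpp_q10_end",
    "map_var_coef",
    "map_q10_begin",
)

#: dynamic features of the published ICP-MAP-CPP-GCS algorithm, importance order
PUBLISHED_ICP_MAP_CPP_GCS = (
    "er_min_end",
    "icp_end",
    "er_max_end",
    "map_q10_coef",
    "er_end",
    "map_coef",
    "mr_end",
    "icp_diff_begin",
    "icp_diff_coef",
    "icp_var_begin",
    "er_var_end",
    "mr_coef",
    "er_max_begin",
)

#: age category accompanies both published models
PUBLISHED_WITH_AGE = {
    "ICP-MAP-CPP": list(PUBLISHED_ICP_MAP_CPP) + ["agecat"],
    "ICP-MAP-CPP-GCS": list(PUBLISHED_ICP_MAP_CPP_GCS) + ["agecat"],
}


def published_feature_list(variant: str, with_age: bool = True) -> list[str]:
    if variant not in PUBLISHED_WITH_AGE:
        raise ValueError(f"unknown variant {variant!r}")
    names = PUBLISHED_WITH_AGE[variant]
    out = list(names) if with_age else [n for n in names if n != "agecat"]
    candidates = {e.name for e in enumerate_features(variant)} | {"agecat"}
    missing = [n for n in out if n not in candidates]
    assert not missing, f"published features absent from candidate scheme: {missing}"
    return out
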