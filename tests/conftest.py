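from datetime import date

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")

# The ten published pairwise 2x2 tables among abnormality categories in
# notified participants: (a, b, c, d) with the printed p-value and the test
# the publication marked for each pair.
PUBLISHED_TABLES = {
    ("blood_sugar", "renal"): ((51, 67, 50, 86), 0.3576, "pearson_yates"),
    ("blood_sugar", "lipid"): ((85, 33, 5, 131), 1e-4, "fisher"),  # printed "<0.0001"
    ("blood_sugar", "hematological"): ((17, 101, 25, 111), 0.4957, "pearson_yates"),
    ("blood_sugar", "liver"): ((18, 100, 10, 126), 0.07115, "pearson_yates"),
    ("renal", "lipid"): ((40, 61, 50, 103), 0.3197, "pearson_yates"),
    ("renal", "hematological"): ((19, 82, 23, 130), 0.5347, "pearson_yates"),
    ("renal", "liver"): ((12, 89, 16, 137), 0.8809, "pearson_yates"),
    ("lipid", "hematological"): ((11, 79, 31, 133), 0.2324, "pearson_yates"),
    ("lipid", "liver"): ((13, 77, 15, 149), 0.2801, "pearson_yates"),
    ("hematological", "liver"): ((3, 39, 25, 187), 0.5889, "fisher"),
}

# Published questionnaire tabulations: per-category counts, no-answer count,
# and the printed percentages (round-half-up, one decimal).
PUBLISHED_BEHAVIOR = {
    "pre_all": ([95, 15, 39, 24, 55], 26, [41.7, 6.6, 17.1, 10.5, 24.1]),
    "post_all": ([116, 3, 21, 8, 15], 91, [71.2, 1.8, 12.9, 4.9, 9.2]),
    "pre_paired": ([68, 7, 25, 14, 37], 0, [45.0, 4.6, 16.6, 9.3, 24.5]),
    "post_paired": ([107, 3, 20, 8, 13], 0, [70.9, 2.0, 13.2, 5.3, 8.6]),
}


@pytest.fixture(scope="session")
def published_tables():
    return PUBLISHED_TABLES


@pytest.fixture(scope="session")
def published_behavior():
    return PUBLISHED_BEHAVIOR


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic synthetic cohort shared across tests."""
    from hbpnotify.synthetic import SyntheticConfig, generate_cohort

    config = SyntheticConfig(n_participants=120, seed=20240901)
    return config, generate_cohort(config)


# A synthetic joint assignment of the five flags over 254 participants whose
# ten pairwise 2x2 cross-tabulations (and five marginals) all equal the
# published tables. Found once by integer programming; the publication only
# determines the pairwise margins, not the joint, so this is a stand-in
# consistent with every printed count. State s encodes flags bitwise in
# category order (bit i = category i).
JOINT_STATE_COUNTS = [
    73, 1, 31, 16, 0, 43, 0, 23, 3, 11, 14, 0, 0, 6, 5, 0,
    7, 5, 0, 0, 0, 1, 0, 12, 3, 0, 0, 0, 0, 0, 0, 0,
]

CATEGORY_ORDER = ("blood_sugar", "renal", "lipid", "hematological", "liver")


def reconstruct_flags_from_tables() -> pd.DataFrame:
    """Per-participant boolean flags reproducing all published pairwise
    cross-tabulations at once (synthetic reconstruction, see above)."""
    rows = []
    pid = 0
    for state, count in enumerate(JOINT_STATE_COUNTS):
        for _ in range(count):
            rows.append(
                {
                    "participant_id": f"N{pid:04d}",
                    **{c: bool((state >> i) & 1) for i, c in enumerate(CATEGORY_ORDER)},
                }
            )
            pid += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def published_flags():
    return reconstruct_flags_from_tables()
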