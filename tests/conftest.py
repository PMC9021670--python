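import numpy as np
import pandas as pd
import pytest

from nhsc import InsurerClaimsTable, RatingSet, fixtures


def make_claims_table(insurer_id, population, rows):
    """rows: list of (icd3, cases, mean_cost)."""
    return InsurerClaimsTable(
        insurer_id=insurer_id,
        population=population,
        rows=pd.DataFrame(rows, columns=["icd3", "cases", "mean_cost"]),
    )


def make_rating_set(values_by_code, round=2, specialties=None, missing=()):
    """Build a RatingSet from {code: [ratings]}; NaN marks missing."""
    recs = []
    for code, values in values_by_code.items():
        for i, v in enumerate(values):
            spec = (
                specialties[i % len(specialties)]
                if specialties
                else ["primary_care", "hospital_specialist", "nursing", "research"][i % 4]
            )
            recs.append(
                {
                    "expert_id": f"e{i:03d}",
                    "icd3": code,
                    "rating": v,
                    "comment_given": bool(np.isnan(v)) or (code, i) in missing,
                    "specialty": spec,
                    "age_band": ["<40", "40-49", "50-59", ">=60"][i % 4],
                    "gender": ["female", "male"][i % 2],
                }
            )
    return RatingSet(round=round, records=pd.DataFrame(recs))


@pytest.fixture(scope="session")
def diagnosis_table():
    return fixtures.load_diagnosis_table()


@pytest.fixture(scope="session")
def round2_summaries():
    return fixtures.load_round2_summaries()


@pytest.fixture(scope="session")
def round2_table():
    return fixtures.load_round2_table()


@pytest.fixture(scope="session")
def workshop_outcomes():
    return fixtures.load_workshop_outcomes()


@pytest.fixture(scope="session")
def category_map():
    return fixtures.load_category_map()[0]


@pytest.fixture(scope="session")
def claims_table():
    return fixtures.load_claims_table()
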