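"""Aggregation of per-insurer hospital discharge-diagnosis tables.

Statutory health insurers deliver, per insurer, an aggregated table of
3-character ICD-10-GM discharge diagnoses (case count and mean cost per
case) for their nursing-home resident population, together with resident
counts by age band and gender and hospitalized-person counts by gender.
This module pools those tables case-weighted, applies the frequency
threshold that defines the "common" diagnoses, and produces the ranked
frequency/cost table and the demographic summary measures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ICD3_RE = re.compile(r"^[A-Z]\d{2}$")

#: Age bands used in the demographic strata, youngest to oldest.
AGE_BANDS = (
    "0-14", "15-19", "20-24", "25-29", "30-34", "35-39", "40-44",
    "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85-89", ">=90",
)

CLAIMS_COLUMNS = ["icd3", "cases", "mean_cost"]


def _validate_icd3(code: str) -> None:
    if not isinstance(code, str) or not ICD3_RE.match(code):
        raise ValueError(f"malformed ICD-10 3-character code: {code!r}")


@dataclass
class InsurerClaimsTable:
    """One insurer's (or the pooled) aggregated discharge-diagnosis table.

    Parameters
    ----------
    insurer_id
        Identifier of the insurer, or ``"pooled"`` for a merged table.
    population
        Number of nursing-home residents insured (person denominator).
    rows
        DataFrame with columns ``icd3``, ``cases`` (int), ``mean_cost``
        (euros per case); optionally ``label``.
    demographics
        Long-format DataFrame ``age_band, gender, residents``; may be empty
        when strata were not delivered.
    hospitalized_persons
        Persons with >= 1 hospitalization, keyed by gender.
    hospitalizations
        Hospitalization counts keyed by gender.
    """

    insurer_id: str
    population: int
    rows: pd.DataFrame
    demographics: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["age_band", "gender", "residents"])
    )
    hospitalized_persons: dict[str, int] = field(default_factory=dict)
    hospitalizations: dict[str, int] = field(default_factory=dict)
    pooled: bool = False

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be positive")
        self.rows = pd.DataFrame(self.rows).reset_index(drop=True)
        for col in CLAIMS_COLUMNS:
            if col not in self.rows.columns:
                raise ValueError(f"claims rows missing column {col!r}")
        for code in self.rows["icd3"]:
            _validate_icd3(code)
        if self.rows["icd3"].duplicated().any():
            dupes = self.rows["icd3"][self.rows["icd3"].duplicated()].tolist()
            raise ValueError(f"duplicate ICD-10 codes in claims table: {dupes}")
        if (self.rows["cases"] < 0).any():
            raise ValueError("negative case counts")
        if not (self.rows["cases"] == self.rows["cases"].astype(int)).all():
            raise ValueError("case counts must be integers")
        self.rows["cases"] = self.rows["cases"].astype(int)
        if (self.rows["mean_cost"] < 0).any():
            raise ValueError("negative mean costs")
        if len(self.demographics):
            strata_total = int(self.demographics["residents"].sum())
            if strata_total != self.population:
                raise ValueError(
                    f"demographic cells sum to {strata_total}, "
                    f"population is {self.population}"
                )
        for gender, hosp in self.hospitalized_persons.items():
            residents = (
                int(self.demographics.loc[self.demographics["gender"] == gender, "residents"].sum())
                if len(self.demographics)
                else self.population
            )
            if hosp > residents:
                raise ValueError(
                    f"hospitalized persons ({hosp}) exceed residents ({residents}) for {gender}"
                )

    @property
    def total_cases(self) -> int:
        return int(self.rows["cases"].sum())

    def case_share(self, icd3: str, denominator: str = "population") -> float:
        """Share of one code, against residents or total hospitalizations."""
        cases = int(self.rows.loc[self.rows["icd3"] == icd3, "cases"].sum())
        denom = self.population if denominator == "population" else self.total_cases
        return cases / denom


@dataclass
class AggregatedDiagnosisTable:
    """Ranked pooled frequency/cost table with a below-threshold remainder."""

    rows: pd.DataFrame  # rank, icd3, label, cases, mean_cost, pct_of_cases, cum_pct
    remainder_cases: int
    remainder_mean_cost: float
    total_cases: int
    total_population: int
    remainder_total_cost: float | None = None

    @property
    def included_cases(self) -> int:
        return int(self.rows["cases"].sum())

    @property
    def included_cost(self) -> float:
        return float((self.rows["cases"] * self.rows["mean_cost"]).sum())

    @property
    def total_cost(self) -> float:
        """Pooled cost of all hospitalizations, included plus remainder.

        Uses the separately delivered remainder total cost when available,
        otherwise remainder cases x remainder mean cost.
        """
        rem = (
            self.remainder_total_cost
            if self.remainder_total_cost is not None
            else self.remainder_cases * self.remainder_mean_cost
        )
        return self.included_cost + rem


@dataclass
class DemographicsReport:
    """Strata percentages and hospitalization summary measures.

    ``by_gender`` rows carry, per gender and for the total population:
    hospitalized-person proportion (hospitalized persons / residents),
    hospitalization ratio (hospitalizations / hospitalized persons, null
    when no person was hospitalized) and annual incidence
    (hospitalizations / residents).
    """

    strata: pd.DataFrame  # age_band, gender, residents, pct_of_total
    by_gender: pd.DataFrame  # gender, residents, hospitalized, hospitalizations, proportion, ratio, incidence


def merge_insurer_tables(tables: list[InsurerClaimsTable]) -> InsurerClaimsTable:
    """Pool insurer tables: case counts summed, mean costs case-weighted.

    Order-invariant; a single table is returned as its own pooled copy.
    """
    if not tables:
        raise ValueError("need at least one insurer table to merge")
    frames = []
    for t in tables:
        f = t.rows[["icd3", "cases", "mean_cost"]].copy()
        if "label" in t.rows.columns:
            f["label"] = t.rows["label"]
        f["cost"] = f["cases"] * f["mean_cost"]
        frames.append(f)
    cat = pd.concat(frames, ignore_index=True)
    agg = {"cases": "sum", "cost": "sum"}
    if "label" in cat.columns:
        agg["label"] = "first"
    pooled = cat.groupby("icd3", as_index=False).agg(agg)
    pooled["mean_cost"] = np.where(
        pooled["cases"] > 0, pooled["cost"] / pooled["cases"].replace(0, 1), 0.0
    )
    pooled = pooled.sort_values("icd3", kind="stable").reset_index(drop=True)
    cols = ["icd3", "cases", "mean_cost"] + (["label"] if "label" in pooled else [])
    demo_frames = [t.demographics for t in tables if len(t.demographics)]
    if demo_frames:
        demo = (
            pd.concat(demo_frames, ignore_index=True)
            .groupby(["age_band", "gender"], as_index=False)["residents"]
            .sum()
        )
    else:
        demo = pd.DataFrame(columns=["age_band", "gender", "residents"])
    hosp_persons: dict[str, int] = {}
    hosps: dict[str, int] = {}
    for t in tables:
        for g, v in t.hospitalized_persons.items():
            hosp_persons[g] = hosp_persons.get(g, 0) + int(v)
        for g, v in t.hospitalizations.items():
            hosps[g] = hosps.get(g, 0) + int(v)
    return InsurerClaimsTable(
        insurer_id="pooled",
        population=sum(t.population for t in tables),
        rows=pooled[cols],
        demographics=demo,
        hospitalized_persons=hosp_persons,
        hospitalizations=hosps,
        pooled=True,
    )


def apply_frequency_threshold(
    tables: InsurerClaimsTable | list[InsurerClaimsTable],
    threshold: float = 0.001,
    scope: str = "per_insurer",
    denominator: str = "population",
) -> set[str]:
    """Codes whose case share exceeds ``threshold``.

    ``scope="per_insurer"`` retains the union of codes passing in at least
    one insurer (the filter runs before pooling, so a code common in one
    fund's population survives even if rare overall); ``scope="pooled"``
    filters the merged table. ``denominator`` selects residents
    (``"population"``) or hospitalizations (``"cases"``) as the base.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if scope not in ("per_insurer", "pooled"):
        raise ValueError(f"unknown scope {scope!r}")
    if isinstance(tables, InsurerClaimsTable):
        tables = [tables]
    if scope == "pooled":
        tables = [merge_insurer_tables(tables)]
    retained: set[str] = set()
    for t in tables:
        denom = t.population if denominator == "population" else t.total_cases
        share = t.rows["cases"] / denom
        keep = t.rows.loc[(share > threshold) & (t.rows["cases"] > 0), "icd3"]
        retained.update(keep)
    return retained


def rank_and_cumulate(
    table: InsurerClaimsTable,
    retained: set[str],
    remainder_mean_cost: float | None = None,
    remainder_total_cost: float | None = None,
) -> AggregatedDiagnosisTable:
    """Rank retained codes by cases descending and cumulate case shares.

    Ties are broken by code lexicographic order. Codes outside ``retained``
    are pooled into the remainder row; its mean cost is carried as provided
    via ``remainder_mean_cost`` when the source table prints one, otherwise
    recomputed case-weighted from the dropped rows.
    """
    unknown = retained - set(table.rows["icd3"])
    if unknown:
        raise ValueError(f"retained codes absent from table: {sorted(unknown)}")
    total = table.total_cases
    if total == 0:
        raise ValueError("table has zero hospitalizations")
    kept = table.rows[table.rows["icd3"].isin(retained)].copy()
    dropped = table.rows[~table.rows["icd3"].isin(retained)]
    kept = kept.sort_values(
        ["cases", "icd3"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    kept.insert(0, "rank", np.arange(1, len(kept) + 1))
    kept["pct_of_cases"] = kept["cases"] / total * 100.0
    kept["cum_pct"] = kept["pct_of_cases"].cumsum()
    rem_cases = int(dropped["cases"].sum())
    if remainder_mean_cost is None:
        rem_mean = (
            float((dropped["cases"] * dropped["mean_cost"]).sum() / rem_cases)
            if rem_cases
            else 0.0
        )
    else:
        rem_mean = float(remainder_mean_cost)
    if "label" not in kept.columns:
        kept["label"] = ""
    cols = ["rank", "icd3", "label", "cases", "mean_cost", "pct_of_cases", "cum_pct"]
    return AggregatedDiagnosisTable(
        rows=kept[cols],
        remainder_cases=rem_cases,
        remainder_mean_cost=rem_mean,
        total_cases=total,
        total_population=table.population,
        remainder_total_cost=remainder_total_cost,
    )


def summarize_demographics(
    table: InsurerClaimsTable, total_hospitalizations: int | None = None
) -> DemographicsReport:
    """Strata percentages plus proportion / ratio / incidence per gender.

    All measures are computed unrounded; display rounding is left to the
    writers. A gender with zero hospitalized persons but positive
    hospitalizations is an inconsistency and raises.
    """
    demo = table.demographics.copy()
    if not len(demo):
        raise ValueError("table carries no demographic strata")
    demo["pct_of_total"] = demo["residents"] / table.population * 100.0
    genders = sorted(set(demo["gender"]))
    rows = []
    for g in genders + ["total"]:
        if g == "total":
            residents = table.population
            hosp = sum(table.hospitalized_persons.values())
            n_hosp = (
                total_hospitalizations
                if total_hospitalizations is not None
                else sum(table.hospitalizations.values())
            )
        else:
            residents = int(demo.loc[demo["gender"] == g, "residents"].sum())
            hosp = int(table.hospitalized_persons.get(g, 0))
            n_hosp = int(table.hospitalizations.get(g, 0))
        if hosp > residents:
            raise ValueError(f"hospitalized persons exceed residents for {g}")
        if hosp == 0 and n_hosp > 0:
            raise ValueError(f"{g}: hospitalizations without hospitalized persons")
        rows.append(
            {
                "gender": g,
                "residents": residents,
                "hospitalized_persons": hosp,
                "hospitalizations": n_hosp,
                "proportion": hosp / residents if residents else np.nan,
                "ratio": n_hosp / hosp if hosp else np.nan,
                "incidence": n_hosp / residents if residents else np.nan,
            }
        )
    return DemographicsReport(strata=demo, by_gender=pd.DataFrame(rows))
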