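"""Loaders for the transcribed study tables shipped with the package.

The shipped fixtures are plain-CSV/JSON transcriptions of the published
pooled tables (decimal commas normalized to points): the pooled
demographics, the 117-row ranked frequency/cost table with its
below-threshold remainder, the round-2 rating summaries with workshop
flags and consensus values, the workshop outcomes, the disease-category
assignment of the final list, and the printed extrapolation reference
values.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .claims import AggregatedDiagnosisTable, InsurerClaimsTable
from .consensus import WorkshopOutcome
from .delphi import DelphiSummary
from .io import _split_demographics

_DATA = resources.files("nhsc") / "data"


def _read_csv(name: str) -> pd.DataFrame:
    with (_DATA / name).open("rb") as fh:
        return pd.read_csv(fh)


def load_diagnosis_meta() -> dict:
    with (_DATA / "pooled_diagnoses_meta.json").open("r", encoding="utf-8") as fh:
        return json.load(fh)


def load_demographics() -> pd.DataFrame:
    return _read_csv("pooled_demographics.csv")


def load_claims_table() -> InsurerClaimsTable:
    """The pooled study table: 117 retained codes + demographic strata.

    The below-threshold remainder is not part of the per-code rows; use
    :func:`load_diagnosis_table` for totals including it.
    """
    meta = load_diagnosis_meta()
    diag = _read_csv("pooled_diagnoses.csv")
    bands, hosp_persons, hosps = _split_demographics(load_demographics())
    return InsurerClaimsTable(
        insurer_id="pooled",
        population=meta["population"],
        rows=diag.rename(columns={"mean_cost_eur": "mean_cost"})[
            ["icd3", "cases", "mean_cost", "label"]
        ],
        demographics=bands,
        hospitalized_persons=hosp_persons,
        hospitalizations=hosps,
        pooled=True,
    )


def load_diagnosis_table() -> AggregatedDiagnosisTable:
    """The ranked frequency/cost table with remainder and printed totals."""
    meta = load_diagnosis_meta()
    diag = _read_csv("pooled_diagnoses.csv").rename(columns={"mean_cost_eur": "mean_cost"})
    diag["pct_of_cases"] = diag["cases"] / meta["total_cases"] * 100.0
    diag["cum_pct"] = diag["pct_of_cases"].cumsum()
    return AggregatedDiagnosisTable(
        rows=diag[["rank", "icd3", "label", "cases", "mean_cost", "pct_of_cases", "cum_pct"]],
        remainder_cases=meta["remainder_cases"],
        remainder_mean_cost=meta["remainder_mean_cost_eur"],
        total_cases=meta["total_cases"],
        total_population=meta["population"],
        remainder_total_cost=meta["remainder_total_cost_eur"],
    )


def load_round2_table() -> pd.DataFrame:
    """Raw transcription of the round-2 summary table (one row per code)."""
    return _read_csv("round2_summaries.csv")


def load_round2_summaries() -> list[DelphiSummary]:
    """Round-2 :class:`DelphiSummary` objects (quartiles not printed -> None)."""
    r2 = load_round2_table()
    return [
        DelphiSummary(
            icd3=r.icd3,
            round=2,
            n_valid=int(r.n),
            median=float(r.r2_median),
            p12_5=float(r.p12_5),
            p87_5=float(r.p87_5),
            width75=float(r.width75),
            sd=float(r.sd),
            kw_p_specialty=float(r.kw_p_specialty),
        )
        for r in r2.itertuples()
    ]


def load_round1_summaries() -> list[DelphiSummary]:
    """Round-1 summaries (only the median was printed; dispersion unknown).

    The printed round-1 medians equal the round-2 medians for every code;
    dispersion fields are filled with the round-2 values so ordering
    invariants hold, and should not be read as round-1 dispersion.
    """
    r2 = load_round2_table()
    return [
        DelphiSummary(
            icd3=r.icd3,
            round=1,
            n_valid=107,
            median=float(r.r1_median),
            p12_5=min(float(r.p12_5), float(r.r1_median)),
            p87_5=max(float(r.p87_5), float(r.r1_median)),
            width75=float(r.width75),
            sd=float(r.sd),
        )
        for r in r2.itertuples()
    ]


def load_workshop_outcomes() -> list[WorkshopOutcome]:
    with (_DATA / "workshop_outcomes.csv").open("rb") as fh:
        frame = pd.read_csv(fh)
    outcomes = []
    for r in frame.itertuples():
        consented = str(r.consented).strip().lower() == "true"
        value = None if pd.isna(r.consented_avoidability) else float(r.consented_avoidability)
        outcomes.append(
            WorkshopOutcome(icd3=r.icd3, consented=consented, consented_avoidability=value)
        )
    return outcomes


def load_category_map() -> tuple[dict[str, int], dict[int, str]]:
    frame = _read_csv("disease_categories.csv")
    return (
        dict(zip(frame["icd3"], frame["category_id"].astype(int))),
        dict(zip(frame["category_id"].astype(int), frame["category_label"])),
    )


def load_extrapolation_reference() -> dict:
    """Printed extrapolation grid (reference values, not inputs)."""
    with (_DATA / "extrapolation_reference.json").open("r", encoding="utf-8") as fh:
        return json.load(fh)
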