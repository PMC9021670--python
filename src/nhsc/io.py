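"""CSV readers and writers for the pipeline's exchange formats.

All files are UTF-8, comma-separated, decimal point. Formats (headers):

* claims:        ``insurer_id,icd3,cases,mean_cost_eur`` (+ optional label)
* demographics:  ``insurer_id,age_band,gender,residents,hospitalized_persons,hospitalizations``
  (hospitalized/hospitalization counts on ``age_band == "all"`` rows)
* ratings:       ``round,expert_id,icd3,rating,comment_given,specialty,age_band,gender``
  (empty rating field = missing)
* aggregated:    ``rank,icd3,label,cases,pct,cum_pct,mean_cost_eur``
* summaries:     per-code round statistics mirroring the round-2 report
* workshop:      ``icd3,consented,consented_avoidability``
* categories:    ``icd3,category_id,category_label``
* consensus:     ``icd3,route,final_avoidability,nhs_flag,category_id``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .claims import AggregatedDiagnosisTable, InsurerClaimsTable
from .consensus import WorkshopOutcome
from .delphi import DelphiSummary, RatingSet


def _split_demographics(demo: pd.DataFrame):
    bands = demo[demo["age_band"] != "all"][["age_band", "gender", "residents"]]
    totals = demo[demo["age_band"] == "all"]
    hosp_persons = {
        r.gender: int(r.hospitalized_persons)
        for r in totals.itertuples()
        if not pd.isna(r.hospitalized_persons)
    }
    hosps = {
        r.gender: int(r.hospitalizations)
        for r in totals.itertuples()
        if not pd.isna(r.hospitalizations)
    }
    return bands.reset_index(drop=True), hosp_persons, hosps


def read_claims_csv(
    claims_path: str | Path, demographics_path: str | Path | None = None
) -> list[InsurerClaimsTable]:
    """Per-insurer tables from the claims (and optional demographics) CSVs."""
    claims = pd.read_csv(claims_path)
    demo_all = pd.read_csv(demographics_path) if demographics_path else None
    tables = []
    for insurer, g in claims.groupby("insurer_id", sort=True):
        cols = ["icd3", "cases", "mean_cost"] + (["label"] if "label" in g.columns else [])
        rows = g.rename(columns={"mean_cost_eur": "mean_cost"})[cols]
        if demo_all is not None:
            demo_i = demo_all[demo_all["insurer_id"] == insurer]
            bands, hosp_persons, hosps = _split_demographics(demo_i)
            population = int(bands["residents"].sum())
        else:
            bands = pd.DataFrame(columns=["age_band", "gender", "residents"])
            hosp_persons, hosps = {}, {}
            population = int(rows["cases"].sum())  # fallback denominator
        tables.append(
            InsurerClaimsTable(
                insurer_id=str(insurer),
                population=population,
                rows=rows.reset_index(drop=True),
                demographics=bands,
                hospitalized_persons=hosp_persons,
                hospitalizations=hosps,
            )
        )
    return tables


def write_claims_csv(
    tables: list[InsurerClaimsTable],
    claims_path: str | Path,
    demographics_path: str | Path | None = None,
) -> None:
    frames = []
    for t in tables:
        f = t.rows.rename(columns={"mean_cost": "mean_cost_eur"}).copy()
        f.insert(0, "insurer_id", t.insurer_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(claims_path, index=False)
    if demographics_path is not None:
        rows = []
        for t in tables:
            for r in t.demographics.itertuples():
                rows.append(
                    {
                        "insurer_id": t.insurer_id,
                        "age_band": r.age_band,
                        "gender": r.gender,
                        "residents": r.residents,
                        "hospitalized_persons": np.nan,
                        "hospitalizations": np.nan,
                    }
                )
            for gender in sorted(set(t.hospitalized_persons) | set(t.hospitalizations)):
                rows.append(
                    {
                        "insurer_id": t.insurer_id,
                        "age_band": "all",
                        "gender": gender,
                        "residents": int(
                            t.demographics.loc[
                                t.demographics["gender"] == gender, "residents"
                            ].sum()
                        ),
                        "hospitalized_persons": t.hospitalized_persons.get(gender),
                        "hospitalizations": t.hospitalizations.get(gender),
                    }
                )
        pd.DataFrame(rows).to_csv(demographics_path, index=False)


def write_aggregated_csv(table: AggregatedDiagnosisTable, path: str | Path) -> None:
    """Ranked table with the remainder and total rows appended (2-decimal shares)."""
    out = table.rows.copy()
    out["pct"] = out["pct_of_cases"].round(2)
    out["cum_pct"] = out["cum_pct"].round(2)
    out["mean_cost_eur"] = out["mean_cost"].round(0).astype(int)
    out = out[["rank", "icd3", "label", "cases", "pct", "cum_pct", "mean_cost_eur"]]
    rem_pct = table.remainder_cases / table.total_cases * 100
    extra = pd.DataFrame(
        [
            {
                "rank": "rest", "icd3": "", "label": "below-threshold remainder",
                "cases": table.remainder_cases, "pct": round(rem_pct, 2),
                "cum_pct": 100.0,
                "mean_cost_eur": int(round(table.remainder_mean_cost)),
            },
            {
                "rank": "total", "icd3": "", "label": "all hospitalizations",
                "cases": table.total_cases, "pct": 100.0, "cum_pct": 100.0,
                "mean_cost_eur": int(round(table.total_cost / table.total_cases)),
            },
        ]
    )
    pd.concat([out, extra], ignore_index=True).to_csv(path, index=False)


def read_ratings_csv(path: str | Path, round: int | None = None) -> list[RatingSet]:
    """Rating sets (one per round present, or the requested round only)."""
    frame = pd.read_csv(path)
    frame["rating"] = pd.to_numeric(frame["rating"], errors="coerce")
    frame["comment_given"] = frame["comment_given"].astype(bool)
    rounds = sorted(frame["round"].unique()) if round is None else [round]
    return [
        RatingSet(round=int(r), records=frame[frame["round"] == r].drop(columns="round"))
        for r in rounds
    ]


def write_ratings_csv(rating_sets: list[RatingSet], path: str | Path) -> None:
    frames = []
    for rs in rating_sets:
        f = rs.records.copy()
        f.insert(0, "round", rs.round)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


SUMMARY_COLUMNS = [
    "icd3", "round", "n_valid", "median", "q1", "q3", "p12_5", "p87_5",
    "width75", "sd", "kw_p_specialty", "kw_p_gender", "kw_p_ageband",
]


def write_summaries_csv(summaries: list[DelphiSummary], path: str | Path) -> None:
    pd.DataFrame([{c: getattr(s, c) for c in SUMMARY_COLUMNS} for s in summaries]).to_csv(
        path, index=False
    )


def read_summaries_csv(path: str | Path) -> list[DelphiSummary]:
    frame = pd.read_csv(path)
    out = []
    for r in frame.to_dict("records"):
        kwargs = {k: (None if pd.isna(v) else v) for k, v in r.items()}
        kwargs["round"] = int(kwargs["round"])
        kwargs["n_valid"] = int(kwargs["n_valid"])
        out.append(DelphiSummary(**kwargs))
    return out


def read_workshop_csv(path: str | Path) -> list[WorkshopOutcome]:
    frame = pd.read_csv(path)
    out = []
    for r in frame.itertuples():
        consented = str(r.consented).strip().lower() in ("true", "1", "yes")
        value = None if pd.isna(r.consented_avoidability) else float(r.consented_avoidability)
        out.append(
            WorkshopOutcome(icd3=r.icd3, consented=consented, consented_avoidability=value)
        )
    return out


def write_workshop_csv(outcomes: list[WorkshopOutcome], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "icd3": o.icd3,
                "consented": str(o.consented).lower(),
                "consented_avoidability": o.consented_avoidability,
            }
            for o in outcomes
        ]
    ).to_csv(path, index=False)


def read_categories_csv(path: str | Path) -> tuple[dict[str, int], dict[int, str]]:
    """(code -> category id, category id -> label) from the categories CSV."""
    frame = pd.read_csv(path)
    code_map = dict(zip(frame["icd3"], frame["category_id"].astype(int)))
    labels = dict(
        zip(frame["category_id"].astype(int), frame["category_label"])
    )
    return code_map, labels


def write_consensus_csv(final: pd.DataFrame, path: str | Path) -> None:
    cols = ["icd3", "route", "final_avoidability", "nhs_flag", "category_id"]
    final[cols].to_csv(path, index=False)
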