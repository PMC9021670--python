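"""National extrapolation of the avoidable hospitalization burden.

Sample cases and costs are scaled by the ratio of the national
nursing-home resident population to the sample population. Per code,
total cost = cases x mean cost; the avoidable part multiplies by the
consented avoidability proportion. Everything is computed at full
precision; rounding (cases to integers, euros to whole euros) happens only
when a report is rendered.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .claims import AggregatedDiagnosisTable

SCOPES = ("all", "included", "nhs")


@dataclass
class ExtrapolationInputs:
    national_population: int
    sample_population: int
    table: AggregatedDiagnosisTable
    avoidability: dict[str, float]  # flagged code -> consented percent

    def __post_init__(self) -> None:
        if self.national_population <= 0 or self.sample_population <= 0:
            raise ValueError("populations must be positive")
        missing = set(self.avoidability) - set(self.table.rows["icd3"])
        if missing:
            raise ValueError(
                f"nursing home-sensitive codes absent from the diagnosis table: "
                f"{sorted(missing)}"
            )


@dataclass
class ExtrapolationReport:
    """Unrounded per-scope totals; render with :meth:`to_frame`."""

    factor: float
    per_code: pd.DataFrame  # icd3, cases, mean_cost, cost, avoidability, avoidable_cases, avoidable_cost
    totals: pd.DataFrame  # scope, level, cases, cost, avoidable_cases, avoidable_cost

    def value(self, scope: str, level: str, column: str) -> float:
        sel = self.totals[(self.totals["scope"] == scope) & (self.totals["level"] == level)]
        return float(sel[column].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        """Report-stage rendering: cases and euros to nearest integer."""
        out = self.totals.copy()
        for col in ("cases", "cost", "avoidable_cases", "avoidable_cost"):
            out[col] = out[col].round(0).astype("Int64")
        return out


def compute_factor(national: int, sample: int) -> float:
    """Exact national/sample population ratio (no rounding)."""
    if sample <= 0:
        raise ValueError("sample population must be positive")
    if national < 0:
        raise ValueError("national population must be non-negative")
    return national / sample


def extrapolate(inputs: ExtrapolationInputs) -> ExtrapolationReport:
    """Scope x level totals for cases, costs and the avoidable burden.

    Scopes: ``all`` (every discharge including the below-threshold
    remainder), ``included`` (the retained frequency-table codes), ``nhs``
    (flagged codes, the only scope with avoidable figures). Levels:
    ``sample`` and ``national`` (sample x factor).
    """
    factor = compute_factor(inputs.national_population, inputs.sample_population)
    t = inputs.table
    per_code = t.rows[["icd3", "cases", "mean_cost"]].copy()
    per_code["cost"] = per_code["cases"] * per_code["mean_cost"]
    per_code["avoidability"] = per_code["icd3"].map(inputs.avoidability)
    av = per_code["avoidability"].fillna(0.0) / 100.0
    per_code["avoidable_cases"] = per_code["cases"] * av
    per_code["avoidable_cost"] = per_code["cost"] * av
    nhs = per_code[per_code["icd3"].isin(inputs.avoidability)]
    scoped = {
        "all": {
            "cases": float(t.total_cases),
            "cost": t.total_cost,
            "avoidable_cases": None,
            "avoidable_cost": None,
        },
        "included": {
            "cases": float(t.included_cases),
            "cost": t.included_cost,
            "avoidable_cases": None,
            "avoidable_cost": None,
        },
        "nhs": {
            "cases": float(nhs["cases"].sum()),
            "cost": float(nhs["cost"].sum()),
            "avoidable_cases": float(nhs["avoidable_cases"].sum()),
            "avoidable_cost": float(nhs["avoidable_cost"].sum()),
        },
    }
    rows = []
    for scope, vals in scoped.items():
        for level, mult in (("sample", 1.0), ("national", factor)):
            rows.append(
                {
                    "scope": scope,
                    "level": level,
                    "cases": vals["cases"] * mult,
                    "cost": vals["cost"] * mult,
                    "avoidable_cases": (
                        vals["avoidable_cases"] * mult
                        if vals["avoidable_cases"] is not None
                        else float("nan")
                    ),
                    "avoidable_cost": (
                        vals["avoidable_cost"] * mult
                        if vals["avoidable_cost"] is not None
                        else float("nan")
                    ),
                }
            )
    return ExtrapolationReport(factor=factor, per_code=per_code, totals=pd.DataFrame(rows))


def share_percentages(report: ExtrapolationReport) -> pd.DataFrame:
    """Case and cost shares of each scope against all and included codes.

    Computed on sample-level unrounded totals (levels share the factor, so
    national shares are identical by construction).
    """
    rows = []
    for denom_scope in ("all", "included"):
        denom_cases = report.value(denom_scope, "sample", "cases")
        denom_cost = report.value(denom_scope, "sample", "cost")
        if denom_cases == 0 or denom_cost == 0:
            raise ValueError(f"zero denominator in scope {denom_scope!r}")
        for scope in SCOPES:
            rows.append(
                {
                    "scope": scope,
                    "denominator": denom_scope,
                    "case_share_pct": report.value(scope, "sample", "cases") / denom_cases * 100,
                    "cost_share_pct": report.value(scope, "sample", "cost") / denom_cost * 100,
                }
            )
    return pd.DataFrame(rows)
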