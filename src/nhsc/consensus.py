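"""Round-2 classification rules, workshop outcomes and the final list.

After the second rating round each code takes exactly one route:

* **direct** -- median avoidability >= 75 and central-75% dispersion width
  <= 15: eligible without further discussion;
* **excluded** -- the 87.5th percentile falls below 75, i.e. the relevant
  avoidability level is outside the central 75% of assessments;
* **workshop** -- everything else (75 lies inside [p12.5, p87.5], endpoints
  inclusive): relevant but ambiguous, resolved by a moderated expert
  workshop.

All boundaries are inclusive. Workshop deliberation is human input, not
computed here; its outcomes arrive as :class:`WorkshopOutcome` records.
The final nursing home-sensitive flag requires a consented or direct
avoidability of at least 70.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .delphi import DelphiSummary

ROUTES = ("direct", "workshop", "excluded")


@dataclass
class ClassificationOutcome:
    icd3: str
    route: str
    rationale: str
    r2_median: float
    p12_5: float
    p87_5: float


@dataclass
class WorkshopOutcome:
    icd3: str
    consented: bool
    consented_avoidability: float | None = None

    def __post_init__(self) -> None:
        if self.consented:
            v = self.consented_avoidability
            if v is None or not (0 <= v <= 100) or v % 5 != 0:
                raise ValueError(
                    f"{self.icd3}: consented avoidability must be on the "
                    f"5-point grid in [0, 100], got {v!r}"
                )
        elif self.consented_avoidability is not None:
            raise ValueError(f"{self.icd3}: avoidability given without consent")


@dataclass
class ConsensusRecord:
    icd3: str
    route: str
    final_avoidability: float | None
    source: str | None  # "direct" | "workshop"; None for excluded/non-consented
    nhs_flag: bool
    category_id: int | None = None


def classify_round2(
    summary: DelphiSummary, high: float = 75.0, max_width: float = 15.0
) -> ClassificationOutcome:
    """Route one round-2 summary to direct / workshop / excluded."""
    if summary.round != 2:
        raise ValueError(f"{summary.icd3}: classification needs a round-2 summary")
    if summary.median >= high and summary.width75 <= max_width:
        route, why = "direct", (
            f"median {summary.median:g} >= {high:g} and width "
            f"{summary.width75:g} <= {max_width:g}"
        )
    elif summary.p87_5 < high:
        route, why = "excluded", (
            f"p87.5 = {summary.p87_5:g} < {high:g}: threshold outside the "
            "central 75% of assessments"
        )
    else:
        route, why = "workshop", (
            f"{high:g} within [{summary.p12_5:g}, {summary.p87_5:g}] but "
            "direct criteria not met"
        )
    return ClassificationOutcome(
        icd3=summary.icd3,
        route=route,
        rationale=why,
        r2_median=summary.median,
        p12_5=summary.p12_5,
        p87_5=summary.p87_5,
    )


def apply_workshop(
    classifications: list[ClassificationOutcome],
    outcomes: list[WorkshopOutcome],
    allow_direct_override: bool = False,
) -> list[ConsensusRecord]:
    """Attach final avoidability values to the routed codes.

    Direct codes keep their round-2 median. Workshop codes take the
    consented value, or are retained unflagged when consent was not
    reached. Excluded codes are retained unflagged for auditability.
    Every workshop-routed code must have an outcome; direct codes must not
    appear among the outcomes unless ``allow_direct_override`` is set.
    """
    by_code = {o.icd3: o for o in outcomes}
    if len(by_code) != len(outcomes):
        raise ValueError("duplicate workshop outcome records")
    records = []
    for c in classifications:
        if c.route == "direct":
            if c.icd3 in by_code and not allow_direct_override:
                raise ValueError(
                    f"{c.icd3}: workshop outcome supplied for a direct-route code"
                )
            out = by_code.get(c.icd3)
            value = (
                out.consented_avoidability
                if out is not None and out.consented
                else c.r2_median
            )
            records.append(
                ConsensusRecord(c.icd3, "direct", float(value), "direct", nhs_flag=False)
            )
        elif c.route == "workshop":
            if c.icd3 not in by_code:
                raise ValueError(f"{c.icd3}: workshop-routed code has no outcome")
            out = by_code[c.icd3]
            if out.consented:
                records.append(
                    ConsensusRecord(
                        c.icd3, "workshop", float(out.consented_avoidability),
                        "workshop", nhs_flag=False,
                    )
                )
            else:
                records.append(
                    ConsensusRecord(c.icd3, "workshop", None, None, nhs_flag=False)
                )
        else:
            records.append(
                ConsensusRecord(c.icd3, "excluded", None, None, nhs_flag=False)
            )
    return records


def finalize_nhs_list(
    records: list[ConsensusRecord],
    category_map: dict[str, int],
    min_avoidability: float = 70.0,
) -> pd.DataFrame:
    """Set the nursing home-sensitive flag and group by disease category.

    A record is flagged iff it came through the direct route or a consented
    workshop outcome and its final avoidability is at least
    ``min_avoidability`` (inclusive). Every flagged code must appear in
    ``category_map``. Returns a DataFrame sorted by category then code,
    with unflagged records retained (category NA).
    """
    rows = []
    for r in records:
        flagged = (
            r.source in ("direct", "workshop")
            and r.final_avoidability is not None
            and r.final_avoidability >= min_avoidability
        )
        if flagged and r.icd3 not in category_map:
            raise ValueError(f"{r.icd3}: flagged code missing from category map")
        r.nhs_flag = flagged
        r.category_id = category_map.get(r.icd3) if flagged else None
        rows.append(
            {
                "icd3": r.icd3,
                "route": r.route,
                "final_avoidability": r.final_avoidability,
                "source": r.source,
                "nhs_flag": r.nhs_flag,
                "category_id": r.category_id,
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["nhs_flag", "category_id", "icd3"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)


def category_counts(final: pd.DataFrame) -> pd.Series:
    """Number of flagged codes per disease category."""
    flagged = final[final["nhs_flag"]].copy()
    flagged["category_id"] = flagged["category_id"].astype(int)
    return flagged.groupby("category_id")["icd3"].count().astype(int)
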