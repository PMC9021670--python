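"""End-to-end orchestration and fixture validation.

``run_pipeline`` executes aggregate -> classify -> workshop -> finalize ->
extrapolate (-> ACS comparison when a catalogue is supplied) on the
shipped study fixtures or on user-provided inputs, logging one line per
stage with record counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures
from .acs import AcsCatalogue, overlap_summary, preventability_differences
from .claims import AggregatedDiagnosisTable
from .consensus import (
    ConsensusRecord,
    apply_workshop,
    category_counts,
    classify_round2,
    finalize_nhs_list,
)
from .extrapolation import (
    ExtrapolationInputs,
    ExtrapolationReport,
    extrapolate,
    share_percentages,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds; defaults are the study's values."""

    frequency_threshold: float = 0.001
    frequency_scope: str = "per_insurer"
    high_avoidability_pct: float = 75.0
    max_dispersion_width_pct: float = 15.0
    min_final_avoidability_pct: float = 70.0
    merge_max_median_diff_pct: float = 5.0
    merge_max_iqr_limit_diff_pct: float = 10.0
    zero_consensus_cutoff: float = 0.75
    percentile_method: str = "weibull"
    national_population: int = 818_289
    sample_population: int = 242_236

    def __post_init__(self) -> None:
        if not 0 <= self.frequency_threshold <= 1:
            raise ValueError("frequency_threshold must lie in [0, 1]")
        for name in (
            "high_avoidability_pct",
            "max_dispersion_width_pct",
            "min_final_avoidability_pct",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")
        if not 0 <= self.zero_consensus_cutoff <= 1:
            raise ValueError("zero_consensus_cutoff must lie in [0, 1]")
        if self.national_population <= 0 or self.sample_population <= 0:
            raise ValueError("populations must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    classifications: list
    consensus: pd.DataFrame
    nhs_codes: list[str]
    category_counts: pd.Series
    extrapolation: ExtrapolationReport
    shares: pd.DataFrame
    acs_overlap: dict | None = None
    acs_differences: pd.DataFrame | None = None


def run_pipeline(
    config: PipelineConfig | None = None,
    summaries=None,
    workshop_outcomes=None,
    diagnosis_table: AggregatedDiagnosisTable | None = None,
    category_map: dict[str, int] | None = None,
    catalogue: AcsCatalogue | None = None,
) -> PipelineResult:
    """Run classification through extrapolation; defaults to the fixtures."""
    config = config or PipelineConfig()
    if summaries is None:
        summaries = fixtures.load_round2_summaries()
    if workshop_outcomes is None:
        workshop_outcomes = fixtures.load_workshop_outcomes()
    if diagnosis_table is None:
        diagnosis_table = fixtures.load_diagnosis_table()
    if category_map is None:
        category_map, _ = fixtures.load_category_map()
    log.info("classify: %d round-2 summaries", len(summaries))
    classifications = [
        classify_round2(
            s, high=config.high_avoidability_pct, max_width=config.max_dispersion_width_pct
        )
        for s in summaries
    ]
    routes = pd.Series([c.route for c in classifications]).value_counts()
    log.info("classify: routes %s", routes.to_dict())
    records = apply_workshop(classifications, workshop_outcomes)
    log.info("workshop: %d outcomes applied", len(workshop_outcomes))
    final = finalize_nhs_list(
        records, category_map, min_avoidability=config.min_final_avoidability_pct
    )
    nhs_codes = sorted(final.loc[final["nhs_flag"], "icd3"])
    log.info("finalize: %d nursing home-sensitive codes", len(nhs_codes))
    avoidability = {
        r.icd3: float(r.final_avoidability)
        for r in final.itertuples()
        if r.nhs_flag
    }
    report = extrapolate(
        ExtrapolationInputs(
            national_population=config.national_population,
            sample_population=config.sample_population,
            table=diagnosis_table,
            avoidability=avoidability,
        )
    )
    shares = share_percentages(report)
    log.info(
        "extrapolate: factor %.5f, national avoidable cost %.0f euros",
        report.factor,
        report.value("nhs", "national", "avoidable_cost"),
    )
    acs_overlap = acs_diffs = None
    if catalogue is not None:
        acs_overlap = overlap_summary(nhs_codes, catalogue, subset="all")
        acs_diffs = preventability_differences(avoidability, catalogue, subset="core")
        log.info(
            "compare: %d/%d codes overlap the catalogue",
            acs_overlap["counts"]["full"] + acs_overlap["counts"]["partial"],
            len(nhs_codes),
        )
    return PipelineResult(
        classifications=classifications,
        consensus=final,
        nhs_codes=nhs_codes,
        category_counts=category_counts(final),
        extrapolation=report,
        shares=shares,
        acs_overlap=acs_overlap,
        acs_differences=acs_diffs,
    )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_fixtures() -> ValidationReport:
    """Structural and consistency checks over the shipped fixtures.

    The known internal inconsistency of the printed remainder mean cost is
    reported as a warning, not an error.
    """
    rep = ValidationReport()
    meta = fixtures.load_diagnosis_meta()
    table = fixtures.load_diagnosis_table()
    r2 = fixtures.load_round2_table()
    cat_map, labels = fixtures.load_category_map()
    outcomes = fixtures.load_workshop_outcomes()

    if len(table.rows) != 117:
        rep.errors.append(f"diagnosis table has {len(table.rows)} rows, expected 117")
    if table.included_cases + table.remainder_cases != table.total_cases:
        rep.errors.append("included + remainder cases != total cases")
    if not table.rows["cases"].is_monotonic_decreasing:
        rep.errors.append("diagnosis table not sorted by cases descending")
    rem_product = table.remainder_cases * table.remainder_mean_cost
    if (
        table.remainder_total_cost is not None
        and abs(rem_product - table.remainder_total_cost) / table.remainder_total_cost > 0.005
    ):
        rep.warnings.append(
            "printed remainder mean cost is inconsistent with the printed cost "
            f"totals (cases x mean = {rem_product:.0f} vs {table.remainder_total_cost:.0f}); "
            "totals use the separately stored remainder total cost"
        )
    if len(r2) != 117:
        rep.errors.append(f"round-2 table has {len(r2)} rows, expected 117")
    bad_domain = r2[
        (r2["r2_median"] < 0) | (r2["r2_median"] > 100)
        | (r2["p12_5"] < 0) | (r2["p87_5"] > 100)
        | (r2["p12_5"] > r2["r2_median"]) | (r2["r2_median"] > r2["p87_5"])
    ]
    if len(bad_domain):
        rep.errors.append(f"round-2 domain violations: {list(bad_domain['icd3'])}")
    if set(r2["icd3"]) != set(table.rows["icd3"]):
        rep.errors.append("round-2 codes do not match the diagnosis table codes")
    if len(cat_map) != 58:
        rep.errors.append(f"category map covers {len(cat_map)} codes, expected 58")
    if len(labels) != 15:
        rep.errors.append(f"{len(labels)} disease categories, expected 15")
    n_workshop_flagged = int(r2["workshop"].sum())
    if n_workshop_flagged != len(outcomes):
        rep.errors.append(
            f"{n_workshop_flagged} workshop-flagged codes vs {len(outcomes)} outcomes"
        )
    n_consented = sum(o.consented for o in outcomes)
    if n_consented != 23:
        rep.errors.append(f"{n_consented} consented workshop codes, expected 23")
    demo = fixtures.load_demographics()
    bands = demo[demo["age_band"] != "all"]
    if meta["population"] != bands["residents"].sum():
        rep.errors.append("demographic strata do not sum to the study population")
    for r in demo[demo["age_band"] == "all"].itertuples():
        band_sum = int(bands.loc[bands["gender"] == r.gender, "residents"].sum())
        if band_sum != int(r.residents):
            rep.warnings.append(
                f"printed {r.gender} resident total ({int(r.residents)}) differs "
                f"from the band sum ({band_sum}) by {band_sum - int(r.residents)}"
            )
    gender_hosp = int(demo[demo["age_band"] == "all"]["hospitalizations"].sum())
    if gender_hosp != meta["total_cases"]:
        rep.warnings.append(
            f"printed per-gender hospitalizations sum to {gender_hosp}, not the "
            f"printed total {meta['total_cases']}; totals use the printed total"
        )
    for w in rep.warnings:
        log.warning("fixture validation: %s", w)
    for e in rep.errors:
        log.error("fixture validation: %s", e)
    return rep
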