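"""Per-round Delphi rating statistics and round-transition rules.

Experts rate, per 3-character ICD-10 code, the share of hospitalizations
avoidable under optimal care conditions on a 0-100 scale in 5-point steps.
A rating may be missing when the expert could not judge the code, in which
case a comment is mandatory; missing ratings are excluded from every
statistic. The classification rules downstream work on the median, the
quartiles and the central-75% dispersion interval (12.5th to 87.5th
percentile), so the summary carries all of them.

Two percentile interpolation conventions are supported because printed
fractional percentiles do not pin down a single one:

* ``"weibull"`` -- weighted average at ``(n+1)p`` (R type 6, the default of
  common social-science statistics packages); package default.
* ``"linear"`` -- weighted average at ``(n-1)p + 1`` (R type 7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PERCENTILE_METHODS = ("weibull", "linear")

SPECIALTIES = ("primary_care", "hospital_specialist", "nursing", "research")
AGE_BANDS = ("<40", "40-49", "50-59", ">=60")

RATING_COLUMNS = [
    "expert_id", "icd3", "rating", "comment_given", "specialty", "age_band", "gender",
]


@dataclass
class RatingSet:
    """Raw per-expert ratings for one Delphi round.

    ``records`` columns follow :data:`RATING_COLUMNS`; ``rating`` is float
    with NaN for missing. One record per expert x code.
    """

    round: int
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.round not in (1, 2):
            raise ValueError("round must be 1 or 2")
        rec = pd.DataFrame(self.records).reset_index(drop=True)
        missing_cols = [c for c in RATING_COLUMNS if c not in rec.columns]
        if missing_cols:
            raise ValueError(f"rating records missing columns {missing_cols}")
        vals = rec["rating"].dropna()
        if ((vals < 0) | (vals > 100) | (vals % 5 != 0)).any():
            raise ValueError("ratings must lie on the 5-point grid in [0, 100]")
        no_comment = rec["rating"].isna() & ~rec["comment_given"].astype(bool)
        if no_comment.any():
            bad = rec.loc[no_comment, ["expert_id", "icd3"]].iloc[0]
            raise ValueError(
                "missing rating without mandatory comment "
                f"(expert {bad['expert_id']}, code {bad['icd3']})"
            )
        if rec.duplicated(["expert_id", "icd3"]).any():
            raise ValueError("duplicate expert x code record")
        self.records = rec

    def for_code(self, icd3: str) -> pd.DataFrame:
        return self.records[self.records["icd3"] == icd3]

    @property
    def codes(self) -> list[str]:
        return sorted(self.records["icd3"].unique())


@dataclass
class DelphiSummary:
    """Distribution statistics for one code in one round."""

    icd3: str
    round: int
    n_valid: int
    median: float
    p12_5: float
    p87_5: float
    width75: float
    sd: float
    q1: float | None = None  # quartiles absent when built from printed summaries
    q3: float | None = None
    kw_p_specialty: float | None = None
    kw_p_gender: float | None = None
    kw_p_ageband: float | None = None

    def __post_init__(self) -> None:
        chain = [self.p12_5, self.q1, self.median, self.q3, self.p87_5]
        chain = [v for v in chain if v is not None]
        if any(a > b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"{self.icd3}: percentile ordering violated ({chain})")

    @property
    def iqr_width(self) -> float:
        if self.q1 is None or self.q3 is None:
            return float("nan")
        return self.q3 - self.q1


@dataclass
class StabilityReport:
    """Between-round agreement: median shifts and dispersion change."""

    per_code: pd.DataFrame  # icd3, median_r1, median_r2, abs_diff
    mean_iqr_width_r1: float
    mean_iqr_width_r2: float
    n_within_5: int
    n_within_10: int


def percentile(values: np.ndarray, p: float, method: str = "weibull") -> float:
    """p-th percentile (p in [0, 100]) under the configured interpolation."""
    if method not in PERCENTILE_METHODS:
        raise ValueError(f"unknown percentile method {method!r}")
    return float(np.percentile(np.asarray(values, dtype=float), p, method=method))


def _kw_groups(frame: pd.DataFrame, factor: str) -> list[np.ndarray]:
    groups = []
    for _, g in frame.groupby(factor):
        vals = g["rating"].dropna().to_numpy()
        if len(vals) >= 2:
            groups.append(vals)
    return groups


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float] | None:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Returns ``None`` when fewer than two groups have >= 2 observations, or
    when every observation is identical (H undefined under tie correction).
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) >= 2]
    if len(groups) < 2:
        return None
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # zero variance in ranks: no evidence of group differences
        return (0.0, 1.0)
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def summarize_ratings(
    ratings: RatingSet,
    icd3: str | None = None,
    method: str = "weibull",
    subgroup_tests: bool = True,
) -> DelphiSummary | list[DelphiSummary]:
    """Summarize one code (``icd3`` given) or every code in the round.

    Median is the standard sample median (mean of the central pair for even
    n); the other percentiles follow ``method``; ``width75`` is the central
    75% dispersion interval width p87.5 - p12.5. SD is the sample standard
    deviation (ddof=1, 0 for a single rating). Subgroup Kruskal-Wallis
    p-values are attached for specialty, gender and age band when enough
    groups have data; no multiplicity correction is applied.
    """
    if icd3 is None:
        return [
            summarize_ratings(ratings, code, method=method, subgroup_tests=subgroup_tests)
            for code in ratings.codes
        ]
    frame = ratings.for_code(icd3)
    values = frame["rating"].dropna().to_numpy(dtype=float)
    if len(values) == 0:
        raise ValueError(f"{icd3}: no assessable ratings")
    p12_5, q1, q3, p87_5 = (percentile(values, p, method) for p in (12.5, 25, 75, 87.5))
    kw: dict[str, float | None] = {}
    for name, factor in (
        ("kw_p_specialty", "specialty"),
        ("kw_p_gender", "gender"),
        ("kw_p_ageband", "age_band"),
    ):
        res = kruskal_wallis(_kw_groups(frame, factor)) if subgroup_tests else None
        kw[name] = res[1] if res is not None else None
    return DelphiSummary(
        icd3=icd3,
        round=ratings.round,
        n_valid=len(values),
        median=float(np.median(values)),
        p12_5=p12_5,
        p87_5=p87_5,
        q1=q1,
        q3=q3,
        width75=p87_5 - p12_5,
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        **kw,
    )


def zero_consensus_excluded(ratings: RatingSet, icd3: str, cutoff: float = 0.75) -> bool:
    """Whether a code is dropped after round 1 for consensus unavoidability.

    True iff at least ``cutoff`` of the valid ratings are exactly zero.
    """
    values = ratings.for_code(icd3)["rating"].dropna().to_numpy()
    if len(values) == 0:
        raise ValueError(f"{icd3}: no assessable ratings")
    return (values == 0).sum() / len(values) >= cutoff


@dataclass
class MergeDecision:
    pair: tuple[str, str]
    merged: bool
    reason: str


def merge_similar_codes(
    summaries: list[DelphiSummary],
    candidate_pairs: list[tuple[str, str]],
    max_median_diff: float = 5.0,
    max_iqr_limit_diff: float = 10.0,
) -> list[MergeDecision]:
    """Evaluate the "nearly identical preventability" merge rule per pair.

    Clinical similarity of the pair is expert input; this only checks the
    statistical conditions: medians within ``max_median_diff`` (inclusive)
    and both interquartile limits strictly less than ``max_iqr_limit_diff``
    apart.
    """
    by_code = {s.icd3: s for s in summaries}
    decisions = []
    for a, b in candidate_pairs:
        if a not in by_code or b not in by_code:
            missing = [c for c in (a, b) if c not in by_code]
            raise ValueError(f"merge pair references unknown code(s): {missing}")
        sa, sb = by_code[a], by_code[b]
        med_ok = abs(sa.median - sb.median) <= max_median_diff
        q1_ok = abs(sa.q1 - sb.q1) < max_iqr_limit_diff
        q3_ok = abs(sa.q3 - sb.q3) < max_iqr_limit_diff
        merged = med_ok and q1_ok and q3_ok
        reason = "; ".join(
            f"{label} {'ok' if ok else 'violated'}"
            for label, ok in (("median", med_ok), ("q1", q1_ok), ("q3", q3_ok))
        )
        decisions.append(MergeDecision(pair=(a, b), merged=merged, reason=reason))
    return decisions


def pool_merged_ratings(ratings: RatingSet, codes: tuple[str, str], new_code: str) -> RatingSet:
    """Pool the raw ratings of a merged pair under a combined code label."""
    rec = ratings.records.copy()
    mask = rec["icd3"].isin(codes)
    if not mask.any():
        raise ValueError(f"no ratings for merge pair {codes}")
    rec.loc[mask, "icd3"] = new_code
    # one expert may have rated both members; keep the first non-missing
    rec = rec.sort_values("rating", na_position="last", kind="stable")
    rec = rec.drop_duplicates(["expert_id", "icd3"], keep="first")
    return RatingSet(round=ratings.round, records=rec.reset_index(drop=True))


def round_stability(
    r1: list[DelphiSummary], r2: list[DelphiSummary]
) -> StabilityReport:
    """Compare round summaries code-by-code (same code set required)."""
    m1 = {s.icd3: s for s in r1}
    m2 = {s.icd3: s for s in r2}
    if set(m1) != set(m2):
        diff = sorted(set(m1) ^ set(m2))
        raise ValueError(f"code sets differ between rounds: {diff}")
    rows = [
        {
            "icd3": code,
            "median_r1": m1[code].median,
            "median_r2": m2[code].median,
            "abs_diff": abs(m1[code].median - m2[code].median),
        }
        for code in sorted(m1)
    ]
    per_code = pd.DataFrame(rows)
    return StabilityReport(
        per_code=per_code,
        mean_iqr_width_r1=float(np.mean([s.iqr_width for s in r1])),
        mean_iqr_width_r2=float(np.mean([s.iqr_width for s in r2])),
        n_within_5=int((per_code["abs_diff"] <= 5).sum()),
        n_within_10=int((per_code["abs_diff"] <= 10).sum()),
    )
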