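"""Synthetic study data with known ground truth.

Generates (i) two rounds of raw expert-panel ratings whose convergence
behaviour mimics a feedback-driven Delphi process, (ii) per-insurer
aggregated claims tables, and (iii) workshop outcomes — so the whole
pipeline is exercisable end to end without any external data.

Ratings: round 1 draws expert ratings from a normal around a per-code
true consensus value (plus a specialty-group offset), discretized to the
5-point grid and clipped to [0, 100]. Round 2 shrinks fresh draws toward
the round-1 code median with weight ``shrinkage``, emulating the observed
between-round dispersion collapse at unchanged medians.

Reproducibility: one root seed derives per-component, per-code
substreams, so enlarging the design does not perturb existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims import AGE_BANDS, InsurerClaimsTable
from .consensus import ClassificationOutcome, WorkshopOutcome
from .delphi import AGE_BANDS as EXPERT_AGE_BANDS
from .delphi import SPECIALTIES, RatingSet

#: Default panel sizes per specialty group (round-1 composition).
DEFAULT_PANEL_SIZES = {
    "primary_care": 31,
    "hospital_specialist": 34,
    "nursing": 31,
    "research": 11,
}


def round_to_grid(x: np.ndarray | float, step: float = 5.0) -> np.ndarray | float:
    """Round half-up to the nearest multiple of ``step``."""
    return np.floor(np.asarray(x, dtype=float) / step + 0.5) * step


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def synthetic_codes(n: int) -> list[str]:
    """Deterministic syntactically valid 3-character codes (X00, X01, ...)."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return [f"{letters[i // 100 % 26]}{i % 100:02d}" for i in range(n)]


@dataclass
class PanelSimConfig:
    """Design of a synthetic two-round rating panel.

    ``true_mu`` holds the per-code true consensus avoidability (percent);
    ``group_offsets`` shift each specialty's mean; ``shrinkage`` is the
    round-2 weight on the round-1 code median.
    """

    true_mu: list[float]
    sigma: float = 10.0
    panel_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PANEL_SIZES))
    group_offsets: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.01
    shrinkage: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_mu:
            raise ValueError("true_mu must name at least one code")
        if any(not 0 <= m <= 100 for m in self.true_mu):
            raise ValueError("true consensus values must lie in [0, 100]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not 0 <= self.shrinkage <= 1:
            raise ValueError("shrinkage must lie in [0, 1]")
        unknown = set(self.panel_sizes) - set(SPECIALTIES)
        if unknown or any(v < 0 for v in self.panel_sizes.values()):
            raise ValueError(f"invalid panel sizes: {self.panel_sizes}")

    @property
    def n_codes(self) -> int:
        return len(self.true_mu)


def _experts(config: PanelSimConfig) -> pd.DataFrame:
    rng = _substream(config.seed, 0)
    rows = []
    for spec in SPECIALTIES:
        for i in range(config.panel_sizes.get(spec, 0)):
            rows.append(
                {
                    "expert_id": f"{spec}_{i:03d}",
                    "specialty": spec,
                    "age_band": EXPERT_AGE_BANDS[rng.integers(len(EXPERT_AGE_BANDS))],
                    "gender": ["female", "male"][rng.integers(2)],
                }
            )
    return pd.DataFrame(rows)


def generate_panel(
    config: PanelSimConfig,
) -> tuple[RatingSet, RatingSet, pd.DataFrame]:
    """Two :class:`RatingSet` rounds plus the ground-truth table."""
    codes = synthetic_codes(config.n_codes)
    experts = _experts(config)
    truth = pd.DataFrame({"icd3": codes, "true_mu": config.true_mu})
    rounds: list[pd.DataFrame] = []
    r1_medians: dict[str, float] = {}
    for rnd in (1, 2):
        recs = []
        for ci, (code, mu) in enumerate(zip(codes, config.true_mu)):
            rng = _substream(config.seed, rnd, ci)
            offsets = experts["specialty"].map(
                lambda s: config.group_offsets.get(s, 0.0)
            ).to_numpy()
            draws = rng.normal(mu + offsets, config.sigma)
            if rnd == 2:
                draws = config.shrinkage * r1_medians[code] + (1 - config.shrinkage) * draws
            ratings = np.clip(round_to_grid(draws), 0.0, 100.0)
            miss = rng.random(len(experts)) < config.missing_rate
            ratings = np.where(miss, np.nan, ratings)
            for e, val, m in zip(experts.itertuples(), ratings, miss):
                recs.append(
                    {
                        "expert_id": e.expert_id,
                        "icd3": code,
                        "rating": val,
                        "comment_given": bool(m),
                        "specialty": e.specialty,
                        "age_band": e.age_band,
                        "gender": e.gender,
                    }
                )
            if rnd == 1:
                valid = ratings[~np.isnan(ratings)]
                r1_medians[code] = float(np.median(valid)) if len(valid) else mu
        rounds.append(pd.DataFrame(recs))
    return (
        RatingSet(round=1, records=rounds[0]),
        RatingSet(round=2, records=rounds[1]),
        truth,
    )


@dataclass
class ClaimsSimConfig:
    """Design of synthetic per-insurer aggregated claims tables.

    Case counts are multinomial over codes with power-law weights
    (rank^-``exponent``); mean costs are log-normal per code and insurer.
    ``incidence`` is annual hospitalizations per resident;
    ``hospitalized_share`` the share of residents with >= 1 stay.
    """

    n_insurers: int = 3
    populations: list[int] | None = None
    n_codes: int = 50
    exponent: float = 1.0
    cost_log_mean: float = 8.2  # exp(8.2) ~ 3,641 euros
    cost_log_sd: float = 0.4
    incidence: float = 0.79
    hospitalized_share: float = 0.44
    female_share: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.populations is None:
            self.populations = [20_000] * self.n_insurers
        if len(self.populations) != self.n_insurers:
            raise ValueError("populations must match n_insurers")
        if any(p <= 0 for p in self.populations):
            raise ValueError("populations must be positive")
        if self.n_codes < 1 or self.exponent < 0:
            raise ValueError("invalid code distribution parameters")
        for name in ("incidence", "hospitalized_share", "female_share"):
            v = getattr(self, name)
            if v < 0 or (name != "incidence" and v > 1):
                raise ValueError(f"invalid {name}: {v}")


# age-band allocation weights skewed toward high ages, mirroring a
# nursing-home resident population
_AGE_WEIGHTS = np.array(
    [0.2, 0.3, 0.5, 0.8, 0.9, 0.9, 1.0, 1.5, 2.4, 3.0, 3.2, 3.9, 4.9, 10.6, 16.4, 21.0, 28.5]
)


def generate_claims(config: ClaimsSimConfig) -> list[InsurerClaimsTable]:
    """One :class:`InsurerClaimsTable` per synthetic insurer."""
    codes = synthetic_codes(config.n_codes)
    weights = np.arange(1, config.n_codes + 1, dtype=float) ** -config.exponent
    weights /= weights.sum()
    tables = []
    for i, pop in enumerate(config.populations):
        rng = _substream(config.seed, 10, i)
        n_cases = int(round(pop * config.incidence))
        cases = rng.multinomial(n_cases, weights)
        mean_cost = np.exp(rng.normal(config.cost_log_mean, config.cost_log_sd, config.n_codes))
        rows = pd.DataFrame({"icd3": codes, "cases": cases, "mean_cost": mean_cost})
        n_female = int(round(pop * config.female_share))
        demo_rows = []
        for gender, g_pop in (("female", n_female), ("male", pop - n_female)):
            alloc = rng.multinomial(g_pop, _AGE_WEIGHTS / _AGE_WEIGHTS.sum())
            for band, n in zip(AGE_BANDS, alloc):
                demo_rows.append({"age_band": band, "gender": gender, "residents": int(n)})
        demo = pd.DataFrame(demo_rows)
        hosp_persons = {}
        hosps = {}
        case_split = rng.binomial(n_cases, n_female / pop)
        for gender, g_cases in (("female", case_split), ("male", n_cases - case_split)):
            g_pop = int(demo.loc[demo["gender"] == gender, "residents"].sum())
            hosp_persons[gender] = min(
                int(round(g_pop * config.hospitalized_share)), g_cases, g_pop
            )
            hosps[gender] = int(g_cases)
        tables.append(
            InsurerClaimsTable(
                insurer_id=f"insurer_{i}",
                population=pop,
                rows=rows,
                demographics=demo,
                hospitalized_persons=hosp_persons,
                hospitalizations=hosps,
            )
        )
    return tables


def generate_workshop(
    classifications: list[ClassificationOutcome],
    truth: pd.DataFrame,
    consent_probability: float = 1.0,
    seed: int = 0,
) -> list[WorkshopOutcome]:
    """Workshop outcomes for the workshop-routed codes.

    Each is consented with ``consent_probability``; the consented value is
    the code's true consensus rounded to the 5-point grid.
    """
    if not 0 <= consent_probability <= 1:
        raise ValueError("consent_probability must lie in [0, 1]")
    mu = dict(zip(truth["icd3"], truth["true_mu"]))
    outcomes = []
    for ci, c in enumerate(sorted(
        (c for c in classifications if c.route == "workshop"), key=lambda c: c.icd3
    )):
        rng = _substream(seed, 20, ci)
        consented = bool(rng.random() < consent_probability)
        value = float(np.clip(round_to_grid(mu[c.icd3]), 0, 100)) if consented else None
        outcomes.append(
            WorkshopOutcome(icd3=c.icd3, consented=consented, consented_avoidability=value)
        )
    return outcomes
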