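"""Comparison against an ambulatory care-sensitive (ACS) catalogue.

An ACS catalogue groups 3- and 4-character ICD-10 codes into disease
groups, each optionally carrying a group-level preventability estimate;
"core" groups are those with preventability above 85%. A nursing
home-sensitive 3-character code overlaps *fully* when it is itself a
member, *partly* when only 4-character children of it are members, and
not at all otherwise.

The published German ACS catalogue is not redistributed here; this module
defines the file format and operates on any catalogue supplied in it
(tests use synthetic catalogues).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

ICD_MEMBER_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")
OVERLAP_CLASSES = ("full", "partial", "none")
CORE_PREVENTABILITY_MIN = 85.0


@dataclass
class AcsGroup:
    group_id: str
    label: str
    members: list[str]
    group_preventability: float | None = None
    core_flag: bool = False

    def __post_init__(self) -> None:
        for m in self.members:
            if not ICD_MEMBER_RE.match(m):
                raise ValueError(f"group {self.group_id}: malformed member code {m!r}")
        if self.core_flag and (
            self.group_preventability is None
            or self.group_preventability < CORE_PREVENTABILITY_MIN
        ):
            raise ValueError(
                f"group {self.group_id}: core groups need preventability >= "
                f"{CORE_PREVENTABILITY_MIN:g}"
            )


@dataclass
class AcsCatalogue:
    groups: list[AcsGroup] = field(default_factory=list)

    def subset(self, which: str = "all") -> "AcsCatalogue":
        if which == "all":
            return self
        if which == "core":
            return AcsCatalogue([g for g in self.groups if g.core_flag])
        raise ValueError(f"unknown subset {which!r}")

    def members(self) -> list[str]:
        return [m for g in self.groups for m in g.members]

    def group_for(self, icd3: str) -> AcsGroup | None:
        """First group (catalogue order) containing the code or a child."""
        for g in self.groups:
            if any(m == icd3 or m.split(".")[0] == icd3 for m in g.members):
                return g
        return None


def classify_overlap(code: str, catalogue: AcsCatalogue) -> str:
    """Overlap class of one 3-character code: full / partial / none."""
    if not re.match(r"^[A-Z]\d{2}$", code or ""):
        raise ValueError(f"malformed 3-character ICD-10 code: {code!r}")
    members = catalogue.members()
    if code in members:
        return "full"
    if any("." in m and m.split(".")[0] == code for m in members):
        return "partial"
    return "none"


def overlap_summary(
    codes: list[str], catalogue: AcsCatalogue, subset: str = "all"
) -> dict:
    """Counts and fractions of full / partial / none overlap for a code list.

    Also reports reverse coverage: catalogue members not matched by any
    code in the list (at the 3-character prefix level).
    """
    if not codes:
        raise ValueError("empty code list")
    cat = catalogue.subset(subset)
    if not cat.groups:
        raise ValueError("empty catalogue")
    classes = {c: classify_overlap(c, cat) for c in codes}
    n = len(codes)
    counts = {k: sum(1 for v in classes.values() if v == k) for k in OVERLAP_CLASSES}
    prefixes = set(codes)
    unmatched = [m for m in cat.members() if m.split(".")[0] not in prefixes]
    return {
        "classes": classes,
        "counts": counts,
        "n": n,
        "overlap_fraction": (counts["full"] + counts["partial"]) / n,
        "unmatched_members": unmatched,
        "reverse_unmatched_fraction": len(unmatched) / len(cat.members()),
    }


def preventability_differences(
    avoidability: dict[str, float], catalogue: AcsCatalogue, subset: str = "core"
) -> pd.DataFrame:
    """Nursing-home minus ACS-group preventability, per matchable code.

    ``avoidability`` maps flagged codes to their consented percentage.
    Codes whose matched group lacks an estimate (or that match no group)
    are skipped with a log note. Returns a frame with a ``difference``
    column; min/max are its extrema.
    """
    cat = catalogue.subset(subset)
    rows = []
    for code, nhs_value in sorted(avoidability.items()):
        group = cat.group_for(code)
        if group is None or group.group_preventability is None:
            log.info("%s: no matched ACS group with an estimate; skipped", code)
            continue
        rows.append(
            {
                "icd3": code,
                "nhs_avoidability": nhs_value,
                "acs_group_id": group.group_id,
                "acs_preventability": group.group_preventability,
                "difference": nhs_value - group.group_preventability,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "icd3", "nhs_avoidability", "acs_group_id", "acs_preventability", "difference",
        ],
    )


def read_catalogue_csv(path) -> AcsCatalogue:
    """Read `group_id,label,member_code,group_preventability,core_flag` CSV."""
    frame = pd.read_csv(path, dtype={"group_id": str})
    groups = []
    for gid, g in frame.groupby("group_id", sort=False):
        prev = g["group_preventability"].dropna()
        groups.append(
            AcsGroup(
                group_id=str(gid),
                label=str(g["label"].iloc[0]),
                members=list(g["member_code"]),
                group_preventability=float(prev.iloc[0]) if len(prev) else None,
                core_flag=bool(g["core_flag"].iloc[0]),
            )
        )
    return AcsCatalogue(groups)


def write_catalogue_csv(catalogue: AcsCatalogue, path) -> None:
    rows = [
        {
            "group_id": g.group_id,
            "label": g.label,
            "member_code": m,
            "group_preventability": g.group_preventability,
            "core_flag": g.core_flag,
        }
        for g in catalogue.groups
        for m in g.members
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
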